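"""Hexagonal-cell landscapes partitioned into multi-owner landholdings.

A landscape is a lattice of 1-ha hexagonal cells ("odd-r" horizontal layout:
odd rows are shifted half a cell to the right).  The lattice is randomly
partitioned into contiguous landholdings whose target areas are drawn from a
Gamma distribution (base parameterization: mean 20 ha, variance 100 ha²),
and every landholding receives a single initial understory age drawn
uniformly from {0, ..., 70} years.  Because each cell is exactly 1 ha, areas
and cell counts are interchangeable throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

__all__ = [
    "HexGrid",
    "AreaDistribution",
    "HexLandscape",
    "LandscapePool",
    "build_grid",
    "gamma_params",
    "partition",
    "assign_initial_ages",
    "generate_landscape",
    "generate_pool",
]

# odd-r horizontal layout: offsets depend on row parity
_EVEN_ROW_OFFSETS = ((0, -1), (0, 1), (-1, -1), (-1, 0), (1, -1), (1, 0))
_ODD_ROW_OFFSETS = ((0, -1), (0, 1), (-1, 0), (-1, 1), (1, 0), (1, 1))


@dataclass(frozen=True)
class HexGrid:
    """Rectangular block of 1-ha hexagonal cells with odd-r adjacency.

    Cells are indexed row-major: ``index = row * n_cols + col``.  Adjacency
    is stored in CSR form (``indptr``/``indices``) plus a flat array of
    unordered adjacent cell pairs, each counted once, used by the
    edge-contrast surface metric.
    """

    n_rows: int
    n_cols: int
    indptr: np.ndarray
    indices: np.ndarray
    edge_pairs: np.ndarray  # shape (n_pairs, 2), i < j

    cell_area_ha: float = 1.0

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    def neighbors(self, cell: int) -> np.ndarray:
        return self.indices[self.indptr[cell] : self.indptr[cell + 1]]

    def degree(self, cell: int) -> int:
        return int(self.indptr[cell + 1] - self.indptr[cell])


def build_grid(n_rows: int, n_cols: int) -> HexGrid:
    """Build an odd-r hexagonal lattice of ``n_rows`` x ``n_cols`` cells.

    Interior cells have exactly 6 neighbors; boundary cells 2-5.
    """
    if n_rows < 1 or n_cols < 1:
        raise ValueError(f"grid dimensions must be >= 1, got {n_rows}x{n_cols}")
    neighbor_lists: list[list[int]] = []
    for r in range(n_rows):
        offsets = _ODD_ROW_OFFSETS if r % 2 else _EVEN_ROW_OFFSETS
        for c in range(n_cols):
            nbrs = []
            for dr, dc in offsets:
                rr, cc = r + dr, c + dc
                if 0 <= rr < n_rows and 0 <= cc < n_cols:
                    nbrs.append(rr * n_cols + cc)
            neighbor_lists.append(sorted(nbrs))
    indptr = np.zeros(n_rows * n_cols + 1, dtype=np.int64)
    for i, nbrs in enumerate(neighbor_lists):
        indptr[i + 1] = indptr[i] + len(nbrs)
    indices = np.fromiter(
        (j for nbrs in neighbor_lists for j in nbrs), dtype=np.int64, count=indptr[-1]
    )
    pairs = [
        (i, j) for i, nbrs in enumerate(neighbor_lists) for j in nbrs if i < j
    ]
    edge_pairs = np.asarray(pairs, dtype=np.int64).reshape(-1, 2)
    return HexGrid(n_rows, n_cols, indptr, indices, edge_pairs)


@dataclass(frozen=True)
class AreaDistribution:
    """Gamma distribution of landholding target areas (ha).

    Parameterized by mean and variance; shape/scale follow by moment
    matching (shape = mean²/variance, scale = variance/mean).
    """

    mean: float = 20.0
    variance: float = 100.0

    def __post_init__(self) -> None:
        if self.mean <= 0 or self.variance <= 0:
            raise ValueError(
                f"mean and variance must be positive, got {self.mean}, {self.variance}"
            )

    @property
    def shape(self) -> float:
        return self.mean**2 / self.variance

    @property
    def scale(self) -> float:
        return self.variance / self.mean

    def sample(self, rng: np.random.Generator, size=None) -> np.ndarray | float:
        return rng.gamma(self.shape, self.scale, size=size)


def gamma_params(mean: float, variance: float) -> tuple[float, float]:
    """Moment-matched Gamma (shape, scale) for a given mean and variance."""
    d = AreaDistribution(mean, variance)
    return d.shape, d.scale


@dataclass
class HexLandscape:
    """A hex grid with an ownership map and per-cell understory ages.

    ``owner_of[cell]`` gives the landholding id (0..n_owners-1); every
    landholding is connected under hex adjacency and all its cells share
    one initial age (whole-property management).
    """

    grid: HexGrid
    owner_of: np.ndarray  # int per cell
    age_of: np.ndarray  # int years per cell
    landscape_id: int = 0

    @property
    def n_owners(self) -> int:
        return int(self.owner_of.max()) + 1

    def owner_cell_counts(self) -> np.ndarray:
        return np.bincount(self.owner_of, minlength=self.n_owners)

    def owner_ages(self) -> np.ndarray:
        """Initial age per owner (all cells of an owner agree)."""
        ages = np.zeros(self.n_owners, dtype=np.int64)
        ages[self.owner_of] = self.age_of
        return ages

    def to_dataframe(self) -> pd.DataFrame:
        n = self.grid.n_cells
        cells = np.arange(n)
        return pd.DataFrame(
            {
                "cell_id": cells,
                "row": cells // self.grid.n_cols,
                "col": cells % self.grid.n_cols,
                "owner_id": self.owner_of,
                "age": self.age_of,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, landscape_id: int = 0) -> "HexLandscape":
        df = pd.read_csv(path)
        n_rows = int(df["row"].max()) + 1
        n_cols = int(df["col"].max()) + 1
        grid = build_grid(n_rows, n_cols)
        order = np.argsort(df["cell_id"].to_numpy())
        return cls(
            grid=grid,
            owner_of=df["owner_id"].to_numpy()[order].astype(np.int64),
            age_of=df["age"].to_numpy()[order].astype(np.int64),
            landscape_id=landscape_id,
        )


def partition(
    grid: HexGrid, dist: AreaDistribution, rng: np.random.Generator
) -> np.ndarray:
    """Partition the grid into contiguous landholdings by region growing.

    Repeatedly: draw a seed cell uniformly from the unassigned cells, draw a
    target area from ``dist`` (rounded to the nearest cell, floored at 1),
    and grow the patch by uniform draws from its unassigned frontier until
    the target is reached or the frontier is exhausted.  Always terminates
    with every cell assigned to exactly one owner.
    """
    n = grid.n_cells
    owner = np.full(n, -1, dtype=np.int64)
    n_unassigned = n
    next_owner = 0
    while n_unassigned > 0:
        unassigned = np.flatnonzero(owner < 0)
        seed = int(unassigned[rng.integers(len(unassigned))])
        target = max(1, int(np.rint(dist.sample(rng))))
        owner[seed] = next_owner
        n_unassigned -= 1
        size = 1
        frontier = {int(j) for j in grid.neighbors(seed) if owner[j] < 0}
        while size < target and frontier:
            choices = sorted(frontier)
            pick = choices[rng.integers(len(choices))]
            frontier.discard(pick)
            owner[pick] = next_owner
            n_unassigned -= 1
            size += 1
            for j in grid.neighbors(pick):
                if owner[j] < 0:
                    frontier.add(int(j))
        next_owner += 1
    return owner


def assign_initial_ages(
    landscape: HexLandscape, rng: np.random.Generator, max_age: int = 70
) -> HexLandscape:
    """Assign one uniform-integer initial age in [0, max_age] per landholding."""
    per_owner = rng.integers(0, max_age + 1, size=landscape.n_owners)
    landscape.age_of = per_owner[landscape.owner_of].astype(np.int64)
    return landscape


def generate_landscape(
    grid: HexGrid,
    dist: AreaDistribution,
    rng: np.random.Generator,
    landscape_id: int = 0,
    max_age: int = 70,
) -> HexLandscape:
    """Partition a grid and assign initial ages; one full random landscape."""
    owner = partition(grid, dist, rng)
    ls = HexLandscape(grid=grid, owner_of=owner, age_of=np.zeros_like(owner), landscape_id=landscape_id)
    return assign_initial_ages(ls, rng, max_age=max_age)


@dataclass
class LandscapePool:
    """Pre-generated pool of independent random landscapes.

    Generating landscapes is much more expensive than simulating on them, so
    a pool (2000 landscapes at full scale) is generated once and replicate
    evaluations sample from it.
    """

    landscapes: list[HexLandscape]
    pool_seed: int
    dist: AreaDistribution = field(default_factory=AreaDistribution)

    def __len__(self) -> int:
        return len(self.landscapes)

    def __getitem__(self, i: int) -> HexLandscape:
        return self.landscapes[i]

    def __iter__(self) -> Iterator[HexLandscape]:
        return iter(self.landscapes)

    def manifest(self) -> dict:
        g = self.landscapes[0].grid
        return {
            "pool_seed": self.pool_seed,
            "n_landscapes": len(self),
            "n_rows": g.n_rows,
            "n_cols": g.n_cols,
            "area_mean": self.dist.mean,
            "area_variance": self.dist.variance,
        }

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        with open(directory / "manifest.json", "w") as fh:
            json.dump(self.manifest(), fh, indent=2)
        for ls in self.landscapes:
            ls.to_csv(directory / f"landscape_{ls.landscape_id:05d}.csv")

    @classmethod
    def load(cls, directory: str | Path) -> "LandscapePool":
        directory = Path(directory)
        with open(directory / "manifest.json") as fh:
            man = json.load(fh)
        landscapes = [
            HexLandscape.from_csv(directory / f"landscape_{i:05d}.csv", landscape_id=i)
            for i in range(man["n_landscapes"])
        ]
        return cls(
            landscapes=landscapes,
            pool_seed=man["pool_seed"],
            dist=AreaDistribution(man["area_mean"], man["area_variance"]),
        )


def generate_pool(
    n: int,
    n_rows: int,
    n_cols: int,
    dist: AreaDistribution | None = None,
    base_seed: int = 0,
    max_age: int = 70,
) -> LandscapePool:
    """Generate ``n`` independent random landscapes, reproducible from the seed.

    The grid is built once and shared; per-landscape randomness comes from
    independent children of ``SeedSequence(base_seed)``.
    """
    if n < 1:
        raise ValueError("pool size must be >= 1")
    dist = dist or AreaDistribution()
    grid = build_grid(n_rows, n_cols)
    children = np.random.SeedSequence(base_seed).spawn(n)
    landscapes = [
        generate_landscape(grid, dist, np.random.default_rng(ss), landscape_id=i, max_age=max_age)
        for i, ss in enumerate(children)
    ]
    return LandscapePool(landscapes=landscapes, pool_seed=base_seed, dist=dist)


def connected_components_ok(landscape: HexLandscape) -> bool:
    """Check every landholding is connected under hex adjacency (BFS)."""
    grid = landscape.grid
    owner = landscape.owner_of
    # each owner must induce exactly one flood-fill component
    comp_count = np.zeros(landscape.n_owners, dtype=np.int64)
    seen = np.zeros(grid.n_cells, dtype=bool)
    for start in range(grid.n_cells):
        if seen[start]:
            continue
        o = owner[start]
        comp_count[o] += 1
        stack = [start]
        seen[start] = True
        while stack:
            cell = stack.pop()
            for j in grid.neighbors(cell):
                if not seen[j] and owner[j] == o:
                    seen[j] = True
                    stack.append(int(j))
    return bool(np.all(comp_count == 1))
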