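"""Decision support on Pareto frontiers.

Level-diagram scoring (range-standardized objectives weighted 6 for cost, 3
for each biodiversity objective and 2 for each fire-risk objective, then
Euclidean distance to the ideal point), restriction-scenario filtering,
re-simulation of compromise regimes, Gaussian-kernel interval densities
with an intersection-based distance, and principal coordinate analysis for
comparing solution sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .dynamics import (
    ManagementRegime,
    SimConfig,
    UncertaintyModel,
    allocate_owners,
    simulate,
)
from .hexgrid import AreaDistribution, build_grid, generate_landscape
from .objectives import MAXIMIZED, OBJECTIVE_NAMES, ObjectiveVector

__all__ = [
    "ParetoFrontier",
    "LevelDiagramScore",
    "standardize_and_score",
    "Constraint",
    "Scenario",
    "standard_scenarios",
    "apply_scenario",
    "compromise_rescan",
    "SolutionDensity",
    "solution_density",
    "density_distance",
    "PcoaResult",
    "pcoa",
]

# objective groups for level-diagram weighting: one cost objective (weight 6),
# three fire-risk objectives (2 each), two biodiversity objectives (3 each),
# so each group's weights sum to 6 (a third of the total weight each)
DEFAULT_WEIGHTS = {"cost": 6.0, "biodiversity": 3.0, "fire": 2.0}
_GROUP_OF = {
    "cost": "cost",
    "fuel_load": "fire",
    "edge_contrast": "fire",
    "skewness": "fire",
    "mid_area": "biodiversity",
    "late_area": "biodiversity",
}


@dataclass
class ParetoFrontier:
    """Regimes plus objective vectors, with optional rank/crowding metadata."""

    regimes: list[ManagementRegime]
    objectives: list[ObjectiveVector]
    genes: np.ndarray | None = None
    ranks: np.ndarray | None = None
    crowding: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.regimes)

    def display_matrix(self) -> np.ndarray:
        return np.stack([o.display() for o in self.objectives])

    def canonical_matrix(self) -> np.ndarray:
        return np.stack([o.canonical() for o in self.objectives])

    def subset(self, mask: np.ndarray) -> "ParetoFrontier":
        idx = np.flatnonzero(mask)
        return ParetoFrontier(
            regimes=[self.regimes[i] for i in idx],
            objectives=[self.objectives[i] for i in idx],
            genes=None if self.genes is None else self.genes[idx],
            ranks=None if self.ranks is None else self.ranks[idx],
            crowding=None if self.crowding is None else self.crowding[idx],
        )

    def to_dataframe(self) -> pd.DataFrame:
        k_max = max(r.n_groups for r in self.regimes) if self.regimes else 0
        rows = []
        for i, (regime, obj) in enumerate(zip(self.regimes, self.objectives)):
            row: dict = {"solution_id": i, "n_groups": regime.n_groups}
            for g in range(k_max):
                row[f"interval_{g}"] = (
                    regime.intervals[g] if g < regime.n_groups else np.nan
                )
                row[f"proportion_{g}"] = (
                    regime.proportions[g] if g < regime.n_groups else np.nan
                )
            row.update(dict(zip(OBJECTIVE_NAMES, obj.display())))
            if self.ranks is not None:
                row["rank"] = int(self.ranks[i])
            if self.crowding is not None:
                row["crowding"] = float(self.crowding[i])
            rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ParetoFrontier":
        df = pd.read_csv(path)
        return cls.from_dataframe(df)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ParetoFrontier":
        regimes, objectives = [], []
        k_max = sum(1 for c in df.columns if c.startswith("interval_"))
        for _, row in df.iterrows():
            intervals, props = [], []
            for g in range(k_max):
                m = row.get(f"interval_{g}", np.nan)
                if pd.notna(m):
                    intervals.append(float(m))
                    props.append(float(row[f"proportion_{g}"]))
            total = sum(props)
            props = [p / total for p in props]
            regimes.append(ManagementRegime(tuple(intervals), tuple(props)))
            objectives.append(
                ObjectiveVector(*[float(row[name]) for name in OBJECTIVE_NAMES])
            )
        ranks = df["rank"].to_numpy() if "rank" in df else None
        crowding = df["crowding"].to_numpy() if "crowding" in df else None
        return cls(regimes=regimes, objectives=objectives, ranks=ranks, crowding=crowding)


@dataclass
class LevelDiagramScore:
    """Standardized objectives (0 = best, 1 = worst) and distance to ideal."""

    standardized: np.ndarray  # (n_solutions, 6)
    distance: np.ndarray  # (n_solutions,)
    weights: np.ndarray  # (6,)


def objective_weights(weights: dict[str, float] | None = None) -> np.ndarray:
    w = dict(DEFAULT_WEIGHTS)
    if weights:
        w.update(weights)
    return np.array([w[_GROUP_OF[name]] for name in OBJECTIVE_NAMES])


def standardize_and_score(
    frontier: ParetoFrontier | Sequence[ObjectiveVector],
    weights: dict[str, float] | None = None,
) -> LevelDiagramScore:
    """Range-standardize objectives over the frontier and score each solution.

    Standardization is min-max in canonical minimization form, so 0 is the
    best value attained for every objective.  The score is the Euclidean
    distance sqrt(sum (w_i z_i)^2) to the ideal point (all zeros); the worst
    possible score under the default 6/3/2 weighting is sqrt(66).
    A zero-range objective standardizes to 0 for every solution.
    """
    objs = frontier.objectives if isinstance(frontier, ParetoFrontier) else list(frontier)
    C = np.stack([o.canonical() for o in objs])
    lo = C.min(axis=0)
    span = C.max(axis=0) - lo
    z = np.zeros_like(C)
    nz = span > 0
    z[:, nz] = (C[:, nz] - lo[nz]) / span[nz]
    w = objective_weights(weights)
    dist = np.sqrt(((w * z) ** 2).sum(axis=1))
    return LevelDiagramScore(standardized=z, distance=dist, weights=w)


@dataclass(frozen=True)
class Constraint:
    """One restriction on a display-form objective.

    kinds:
      - ``band``: |value - center| <= halfwidth
      - ``threshold``: value op bound (op in {le, ge})
      - ``quantile``: value op (q-quantile of the input frontier's values)
    """

    objective: str
    kind: str  # band | threshold | quantile
    op: str = "le"  # for threshold/quantile
    value: float = 0.0  # bound, or quantile level q in [0,1]
    halfwidth: float = 0.0  # for band

    def __post_init__(self) -> None:
        if self.objective not in OBJECTIVE_NAMES:
            raise ValueError(f"unknown objective {self.objective!r}")
        if self.kind not in ("band", "threshold", "quantile"):
            raise ValueError(f"unknown constraint kind {self.kind!r}")
        if self.kind != "band" and self.op not in ("le", "ge"):
            raise ValueError("op must be 'le' or 'ge'")


@dataclass(frozen=True)
class Scenario:
    """A named set of objective constraints (a decision-maker's preferences)."""

    name: str
    constraints: tuple[Constraint, ...] = ()


def standard_scenarios() -> dict[str, Scenario]:
    """The four printed restriction scenarios plus the unrestricted one.

    * cost5 / cost10 — funding agency: annual managed area 5% or 10% (±0.375%).
    * fire — forest management agency: each fire objective within the 25%
      best results (fuel load below its 25th percentile, edge contrast and
      skewness above their 75th percentiles).
    * biodiversity — conservation agency: at least 9.9% of the landscape
      maintained in each of the 30-60 y and >60 y classes.
    * compromise — all preferences relaxed: cost <= 20%, fuel load below its
      60th percentile, edge contrast and skewness above their 40th
      percentiles, and at least 9% in each biodiversity class.
    """
    return {
        "none": Scenario("none"),
        "cost5": Scenario(
            "cost5", (Constraint("cost", "band", value=5.0, halfwidth=0.375),)
        ),
        "cost10": Scenario(
            "cost10", (Constraint("cost", "band", value=10.0, halfwidth=0.375),)
        ),
        "fire": Scenario(
            "fire",
            (
                Constraint("fuel_load", "quantile", op="le", value=0.25),
                Constraint("edge_contrast", "quantile", op="ge", value=0.75),
                Constraint("skewness", "quantile", op="ge", value=0.75),
            ),
        ),
        "biodiversity": Scenario(
            "biodiversity",
            (
                Constraint("mid_area", "threshold", op="ge", value=9.9),
                Constraint("late_area", "threshold", op="ge", value=9.9),
            ),
        ),
        "compromise": Scenario(
            "compromise",
            (
                Constraint("cost", "threshold", op="le", value=20.0),
                Constraint("fuel_load", "quantile", op="le", value=0.60),
                Constraint("edge_contrast", "quantile", op="ge", value=0.40),
                Constraint("skewness", "quantile", op="ge", value=0.40),
                Constraint("mid_area", "threshold", op="ge", value=9.0),
                Constraint("late_area", "threshold", op="ge", value=9.0),
            ),
        ),
    }


def scenario_mask(frontier: ParetoFrontier, scenario: Scenario) -> np.ndarray:
    """Boolean mask of solutions meeting every constraint of the scenario.

    Quantile thresholds use linear-interpolation quantiles of the *input*
    frontier's display values.
    """
    n = len(frontier)
    mask = np.ones(n, dtype=bool)
    if n == 0:
        return mask
    D = frontier.display_matrix()
    for c in scenario.constraints:
        col = D[:, OBJECTIVE_NAMES.index(c.objective)]
        if c.kind == "band":
            mask &= np.abs(col - c.value) <= c.halfwidth + 1e-12
        else:
            bound = (
                float(np.quantile(col, c.value)) if c.kind == "quantile" else c.value
            )
            mask &= (col <= bound + 1e-12) if c.op == "le" else (col >= bound - 1e-12)
    return mask


def apply_scenario(frontier: ParetoFrontier, scenario: Scenario) -> ParetoFrontier:
    """Sub-frontier of solutions satisfying a restriction scenario."""
    return frontier.subset(scenario_mask(frontier, scenario))


def compromise_rescan(
    regimes: Sequence[ManagementRegime],
    *,
    n_rows: int = 50,
    n_cols: int = 50,
    area_dist: AreaDistribution | None = None,
    model: UncertaintyModel | None = None,
    sim_config: SimConfig | None = None,
    n_sims: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Re-simulate regimes on fresh random landscapes; per-year mean ± SD.

    Each of ``n_sims`` simulations of each regime uses an independent random
    landscape and owner allocation.  Returns a tidy frame with columns
    regime_id, year, variable, mean, sd covering the objective variables
    and the age-class composition.
    """
    area_dist = area_dist or AreaDistribution()
    model = model or UncertaintyModel()
    sim_config = sim_config or SimConfig()
    grid = build_grid(n_rows, n_cols)
    variables = (
        "mean_biomass",
        "edge_contrast",
        "skewness",
        "pct_young",
        "pct_mid",
        "pct_late",
        "pct_managed",
    )
    records = []
    for ridx, regime in enumerate(regimes):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(ridx,)))
        series = {v: np.zeros((n_sims, sim_config.horizon)) for v in variables}
        for s in range(n_sims):
            landscape = generate_landscape(grid, area_dist, rng, landscape_id=s)
            allocation = allocate_owners(landscape.n_owners, regime, rng)
            traj = simulate(landscape, regime, allocation, model, sim_config, rng)
            for v in variables:
                series[v][s] = getattr(traj, v)
        for v in variables:
            mean = series[v].mean(axis=0)
            sd = series[v].std(axis=0)
            for year in range(sim_config.horizon):
                records.append(
                    {
                        "regime_id": ridx,
                        "year": year,
                        "variable": v,
                        "mean": mean[year],
                        "sd": sd[year],
                    }
                )
    return pd.DataFrame(records)


# density grid: the interval axis padded by ±3 bandwidths beyond [3, 100]
DENSITY_GRID = np.round(np.arange(-12.0, 115.0 + 1e-9, 0.1), 10)


@dataclass
class SolutionDensity:
    """Gaussian-mixture density of a regime's intervals on a fixed grid."""

    regime: ManagementRegime
    grid: np.ndarray
    values: np.ndarray
    bandwidth: float = 5.0


def solution_density(
    regime: ManagementRegime,
    bandwidth: float = 5.0,
    grid: np.ndarray | None = None,
) -> SolutionDensity:
    """Kernel density of a regime over the management-interval axis.

    Mixture of Gaussians centered at the group intervals with sd =
    bandwidth, weighted by the group proportions.  No-management groups sit
    at 100 like any other interval.
    """
    grid = DENSITY_GRID if grid is None else np.asarray(grid, dtype=float)
    values = np.zeros_like(grid)
    for m, p in zip(regime.intervals, regime.proportions):
        values += p * norm.pdf(grid, loc=m, scale=bandwidth)
    return SolutionDensity(regime=regime, grid=grid, values=values, bandwidth=bandwidth)


def density_distance(d1: SolutionDensity, d2: SolutionDensity) -> float:
    """1 - intersection of two interval densities (in [0, 1]).

    The intersection is the integral of the pointwise minimum (trapezoid
    rule on the shared grid); identical regimes give 0.
    """
    if not np.array_equal(d1.grid, d2.grid):
        raise ValueError("densities must share the same grid")
    overlap = np.trapezoid(np.minimum(d1.values, d2.values), d1.grid)
    return float(np.clip(1.0 - overlap, 0.0, 1.0))


@dataclass
class PcoaResult:
    """Classical-scaling embedding of a distance matrix."""

    coordinates: np.ndarray  # (n, n_positive_axes)
    eigenvalues: np.ndarray  # descending, all axes
    proportion_explained: np.ndarray  # over positive eigenvalues only


def pcoa(distance_matrix: np.ndarray) -> PcoaResult:
    """Principal coordinate analysis (classical multidimensional scaling).

    Double-centers -D²/2, eigendecomposes, and scales eigenvectors by the
    square roots of the positive eigenvalues.  Negative eigenvalues (from
    non-Euclidean distances) are dropped from both the coordinates and the
    variance-explained denominator.
    """
    D = np.asarray(distance_matrix, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-10):
        raise ValueError("distance matrix must have a zero diagonal")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    eigval, eigvec = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = max(1e-12, 1e-10 * max(abs(eigval[0]), 1.0))
    positive = eigval > tol
    coords = eigvec[:, positive] * np.sqrt(eigval[positive])
    pos_sum = eigval[positive].sum()
    explained = eigval[positive] / pos_sum if pos_sum > 0 else eigval[positive]
    return PcoaResult(
        coordinates=coords, eigenvalues=eigval, proportion_explained=explained
    )
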