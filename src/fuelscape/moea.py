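"""Elitist nondominated-sorting genetic algorithm over management regimes.

Real-coded NSGA-II: binary tournament selection by (rank, crowding),
simulated binary crossover (SBX, probability 0.7, distribution index 5) and
polynomial mutation (per-gene probability 0.2, index 10), (mu+lambda)
survival by nondominated rank then crowding distance.  A genotype holds k
interval genes in [3, 100] and k non-negative weight genes that normalize
to the group proportions.  Each genotype is evaluated on a sample of
replicate landscapes from a pre-generated pool; the objective vector is the
componentwise worst case over replicates.

Convergence is monitored with the hypervolume dominated by the cumulative
nondominated archive, bounded above by the worst value of each objective
seen in any generation (reference point fixed after the run), so the series
is non-decreasing by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .dynamics import (
    INTERVAL_MIN,
    NO_MANAGEMENT,
    ManagementRegime,
    SimConfig,
    UncertaintyModel,
    allocate_owners,
    simulate,
)
from .hexgrid import LandscapePool
from .objectives import ObjectiveVector, aggregate_replicates, objectives_from_trajectory

__all__ = [
    "OptimizerConfig",
    "NSGA2Result",
    "RegimeProblem",
    "decode",
    "genotype_bounds",
    "dominates",
    "fast_nondominated_sort",
    "crowding_distance",
    "evaluate",
    "nsga2_run",
    "hypervolume",
]


@dataclass(frozen=True)
class OptimizerConfig:
    population: int = 800
    generations: int = 400
    crossover_prob: float = 0.7
    mutation_prob: float = 0.2
    crossover_eta: float = 5.0
    mutation_eta: float = 10.0
    hv_samples: int = 100_000

    def __post_init__(self) -> None:
        if self.population < 2 or self.population % 2:
            raise ValueError("population must be even and >= 2")
        for p in (self.crossover_prob, self.mutation_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


def genotype_bounds(n_groups: int) -> tuple[np.ndarray, np.ndarray]:
    """Lower/upper gene bounds: k intervals in [3,100] then k weights in [0,1]."""
    if not 1 <= n_groups <= 5:
        raise ValueError("n_groups must be in 1..5")
    xl = np.concatenate([np.full(n_groups, INTERVAL_MIN), np.zeros(n_groups)])
    xu = np.concatenate([np.full(n_groups, NO_MANAGEMENT), np.ones(n_groups)])
    return xl, xu


def decode(genotype: np.ndarray, n_groups: int | None = None) -> ManagementRegime:
    """Decode a flat gene vector into a valid ManagementRegime.

    Intervals are clipped to [3, 100]; weights are clipped at 0 and
    normalized to proportions (uniform fallback when all weights are zero).
    """
    x = np.asarray(genotype, dtype=float)
    if n_groups is None:
        if x.size % 2:
            raise ValueError("genotype length must be 2k")
        n_groups = x.size // 2
    if x.size != 2 * n_groups:
        raise ValueError(f"expected {2 * n_groups} genes, got {x.size}")
    intervals = np.clip(x[:n_groups], INTERVAL_MIN, NO_MANAGEMENT)
    weights = np.clip(x[n_groups:], 0.0, None)
    total = weights.sum()
    if total <= 0:
        proportions = np.full(n_groups, 1.0 / n_groups)
    else:
        proportions = weights / total
    return ManagementRegime(tuple(intervals), tuple(proportions))


def dominates(a: np.ndarray, b: np.ndarray) -> bool:
    """Pareto dominance in canonical minimization form."""
    a = np.asarray(a)
    b = np.asarray(b)
    return bool(np.all(a <= b) and np.any(a < b))


def fast_nondominated_sort(F: np.ndarray) -> np.ndarray:
    """Deb's fast nondominated sort; returns 1-based ranks.

    Rank 1 are the nondominated points; rank r+1 the nondominated points
    after removing ranks <= r.
    """
    F = np.asarray(F, dtype=float)
    n = len(F)
    if n == 0:
        raise ValueError("empty objective set")
    # vectorized pairwise dominance matrix: dom[i, j] = i dominates j
    le = np.all(F[:, None, :] <= F[None, :, :], axis=2)
    lt = np.any(F[:, None, :] < F[None, :, :], axis=2)
    dom = le & lt
    n_dominators = dom.sum(axis=0)
    ranks = np.zeros(n, dtype=np.int64)
    current = np.flatnonzero(n_dominators == 0)
    r = 1
    while current.size:
        ranks[current] = r
        n_dominators[current] = -1  # retire
        for i in current:
            n_dominators[dom[i]] -= 1
        current = np.flatnonzero(n_dominators == 0)
        r += 1
    return ranks


def crowding_distance(F: np.ndarray) -> np.ndarray:
    """NSGA-II crowding distance within a single front.

    Per objective, points are sorted and each interior point accrues the
    normalized gap between its neighbors; boundary points are infinite.
    Objectives with zero range contribute nothing.
    """
    F = np.asarray(F, dtype=float)
    n, m = F.shape
    if n == 0:
        raise ValueError("empty front")
    dist = np.zeros(n)
    if n <= 2:
        dist[:] = np.inf
        return dist
    for j in range(m):
        order = np.argsort(F[:, j], kind="stable")
        fj = F[order, j]
        span = fj[-1] - fj[0]
        if span <= 0:
            continue  # degenerate objective: contributes nothing
        dist[order[0]] = np.inf
        dist[order[-1]] = np.inf
        gaps = (fj[2:] - fj[:-2]) / span
        interior = order[1:-1]
        finite = np.isfinite(dist[interior])
        dist[interior[finite]] += gaps[finite]
    return dist


def _crowded_sort_key(ranks: np.ndarray, crowding: np.ndarray) -> np.ndarray:
    """Indices sorted by (rank asc, crowding desc), stable."""
    return np.lexsort((-crowding, ranks))


def hypervolume(
    front: np.ndarray,
    reference: np.ndarray,
    rng: np.random.Generator | None = None,
    n_samples: int = 100_000,
) -> float:
    """Hypervolume dominated by a front, bounded above by ``reference``.

    Exact sweep in 2-D; Monte-Carlo estimate (uniform samples in the
    bounding box, fixed count) in higher dimensions.  All points must lie
    within the reference box (componentwise <= reference).
    """
    front = np.atleast_2d(np.asarray(front, dtype=float))
    reference = np.asarray(reference, dtype=float)
    if np.any(front > reference):
        raise ValueError("all front points must dominate the reference point")
    # keep the nondominated subset; dominated points add no volume
    ranks = fast_nondominated_sort(front)
    front = front[ranks == 1]
    m = front.shape[1]
    if m == 1:
        return float(reference[0] - front[:, 0].min())
    if m == 2:
        order = np.lexsort((front[:, 1], front[:, 0]))
        pts = front[order]
        vol = 0.0
        prev2 = reference[1]
        for x1, x2 in pts:
            if x2 < prev2:
                vol += (reference[0] - x1) * (prev2 - x2)
                prev2 = x2
        return float(vol)
    if rng is None:
        rng = np.random.default_rng(0)
    lower = front.min(axis=0)
    box = reference - lower
    if np.any(box <= 0):
        # degenerate: some coordinate has zero extent
        box = np.maximum(box, 0.0)
        if box.prod() == 0:
            return 0.0
    samples = lower + rng.random((n_samples, m)) * box
    dominated = np.zeros(n_samples, dtype=bool)
    for p in front:
        dominated |= np.all(samples >= p, axis=1)
    return float(dominated.mean() * box.prod())


def evaluate(
    genotype: np.ndarray,
    pool: LandscapePool,
    model: UncertaintyModel,
    config: SimConfig,
    rng: np.random.Generator,
    n_groups: int | None = None,
) -> ObjectiveVector:
    """Worst-case objective vector of a genotype over replicate landscapes.

    RNG consumption order (relied upon by the determinism contract): first
    the without-replacement choice of ``config.replicates`` pool indices,
    then per replicate the owner allocation followed by the simulation.
    """
    if len(pool) < config.replicates:
        raise ValueError("pool smaller than the number of replicates")
    regime = decode(genotype, n_groups)
    picks = rng.choice(len(pool), size=config.replicates, replace=False)
    vectors = []
    for i in picks:
        landscape = pool[int(i)]
        allocation = allocate_owners(landscape.n_owners, regime, rng)
        traj = simulate(landscape, regime, allocation, model, config, rng)
        vectors.append(objectives_from_trajectory(traj, burn_in=config.burn_in))
    return aggregate_replicates(vectors)


@dataclass
class RegimeProblem:
    """Bundles the simulation stack into an objective function for NSGA-II."""

    pool: LandscapePool
    model: UncertaintyModel
    sim_config: SimConfig
    n_groups: int = 3

    @property
    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        return genotype_bounds(self.n_groups)

    def __call__(self, x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        return evaluate(
            x, self.pool, self.model, self.sim_config, rng, self.n_groups
        ).canonical()


def _sbx_pair(
    p1: np.ndarray,
    p2: np.ndarray,
    xl: np.ndarray,
    xu: np.ndarray,
    eta: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulated binary crossover on one parent pair (per-variable prob 0.5)."""
    c1, c2 = p1.copy(), p2.copy()
    for j in range(len(p1)):
        if rng.random() > 0.5 or abs(p1[j] - p2[j]) < 1e-14:
            continue
        u = rng.random()
        if u <= 0.5:
            beta = (2.0 * u) ** (1.0 / (eta + 1.0))
        else:
            beta = (1.0 / (2.0 * (1.0 - u))) ** (1.0 / (eta + 1.0))
        v1 = 0.5 * ((1.0 + beta) * p1[j] + (1.0 - beta) * p2[j])
        v2 = 0.5 * ((1.0 - beta) * p1[j] + (1.0 + beta) * p2[j])
        c1[j] = np.clip(v1, xl[j], xu[j])
        c2[j] = np.clip(v2, xl[j], xu[j])
    return c1, c2


def _polynomial_mutation(
    x: np.ndarray,
    xl: np.ndarray,
    xu: np.ndarray,
    prob: float,
    eta: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Bounded polynomial mutation, applied per gene with probability ``prob``."""
    y = x.copy()
    for j in range(len(x)):
        if rng.random() >= prob:
            continue
        span = xu[j] - xl[j]
        if span <= 0:
            continue
        d1 = (y[j] - xl[j]) / span
        d2 = (xu[j] - y[j]) / span
        u = rng.random()
        exp = 1.0 / (eta + 1.0)
        if u < 0.5:
            delta = (2.0 * u + (1.0 - 2.0 * u) * (1.0 - d1) ** (eta + 1.0)) ** exp - 1.0
        else:
            delta = 1.0 - (
                2.0 * (1.0 - u) + 2.0 * (u - 0.5) * (1.0 - d2) ** (eta + 1.0)
            ) ** exp
        y[j] = np.clip(y[j] + delta * span, xl[j], xu[j])
    return y


def _tournament(
    ranks: np.ndarray, crowding: np.ndarray, rng: np.random.Generator
) -> int:
    """Binary tournament by crowded comparison (lower rank, then larger crowding)."""
    i, j = rng.integers(len(ranks), size=2)
    if ranks[i] < ranks[j]:
        return int(i)
    if ranks[j] < ranks[i]:
        return int(j)
    if crowding[i] > crowding[j]:
        return int(i)
    if crowding[j] > crowding[i]:
        return int(j)
    return int(i)


def _rank_and_crowd(F: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ranks = fast_nondominated_sort(F)
    crowding = np.zeros(len(F))
    for r in np.unique(ranks):
        mask = ranks == r
        crowding[mask] = crowding_distance(F[mask])
    return ranks, crowding


def _archive_update(arch_X: list, arch_F: list, X: np.ndarray, F: np.ndarray) -> None:
    """Merge new points into a cumulative nondominated archive (in place)."""
    for x, f in zip(X, F):
        if any(dominates(g, f) or np.array_equal(g, f) for g in arch_F):
            continue
        keep = [k for k, g in enumerate(arch_F) if not dominates(f, g)]
        arch_F[:] = [arch_F[k] for k in keep] + [f.copy()]
        arch_X[:] = [arch_X[k] for k in keep] + [x.copy()]


@dataclass
class NSGA2Result:
    X: np.ndarray  # final population genotypes
    F: np.ndarray  # final population canonical objectives
    ranks: np.ndarray
    crowding: np.ndarray
    front_X: np.ndarray  # rank-1 subset of the final population
    front_F: np.ndarray
    hypervolume_series: np.ndarray  # per generation (archive-based)
    reference_point: np.ndarray
    archive_X: np.ndarray
    archive_F: np.ndarray
    n_evaluations: int = 0


def nsga2_run(
    evaluate_fn: Callable[[np.ndarray, np.random.Generator], np.ndarray],
    xl: np.ndarray,
    xu: np.ndarray,
    config: OptimizerConfig,
    rng: np.random.Generator,
) -> NSGA2Result:
    """Run NSGA-II and return the final frontier plus convergence series.

    ``evaluate_fn(x, rng)`` must return the objective vector in canonical
    minimization form.  Genotypes keep the objective vector from their one
    evaluation (no noisy re-evaluation of survivors).
    """
    xl = np.asarray(xl, dtype=float)
    xu = np.asarray(xu, dtype=float)
    n_var = len(xl)
    pop = config.population

    X = xl + rng.random((pop, n_var)) * (xu - xl)
    F = np.stack([evaluate_fn(x, rng) for x in X])
    n_evals = pop
    ranks, crowding = _rank_and_crowd(F)

    arch_X: list[np.ndarray] = []
    arch_F: list[np.ndarray] = []
    _archive_update(arch_X, arch_F, X, F)
    gen_archives = [np.stack(arch_F)]
    worst = F.max(axis=0)

    for _ in range(config.generations):
        # variation: tournament parents -> SBX -> polynomial mutation
        offspring = np.empty_like(X)
        for k in range(0, pop, 2):
            i = _tournament(ranks, crowding, rng)
            j = _tournament(ranks, crowding, rng)
            if rng.random() < config.crossover_prob:
                c1, c2 = _sbx_pair(X[i], X[j], xl, xu, config.crossover_eta, rng)
            else:
                c1, c2 = X[i].copy(), X[j].copy()
            offspring[k] = _polynomial_mutation(
                c1, xl, xu, config.mutation_prob, config.mutation_eta, rng
            )
            offspring[k + 1] = _polynomial_mutation(
                c2, xl, xu, config.mutation_prob, config.mutation_eta, rng
            )
        off_F = np.stack([evaluate_fn(x, rng) for x in offspring])
        n_evals += pop

        # (mu + lambda) elitist survival
        all_X = np.vstack([X, offspring])
        all_F = np.vstack([F, off_F])
        all_ranks, all_crowd = _rank_and_crowd(all_F)
        order = _crowded_sort_key(all_ranks, all_crowd)[:pop]
        X, F = all_X[order], all_F[order]
        ranks, crowding = _rank_and_crowd(F)

        worst = np.maximum(worst, all_F.max(axis=0))
        _archive_update(arch_X, arch_F, offspring, off_F)
        gen_archives.append(np.stack(arch_F))

    # reference point: worst of each objective achieved in any generation,
    # fixed after the run; one fixed MC sample stream per hypervolume call
    reference = worst + 1e-9
    hv_seed = int(rng.integers(2**31))
    series = np.array(
        [
            hypervolume(
                snap, reference, np.random.default_rng(hv_seed), config.hv_samples
            )
            for snap in gen_archives
        ]
    )
    front_mask = ranks == 1
    return NSGA2Result(
        X=X,
        F=F,
        ranks=ranks,
        crowding=crowding,
        front_X=X[front_mask],
        front_F=F[front_mask],
        hypervolume_series=series,
        reference_point=reference,
        archive_X=np.stack(arch_X),
        archive_F=np.stack(arch_F),
        n_evaluations=n_evals,
    )
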