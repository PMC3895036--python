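"""A-priori-assumption sweeps: landholding-area and uncertainty gradients.

One optimization run per level of the swept parameter (everything else held
fixed), followed by cross-run comparison: scenario-filter each frontier,
pool the surviving solutions, compute pairwise interval-density distances,
and embed them with principal coordinate analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .config import RunConfig
from .dynamics import NO_MANAGEMENT
from .experiment import run_optimization, substream
from .postprocess import (
    ParetoFrontier,
    PcoaResult,
    Scenario,
    apply_scenario,
    density_distance,
    pcoa,
    solution_density,
)

__all__ = [
    "AREA_LEVELS",
    "UNCERTAINTY_LEVELS",
    "SweepSpec",
    "run_sweep",
    "SweepComparison",
    "compare_runs",
]

# printed sweep levels: (mean, variance) pairs for landholding areas, and
# max-variance values (variance at the 100-year interval) for uncertainty
AREA_LEVELS: tuple[tuple[float, float], ...] = (
    (20.0, 100.0),
    (60.0, 900.0),
    (100.0, 2500.0),
    (140.0, 4900.0),
    (200.0, 10000.0),
)
UNCERTAINTY_LEVELS: tuple[float, ...] = (1.0, 5.0, 10.0, 50.0, 100.0, 500.0, 1000.0)


@dataclass(frozen=True)
class SweepSpec:
    axis: str  # "landholding_area" | "uncertainty"
    levels: tuple = ()
    replicates: int = 12
    generations: int = 400

    def __post_init__(self) -> None:
        if self.axis not in ("landholding_area", "uncertainty"):
            raise ValueError(f"unknown sweep axis {self.axis!r}")
        if not self.levels:
            default = AREA_LEVELS if self.axis == "landholding_area" else UNCERTAINTY_LEVELS
            object.__setattr__(self, "levels", default)

    def level_label(self, level) -> str:
        if self.axis == "landholding_area":
            mean, var = level
            return f"{mean:g}/{var:g}"
        return f"V={level:g}"

    def apply_level(self, base: RunConfig, level, seed: int) -> RunConfig:
        common = dict(
            replicates=self.replicates, generations=self.generations, seed=seed
        )
        if self.axis == "landholding_area":
            mean, var = level
            return base.replace(area_mean=mean, area_variance=var, **common)
        # uncertainty level V is the variance at the 100-year interval
        return base.replace(uncertainty_shape=NO_MANAGEMENT**2 / level, **common)


def run_sweep(
    spec: SweepSpec, base: RunConfig, base_seed: int | None = None
) -> dict[str, ParetoFrontier]:
    """One optimization per level; per-level seeds derived from the base seed.

    Pools are regenerated per level (the area axis changes the landholding
    distribution, so reuse would be inconsistent).
    """
    base_seed = base.seed if base_seed is None else base_seed
    frontiers: dict[str, ParetoFrontier] = {}
    for i, level in enumerate(spec.levels):
        level_seed = int(substream(base_seed, "sweep", i).generate_state(1)[0] % 2**31)
        config = spec.apply_level(base, level, level_seed)
        frontier, _ = run_optimization(config)
        frontiers[spec.level_label(level)] = frontier
    return frontiers


@dataclass
class SweepComparison:
    labels: list[str]  # level label per pooled solution
    distance_matrix: np.ndarray
    embedding: PcoaResult | None
    degenerate: bool = False  # <2 solutions, or all distances zero

    def distance_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.distance_matrix, index=self.labels, columns=self.labels)


def compare_runs(
    frontiers: dict[str, ParetoFrontier],
    scenario: Scenario,
    bandwidth: float = 5.0,
) -> SweepComparison:
    """Scenario-filter frontiers, pool solutions, embed density distances."""
    if len(frontiers) < 2:
        raise ValueError("need at least 2 levels to compare")
    labels: list[str] = []
    densities = []
    for label, frontier in frontiers.items():
        sub = apply_scenario(frontier, scenario)
        for regime in sub.regimes:
            labels.append(label)
            densities.append(solution_density(regime, bandwidth=bandwidth))
    n = len(densities)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = density_distance(densities[i], densities[j])
    if n < 2:
        return SweepComparison(labels=labels, distance_matrix=D, embedding=None, degenerate=True)
    result = pcoa(D)
    degenerate = result.coordinates.shape[1] == 0
    return SweepComparison(
        labels=labels,
        distance_matrix=D,
        embedding=None if degenerate else result,
        degenerate=degenerate,
    )
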