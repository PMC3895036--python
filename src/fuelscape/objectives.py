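"""Six landscape-level objectives and their worst-case aggregation.

Three fire-risk surrogates (maximum annual mean fuel load, minimized;
minimum annual edge contrast and fuel-concentration skewness, maximized),
two biodiversity surrogates (minimum annual % area in the 30-60 year and
>60 year understory age classes, maximized) and a cost surrogate (mean %
area managed per year, minimized).  Extremes over years replace means so
that single years of extreme fire risk are not averaged away; the first 20
simulation years are discarded from all objectives except cost, to let the
landscape adapt to the regime.

Internally every objective is stored in *canonical minimization form*:
maximization objectives are negated.  Display form is the natural sign.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "OBJECTIVE_NAMES",
    "MAXIMIZED",
    "ObjectiveVector",
    "mean_fuel_load",
    "edge_contrast",
    "edge_contrast_from_pairs",
    "fuel_skewness",
    "age_class_fraction",
    "objectives_from_trajectory",
    "aggregate_replicates",
]

OBJECTIVE_NAMES = ("cost", "fuel_load", "edge_contrast", "skewness", "mid_area", "late_area")
# direction convention: True where the display-form objective is maximized
MAXIMIZED = np.array([False, False, True, True, True, True])
_SIGN = np.where(MAXIMIZED, -1.0, 1.0)


@dataclass(frozen=True)
class ObjectiveVector:
    """The six objectives in display form (natural units and directions)."""

    cost: float  # % area managed / year (minimize)
    fuel_load: float  # kg/ha, worst (max) post-burn-in year (minimize)
    edge_contrast: float  # (kg/ha)^2, worst (min) year (maximize)
    skewness: float  # dimensionless, worst (min) year (maximize)
    mid_area: float  # %, worst (min) year (maximize)
    late_area: float  # %, worst (min) year (maximize)

    def display(self) -> np.ndarray:
        return np.array(
            [self.cost, self.fuel_load, self.edge_contrast, self.skewness,
             self.mid_area, self.late_area]
        )

    def canonical(self) -> np.ndarray:
        """All six as minimization values (maximized objectives negated)."""
        return self.display() * _SIGN

    @classmethod
    def from_canonical(cls, values: np.ndarray) -> "ObjectiveVector":
        disp = np.asarray(values, dtype=float) * _SIGN
        return cls(*disp)

    @classmethod
    def from_display(cls, values: np.ndarray) -> "ObjectiveVector":
        return cls(*np.asarray(values, dtype=float))


def mean_fuel_load(biomass_map: np.ndarray) -> float:
    """Mean understory biomass per hectare across all cells (cells are 1 ha)."""
    biomass_map = np.asarray(biomass_map, dtype=float)
    if biomass_map.size == 0:
        raise ValueError("empty biomass map")
    return float(biomass_map.mean())


def edge_contrast_from_pairs(v1: np.ndarray, v2: np.ndarray) -> float:
    """Variance of |v1 - v2| given pre-gathered adjacent-pair endpoint values."""
    d = np.abs(np.asarray(v1, dtype=float) - np.asarray(v2, dtype=float))
    if d.size == 0:
        raise ValueError("no adjacent pairs")
    return float(d.var())  # population variance

def edge_contrast(biomass_map: np.ndarray, pairs: np.ndarray) -> float:
    """Variance-of-edge-contrast surface metric ("root mean square slope").

    Population variance of the absolute biomass differences over all
    unordered pairs of adjacent cells, each pair counted once.
    """
    biomass_map = np.asarray(biomass_map, dtype=float)
    pairs = np.asarray(pairs)
    return edge_contrast_from_pairs(biomass_map[pairs[:, 0]], biomass_map[pairs[:, 1]])


def fuel_skewness(values: np.ndarray) -> float:
    """Surface skewness g1 = m3 / m2^(3/2) of per-cell biomass.

    Population moments; a zero-variance input returns 0 (flat landscapes
    have no fuel concentration).  High values mean most cells carry little
    fuel and a few carry much.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ValueError("skewness needs at least 3 values")
    centered = values - values.mean()
    m2 = np.mean(centered**2)
    if m2 <= 0:
        return 0.0
    m3 = np.mean(centered**3)
    return float(m3 / m2**1.5)


def age_class_fraction(age_map: np.ndarray, lo: float, hi: float = np.inf) -> float:
    """% of cells with lo <= age <= hi (hi=inf gives an open-ended class)."""
    if lo >= hi:
        raise ValueError("lo must be < hi")
    age_map = np.asarray(age_map)
    inside = (age_map >= lo) & (age_map <= hi)
    return float(100.0 * np.count_nonzero(inside) / age_map.size)


def objectives_from_trajectory(trajectory, burn_in: int = 20) -> ObjectiveVector:
    """Summarize a yearly trajectory into the six objectives.

    Cost is the mean managed fraction over *all* years; the five remaining
    objectives take their worst value over years >= burn_in (max for fuel
    load, min for the maximized objectives).
    """
    horizon = trajectory.horizon
    if horizon <= burn_in:
        raise ValueError("horizon must exceed burn_in")
    s = slice(burn_in, None)
    return ObjectiveVector(
        cost=float(trajectory.pct_managed.mean()),
        fuel_load=float(trajectory.mean_biomass[s].max()),
        edge_contrast=float(trajectory.edge_contrast[s].min()),
        skewness=float(trajectory.skewness[s].min()),
        mid_area=float(trajectory.pct_mid[s].min()),
        late_area=float(trajectory.pct_late[s].min()),
    )


def aggregate_replicates(vectors: Sequence[ObjectiveVector]) -> ObjectiveVector:
    """Componentwise worst case over replicate evaluations.

    The worst is the maximum in canonical minimization form — i.e. the
    highest cost/fuel load and the lowest edge contrast, skewness and
    age-class areas attained in any replicate.
    """
    vectors = list(vectors)
    if not vectors:
        raise ValueError("at least one replicate vector required")
    stacked = np.stack([v.canonical() for v in vectors])
    return ObjectiveVector.from_canonical(stacked.max(axis=0))
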