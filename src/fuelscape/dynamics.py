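"""Yearly landscape dynamics under a non-spatial management regime.

Each landowner belongs to one management group; a group prescribes a
clearing interval in years, with interval 100 meaning "no management".
Implementation uncertainty makes realized intervals Gamma-distributed
around the prescription with constant shape (base 100), so the variance of
landowner behavior grows with the prescribed interval.  Clearing resets a
whole landholding's understory age to 0; understory biomass then
re-accumulates along a saturating growth curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import objectives as _obj
from .hexgrid import HexLandscape

__all__ = [
    "NO_MANAGEMENT",
    "INTERVAL_MIN",
    "ManagementRegime",
    "UncertaintyModel",
    "uncertainty_from_max_variance",
    "BiomassCurve",
    "SimConfig",
    "SimulationTrajectory",
    "allocate_owners",
    "sample_interval",
    "biomass",
    "simulate",
    "managed_fraction",
]

INTERVAL_MIN = 3.0
NO_MANAGEMENT = 100.0  # upper interval bound; encodes absence of management


@dataclass(frozen=True)
class ManagementRegime:
    """1-5 groups of (prescribed interval, proportion of landowners).

    Proportions must sum to 1; intervals lie in [3, 100] and an interval of
    exactly 100 years means the group never clears.
    """

    intervals: tuple[float, ...]
    proportions: tuple[float, ...]

    def __post_init__(self) -> None:
        if not 1 <= len(self.intervals) <= 5:
            raise ValueError("a regime has between 1 and 5 groups")
        if len(self.intervals) != len(self.proportions):
            raise ValueError("intervals and proportions must have equal length")
        if any(p < 0 for p in self.proportions):
            raise ValueError("proportions must be non-negative")
        if abs(sum(self.proportions) - 1.0) > 1e-9:
            raise ValueError(f"proportions must sum to 1, got {sum(self.proportions)}")
        for m in self.intervals:
            if not INTERVAL_MIN <= m <= NO_MANAGEMENT:
                raise ValueError(f"interval {m} outside [{INTERVAL_MIN}, {NO_MANAGEMENT}]")

    @property
    def n_groups(self) -> int:
        return len(self.intervals)

    @classmethod
    def from_string(cls, text: str) -> "ManagementRegime":
        """Parse ``"interval:proportion,interval:proportion,..."``."""
        intervals, props = [], []
        for part in text.split(","):
            m, p = part.split(":")
            intervals.append(float(m))
            props.append(float(p))
        return cls(tuple(intervals), tuple(props))

    def to_string(self) -> str:
        return ",".join(f"{m:g}:{p:g}" for m, p in zip(self.intervals, self.proportions))


@dataclass(frozen=True)
class UncertaintyModel:
    """Gamma implementation noise with constant shape (base model: 100).

    A realized interval for prescription m is Gamma with mean m and variance
    m²/shape, so uncertainty is larger at larger intervals.
    """

    shape: float = 100.0

    def __post_init__(self) -> None:
        if self.shape <= 0:
            raise ValueError("shape must be positive")

    def variance(self, prescribed: float) -> float:
        return prescribed**2 / self.shape

    @property
    def max_variance(self) -> float:
        """Variance at the 100-year interval (the sweep parameterization)."""
        return NO_MANAGEMENT**2 / self.shape


def uncertainty_from_max_variance(max_variance: float) -> UncertaintyModel:
    """Build the noise model from its variance at the 100-year interval.

    shape = 100²/V; V = 100 recovers the base model (shape 100).
    """
    if max_variance <= 0:
        raise ValueError("max variance must be positive")
    return UncertaintyModel(shape=NO_MANAGEMENT**2 / max_variance)


def sample_interval(
    prescribed: float | np.ndarray,
    model: UncertaintyModel,
    rng: np.random.Generator,
    size=None,
) -> np.ndarray | float:
    """Draw realized clearing interval(s) for a prescription.

    Gamma with mean = prescribed, shape = model.shape (scale = mean/shape).
    """
    return rng.gamma(model.shape, np.asarray(prescribed) / model.shape, size=size)


@dataclass(frozen=True)
class BiomassCurve:
    """Saturating understory biomass accumulation after clearing.

    Monomolecular form B(a) = b_max (1 - exp(-rate a)); with the defaults
    (b_max 20,000 kg/ha, rate 0.06 /yr) the curve reaches ~95% of its
    plateau by age 50, so variation after 50 years is slight.  All
    objectives are invariant to b_max (two are range/shape statistics, the
    fuel-load maximum scales linearly).
    """

    b_max: float = 20_000.0
    rate: float = 0.06

    def value(self, age) -> np.ndarray | float:
        age = np.asarray(age, dtype=float)
        if np.any(age < 0):
            raise ValueError("age must be non-negative")
        return self.b_max * (1.0 - np.exp(-self.rate * age))

    def lookup_table(self, max_age: int) -> np.ndarray:
        """Biomass at integer ages 0..max_age (used by the simulator)."""
        return np.asarray(self.value(np.arange(max_age + 1)))


def biomass(age, curve: BiomassCurve | None = None):
    """Understory biomass (kg/ha) at a given age since clearing."""
    return (curve or BiomassCurve()).value(age)


@dataclass(frozen=True)
class SimConfig:
    """Simulation horizon, burn-in and replicate counts."""

    horizon: int = 100
    burn_in: int = 20
    replicates: int = 24
    curve: BiomassCurve = field(default_factory=BiomassCurve)

    def __post_init__(self) -> None:
        if not 0 <= self.burn_in < self.horizon:
            raise ValueError("burn_in must satisfy 0 <= burn_in < horizon")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


@dataclass
class SimulationTrajectory:
    """Per-year landscape summaries over one simulated management run."""

    mean_biomass: np.ndarray  # kg/ha
    edge_contrast: np.ndarray  # (kg/ha)^2
    skewness: np.ndarray  # dimensionless
    pct_young: np.ndarray  # % area age < 10
    pct_mid: np.ndarray  # % area age 30-60
    pct_late: np.ndarray  # % area age > 60
    pct_managed: np.ndarray  # % area cleared that year

    @property
    def horizon(self) -> int:
        return len(self.pct_managed)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "year": np.arange(self.horizon),
                "mean_biomass_kg_ha": self.mean_biomass,
                "edge_contrast": self.edge_contrast,
                "skewness": self.skewness,
                "pct_age_lt10": self.pct_young,
                "pct_age_30_60": self.pct_mid,
                "pct_age_gt60": self.pct_late,
                "pct_managed": self.pct_managed,
            }
        )


def allocate_owners(
    n_owners: int, regime: ManagementRegime, rng: np.random.Generator
) -> np.ndarray:
    """Independently assign each owner to a group with the regime's proportions."""
    if n_owners == 0:
        return np.zeros(0, dtype=np.int64)
    p = np.asarray(regime.proportions, dtype=float)
    p = p / p.sum()  # guard against 1e-9 rounding
    return rng.choice(regime.n_groups, size=n_owners, p=p)


def simulate(
    landscape: HexLandscape,
    regime: ManagementRegime,
    allocation: np.ndarray,
    model: UncertaintyModel,
    config: SimConfig,
    rng: np.random.Generator,
    return_owner_ages: bool = False,
):
    """Simulate ``config.horizon`` years of management on one landscape.

    Yearly loop: owners whose clearing is due clear all their cells (age 0)
    and schedule the next clearing one fresh Gamma interval later; all other
    cells age one year; per-year summaries are recorded (end-of-year state).

    Clearing starts at year 0 for owners whose initial understory age is at
    least the *prescribed* interval; otherwise the first clearing falls in
    the first integer year at which the understory reaches the *sampled*
    interval.  Owners in a 100-year group never clear.  Due times are kept
    real-valued across clearings so the long-run clearing rate is exactly
    the reciprocal of the prescribed interval.
    """
    grid = landscape.grid
    n_cells = grid.n_cells
    n_owners = landscape.n_owners
    if len(allocation) != n_owners:
        raise ValueError("allocation length must equal the number of owners")

    intervals = np.asarray(regime.intervals, dtype=float)[allocation]
    managed = intervals < NO_MANAGEMENT
    ages = landscape.owner_ages().astype(np.int64).copy()

    due = np.full(n_owners, np.inf)
    idx = np.flatnonzero(managed)
    if idx.size:
        start_now = ages[idx] >= intervals[idx]
        due[idx[start_now]] = 0.0
        later = idx[~start_now]
        if later.size:
            first = sample_interval(intervals[later], model, rng)
            due[later] = np.maximum(0.0, first - ages[later])

    counts = landscape.owner_cell_counts().astype(float)
    owner_of = landscape.owner_of
    pairs = grid.edge_pairs
    # pair endpoints expressed as owners: ages are per-owner, so all gathers
    # can run on the (much smaller) owner arrays
    po1 = owner_of[pairs[:, 0]]
    po2 = owner_of[pairs[:, 1]]
    horizon = config.horizon
    lut = config.curve.lookup_table(int(ages.max()) + horizon + 1)

    out = SimulationTrajectory(
        mean_biomass=np.zeros(horizon),
        edge_contrast=np.zeros(horizon),
        skewness=np.zeros(horizon),
        pct_young=np.zeros(horizon),
        pct_mid=np.zeros(horizon),
        pct_late=np.zeros(horizon),
        pct_managed=np.zeros(horizon),
    )
    ages_log = np.zeros((horizon, n_owners), dtype=np.int64) if return_owner_ages else None

    for t in range(horizon):
        clearing = due <= t
        cleared_area = counts[clearing].sum()
        ages[clearing] = 0
        ages[~clearing] += 1
        n_clearing = int(clearing.sum())
        if n_clearing:
            due[clearing] += sample_interval(intervals[clearing], model, rng)

        cell_ages = ages[owner_of]
        b = lut[cell_ages]
        out.mean_biomass[t] = _obj.mean_fuel_load(b)
        out.edge_contrast[t] = _obj.edge_contrast_from_pairs(lut[ages[po1]], lut[ages[po2]])
        out.skewness[t] = _obj.fuel_skewness(b)
        out.pct_young[t] = 100.0 * np.count_nonzero(cell_ages < 10) / n_cells
        out.pct_mid[t] = 100.0 * np.count_nonzero((cell_ages >= 30) & (cell_ages <= 60)) / n_cells
        out.pct_late[t] = 100.0 * np.count_nonzero(cell_ages >= 61) / n_cells
        out.pct_managed[t] = 100.0 * cleared_area / n_cells
        if ages_log is not None:
            ages_log[t] = ages

    if return_owner_ages:
        return out, ages_log
    return out


def managed_fraction(trajectory: SimulationTrajectory, year: int) -> float:
    """% of landscape area cleared in a given year."""
    if not 0 <= year < trajectory.horizon:
        raise ValueError(f"year {year} outside [0, {trajectory.horizon})")
    return float(trajectory.pct_managed[year])
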