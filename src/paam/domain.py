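"""Core domain types for small-area healthcare demand--supply simulation.

The model world consists of *meshes* (500-m grid cells carrying an
age-by-sex population vector, the unit of demand) and *hospitals*
(located facilities with a bed count, the unit of supply).  Demographic
and inpatient-care rates are indexed by sex and 5-year age band; a
:class:`Scenario` bundles the policy levers (inpatient-rate reduction,
average-length-of-stay reduction, bed utilization rate) that modulate
demand and capacity.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np

#: Sexes, in the fixed row order used by every (2, 18) rate/count matrix.
SEXES: tuple[str, str] = ("female", "male")
N_SEXES = 2

#: Five-year age bands, 0-4 through 80-84 plus an absorbing 85+ band.
AGE_BANDS: tuple[str, ...] = tuple(f"{5 * i}-{5 * i + 4}" for i in range(17)) + ("85+",)
N_BANDS = 18

#: Index range of the reproductive female bands (15-19 .. 45-49).
FERTILE_BANDS = slice(3, 10)

_FLOOR_EPS = 1e-9  # guards floor() against binary-float artefacts like 29*0.8


class SizeClass(enum.IntEnum):
    """Hospital size class; ordering small < medium < large is meaningful."""

    small = 0
    medium = 1
    large = 2


def classify_hospital_size(total_beds: int) -> SizeClass:
    """Classify a hospital by bed count.

    Small: up to 100 beds; medium: 101-399; large: 400 or more.
    """
    if not float(total_beds).is_integer() or total_beds < 1:
        raise ValueError(f"total_beds must be a positive integer, got {total_beds!r}")
    beds = int(total_beds)
    if beds <= 100:
        return SizeClass.small
    if beds < 400:
        return SizeClass.medium
    return SizeClass.large


@dataclass(frozen=True)
class Hospital:
    """A located facility with a bed capacity.

    ``in_region`` distinguishes hospitals inside the planning region from
    adjacent-region hospitals whose beds are only partially open to the
    region's patients.
    """

    id: str
    x: float
    y: float
    total_beds: int
    in_region: bool = True

    def __post_init__(self) -> None:
        if not math.isfinite(self.x) or not math.isfinite(self.y):
            raise ValueError(f"hospital {self.id!r}: non-finite coordinates")
        classify_hospital_size(self.total_beds)  # validates total_beds >= 1

    @property
    def size_class(self) -> SizeClass:
        return classify_hospital_size(self.total_beds)


def available_beds(
    hospital: Hospital,
    utilization_rate: float,
    external_bed_fraction: float = 0.20,
) -> int:
    """Beds of ``hospital`` usable for allocation under a utilization rate.

    In-region hospitals contribute ``floor(total_beds * utilization_rate)``;
    out-of-region hospitals are additionally capped at
    ``external_bed_fraction`` of that (patients may occupy at most that
    share of a neighbouring region's beds).  Flooring means capacity is
    never overstated.
    """
    if not 0.0 < utilization_rate <= 1.0:
        raise ValueError(f"utilization_rate must be in (0, 1], got {utilization_rate}")
    if not 0.0 <= external_bed_fraction <= 1.0:
        raise ValueError(
            f"external_bed_fraction must be in [0, 1], got {external_bed_fraction}"
        )
    beds = hospital.total_beds * utilization_rate
    if not hospital.in_region:
        beds *= external_bed_fraction
    return int(math.floor(beds + _FLOOR_EPS))


@dataclass(eq=False)
class AgeSexPopulation:
    """Counts of people per sex and 5-year age band: a (2, 18) matrix.

    Stochastic stages produce integral counts; expectation-mode
    projections carry real-valued counts (``fractional=True``).
    """

    counts: np.ndarray
    fractional: bool = False

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts, dtype=float if self.fractional else None)
        if arr.shape != (N_SEXES, N_BANDS):
            raise ValueError(
                f"counts must have shape ({N_SEXES}, {N_BANDS}), got {arr.shape}"
            )
        if not np.all(np.isfinite(arr)):
            raise ValueError("counts must be finite")
        if np.any(arr < 0):
            raise ValueError("counts must be non-negative")
        if not self.fractional:
            if not np.all(np.equal(np.mod(arr, 1), 0)):
                raise ValueError("counts must be integral unless fractional=True")
            arr = arr.astype(np.int64)
        self.counts = arr

    @classmethod
    def zeros(cls, fractional: bool = False) -> "AgeSexPopulation":
        dtype = float if fractional else np.int64
        return cls(np.zeros((N_SEXES, N_BANDS), dtype=dtype), fractional=fractional)

    def total(self) -> float:
        return float(self.counts.sum())

    def copy(self) -> "AgeSexPopulation":
        return AgeSexPopulation(self.counts.copy(), fractional=self.fractional)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AgeSexPopulation):
            return NotImplemented
        return self.fractional == other.fractional and np.array_equal(
            self.counts, other.counts
        )


@dataclass(frozen=True)
class Mesh:
    """A grid cell: the small-area unit of population and patient demand.

    ``x``/``y`` are the centroid in a planar projected CRS, metres.
    """

    id: str
    x: float
    y: float
    population: AgeSexPopulation

    def __post_init__(self) -> None:
        if not math.isfinite(self.x) or not math.isfinite(self.y):
            raise ValueError(f"mesh {self.id!r}: non-finite centroid")


@dataclass
class RateTables:
    """Demographic and inpatient-care rates per sex and age band.

    fertility
        Births per woman per 5-year projection step, full 18-vector
        (non-zero only for the reproductive bands 15-49).
    sex_ratio_at_birth
        Male births per female birth (dimensionless, > 0).
    survival
        Probability of surviving one 5-year step, (2, 18), each in [0, 1].
    net_migration
        Signed net migration rate per step as a fraction of the band;
        negative values are outflow.
    inpatient_rate
        Probability that a person is a hospital inpatient on a given day
        (a daily census prevalence, not an admission rate), (2, 18).
    """

    fertility: np.ndarray
    sex_ratio_at_birth: float
    survival: np.ndarray
    net_migration: np.ndarray
    inpatient_rate: np.ndarray

    def __post_init__(self) -> None:
        self.fertility = np.asarray(self.fertility, dtype=float)
        self.survival = np.asarray(self.survival, dtype=float)
        self.net_migration = np.asarray(self.net_migration, dtype=float)
        self.inpatient_rate = np.asarray(self.inpatient_rate, dtype=float)
        if self.fertility.shape != (N_BANDS,):
            raise ValueError(f"fertility must have shape ({N_BANDS},)")
        for name in ("survival", "net_migration", "inpatient_rate"):
            if getattr(self, name).shape != (N_SEXES, N_BANDS):
                raise ValueError(f"{name} must have shape ({N_SEXES}, {N_BANDS})")
        if np.any(self.fertility < 0):
            raise ValueError("fertility must be non-negative")
        if self.sex_ratio_at_birth <= 0:
            raise ValueError("sex_ratio_at_birth must be positive")
        for name in ("survival", "inpatient_rate"):
            arr = getattr(self, name)
            if np.any(arr < 0) or np.any(arr > 1):
                raise ValueError(f"{name} entries must lie in [0, 1]")
        if not np.all(np.isfinite(self.net_migration)):
            raise ValueError("net_migration must be finite")
        if np.any(self.net_migration < -1):
            raise ValueError("net_migration cannot remove more than the whole band")


@dataclass
class Scenario:
    """Policy scenario: demand-side reductions plus supply-side utilization.

    ``inpatient_rate_reduction`` and ``alos_reduction`` enter demand as the
    factors ``(1 - inpatient_rate_reduction) * (1 - alos_reduction)``; the
    average-length-of-stay reduction lowers the *apparent* daily census
    because each patient occupies a bed for fewer days.
    """

    name: str
    inpatient_rate_reduction: float = 0.0
    alos_reduction: float = 0.0
    utilization_rate: float = 0.80
    external_bed_fraction: float = 0.20
    paa_threshold_minutes: float = 60.0
    n_samples: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.inpatient_rate_reduction < 1.0:
            raise ValueError("inpatient_rate_reduction must be in [0, 1)")
        if not 0.0 <= self.alos_reduction < 1.0:
            raise ValueError("alos_reduction must be in [0, 1)")
        if not 0.0 < self.utilization_rate <= 1.0:
            raise ValueError("utilization_rate must be in (0, 1]")
        if not 0.0 <= self.external_bed_fraction <= 1.0:
            raise ValueError("external_bed_fraction must be in [0, 1]")
        if self.paa_threshold_minutes <= 0:
            raise ValueError("paa_threshold_minutes must be positive")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
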