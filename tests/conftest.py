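import numpy as np
import pytest

from paam import (
    AgeSexPopulation,
    Hospital,
    Mesh,
    RateTables,
    RegionSpec,
    RoadNetwork,
    generate_region,
)
from paam.domain import N_BANDS, N_SEXES


def make_rates(
    survival=1.0,
    migration=0.0,
    fertility=0.0,
    inpatient=0.0,
    sex_ratio=1.05,
) -> RateTables:
    """Rate tables with scalar values broadcast over every band."""
    fert = np.zeros(N_BANDS)
    fert[3:10] = fertility
    return RateTables(
        fertility=fert,
        sex_ratio_at_birth=sex_ratio,
        survival=np.full((N_SEXES, N_BANDS), float(survival)),
        net_migration=np.full((N_SEXES, N_BANDS), float(migration)),
        inpatient_rate=np.full((N_SEXES, N_BANDS), float(inpatient)),
    )


def uniform_population(per_cell: int = 10) -> AgeSexPopulation:
    return AgeSexPopulation(np.full((N_SEXES, N_BANDS), per_cell, dtype=np.int64))


@pytest.fixture
def rates_identity() -> RateTables:
    """Pure-aging rates: everyone survives, nobody moves or is born."""
    return make_rates(survival=1.0, migration=0.0, fertility=0.0)


@pytest.fixture
def line_network() -> RoadNetwork:
    """Three nodes on a line: A -10min- B -20min- C."""
    return RoadNetwork.from_tables(
        nodes=[("A", 0.0, 0.0), ("B", 10000.0, 0.0), ("C", 30000.0, 0.0)],
        edges=[("A", "B", 10.0), ("B", "C", 20.0)],
    )


@pytest.fixture
def small_region():
    """A 3x3 region with ~3000 people and 3 hospitals, fully reproducible."""
    return generate_region(
        RegionSpec(nx=3, ny=3, total_population=3000, n_hospitals=3, seed=42)
    )


def tiny_spec(seed: int, **kw) -> RegionSpec:
    defaults = dict(nx=3, ny=2, total_population=1500, n_hospitals=2, seed=seed)
    defaults.update(kw)
    return RegionSpec(**defaults)
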