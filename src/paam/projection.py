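"""Cohort-component population projection with per-person sampling.

Each 5-year step applies, in a fixed order: (1) survival, (2) net
migration, (3) aging (shift one band up, top band absorbing), (4) births
entering the bottom band.  In *stochastic* mode every event is drawn per
person (binomial survival and out-migration, Poisson in-migration and
births), so small-area counts fluctuate between samplings; *expected*
mode runs the identical arithmetic on expectations and is the stochastic
mode's deterministic oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .domain import FERTILE_BANDS, N_BANDS, N_SEXES, AgeSexPopulation, Mesh, RateTables
from .rng import key_int, substream

_FEMALE, _MALE = 0, 1


@dataclass
class ProjectionConfig:
    """Projection settings.

    ``apply_newborn_survival`` applies the bottom-band survival rate to
    children born within the step (they are exposed for part of it).
    """

    n_steps: int = 6
    step_years: int = 5
    mode: str = "stochastic"
    seed: int = 0
    apply_newborn_survival: bool = True

    def __post_init__(self) -> None:
        if self.n_steps < 0:
            raise ValueError("n_steps must be >= 0")
        if self.mode not in ("stochastic", "expected"):
            raise ValueError(f"mode must be 'stochastic' or 'expected', got {self.mode!r}")


def project_step(
    population: AgeSexPopulation,
    rates: RateTables,
    config: ProjectionConfig,
    rng: np.random.Generator | None = None,
) -> AgeSexPopulation:
    """Advance one 5-year step (survive -> migrate -> age -> births)."""
    if config.mode == "expected":
        return _step_expected(population, rates, config)
    if rng is None:
        rng = substream(config.seed, "projection")
    return _step_stochastic(population, rates, config, rng)


def _step_expected(
    population: AgeSexPopulation, rates: RateTables, config: ProjectionConfig
) -> AgeSexPopulation:
    counts = population.counts.astype(float)
    survivors = counts * rates.survival
    migrated = survivors * (1.0 + rates.net_migration)
    shifted = np.zeros((N_SEXES, N_BANDS))
    shifted[:, 1:] = migrated[:, :-1]
    shifted[:, -1] += migrated[:, -1]  # 85+ absorbs

    births = float(np.sum(rates.fertility[FERTILE_BANDS] * shifted[_FEMALE, FERTILE_BANDS]))
    sr = rates.sex_ratio_at_birth
    newborn = np.array([births / (1.0 + sr), births * sr / (1.0 + sr)])
    if config.apply_newborn_survival:
        newborn *= rates.survival[:, 0]
    shifted[:, 0] += newborn
    return AgeSexPopulation(shifted, fractional=True)


def _step_stochastic(
    population: AgeSexPopulation,
    rates: RateTables,
    config: ProjectionConfig,
    rng: np.random.Generator,
) -> AgeSexPopulation:
    counts = population.counts.astype(np.int64)
    survivors = rng.binomial(counts, rates.survival)

    migration = rates.net_migration
    inflow = rng.poisson(np.where(migration > 0, migration, 0.0) * survivors)
    outflow = rng.binomial(survivors, np.where(migration < 0, -migration, 0.0))
    migrated = survivors + inflow - outflow

    shifted = np.zeros((N_SEXES, N_BANDS), dtype=np.int64)
    shifted[:, 1:] = migrated[:, :-1]
    shifted[:, -1] += migrated[:, -1]

    mean_births = float(np.sum(rates.fertility[FERTILE_BANDS] * shifted[_FEMALE, FERTILE_BANDS]))
    births = rng.poisson(mean_births)
    sr = rates.sex_ratio_at_birth
    male_births = rng.binomial(births, sr / (1.0 + sr))
    newborn = np.array([births - male_births, male_births], dtype=np.int64)
    if config.apply_newborn_survival:
        newborn = rng.binomial(newborn, rates.survival[:, 0])
    shifted[:, 0] += newborn
    return AgeSexPopulation(shifted)


def project_series(
    meshes: Sequence[Mesh],
    rates: RateTables,
    config: ProjectionConfig,
    sample_index: int = 0,
) -> list[dict[str, AgeSexPopulation]]:
    """Project every mesh forward; returns ``n_steps + 1`` snapshots
    (index 0 is the input populations).

    Each (mesh, step, sample) triple draws from its own RNG substream, so
    results are identical whether meshes are projected together or
    separately and are independent of execution order.
    """
    current: dict[str, AgeSexPopulation] = {m.id: m.population for m in meshes}
    series = [dict(current)]
    for step in range(config.n_steps):
        nxt: dict[str, AgeSexPopulation] = {}
        for mesh_id, pop in current.items():
            rng = (
                substream(config.seed, "projection", sample_index, key_int(mesh_id), step)
                if config.mode == "stochastic"
                else None
            )
            nxt[mesh_id] = project_step(pop, rates, config, rng)
        series.append(nxt)
        current = nxt
    return series


def series_to_frame(
    series: Sequence[Mapping[str, AgeSexPopulation]],
    years: Sequence[int],
    sample_index: int = 0,
):
    """Long-format table (mesh_id, year, sex, age_band, count, sample_index)."""
    import pandas as pd

    from .domain import AGE_BANDS, SEXES

    rows = []
    for snapshot, year in zip(series, years):
        for mesh_id in sorted(snapshot):
            counts = snapshot[mesh_id].counts
            for si, sex in enumerate(SEXES):
                for bi, band in enumerate(AGE_BANDS):
                    rows.append((mesh_id, year, sex, band, counts[si, bi], sample_index))
    return pd.DataFrame(
        rows, columns=["mesh_id", "year", "sex", "age_band", "count", "sample_index"]
    )
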