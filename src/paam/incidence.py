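"""Daily inpatient demand per mesh.

The expected daily inpatient census of a population is

    N = sum over sex s, age band a of
        P[s, a] * r[s, a] * (1 - R_ad) * (1 - D_ad)

where ``r`` is the daily inpatient-care rate (probability a person of
that sex/age is an inpatient on a given day), ``R_ad`` is a scenario
reduction in that rate, and ``D_ad`` is a reduction in average length of
stay — shorter stays lower the apparent number of occupied beds per day
by the same factor.  The stochastic form draws each cell binomially with
the adjusted probability, i.e. per-person Bernoulli sampling.
"""

from __future__ import annotations

import numpy as np

from .domain import AgeSexPopulation, RateTables


def _adjusted_rates(rates: RateTables, r_ad: float, d_ad: float) -> np.ndarray:
    if not 0.0 <= r_ad < 1.0:
        raise ValueError(f"inpatient-rate reduction must be in [0, 1), got {r_ad}")
    if not 0.0 <= d_ad < 1.0:
        raise ValueError(f"ALOS reduction must be in [0, 1), got {d_ad}")
    p = rates.inpatient_rate * (1.0 - r_ad) * (1.0 - d_ad)
    if np.any(p > 1.0):
        raise ValueError("adjusted inpatient probability exceeds 1")
    return p


def expected_inpatients(
    population: AgeSexPopulation,
    rates: RateTables,
    r_ad: float = 0.0,
    d_ad: float = 0.0,
) -> float:
    """Expected daily inpatient count (real-valued)."""
    p = _adjusted_rates(rates, r_ad, d_ad)
    return float(np.sum(population.counts * p))


def sample_inpatients(
    population: AgeSexPopulation,
    rates: RateTables,
    r_ad: float = 0.0,
    d_ad: float = 0.0,
    rng: np.random.Generator | None = None,
) -> int:
    """One stochastic realisation of the daily inpatient count.

    Each person is an inpatient with the adjusted per-cell probability;
    the result never exceeds the population total.
    """
    if rng is None:
        rng = np.random.default_rng()
    p = _adjusted_rates(rates, r_ad, d_ad)
    counts = population.counts.astype(np.int64)
    return int(rng.binomial(counts, p).sum())
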