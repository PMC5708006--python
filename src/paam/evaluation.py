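"""Scenario orchestration: project, sample, allocate, aggregate.

A scenario run repeats, ``n_samples`` times: project every mesh's
population across the year grid, draw the day's inpatients per mesh,
and allocate them to beds within each mesh's Patient Access Area.
Aggregates are means (and standard deviations) over samplings of total
patients, total over-demand and total over-supply per year, plus
per-mesh mean over-demand and per-hospital mean vacancy — the inputs
for choropleth-style over-demand maps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .allocation import allocate
from .domain import Hospital, Mesh, RateTables, Scenario, available_beds
from .incidence import sample_inpatients
from .network import PAA, RoadNetwork, TravelTimeMatrix, build_travel_matrix, compute_paa
from .projection import ProjectionConfig, project_series
from .rng import key_int, substream

#: Policy scenarios: current projection and two improvement scenarios in
#: which the inpatient-care rate and average length of stay each fall by
#: 5% / 10% while bed utilization rises to 85% / 90%.
DEFAULT_SCENARIOS: tuple[Scenario, ...] = (
    Scenario("Ex.1 current projection", 0.00, 0.00, utilization_rate=0.80),
    Scenario("Ex.2 5% improvement", 0.05, 0.05, utilization_rate=0.85),
    Scenario("Ex.3 10% improvement", 0.10, 0.10, utilization_rate=0.90),
)

#: Default year grid: seven points spaced five years apart.
DEFAULT_YEARS: tuple[int, ...] = tuple(range(2010, 2041, 5))


@dataclass
class Region:
    """A study region: meshes, hospital registry, rate tables, road network."""

    meshes: list[Mesh]
    hospitals: list[Hospital]
    rates: RateTables
    network: RoadNetwork | None = None
    mesh_size_m: float = 500.0

    def __post_init__(self) -> None:
        mesh_ids = [m.id for m in self.meshes]
        if len(set(mesh_ids)) != len(mesh_ids):
            raise ValueError("duplicate mesh ids")
        hosp_ids = [h.id for h in self.hospitals]
        if len(set(hosp_ids)) != len(hosp_ids):
            raise ValueError("duplicate hospital ids")


@dataclass
class ScenarioSuite:
    """A set of scenarios to compare on one region and year grid."""

    scenarios: Sequence[Scenario]
    years: Sequence[int] = DEFAULT_YEARS

    def __post_init__(self) -> None:
        names = [s.name for s in self.scenarios]
        if len(set(names)) != len(names):
            raise ValueError("scenario names must be unique")


@dataclass
class ScenarioResult:
    """Aggregated outcome of one scenario.

    ``totals`` is indexed by year with mean/std columns for patients,
    over-demand and over-supply; ``mesh_overdemand`` and
    ``hospital_vacancy`` hold per-entity means (rows) by year (columns).
    """

    scenario: Scenario
    years: tuple[int, ...]
    totals: pd.DataFrame
    mesh_overdemand: pd.DataFrame
    hospital_vacancy: pd.DataFrame

    @property
    def first_overdemand_year(self) -> int | None:
        """First year whose mean over-demand is positive; None if never."""
        for year in self.years:
            if self.totals.loc[year, "overdemand_mean"] > 0:
                return int(year)
        return None


def _capacities(hospitals: Sequence[Hospital], scenario: Scenario) -> dict[str, int]:
    return {
        h.id: available_beds(h, scenario.utilization_rate, scenario.external_bed_fraction)
        for h in hospitals
    }


def run_scenario(
    region: Region,
    scenario: Scenario,
    years: Sequence[int] = DEFAULT_YEARS,
    *,
    matrix: TravelTimeMatrix | None = None,
    strategy: str = "size_first",
    reuse_projection: bool = False,
    travel_mode: str = "network",
) -> ScenarioResult:
    """Run one scenario over the year grid with repeated sampling.

    ``reuse_projection`` is a variance-reduction option that projects the
    population once (sample 0's streams) and re-samples only incidence
    and allocation.
    """
    if not region.meshes or not region.hospitals:
        raise ValueError("region must contain meshes and hospitals")
    if len(years) < 1:
        raise ValueError("years must be non-empty")
    years = tuple(int(y) for y in years)

    if matrix is None:
        matrix = build_travel_matrix(
            region.meshes, region.hospitals, region.network, mode=travel_mode
        )
    paa = compute_paa(matrix, scenario.paa_threshold_minutes)

    mesh_ids = [m.id for m in region.meshes]
    hosp_ids = [h.id for h in region.hospitals]
    n_years, n_samples = len(years), scenario.n_samples

    tot_patients = np.zeros((n_samples, n_years))
    tot_overdemand = np.zeros((n_samples, n_years))
    tot_oversupply = np.zeros((n_samples, n_years))
    mesh_od = np.zeros((len(mesh_ids), n_years))
    hosp_vac = np.zeros((len(hosp_ids), n_years))

    config = ProjectionConfig(n_steps=n_years - 1, mode="stochastic", seed=scenario.seed)
    shared_series = project_series(region.meshes, region.rates, config, sample_index=0)

    for s in range(n_samples):
        series = (
            shared_series
            if reuse_projection
            else (
                shared_series
                if s == 0
                else project_series(region.meshes, region.rates, config, sample_index=s)
            )
        )
        for yi, year in enumerate(years):
            snapshot = series[yi]
            loads = {
                mid: sample_inpatients(
                    snapshot[mid],
                    region.rates,
                    scenario.inpatient_rate_reduction,
                    scenario.alos_reduction,
                    substream(scenario.seed, "patients", s, yi, key_int(mid)),
                )
                for mid in mesh_ids
            }
            result = allocate(
                loads,
                paa,
                region.hospitals,
                matrix,
                scenario,
                rng=substream(scenario.seed, "allocation", s, yi),
                strategy=strategy,
                sample_index=s,
                year=year,
            )
            tot_patients[s, yi] = sum(loads.values())
            tot_overdemand[s, yi] = result.total_overdemand
            tot_oversupply[s, yi] = result.total_oversupply
            mesh_od[:, yi] += [result.unallocated[m] for m in mesh_ids]
            vac = result.vacant
            hosp_vac[:, yi] += [vac[h] for h in hosp_ids]

    totals = pd.DataFrame(
        {
            "patients_mean": tot_patients.mean(axis=0),
            "patients_std": tot_patients.std(axis=0, ddof=0),
            "overdemand_mean": tot_overdemand.mean(axis=0),
            "overdemand_std": tot_overdemand.std(axis=0, ddof=0),
            "oversupply_mean": tot_oversupply.mean(axis=0),
            "oversupply_std": tot_oversupply.std(axis=0, ddof=0),
        },
        index=pd.Index(years, name="year"),
    )
    mesh_df = pd.DataFrame(
        mesh_od / n_samples, index=pd.Index(mesh_ids, name="mesh_id"), columns=years
    )
    hosp_df = pd.DataFrame(
        hosp_vac / n_samples, index=pd.Index(hosp_ids, name="hospital_id"), columns=years
    )
    return ScenarioResult(scenario, years, totals, mesh_df, hosp_df)


@dataclass
class ScenarioComparison:
    """Aligned per-year scenario means plus each scenario's onset year."""

    table: pd.DataFrame  # year x scenario, mean over-demand
    patients: pd.DataFrame  # year x scenario, mean patients
    first_overdemand_year: dict[str, int | None]
    results: dict[str, ScenarioResult]


def compare_scenarios(
    region: Region,
    suite: ScenarioSuite,
    *,
    strategy: str = "size_first",
    travel_mode: str = "network",
) -> ScenarioComparison:
    """Run every scenario of the suite on one region and align the means."""
    if len(suite.scenarios) < 2:
        raise ValueError("a comparison needs at least two scenarios")
    matrix = build_travel_matrix(
        region.meshes, region.hospitals, region.network, mode=travel_mode
    )
    results: dict[str, ScenarioResult] = {}
    for scenario in suite.scenarios:
        results[scenario.name] = run_scenario(
            region, scenario, suite.years, matrix=matrix, strategy=strategy
        )
    table = pd.DataFrame(
        {name: r.totals["overdemand_mean"] for name, r in results.items()}
    )
    patients = pd.DataFrame(
        {name: r.totals["patients_mean"] for name, r in results.items()}
    )
    first = {name: r.first_overdemand_year for name, r in results.items()}
    return ScenarioComparison(table, patients, first, results)


def export_overdemand_map(
    values: Mapping[str, float],
    meshes: Sequence[Mesh],
    path,
    mesh_size_m: float = 500.0,
    property_name: str = "mean_over_demand",
) -> None:
    """Write a GeoJSON FeatureCollection of mesh squares carrying the
    per-mesh mean over-demand, ready for choropleth rendering."""
    from shapely.geometry import box, mapping

    mesh_ids = {m.id for m in meshes}
    unknown = set(values) - mesh_ids
    if unknown:
        raise ValueError(f"over-demand values for unknown meshes: {sorted(unknown)[:5]}")
    half = mesh_size_m / 2.0
    features = []
    for m in meshes:
        geom = box(m.x - half, m.y - half, m.x + half, m.y + half)
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(geom),
                "properties": {"mesh_id": m.id, property_name: float(values.get(m.id, 0.0))},
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh, indent=None)


def read_overdemand_map(path, property_name: str = "mean_over_demand") -> dict[str, float]:
    """Read back a map written by :func:`export_overdemand_map`."""
    with open(path) as fh:
        data = json.load(fh)
    return {
        f["properties"]["mesh_id"]: float(f["properties"][property_name])
        for f in data["features"]
    }
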