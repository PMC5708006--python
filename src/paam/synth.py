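"""Synthetic region generator.

Produces a complete, reproducible study region — gridded meshes with
age-by-sex populations, a hospital registry, demographic / inpatient
rate tables, and a grid road network — so that the whole pipeline can be
exercised without any external census, hospital-registry or map data.

The default parameters sketch an aged, low-fertility society: roughly a
third of residents aged 60+, total fertility around 1.2 children per
woman, mild out-migration of young adults, a daily inpatient prevalence
near 1% that rises steeply with age, and a bed stock of roughly 12-16
beds per 1,000 residents concentrated in small hospitals.  They are
plain parameters, not any country's vital statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .domain import (
    AGE_BANDS,
    N_BANDS,
    N_SEXES,
    AgeSexPopulation,
    Hospital,
    Mesh,
    RateTables,
)
from .network import RoadNetwork
from .rng import substream

_PYRAMID_RAW = np.array(
    [3.8, 3.9, 4.1, 4.4, 4.8, 5.2, 5.6, 6.0, 6.6, 7.2, 6.8, 6.2,
     7.0, 7.4, 6.4, 5.0, 3.6, 3.0]
)
#: Aged-society age pyramid (fractions over the 18 bands, sums to 1).
DEFAULT_AGE_PYRAMID = _PYRAMID_RAW / _PYRAMID_RAW.sum()

#: Hospital size mixture: (weight, (min_beds, max_beds)) per class.
#: Expected bed stock ~65 beds/hospital, i.e. ~12.5 beds per 1,000
#: residents for the default 50k-person, 10-hospital region.
DEFAULT_BED_MIX: dict[str, tuple[float, tuple[int, int]]] = {
    "small": (0.90, (20, 90)),
    "medium": (0.09, (101, 160)),
    "large": (0.01, (400, 420)),
}


def default_rate_tables() -> RateTables:
    """Aged-society demographic and inpatient rates (per 5-year step)."""
    fertility = np.zeros(N_BANDS)
    # births per woman per 5-year step, bands 15-19 .. 45-49 (TFR ~ 1.2)
    fertility[3:10] = [0.010, 0.150, 0.350, 0.400, 0.225, 0.050, 0.003]

    survival_f = [0.998, 0.9995, 0.9995, 0.999, 0.999, 0.998, 0.997, 0.996,
                  0.995, 0.992, 0.988, 0.981, 0.970, 0.950, 0.920, 0.865,
                  0.780, 0.600]
    survival_m = [0.998, 0.9995, 0.999, 0.998, 0.998, 0.997, 0.996, 0.994,
                  0.992, 0.988, 0.981, 0.970, 0.952, 0.925, 0.880, 0.800,
                  0.680, 0.480]

    migration = np.zeros((N_SEXES, N_BANDS))
    migration[:, 3:6] = -0.02  # young-adult outflow

    inpatient_f = [0.0020, 0.0008, 0.0008, 0.0010, 0.0014, 0.0016, 0.0016,
                   0.0018, 0.0022, 0.0030, 0.0042, 0.0060, 0.0085, 0.0120,
                   0.0180, 0.0270, 0.0420, 0.0700]
    inpatient_m = [0.0025, 0.0009, 0.0008, 0.0010, 0.0012, 0.0014, 0.0016,
                   0.0020, 0.0026, 0.0036, 0.0052, 0.0075, 0.0105, 0.0150,
                   0.0220, 0.0320, 0.0480, 0.0750]

    return RateTables(
        fertility=fertility,
        sex_ratio_at_birth=1.05,
        survival=np.array([survival_f, survival_m]),
        net_migration=migration,
        inpatient_rate=np.array([inpatient_f, inpatient_m]),
    )


@dataclass
class RegionSpec:
    """Parameters of a synthetic study region."""

    nx: int = 20
    ny: int = 20
    mesh_size_m: float = 500.0
    total_population: int = 50_000
    age_pyramid: np.ndarray = field(default_factory=lambda: DEFAULT_AGE_PYRAMID.copy())
    sex_split: float = 0.51  # fraction female
    n_hospitals: int = 10
    bed_mix: Mapping[str, tuple[float, tuple[int, int]]] = field(
        default_factory=lambda: dict(DEFAULT_BED_MIX)
    )
    hospital_placement: str = "population_weighted"
    network_speed_kmh: float = 40.0
    seed: int = 0
    # spatial density: Gaussian urban core over a uniform floor; an explicit
    # per-mesh weight vector overrides it (useful for degenerate layouts)
    density_sigma_fraction: float = 0.25
    density_floor: float = 0.10
    mesh_weights: np.ndarray | None = None
    # optional topology degradation: fraction of road edges removed at random,
    # creating access-poor pockets
    drop_edge_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.nx < 1 or self.ny < 1:
            raise ValueError("grid must contain at least one mesh")
        if self.mesh_size_m <= 0:
            raise ValueError("mesh_size_m must be positive")
        if self.total_population < 0:
            raise ValueError("total_population must be non-negative")
        self.age_pyramid = np.asarray(self.age_pyramid, dtype=float)
        if self.age_pyramid.shape != (N_BANDS,):
            raise ValueError(f"age_pyramid must have {N_BANDS} entries")
        if abs(self.age_pyramid.sum() - 1.0) > 1e-9 or np.any(self.age_pyramid < 0):
            raise ValueError("age_pyramid must be non-negative and sum to 1")
        if not 0.0 <= self.sex_split <= 1.0:
            raise ValueError("sex_split must be in [0, 1]")
        if self.n_hospitals < 0:
            raise ValueError("n_hospitals must be non-negative")
        weights = [w for w, _ in self.bed_mix.values()]
        if abs(sum(weights) - 1.0) > 1e-9 or any(w < 0 for w in weights):
            raise ValueError("bed_mix weights must be non-negative and sum to 1")
        for cls, (_, (lo, hi)) in self.bed_mix.items():
            if lo < 1 or hi < lo:
                raise ValueError(f"bed_mix range for {cls!r} is invalid")
        if self.hospital_placement not in ("population_weighted", "uniform"):
            raise ValueError("hospital_placement must be population_weighted or uniform")
        if self.network_speed_kmh <= 0:
            raise ValueError("network_speed_kmh must be positive")
        if not 0.0 <= self.drop_edge_fraction < 1.0:
            raise ValueError("drop_edge_fraction must be in [0, 1)")
        if self.mesh_weights is not None:
            self.mesh_weights = np.asarray(self.mesh_weights, dtype=float)
            if self.mesh_weights.shape != (self.nx * self.ny,):
                raise ValueError("mesh_weights must have nx*ny entries")
            if np.any(self.mesh_weights < 0) or self.mesh_weights.sum() <= 0:
                raise ValueError("mesh_weights must be non-negative with positive sum")


def _mesh_density(spec: RegionSpec) -> np.ndarray:
    """Per-mesh population weights (urban core + uniform floor), sum 1."""
    if spec.mesh_weights is not None:
        w = spec.mesh_weights
        return w / w.sum()
    ix, iy = np.meshgrid(np.arange(spec.nx), np.arange(spec.ny), indexing="ij")
    cx, cy = (spec.nx - 1) / 2.0, (spec.ny - 1) / 2.0
    extent = max(spec.nx, spec.ny)
    sigma = max(spec.density_sigma_fraction * extent, 1e-9)
    core = np.exp(-((ix - cx) ** 2 + (iy - cy) ** 2) / (2.0 * sigma**2))
    w = (core + spec.density_floor).ravel()
    return w / w.sum()


def _mesh_id(ix: int, iy: int) -> str:
    return f"m{ix:03d}_{iy:03d}"


def _node_id(ix: int, iy: int) -> str:
    return f"n{ix:03d}_{iy:03d}"


def generate_region(spec: RegionSpec):
    """Generate (meshes, hospitals, rate tables, road network) from a spec.

    The grand population total equals ``spec.total_population`` exactly
    (one multinomial draw over every mesh x sex x band cell); everything
    is reproducible from ``spec.seed``.
    """
    from .evaluation import Region  # local import to avoid a cycle

    rng = substream(spec.seed, "synth")
    n_mesh = spec.nx * spec.ny

    # population: single multinomial over (mesh, sex, band) cells
    density = _mesh_density(spec)
    sex_p = np.array([spec.sex_split, 1.0 - spec.sex_split])
    cell_p = density[:, None, None] * sex_p[None, :, None] * spec.age_pyramid[None, None, :]
    cell_p = cell_p.ravel()
    cell_p = cell_p / cell_p.sum()
    counts = rng.multinomial(spec.total_population, cell_p).reshape(
        n_mesh, N_SEXES, N_BANDS
    )

    meshes: list[Mesh] = []
    for k in range(n_mesh):
        ix, iy = divmod(k, spec.ny)
        meshes.append(
            Mesh(
                id=_mesh_id(ix, iy),
                x=(ix + 0.5) * spec.mesh_size_m,
                y=(iy + 0.5) * spec.mesh_size_m,
                population=AgeSexPopulation(counts[k]),
            )
        )

    # hospitals
    if spec.hospital_placement == "population_weighted":
        totals = counts.sum(axis=(1, 2)).astype(float)
        placement_p = totals / totals.sum() if totals.sum() > 0 else np.full(n_mesh, 1.0 / n_mesh)
    else:
        placement_p = np.full(n_mesh, 1.0 / n_mesh)
    classes = list(spec.bed_mix)
    class_w = np.array([spec.bed_mix[c][0] for c in classes])
    hospitals: list[Hospital] = []
    for h in range(spec.n_hospitals):
        k = int(rng.choice(n_mesh, p=placement_p))
        cls = classes[int(rng.choice(len(classes), p=class_w))]
        lo, hi = spec.bed_mix[cls][1]
        beds = int(rng.integers(lo, hi + 1))
        hospitals.append(
            Hospital(
                id=f"h{h:03d}",
                x=meshes[k].x,
                y=meshes[k].y,
                total_beds=beds,
                in_region=True,
            )
        )

    # 4-connected grid road network over mesh centroids
    edge_minutes = spec.mesh_size_m / 1000.0 / spec.network_speed_kmh * 60.0
    nodes = [(_node_id(ix, iy), (ix + 0.5) * spec.mesh_size_m, (iy + 0.5) * spec.mesh_size_m)
             for ix in range(spec.nx) for iy in range(spec.ny)]
    edges: list[tuple[str, str, float]] = []
    for ix in range(spec.nx):
        for iy in range(spec.ny):
            if ix + 1 < spec.nx:
                edges.append((_node_id(ix, iy), _node_id(ix + 1, iy), edge_minutes))
            if iy + 1 < spec.ny:
                edges.append((_node_id(ix, iy), _node_id(ix, iy + 1), edge_minutes))
    if spec.drop_edge_fraction > 0 and edges:
        keep = rng.random(len(edges)) >= spec.drop_edge_fraction
        edges = [e for e, k in zip(edges, keep) if k]
    network = RoadNetwork.from_tables(nodes, edges)

    return Region(
        meshes=meshes,
        hospitals=hospitals,
        rates=default_rate_tables(),
        network=network,
        mesh_size_m=spec.mesh_size_m,
    )
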