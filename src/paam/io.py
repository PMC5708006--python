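"""Readers and writers for the simulator's tabular and geospatial formats.

All tabular inputs are plain CSV; mesh geometry can additionally round-trip
through GeoJSON (one square polygon per mesh).  Readers validate the
domain invariants (unique ids, non-negative counts, rates in range) and
raise :class:`ParseError` on violations, so that a region directory read
back from disk is always a valid :class:`~paam.evaluation.Region`.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .domain import (
    AGE_BANDS,
    N_BANDS,
    N_SEXES,
    SEXES,
    AgeSexPopulation,
    Hospital,
    Mesh,
    RateTables,
)
from .network import RoadNetwork, TravelTimeMatrix


class ParseError(ValueError):
    """An input file violates its column contract or a domain invariant."""


def _band_token(band: str) -> str:
    return band.replace("-", "_").replace("+", "plus")


_POP_COLUMNS = [
    f"pop_{sex[0]}_{_band_token(band)}" for sex in SEXES for band in AGE_BANDS
]

# ---------------------------------------------------------------- meshes


def write_meshes(meshes: Sequence[Mesh], path) -> None:
    rows = []
    for m in meshes:
        row = {"mesh_id": m.id, "x": m.x, "y": m.y}
        row.update(dict(zip(_POP_COLUMNS, m.population.counts.ravel().tolist())))
        rows.append(row)
    pd.DataFrame(rows, columns=["mesh_id", "x", "y", *_POP_COLUMNS]).to_csv(
        path, index=False
    )


def read_meshes(path) -> list[Mesh]:
    df = pd.read_csv(path, dtype={"mesh_id": str})
    missing = {"mesh_id", "x", "y", *_POP_COLUMNS} - set(df.columns)
    if missing:
        raise ParseError(f"mesh file {path}: missing columns {sorted(missing)}")
    if df["mesh_id"].duplicated().any():
        dupes = df.loc[df["mesh_id"].duplicated(), "mesh_id"].tolist()
        raise ParseError(f"mesh file {path}: duplicate mesh ids {dupes[:5]}")
    meshes = []
    for _, row in df.iterrows():
        counts = np.array([row[c] for c in _POP_COLUMNS], dtype=float)
        if np.any(counts < 0):
            raise ParseError(f"mesh file {path}: negative population in {row['mesh_id']!r}")
        if not np.all(np.equal(np.mod(counts, 1), 0)):
            raise ParseError(f"mesh file {path}: non-integral population in {row['mesh_id']!r}")
        try:
            meshes.append(
                Mesh(
                    id=row["mesh_id"],
                    x=float(row["x"]),
                    y=float(row["y"]),
                    population=AgeSexPopulation(
                        counts.astype(np.int64).reshape(N_SEXES, N_BANDS)
                    ),
                )
            )
        except ValueError as exc:
            raise ParseError(f"mesh file {path}: {exc}") from exc
    return meshes


def write_meshes_geojson(meshes: Sequence[Mesh], path, mesh_size_m: float = 500.0) -> None:
    """One square Polygon per mesh with the population vector as properties."""
    from shapely.geometry import box, mapping

    half = mesh_size_m / 2.0
    features = []
    for m in meshes:
        props = {"mesh_id": m.id, "x": m.x, "y": m.y}
        props.update(dict(zip(_POP_COLUMNS, m.population.counts.ravel().tolist())))
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(box(m.x - half, m.y - half, m.x + half, m.y + half)),
                "properties": props,
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_meshes_geojson(path) -> list[Mesh]:
    with open(path) as fh:
        data = json.load(fh)
    meshes, seen = [], set()
    for feat in data.get("features", []):
        props = feat["properties"]
        if not {"mesh_id", "x", "y", *_POP_COLUMNS} <= set(props):
            raise ParseError(f"geojson {path}: feature missing required properties")
        if props["mesh_id"] in seen:
            raise ParseError(f"geojson {path}: duplicate mesh id {props['mesh_id']!r}")
        seen.add(props["mesh_id"])
        counts = np.array([props[c] for c in _POP_COLUMNS], dtype=float)
        if np.any(counts < 0):
            raise ParseError(f"geojson {path}: negative population")
        meshes.append(
            Mesh(
                id=props["mesh_id"],
                x=float(props["x"]),
                y=float(props["y"]),
                population=AgeSexPopulation(
                    counts.astype(np.int64).reshape(N_SEXES, N_BANDS)
                ),
            )
        )
    return meshes


# -------------------------------------------------------------- hospitals


def write_hospitals(hospitals: Sequence[Hospital], path) -> None:
    pd.DataFrame(
        [
            {
                "hospital_id": h.id,
                "x": h.x,
                "y": h.y,
                "total_beds": h.total_beds,
                "in_region": h.in_region,
            }
            for h in hospitals
        ],
        columns=["hospital_id", "x", "y", "total_beds", "in_region"],
    ).to_csv(path, index=False)


def read_hospitals(path) -> list[Hospital]:
    df = pd.read_csv(path, dtype={"hospital_id": str})
    missing = {"hospital_id", "x", "y", "total_beds", "in_region"} - set(df.columns)
    if missing:
        raise ParseError(f"hospital file {path}: missing columns {sorted(missing)}")
    if df["hospital_id"].duplicated().any():
        raise ParseError(f"hospital file {path}: duplicate hospital ids")
    hospitals = []
    for _, row in df.iterrows():
        try:
            hospitals.append(
                Hospital(
                    id=row["hospital_id"],
                    x=float(row["x"]),
                    y=float(row["y"]),
                    total_beds=int(row["total_beds"]),
                    in_region=bool(row["in_region"]),
                )
            )
        except ValueError as exc:
            raise ParseError(f"hospital file {path}: {exc}") from exc
    return hospitals


# ------------------------------------------------------------ rate tables


def write_rate_tables(rates: RateTables, path) -> None:
    """One row per sex x age band; fertility populated only on the female
    reproductive bands; the scalar sex ratio at birth repeated per row."""
    rows = []
    for si, sex in enumerate(SEXES):
        for bi, band in enumerate(AGE_BANDS):
            fert = rates.fertility[bi] if (si == 0 and 3 <= bi <= 9) else ""
            rows.append(
                {
                    "sex": sex,
                    "age_band": band,
                    "fertility": fert,
                    "survival": rates.survival[si, bi],
                    "net_migration": rates.net_migration[si, bi],
                    "inpatient_rate": rates.inpatient_rate[si, bi],
                    "sex_ratio_at_birth": rates.sex_ratio_at_birth,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_rate_tables(path) -> RateTables:
    df = pd.read_csv(path, dtype={"sex": str, "age_band": str})
    required = {
        "sex", "age_band", "fertility", "survival",
        "net_migration", "inpatient_rate", "sex_ratio_at_birth",
    }
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"rate file {path}: missing columns {sorted(missing)}")
    fertility = np.zeros(N_BANDS)
    survival = np.full((N_SEXES, N_BANDS), np.nan)
    migration = np.full((N_SEXES, N_BANDS), np.nan)
    inpatient = np.full((N_SEXES, N_BANDS), np.nan)
    band_index = {b: i for i, b in enumerate(AGE_BANDS)}
    sex_index = {s: i for i, s in enumerate(SEXES)}
    for _, row in df.iterrows():
        if row["sex"] not in sex_index or row["age_band"] not in band_index:
            raise ParseError(
                f"rate file {path}: unknown sex/age band {row['sex']!r}/{row['age_band']!r}"
            )
        si, bi = sex_index[row["sex"]], band_index[row["age_band"]]
        survival[si, bi] = row["survival"]
        migration[si, bi] = row["net_migration"]
        inpatient[si, bi] = row["inpatient_rate"]
        if si == 0 and not pd.isna(row["fertility"]):
            fertility[bi] = row["fertility"]
    if np.any(np.isnan(survival)) or np.any(np.isnan(migration)) or np.any(np.isnan(inpatient)):
        raise ParseError(f"rate file {path}: missing sex x age band rows")
    try:
        return RateTables(
            fertility=fertility,
            sex_ratio_at_birth=float(df["sex_ratio_at_birth"].iloc[0]),
            survival=survival,
            net_migration=migration,
            inpatient_rate=inpatient,
        )
    except ValueError as exc:
        raise ParseError(f"rate file {path}: {exc}") from exc


# ---------------------------------------------------------------- network


def write_network(network: RoadNetwork, nodes_path, edges_path) -> None:
    g = network.graph
    pd.DataFrame(
        [{"node_id": n, "x": g.nodes[n]["x"], "y": g.nodes[n]["y"]} for n in sorted(g.nodes)],
        columns=["node_id", "x", "y"],
    ).to_csv(nodes_path, index=False)
    pd.DataFrame(
        [
            {"node_a": a, "node_b": b, "minutes": g.edges[a, b]["minutes"]}
            for a, b in sorted(map(lambda e: tuple(sorted(e)), g.edges))
        ],
        columns=["node_a", "node_b", "minutes"],
    ).to_csv(edges_path, index=False)


def read_network(nodes_path, edges_path) -> RoadNetwork:
    nodes = pd.read_csv(nodes_path, dtype={"node_id": str})
    edges = pd.read_csv(edges_path, dtype={"node_a": str, "node_b": str})
    if {"node_id", "x", "y"} - set(nodes.columns):
        raise ParseError(f"node file {nodes_path}: missing columns")
    if {"node_a", "node_b", "minutes"} - set(edges.columns):
        raise ParseError(f"edge file {edges_path}: missing columns")
    if nodes["node_id"].duplicated().any():
        raise ParseError(f"node file {nodes_path}: duplicate node ids")
    try:
        return RoadNetwork.from_tables(
            nodes.itertuples(index=False),
            edges.itertuples(index=False),
        )
    except ValueError as exc:
        raise ParseError(f"network ({nodes_path}, {edges_path}): {exc}") from exc


# ------------------------------------------------------------ travel matrix


def write_travel_matrix(matrix: TravelTimeMatrix, path) -> None:
    pd.DataFrame(
        matrix.minutes,
        index=pd.Index(matrix.mesh_ids, name="mesh_id"),
        columns=matrix.hospital_ids,
    ).to_csv(path)


def read_travel_matrix(path) -> TravelTimeMatrix:
    df = pd.read_csv(path, index_col="mesh_id")
    return TravelTimeMatrix(
        tuple(df.index.astype(str)), tuple(df.columns.astype(str)), df.to_numpy(float)
    )


# ---------------------------------------------------------- region bundles

_REGION_FILES = ("meshes.csv", "hospitals.csv", "rates.csv", "nodes.csv", "edges.csv")


def save_region(region, out_dir) -> None:
    """Write a region as the five-file directory the CLI consumes."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_meshes(region.meshes, out / "meshes.csv")
    write_hospitals(region.hospitals, out / "hospitals.csv")
    write_rate_tables(region.rates, out / "rates.csv")
    if region.network is not None:
        write_network(region.network, out / "nodes.csv", out / "edges.csv")


def load_region(region_dir):
    """Read a region directory written by :func:`save_region`."""
    from .evaluation import Region

    d = Path(region_dir)
    for name in ("meshes.csv", "hospitals.csv", "rates.csv"):
        if not (d / name).exists():
            raise ParseError(f"region directory {d}: missing {name}")
    network = None
    if (d / "nodes.csv").exists() and (d / "edges.csv").exists():
        network = read_network(d / "nodes.csv", d / "edges.csv")
    return Region(
        meshes=read_meshes(d / "meshes.csv"),
        hospitals=read_hospitals(d / "hospitals.csv"),
        rates=read_rate_tables(d / "rates.csv"),
        network=network,
    )
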