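"""Travel times on a road network and Patient Access Areas (PAAs).

A Patient Access Area is the isochrone-style access set induced by a
travel-time threshold: viewed from a mesh, the hospitals reachable
within the threshold; viewed from a hospital, the meshes it serves.
Travel times are shortest-path minutes on an undirected road network;
mesh centroids and hospital locations are snapped to their nearest
network node.  A *direct* mode bypasses the network and uses
straight-line distance at a configured speed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .domain import Hospital, Mesh

UNREACHABLE = math.inf


@dataclass
class RoadNetwork:
    """Undirected road graph: nodes with planar coordinates, edges with
    positive travel minutes.  The graph may be disconnected; disconnection
    is meaningful (inaccessible meshes), not an error."""

    graph: nx.Graph

    def __post_init__(self) -> None:
        for node, data in self.graph.nodes(data=True):
            if "x" not in data or "y" not in data:
                raise ValueError(f"node {node!r} lacks x/y coordinates")
        for a, b, data in self.graph.edges(data=True):
            minutes = data.get("minutes")
            if minutes is None or not math.isfinite(minutes) or minutes <= 0:
                raise ValueError(f"edge ({a!r}, {b!r}) has invalid minutes {minutes!r}")

    @classmethod
    def from_tables(
        cls,
        nodes: Iterable[tuple[str, float, float]],
        edges: Iterable[tuple[str, str, float]],
    ) -> "RoadNetwork":
        g = nx.Graph()
        for node_id, x, y in nodes:
            g.add_node(node_id, x=float(x), y=float(y))
        for a, b, minutes in edges:
            if a not in g or b not in g:
                raise ValueError(f"edge ({a!r}, {b!r}) references unknown node")
            g.add_edge(a, b, minutes=float(minutes))
        return cls(g)

    def nearest_node(self, x: float, y: float) -> str:
        """Nearest node by Euclidean distance; ties break to the lowest id."""
        if self.graph.number_of_nodes() == 0:
            raise ValueError("network has no nodes")
        ids = sorted(self.graph.nodes)
        coords = np.array([(self.graph.nodes[n]["x"], self.graph.nodes[n]["y"]) for n in ids])
        d2 = (coords[:, 0] - x) ** 2 + (coords[:, 1] - y) ** 2
        return ids[int(np.argmin(d2))]


def shortest_travel_time(network: RoadNetwork, origin: str, destination: str) -> float:
    """Minimum total minutes from ``origin`` to ``destination``.

    Returns ``math.inf`` when no path exists.
    """
    g = network.graph
    if origin not in g:
        raise ValueError(f"unknown origin node {origin!r}")
    if destination not in g:
        raise ValueError(f"unknown destination node {destination!r}")
    try:
        return float(nx.dijkstra_path_length(g, origin, destination, weight="minutes"))
    except nx.NetworkXNoPath:
        return UNREACHABLE


@dataclass
class TravelTimeMatrix:
    """Mesh-by-hospital travel minutes; ``inf`` marks unreachable pairs."""

    mesh_ids: tuple[str, ...]
    hospital_ids: tuple[str, ...]
    minutes: np.ndarray

    def __post_init__(self) -> None:
        self.minutes = np.asarray(self.minutes, dtype=float)
        if self.minutes.shape != (len(self.mesh_ids), len(self.hospital_ids)):
            raise ValueError("minutes shape does not match id lists")
        if np.any(self.minutes < 0) or np.any(np.isnan(self.minutes)):
            raise ValueError("travel minutes must be non-negative (inf = unreachable)")
        self._mesh_index = {m: i for i, m in enumerate(self.mesh_ids)}
        self._hospital_index = {h: j for j, h in enumerate(self.hospital_ids)}

    def lookup(self, mesh_id: str, hospital_id: str) -> float:
        return float(self.minutes[self._mesh_index[mesh_id], self._hospital_index[hospital_id]])


def build_travel_matrix(
    meshes: Sequence[Mesh],
    hospitals: Sequence[Hospital],
    network: RoadNetwork | None = None,
    *,
    mode: str = "network",
    speed_kmh: float = 40.0,
) -> TravelTimeMatrix:
    """Travel minutes from every mesh centroid to every hospital.

    ``network`` mode snaps each centroid/location to its nearest network
    node and uses shortest-path minutes (one Dijkstra sweep per hospital
    node).  ``direct`` mode uses Euclidean distance at ``speed_kmh``.
    """
    if not meshes or not hospitals:
        raise ValueError("meshes and hospitals must be non-empty")
    mesh_ids = tuple(m.id for m in meshes)
    hospital_ids = tuple(h.id for h in hospitals)

    if mode == "direct":
        mx = np.array([[m.x, m.y] for m in meshes])
        hx = np.array([[h.x, h.y] for h in hospitals])
        dist_m = np.hypot(
            mx[:, None, 0] - hx[None, :, 0], mx[:, None, 1] - hx[None, :, 1]
        )
        minutes = dist_m / 1000.0 / speed_kmh * 60.0
        return TravelTimeMatrix(mesh_ids, hospital_ids, minutes)

    if mode != "network":
        raise ValueError(f"unknown mode {mode!r}")
    if network is None or network.graph.number_of_nodes() == 0:
        raise ValueError("network mode requires a non-empty RoadNetwork")

    mesh_nodes = [network.nearest_node(m.x, m.y) for m in meshes]
    hosp_nodes = [network.nearest_node(h.x, h.y) for h in hospitals]
    minutes = np.full((len(meshes), len(hospitals)), UNREACHABLE)
    # one single-source sweep per distinct hospital node
    for node in set(hosp_nodes):
        lengths = nx.single_source_dijkstra_path_length(
            network.graph, node, weight="minutes"
        )
        col = np.array([lengths.get(mn, UNREACHABLE) for mn in mesh_nodes])
        for j, hn in enumerate(hosp_nodes):
            if hn == node:
                minutes[:, j] = col
    return TravelTimeMatrix(mesh_ids, hospital_ids, minutes)


@dataclass
class PAA:
    """Patient Access Areas in both directions at a fixed threshold.

    Invariant (by construction): hospital h in by_mesh[m] iff mesh m in
    by_hospital[h].
    """

    threshold_minutes: float
    by_mesh: Mapping[str, tuple[str, ...]]
    by_hospital: Mapping[str, tuple[str, ...]]


def compute_paa(matrix: TravelTimeMatrix, threshold_minutes: float) -> PAA:
    """Threshold the travel matrix into access sets (inclusive comparison:
    a hospital exactly at the threshold is reachable)."""
    if threshold_minutes <= 0:
        raise ValueError("threshold_minutes must be positive")
    within = matrix.minutes <= threshold_minutes
    by_mesh = {
        m: tuple(h for j, h in enumerate(matrix.hospital_ids) if within[i, j])
        for i, m in enumerate(matrix.mesh_ids)
    }
    by_hospital = {
        h: tuple(m for i, m in enumerate(matrix.mesh_ids) if within[i, j])
        for j, h in enumerate(matrix.hospital_ids)
    }
    return PAA(float(threshold_minutes), by_mesh, by_hospital)
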