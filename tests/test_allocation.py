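"""Greedy bed allocation: conservation, PAA containment, priority order,
and comparison against a maximum-bipartite-flow lower-bound oracle."""

import numpy as np
import pytest

from paam import Hospital, Scenario, allocate, available_beds, compute_paa
from paam.network import TravelTimeMatrix
from paam.rng import substream


def make_matrix(minutes):
    minutes = np.asarray(minutes, dtype=float)
    return TravelTimeMatrix(
        tuple(f"m{i}" for i in range(minutes.shape[0])),
        tuple(f"h{j}" for j in range(minutes.shape[1])),
        minutes,
    )


def scenario(util=1.0, **kw):
    return Scenario("test", utilization_rate=util, n_samples=1, **kw)


def min_overdemand_by_maxflow(loads, paa, capacities):
    """Minimum achievable over-demand via maximum bipartite flow (oracle)."""
    import networkx as nx

    g = nx.DiGraph()
    for m, n in loads.items():
        if n > 0:
            g.add_edge("S", f"M:{m}", capacity=n)
            for h in paa.by_mesh.get(m, ()):
                g.add_edge(f"M:{m}", f"H:{h}", capacity=n)
    for h, c in capacities.items():
        if c > 0:
            g.add_edge(f"H:{h}", "T", capacity=c)
    if "S" not in g or "T" not in g:
        return sum(loads.values())
    flow = nx.maximum_flow_value(g, "S", "T")
    return sum(loads.values()) - flow


class TestConservation:
    def test_capacity_limited_single_hospital(self):
        hospitals = [Hospital("h0", 0, 0, 5)]
        matrix = make_matrix([[10.0]])
        paa = compute_paa(matrix, 60)
        result = allocate(
            {"m0": 7}, paa, hospitals, matrix, scenario(), substream(0, "a")
        )
        assert result.allocated["h0"] == 5
        assert result.unallocated["m0"] == 2
        assert result.vacant["h0"] == 0

    def test_empty_paa_all_overdemand(self):
        hospitals = [Hospital("h0", 0, 0, 100)]
        matrix = make_matrix([[120.0]])  # beyond the threshold
        paa = compute_paa(matrix, 60)
        result = allocate(
            {"m0": 9}, paa, hospitals, matrix, scenario(), substream(0, "b")
        )
        assert result.unallocated["m0"] == 9
        assert result.allocated["h0"] == 0

    def test_mesh_missing_from_paa_rejected(self):
        hospitals = [Hospital("h0", 0, 0, 10)]
        matrix = make_matrix([[10.0]])
        paa = compute_paa(matrix, 60)
        with pytest.raises(ValueError, match="no PAA entry"):
            allocate({"mX": 3}, paa, hospitals, matrix, scenario(), substream(0, "c"))


class TestPriorityOrder:
    def _setup(self):
        # nearer small hospital (10 min) vs farther large hospital (50 min)
        hospitals = [Hospital("near_small", 0, 0, 50), Hospital("far_large", 0, 0, 500)]
        matrix = TravelTimeMatrix(("m0",), ("near_small", "far_large"),
                                  np.array([[10.0, 50.0]]))
        return hospitals, matrix, compute_paa(matrix, 60)

    def test_size_first_prefers_far_large(self):
        hospitals, matrix, paa = self._setup()
        result = allocate({"m0": 1}, paa, hospitals, matrix, scenario(),
                          substream(1, "d"), strategy="size_first")
        assert result.allocated["far_large"] == 1

    def test_time_first_prefers_near_small(self):
        hospitals, matrix, paa = self._setup()
        result = allocate({"m0": 1}, paa, hospitals, matrix, scenario(),
                          substream(1, "e"), strategy="time_first")
        assert result.allocated["near_small"] == 1

    def test_tie_breaks_by_hospital_id(self):
        hospitals = [Hospital("hb", 0, 0, 50), Hospital("ha", 0, 0, 50)]
        matrix = TravelTimeMatrix(("m0",), ("hb", "ha"), np.array([[10.0, 10.0]]))
        paa = compute_paa(matrix, 60)
        result = allocate({"m0": 1}, paa, hospitals, matrix, scenario(),
                          substream(1, "f"))
        assert result.allocated["ha"] == 1

    def test_overflow_spills_to_next_priority(self):
        hospitals, matrix, paa = self._setup()
        # large fills (500 beds) then small takes the rest
        result = allocate({"m0": 520}, paa, hospitals, matrix, scenario(),
                          substream(1, "g"))
        assert result.allocated["far_large"] == 500
        assert result.allocated["near_small"] == 20

    def test_unknown_strategy_rejected(self):
        hospitals, matrix, paa = self._setup()
        with pytest.raises(ValueError, match="strategy"):
            allocate({"m0": 1}, paa, hospitals, matrix, scenario(),
                     substream(1, "h"), strategy="nearest")


class TestHuffStrategy:
    def test_huff_respects_capacity_and_paa(self):
        hospitals = [Hospital("h0", 0, 0, 3), Hospital("h1", 0, 0, 4)]
        matrix = make_matrix([[5.0, 100.0]])  # h1 outside threshold
        paa = compute_paa(matrix, 60)
        result = allocate({"m0": 10}, paa, hospitals, matrix, scenario(),
                          substream(2, "i"), strategy="huff")
        assert result.allocated["h0"] == 3
        assert result.allocated["h1"] == 0  # outside the PAA, never chosen
        assert result.unallocated["m0"] == 7

    def test_huff_favours_big_close_hospitals(self):
        hospitals = [Hospital("big_close", 0, 0, 400), Hospital("small_far", 0, 0, 20)]
        matrix = TravelTimeMatrix(("m0",), ("big_close", "small_far"),
                                  np.array([[10.0, 50.0]]))
        paa = compute_paa(matrix, 60)
        counts = {"big_close": 0, "small_far": 0}
        for i in range(60):
            r = allocate({"m0": 1}, paa, hospitals, matrix, scenario(),
                         substream(3, "j", i), strategy="huff")
            for h in counts:
                counts[h] += r.allocated[h]
        assert counts["big_close"] > counts["small_far"]


class TestFlowOracle:
    def test_greedy_overdemand_bounded_below_by_maxflow(self):
        """On random small instances the greedy allocator's over-demand is
        at least the minimum over-demand achievable by any assignment."""
        rng = np.random.default_rng(31)
        for rep in range(50):
            n_mesh = int(rng.integers(1, 6))
            n_hosp = int(rng.integers(1, 6))
            minutes = rng.uniform(0, 120, size=(n_mesh, n_hosp))
            matrix = make_matrix(minutes)
            paa = compute_paa(matrix, 60)
            hospitals = [
                Hospital(f"h{j}", 0, 0, int(rng.integers(1, 30)))
                for j in range(n_hosp)
            ]
            loads = {f"m{i}": int(rng.integers(0, 40)) for i in range(n_mesh)}
            sc = scenario()
            result = allocate(loads, paa, hospitals, matrix, sc,
                              substream(31, "flow", rep))
            caps = {h.id: available_beds(h, sc.utilization_rate) for h in hospitals}
            lower = min_overdemand_by_maxflow(loads, paa, caps)
            assert result.total_overdemand >= lower
            # conservation identities
            assert result.total_allocated + result.total_overdemand == sum(loads.values())
            assert all(result.allocated[h] <= caps[h] for h in caps)

    def test_equality_when_all_paas_coincide(self):
        """When every mesh sees every hospital, the greedy fill achieves
        the max-flow optimum exactly."""
        rng = np.random.default_rng(32)
        for rep in range(30):
            n_mesh = int(rng.integers(1, 6))
            n_hosp = int(rng.integers(1, 6))
            minutes = rng.uniform(0, 59, size=(n_mesh, n_hosp))  # all reachable
            matrix = make_matrix(minutes)
            paa = compute_paa(matrix, 60)
            hospitals = [
                Hospital(f"h{j}", 0, 0, int(rng.integers(1, 30)))
                for j in range(n_hosp)
            ]
            loads = {f"m{i}": int(rng.integers(0, 40)) for i in range(n_mesh)}
            sc = scenario()
            result = allocate(loads, paa, hospitals, matrix, sc,
                              substream(32, "eq", rep))
            caps = {h.id: available_beds(h, sc.utilization_rate) for h in hospitals}
            assert result.total_overdemand == min_overdemand_by_maxflow(loads, paa, caps)

    def test_zero_overdemand_when_feasible_and_fully_connected(self):
        hospitals = [Hospital("h0", 0, 0, 30), Hospital("h1", 0, 0, 30)]
        matrix = make_matrix([[5.0, 6.0], [6.0, 5.0]])
        paa = compute_paa(matrix, 60)
        result = allocate({"m0": 25, "m1": 30}, paa, hospitals, matrix,
                          scenario(), substream(5, "k"))
        assert result.total_overdemand == 0
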