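"""Capacity-constrained allocation of patients to hospital beds.

All patients of one sampling day are shuffled into a single random
order.  Each patient in turn considers the hospitals inside their mesh's
Patient Access Area that still have an available bed and takes a bed at
the top-priority one; a patient with no candidate counts toward their
mesh's *over-demand*.  The default priority mimics observed
health-seeking behaviour — larger size class first, then shorter travel
time — with hospital id as a deterministic tie-break.  A gravity-style
``huff`` strategy instead draws the hospital with probability
proportional to ``beds^alpha / minutes^beta`` among the candidates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .domain import Hospital, Scenario, available_beds
from .network import PAA, TravelTimeMatrix

STRATEGIES = ("size_first", "time_first", "huff")

# travel time can legitimately be 0 (hospital in the same mesh); the Huff
# weight divides by max(minutes, _MIN_MINUTES) to stay finite
_MIN_MINUTES = 0.5


@dataclass
class AllocationResult:
    """Outcome of one allocation run.

    Invariants (checked at construction): per hospital
    ``allocated + remaining = available``; globally
    ``sum(allocated) + sum(unallocated) = total patients``.
    """

    unallocated: dict[str, int]
    allocated: dict[str, int]
    available: dict[str, int]
    sample_index: int = 0
    year: int | None = None

    def __post_init__(self) -> None:
        for h, n in self.allocated.items():
            if n < 0 or n > self.available[h]:
                raise ValueError(f"hospital {h!r}: allocated {n} outside [0, available]")
        if any(n < 0 for n in self.unallocated.values()):
            raise ValueError("negative over-demand")

    @property
    def vacant(self) -> dict[str, int]:
        """Remaining empty available beds per hospital (over-supply)."""
        return {h: self.available[h] - self.allocated[h] for h in self.available}

    @property
    def total_overdemand(self) -> int:
        return sum(self.unallocated.values())

    @property
    def total_oversupply(self) -> int:
        return sum(self.vacant.values())

    @property
    def total_allocated(self) -> int:
        return sum(self.allocated.values())


def allocate(
    patient_loads: Mapping[str, int],
    paa: PAA,
    hospitals: Sequence[Hospital],
    matrix: TravelTimeMatrix,
    scenario: Scenario,
    rng: np.random.Generator,
    strategy: str = "size_first",
    huff_alpha: float = 1.0,
    huff_beta: float = 2.0,
    sample_index: int = 0,
    year: int | None = None,
) -> AllocationResult:
    """Allocate one day's sampled patients to beds.

    ``patient_loads`` maps mesh id -> patient count; every mesh with
    patients must appear in the PAA index.  Capacities come from
    :func:`paam.domain.available_beds` under the scenario's utilization
    rate and external-bed cap.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")
    for mesh_id, n in patient_loads.items():
        if n < 0:
            raise ValueError(f"mesh {mesh_id!r}: negative patient count")
        if n > 0 and mesh_id not in paa.by_mesh:
            raise ValueError(f"mesh {mesh_id!r} has patients but no PAA entry")

    hosp_by_id = {h.id: h for h in hospitals}
    capacity = {
        h.id: available_beds(h, scenario.utilization_rate, scenario.external_bed_fraction)
        for h in hospitals
    }
    available = dict(capacity)

    # per-mesh candidate lists in fixed priority order
    def _order(mesh_id: str) -> list[str]:
        cands = list(paa.by_mesh.get(mesh_id, ()))
        unknown = [h for h in cands if h not in hosp_by_id]
        if unknown:
            raise ValueError(f"PAA of mesh {mesh_id!r} references unknown hospitals {unknown}")
        if strategy == "time_first":
            key = lambda h: (matrix.lookup(mesh_id, h), -int(hosp_by_id[h].size_class), h)
        else:  # size_first ordering also seeds the huff candidate list
            key = lambda h: (-int(hosp_by_id[h].size_class), matrix.lookup(mesh_id, h), h)
        return sorted(cands, key=key)

    ordered = {m: _order(m) for m in patient_loads if patient_loads[m] > 0}

    # one global random patient order
    mesh_ids = sorted(m for m, n in patient_loads.items() if n > 0)
    patients = np.repeat(
        np.arange(len(mesh_ids)), [patient_loads[m] for m in mesh_ids]
    )
    rng.shuffle(patients)

    allocated = {h.id: 0 for h in hospitals}
    unallocated = {m: 0 for m in patient_loads}

    for mi in patients:
        mesh_id = mesh_ids[mi]
        cands = [h for h in ordered[mesh_id] if capacity[h] > 0]
        if not cands:
            unallocated[mesh_id] += 1
            continue
        if strategy == "huff":
            w = np.array(
                [
                    hosp_by_id[h].total_beds ** huff_alpha
                    / max(matrix.lookup(mesh_id, h), _MIN_MINUTES) ** huff_beta
                    for h in cands
                ]
            )
            chosen = cands[int(rng.choice(len(cands), p=w / w.sum()))]
        else:
            chosen = cands[0]
        capacity[chosen] -= 1
        allocated[chosen] += 1

    result = AllocationResult(
        unallocated=unallocated,
        allocated=allocated,
        available=available,
        sample_index=sample_index,
        year=year,
    )
    # conservation: every patient is either in a bed or over-demand
    assert result.total_allocated + result.total_overdemand == int(sum(patient_loads.values()))
    return result
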