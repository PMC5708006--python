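# Methods

## The model

`paam` simulates the future balance between inpatient healthcare demand and
hospital bed supply at small-area resolution. A study region is a grid of
*meshes* (default 500 m cells), each carrying a population vector indexed by
sex and 5-year age band (18 bands, 0–4 … 80–84, 85+). Hospitals are point
facilities with a bed count; a road network connects mesh centroids. One
simulation *sampling* chains four stages:

1. **Cohort-component projection.** Each mesh's population advances in
   5-year steps. Within a step the order of events is fixed: survival →
   net migration → aging (one band up; 85+ absorbs) → births (entering the
   bottom band). In stochastic mode every event is sampled per person:
   survivors and out-migrants binomially, in-migrants and births Poisson,
   the male share of births binomially with probability
   `sr / (1 + sr)` where `sr` is the sex ratio at birth. Expectation mode
   runs the identical arithmetic on real numbers; because every stage is
   linear in expectation, it is exactly the mean of the stochastic mode and
   serves as its oracle in the tests. Newborns are binomially thinned by the
   bottom-band survival rate within their birth step
   (`apply_newborn_survival`, on by default — they are exposed for part of
   the step; a switch turns it off).

2. **Inpatient incidence.** The expected daily inpatient census of a
   population is

   `N = Σ_{s,a} P[s,a] · r[s,a] · (1 − R_ad) · (1 − D_ad)`

   where `r` is the daily inpatient-care rate (the probability that a
   person of sex `s`, age band `a` occupies a bed on a given day), `R_ad`
   a scenario reduction of that rate, and `D_ad` a reduction of the average
   length of stay. Shorter stays reduce the *apparent* daily census by the
   same factor, which is why `D_ad` enters multiplicatively; no
   admission/discharge queueing is modelled. The stochastic form draws each
   cell binomially with the adjusted probability.

3. **Patient Access Areas.** Travel minutes from every mesh centroid to
   every hospital are shortest paths on the road network (Dijkstra), after
   snapping both endpoints to their nearest network node (Euclidean
   nearest; ties to the lowest node id; walk-on access time is ignored). A
   mesh's PAA is the set of hospitals within the threshold — 60 minutes by
   default, compared inclusively (exactly 60 is reachable). A `direct` mode
   replaces network routing with straight-line distance at a configured
   speed. Disconnected network components yield infinite times and hence
   empty access sets: inaccessibility is a meaningful outcome, not an
   error.

4. **Allocation.** Hospital capacity is
   `floor(total_beds × utilization_rate)`, further multiplied by
   `external_bed_fraction` (default 0.20) for out-of-region hospitals
   before flooring. All patients of the day are shuffled into one global
   random order; each in turn takes a bed at the highest-priority hospital
   in their mesh's PAA that still has capacity. The default priority is
   size class (large > medium > small; small ≤ 100 beds, medium 101–399,
   large ≥ 400 — the 400-bed boundary is assigned to large) descending,
   then travel minutes ascending, then hospital id. `time_first` swaps the
   first two keys; `huff` instead draws among the remaining candidates
   with probability ∝ `beds^α / minutes^β` (defaults α = 1, β = 2, the
   classic gravity form; travel times below 0.5 min are clamped to keep
   the weight finite). Patients with no candidate accumulate as their
   mesh's **over-demand**; available beds that end the day empty are each
   hospital's **over-supply**.

Scenario runs repeat the chain `n_samples` times (default 100) over the
year grid (default 7 points, 5 years apart, labelled 2010–2040) and report
means and standard deviations over samplings. The population is
re-projected independently in every sampling; `reuse_projection=True` is a
variance-reduction option that freezes one projection. Three default
scenarios span the policy space: current projection (±0% demand, 80%
utilization), 5% improvement (−5%/−5%, 85%) and 10% improvement
(−10%/−10%, 90%).

## Reproducibility

One global integer seed derives every random stream via hashed
`SeedSequence` substreams keyed by stage name, sample index, mesh id and
step (string keys are CRC-32 hashed, so streams are stable across
processes). Consequences verified by tests: projecting meshes jointly or
separately gives identical results, aggregates do not depend on execution
order, and two CLI runs with the same config and seed are byte-identical.

## The synthetic region generator

The generator emulates the *statistical shape* of a real region so that
every stage is testable without census, hospital-registry or map data:

- **Population.** A single multinomial draw distributes the exact total
  over (mesh × sex × band) cells, with spatial weights from a Gaussian
  urban core over a uniform floor, and age weights from the default
  pyramid — an aged society with roughly a third of residents 60+.
- **Rates.** Defaults sketch an aged, low-fertility society: total
  fertility ≈ 1.2 (5-year-step rates over bands 15–49), sex ratio at birth
  1.05, survival declining from ≈0.999 per step in childhood to 0.48–0.60
  in the 85+ band, mild young-adult out-migration (−2% per step), and a
  daily inpatient prevalence near 1% overall that rises from ~0.1% in
  young adults to 7–8.5% at 85+. They are plain parameters, not any
  country's vital statistics.
- **Hospitals.** Placed population-weighted (or uniformly) at mesh
  centroids; bed counts drawn from a size-class mixture whose default
  expects ≈65 beds per hospital, i.e. ≈12.5 beds per 1,000 residents for
  the default 50,000-person, 10-hospital region — the bed density of a
  high-bed-stock system, so that growing demand plausibly crosses capacity
  mid-horizon.
- **Network.** A 4-connected grid over mesh centroids with edge minutes =
  edge length / speed (default 40 km/h). `drop_edge_fraction` removes
  random edges to create access-poor pockets; `mesh_weights` overrides the
  density surface (used by tests to build degenerate layouts).

What the generator does *not* emulate: real geography (rail lines,
rivers, administrative boundaries), disease-class structure of inpatient
rates, within-mesh location variation, hospital functional differentiation
and time-varying rate tables (accepted as inputs but not generated).
Passing tests therefore demonstrate correctness of the machinery and the
qualitative scenario ordering, not calibrated forecasts for any real
region.

## Numerical choices

- Capacity flooring adds 1e-9 before `floor` so binary-float products
  (e.g. `29 × 0.8 = 23.200000000000003`) do not lose a bed.
- Travel-time threshold comparison is inclusive; unreachable is `inf`.
- Net migration is applied as Poisson additions (rate ≥ 0, integral and
  unbounded) or binomial removals (rate < 0, never exceeding the band).
- Over-demand means are kept real-valued; no rounding before averaging.
- Allocation ties (same size class and minutes) break by hospital id;
  empty meshes and zero-patient days are handled as ordinary inputs.
- Counts in stochastic mode are int64 throughout; expectation mode is
  float64.

## Problem sizes

The test suite runs tiny regions (≤ 5×5 meshes, ≤ 6,000 people) for unit
and property checks, 500 replicates for law-of-large-numbers comparisons
(3-standard-error tolerance), 200 random regions for conservation
properties, and one full-scale comparison — 20×20 meshes, ~50,000 people,
10 hospitals, 3 scenarios × 100 samplings × 7 years — for scenario
monotonicity. `scripts/acceptance.py` repeats that full-scale comparison
from a single seed.

## Known limitations

- Demand is a daily census; admissions, discharges and length-of-stay
  dynamics are not modelled beyond the `(1 − D_ad)` factor.
- Single all-cause inpatient rate per sex × band; no disease axis and no
  matching of patients to hospital function.
- One travel mode and a static network; no congestion, schedules or
  multi-modal routing.
- The greedy allocator is order-dependent by design (it models
  uncoordinated patient choice); it can exceed the system-optimal
  over-demand when access sets differ, which the max-flow bound tests
  quantify on small instances.
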