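# paam — patient access area simulation of inpatient demand and bed supply

`paam` answers a healthcare-planning question: **when and where will the
number of inpatients exceed the hospital beds that patients can actually
reach?** It is aimed at health-services researchers and regional planners
who need small-area, forward-looking estimates of over-demand (patients
who cannot be admitted within reach of home) and over-supply (beds that
stay empty) under policy scenarios.

## The model

A region is a grid of 500-m meshes with age×sex populations and a set of
hospitals on a road network. Each simulation sampling:

1. **projects** every mesh's population in 5-year steps with per-person
   Monte-Carlo sampling of survival, net migration and births
   (cohort-component method, stochastic because small-area expected counts
   fall below one person);
2. **converts** population to daily inpatient demand,

   N = Σ<sub>s,a</sub> P<sub>s,a</sub> · r<sub>s,a</sub> · (1 − R<sub>ad</sub>) · (1 − D<sub>ad</sub>),

   with `r` the daily inpatient-care rate by sex and age band, `R_ad` a
   scenario reduction of that rate and `D_ad` a reduction of average
   length of stay (shorter stays lower the apparent daily census);
3. **bounds** each patient's hospital choice to their mesh's *Patient
   Access Area* — hospitals within 60 road-minutes by default;
4. **allocates** patients one by one, in one global random order, to the
   largest-then-nearest reachable hospital with a free bed, where capacity
   is `floor(beds × utilization_rate)` (out-of-region hospitals capped at
   20% of that). Unplaceable patients are over-demand per mesh; unfilled
   beds are over-supply per hospital.

Scenario runs repeat this 100 times and report means (and standard
deviations) per year. A synthetic-region generator produces complete,
statistically controllable inputs, so nothing needs to be downloaded.
See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

```sh
paam synth --out region/ --seed 2026          # default 20x20 region, 50k people
paam compare --region region/ --out results/ --seed 2026 --n-samples 20
```

prints (abridged):

```
Ex.1 current projection: first over-demand year = 2020
Ex.2 5% improvement: first over-demand year = None
Ex.3 10% improvement: first over-demand year = None
```

and `results/overdemand_comparison.csv` holds the per-year means behind
it. For this region (841 beds, ~672 available at 80% utilization), mean
daily inpatient demand under the current-projection scenario grows from
≈499 in 2010 to a peak of ≈668 around 2030 as the population ages, so
over-demand appears from 2020 and peaks at ≈7 unplaced patients per day in
2025–2030. Under the 5% and 10% improvement scenarios (lower inpatient
rate and length of stay, higher utilization) demand stays below capacity
and over-demand never occurs — improvement scenarios can only postpone
the onset year, never advance it.

The same pipeline is available as a library:

```python
from paam import (RegionSpec, generate_region, Scenario, run_scenario)

region = generate_region(RegionSpec(seed=2026))
result = run_scenario(region, Scenario("base", n_samples=20, seed=2026))
print(result.totals)                 # patients / over-demand / over-supply per year
print(result.first_overdemand_year)
result.mesh_overdemand               # per-mesh means, ready for choropleth export
```

`paam run` additionally writes per-mesh over-demand GeoJSON maps for
choropleth rendering.

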