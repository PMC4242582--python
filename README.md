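# limosa

Why do male and female bar-tailed godwits (*Limosa lapponica*) winter in
different places?  The sexes of this strongly dimorphic shorebird segregate
across the NW-European winter range: females — about 20% heavier, with 25%
longer bills — concentrate in the cold northern Wadden Sea close to the Arctic
breeding grounds, males in milder sites like the UK estuaries.  Two classic
explanations compete:

* **Bergmann (cost) hypothesis** — the larger sex loses proportionally less
  heat, so females can afford the colder, closer sites;
* **resource partitioning** — long-billed females can probe for deeply buried
  prey (e.g. lugworms down to 30 cm), short-billed males peck at the top few
  centimetres, so each sex goes where *its* food layer is rich.

`limosa` implements the full analysis pipeline that separates these: a
sex-specific bioenergetic wintering-cost model, layered benthic-biomass
processing, sex-ratio estimation from flock scans, the statistical battery
that compares the hypotheses, and a seeded synthetic-study generator so every
stage is testable end to end.  It is aimed at quantitative ecologists who want
a reproducible, unit-tested version of this style of cost/benefit
distribution analysis.

## The model

Seasonal cost of wintering at a site, per sex:

```
M_maint = BMR + H_sm                              maintenance power (W)
BMR     = 5.06 · BM^0.729                         shorebird allometry (BM in kg)
H_sm    = max(0, K_es·(T_b − T_a) + K_u·u^exp − K_r·R_g)
C_flight = (2·D / S) · C_sex                      round-trip migration (kJ)
total   = M_maint · 182 d · 86.4 kJ/(W·d) + C_flight
```

with sex profiles male = (0.270 kg, K_es 0.0914 W/°C, 55 kJ/h) and
female = (0.323 kg, 0.1111 W/°C, 67 kJ/h), body temperature T_b = 41 °C,
flight speed S = 75 km/h, and D the one-way great-circle distance to the
breeding grounds (70°16′N 24°05′E).  Benthic cores (0.0177 m², 30 cm) are
split into a top (0–4 cm, peck-accessible) and bottom (5–30 cm, probe-only)
layer; edible biomass is ash-free dry mass, AFDM = dry − ash.  Flock scans
give per-session female proportions, analysed as empirical logits
log(p/(1−p)) with p = (y+0.5)/(n+1).  The four-way panel then correlates the
per-site percentage of females with (a) wintering cost, (b) per-core bottom
AFDM, (c) per-core top AFDM and (d) the bottom-layer share of AFDM.

## Worked example

```python
from limosa import datasets, cost_table
from limosa.simulate import Scenario, generate
from limosa.pipeline import RunConfig, run_pipeline

# seasonal costs at the six published study sites
costs = cost_table(datasets.site_table())
print(costs[costs.site == "Sylt-Romo Wadden Sea"][
    ["sex", "maintenance_w", "migration_kj", "seasonal_total_kj"]])
#       sex  maintenance_w  migration_kj  seasonal_total_kj
#    female       6.765030   3466.133333      109844.869927
#      male       5.685413   2845.333333       92247.322668

# a full synthetic study under resource partitioning, analysed end to end
results = run_pipeline(RunConfig(
    scenario=Scenario(hypothesis="resource_partitioning"), seed=1))
for name, res in results["panel"].items():
    print(f"{name:10s} r={res.statistic:+.2f}  p={res.p_label}")
# cost       r=-0.21  p=0.6918
# bottom_pct r=+1.00  p=2.419e-05
# bottom     r=+0.31  p=0.01779
# top        r=-0.30  p=0.01803
```

At the coldest site a female needs ~6.8 W of maintenance power against the
male's ~5.7 W, and her season (182 days plus the round trip) costs ~110 MJ —
roughly 19% more than his.  In the synthetic study the female percentage
tracks the deep-layer biomass share (bottom r > 0, significant) while the
cost correlation is indistinguishable from zero: the resource-partitioning
signature.

The same pipeline is scriptable:

```
limosa simulate --hypothesis resource_partitioning --seed 1 --out sim/
limosa analyze --sites sim/sites.csv --cores sim/cores.csv \
               --counts sim/counts.csv --aps sim/aps.csv --out out/
```

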