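# nataldisp

Genotype-matching based natal dispersal analysis for territorial raptors.

Natal dispersal — the distance between where an animal hatched and where it
first breeds — drives gene flow, range expansion and density regulation,
but is notoriously hard to measure in long-lived, elusive birds of prey:
an eagle ringed as a nestling may not breed for five years or more, and
breeding adults are rarely recaptured. Long-term monitoring schemes solve
this by combining two identification streams: re-sightings of engraved
colour rings, and multilocus microsatellite genotypes from nestling
feathers matched years later against genotypes from moulted feathers
collected at breeding nests. `nataldisp` implements that full analysis
chain for the white-tailed eagle (*Haliaeetus albicilla*) monitoring
system, end to end:

1. **Identity screening** — adult vs. nestling genotype matching with a
   ≥ 9-of-14-locus retention rule, missing-locus wildcards, ambiguity
   flagging, cross-laboratory allele-size calibration, and probability-of-
   identity statistics (PID = 2(Σp²)² − Σp⁴ and its full-sibling
   counterpart, multiplied across loci).
2. **Link fusion and filtering** — one natal→breeding event per
   individual from ring and genotype evidence, then exclusion of
   unknown-sex birds and birds first detected at calendar age < 5.
3. **Spatial statistics** — haversine geodesics, territory-year activity
   from ordinal nest-occupancy stages, active-territory counts in 30 km /
   10 km buffers at the expected recruitment year (hatch + 5), and
   distance to a border polyline.
4. **Models** — a binomial GLM of recruitment on border distance whose
   predictions become case weights; then two REML linear mixed models with
   *crossed* random intercepts (natal territory × recruitment year),
   written

       ln d_i = β₀ + β₁ male_i + β₂ z(density30_i) + β₃ z(year_i)
                + u_territory + u_year + ε_i,      ε_i ~ N(0, σ²/w_i)

   for log dispersal distance (metres), and an analogous unweighted model
   of the breeding-minus-natal 10 km density difference with the expected
   density difference as a control covariate. Negative density effects in
   both models are the signature of conspecific attraction interacting
   with intraspecific competition.
5. **Synthetic data** — a generator (clustered territory landscape,
   Mendelian genotypes, border-distance-dependent emigration, generative
   dispersal model) and a deterministic fixture reproducing the study's
   identification bookkeeping exactly (335 linked individuals, 84/233/18
   by source, 156/141/38 by sex, 285 after filters), so the whole chain
   runs and validates with no field data.

The crossed-random-effects REML engine is implemented in-house (profiled
criterion, bounded quasi-Newton over variance ratios, Satterthwaite-style
df) and is cross-checked in the test suite against direct restricted-
likelihood maximisation and against `lme4`.

## Worked example

Run the packaged study-composition dataset through the whole pipeline:

```python
import numpy as np
from nataldisp import make_study_fixture, run_pipeline, PipelineConfig, SimConfig

sim = make_study_fixture()
report = run_pipeline(PipelineConfig(out_dir="out"), inputs={
    "territories": sim.territories, "nestlings": sim.nestlings,
    "genotypes": sim.genotypes, "resights": sim.ring_resights,
    "border": np.asarray(SimConfig().border, float)})
print(report["filter_log"].format())
print(report["distance_model"].format_table())
```

prints the dataset-assembly arithmetic

```
dataset assembly: 335 linked individuals; removed 38 of unknown sex and
12 detected at age < threshold; 285 retained
```

and the fitted distance model (one realisation of the fixture):

```
log_distance ~ sex_male + density30_z + year_z + sex_male:year_z
             + (1 | natal_territory) + (1 | recruit_year), weights = recruitment probability

Fixed effects:
term                          estimate       SE      chi2       df         p
Intercept                       10.779    0.066  26537.11    88.26   3.2e-111
sex_male                        -0.363    0.086     17.67   280.00  3.545e-05
density30_z                     -0.297    0.044     45.59   280.00  8.403e-11
year_z                           0.002    0.066      0.00    73.76     0.9736
```

Reading it: the intercept 10.78 is mean log-distance in metres
(e^10.78 ≈ 48 km); males settle ~30% closer than females
(e^−0.363 ≈ 0.70); one SD more breeder density within 30 km of the natal
nest shortens dispersal by ~26% (e^−0.297) — birds from dense natal areas
stay closer to home. The companion density-difference model on the same
run recovers a negative natal-density effect (−0.478 ± 0.146): birds from
the densest areas nevertheless settle in relatively sparser
neighbourhoods. The recruitment GLM slope is 0.0043 ± 0.0004 per km and
the median dispersal distance 42.9 km.

A command-line interface mirrors the library
(`nataldisp simulate | fixture | match | link | metrics | fit | run |
report`); `nataldisp run --config pipeline.yaml` executes the full chain on
CSV inputs and writes a bundle of per-stage tables, model JSON and a run
manifest.

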