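# audioclust

Prognostic stratification of unilateral sudden sensorineural hearing loss
(USSNHL) from the audiogram of the **unaffected** ear.

## The problem

In USSNHL the contralateral ("unaffected") ear is the only available proxy
for a patient's premorbid cochlear state, but its pure-tone audiogram has
no agreed summary beyond the mean threshold. `audioclust` implements a
pipeline for clinicians and hearing researchers that:

1. compresses a contralateral audiogram (thresholds at 250, 500, 1000,
   2000, 4000, 8000 Hz, dB HL) into three fitted-line slopes on the octave
   axis — **ka** over 250–1000 Hz, **kb** over 2000–8000 Hz and **kc**
   over 4000–8000 Hz, in dB/octave with positive = upward trend;
2. stratifies patients by two-cluster K-means on the z-scored slope
   triple, with silhouette-based selection of the cluster count.
   Cluster **X** (code 0) collects the audiograms with a pronounced
   mid-to-high-frequency descent; cluster **Y** (code 1) the flatter ones;
3. applies the clinical machinery around the stratification: the Chinese
   (≥ 20 dB at ≥ 2 consecutive frequencies) and international (≥ 30 dB at
   ≥ 3) diagnostic definitions, affected-ear audiogram typing
   (upsloping / downsloping / flat / profound), Siegel-style recovery
   grading with a conservative boundary tie-break, and the three efficacy
   metrics (mean threshold improvement, cure rate, improvement rate);
4. links cluster membership to outcome with univariate → multivariate
   ordinary least squares (threshold improvement, dB) and binary logistic
   regression ("no improvement" coded 1, reported as odds ratios), using
   the p < 0.05 univariate selection rule;
5. generates synthetic USSNHL cohorts with the latent two-class structure
   above, so the entire pipeline is testable end to end without patient
   data.

The K-means engine (k-means++ seeding, Lloyd iterations, best of 50
restarts), silhouette, OLS and logistic-IRLS estimators are implemented in
the package and verified in the test-suite against brute-force oracles and
against scikit-learn / statsmodels.

## Worked example

```sh
audioclust simulate --out demo --seed 1 --n 229
audioclust fit      --in demo/cohort.csv --out demo/fit --seed 1
audioclust grade    --in demo/cohort.csv --out demo/grade
audioclust analyze  --in demo/cohort.csv --model demo/fit/model.json \
                    --rule international --out demo/analysis
```

which logs:

```
INFO audioclust: simulated 229 patients (seed 1) -> demo
INFO audioclust: silhouette by k: {2: 0.5423, 3: 0.3662, 4: 0.3354, 5: 0.3105}; chosen k=2
INFO audioclust: fitted model: 67 in cluster X, 162 in cluster Y (seed 1)
INFO audioclust: graded 229 patients: mean improvement 19.88 dB, cure 0.271, improvement 0.659
INFO audioclust: 172 of 229 patients meet the international diagnostic rule
INFO audioclust: analysis written to demo/analysis (selected linear covariates: ['cluster', 'age', 'type'] ...)
```

Reading this: the silhouette peaks at two clusters (0.54), the cohort
splits roughly 1:3 into X vs Y, and 172/229 patients survive the stricter
international diagnostic definition. The multivariate rows of
`demo/analysis/regression.csv` then quantify the prognostic gap — e.g.

```
variable level  estimate      se  statistic        p   ci_low  ci_high model kind
cluster      Y    13.247   2.312      5.730  4.6e-08    8.682   17.812 multi  ols
age           -    -0.258   0.058     -4.452  1.6e-05   -0.373   -0.144 multi  ols
```

i.e. on this synthetic cohort a cluster-Y patient gains ≈ 13 dB more
threshold improvement than a cluster-X patient of the same age and
audiogram type, and each year of age costs ≈ 0.26 dB — recovering the
+10 dB cluster effect and −0.25 dB/yr age effect the generator planted
(the cluster coefficient here also absorbs some of the correlated slope
structure of this particular draw; see `docs/methods.md`).

`fit` also writes the portable model (`model.json`: standardization stats,
centroids, label map) which `audioclust predict` applies to new patients,
mirroring the train-once / classify-anywhere workflow.

## Library use

```python
from audioclust import (Audiogram, extract_slopes, fit_model, assign,
                        SimulationConfig, simulate_cohort)

ag = Audiogram.from_values([15, 15, 20, 45, 65, 80])   # 250 -> 8000 Hz
print(extract_slopes(ag))      # SlopeFeatures(ka=-2.5, kb=-17.5, kc=-15.0)

records, truth = simulate_cohort(SimulationConfig(n_patients=200, seed=7))
model, codes = fit_model([extract_slopes(r.unaffected) for r in records])
print(assign(model, extract_slopes(ag)))               # (0, 'X')
```

## Layout

| module | contents |
|---|---|
| `audiogram_io` | `Audiogram`/`PatientRecord`, CSV dialect, NR censoring |
| `slope_features` | (ka, kb, kc) extraction, mean threshold |
| `clustering` | standardize, K-means, silhouette, model JSON, ARI |
| `cohort` | diagnostic rules, audiogram typing, Siegel grading, efficacy |
| `stats` | OLS, logistic IRLS, selection rule, t / Mann–Whitney / χ², quartiles |
| `synthetic_data` | the cohort generator and its truth sidecar |
| `cli` | the `audioclust` subcommands |

Methodological details, parameter defaults and limitations are documented
in `docs/methods.md`.
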