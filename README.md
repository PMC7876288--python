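# mobimood

Digital phenotyping for mental health: extract mobility, phone-usage,
wearable and mood features from raw sensor streams, score DASS-21
symptom outcomes, and predict symptom severity with multilevel models
under multilevel multiple imputation.

The package is aimed at researchers analysing passive-sensing studies in
which repeated symptom questionnaires (here the 21-item Depression
Anxiety Stress Scales) are paired with continuous smartphone GPS and
screen data, daily wearable summaries (steps, MET, TST/SOL/WASO/TIB,
nightly RMSSD) and momentary valence/arousal self-reports. Because such
datasets usually cannot be shared, a synthetic cohort generator with
planted effect sizes and missing-at-random masking makes every stage of
the pipeline runnable and testable end to end.

## The model

Five location features are computed from cleaned GPS traces after
stationary/transition labelling (speed > 1 km/h = transition) and
K-means stay-point clustering: total distance, location variance
`ln(var(lat) + var(lon))`, location entropy

```
H = − Σ_i p_i ln p_i
```

with `p_i` the share of dwell time in cluster i, normalized entropy
`H / ln N`, and homestay (share of the 24-h day in the night-defined
home cluster). Daily features are pooled into two 15-day windows paired
with the midpoint and endpoint DASS-21 subscores, z-standardized, and
modelled with linear mixed models — windows (level 1) nested in
participants (level 2), random intercepts and random slopes, maximum
likelihood, Satterthwaite degrees of freedom:

```
y_jt = β₀ + Σ_k β_k x_kjt + b_j + u_kj x_kjt + ε_jt
```

Missing assessments and sensing windows are handled by multilevel
predictive-mean-matching multiple imputation (m = 20, 15 iterations),
with Rubin's rules for pooled estimates and the pooled likelihood-ratio
(D3) statistic for comparing the nested model ladder: baseline → EMA →
GPS → GPS + wearable → combined.

## Worked example

```bash
mobimood run --seed 11 --n-participants 10 -m 5 --workdir out/
cat out/report/report.txt
```

runs simulate → extract → analyze → report on a 10-participant synthetic
cohort. The report starts with the intraclass correlations and the
cluster-wise Holm-adjusted Spearman screen:

```
Intraclass correlations (participant level):
  depression   ICC = 0.824
  anxiety      ICC = 0.115
  stress       ICC = 0.807

Correlations between sensor features and symptom severity
feature               outcome         rho       p   p adj
-- GPS features --
location_variance     depression     0.13   0.633  1.000
total_distance        depression     0.07   0.802  1.000
entropy               depression     0.03   0.906  1.000
...
```

The ICCs say that 12–82% of outcome variance sits between participants —
repeated windows from the same person are far from independent, which is
why the modelling layer is multilevel. The correlation block screens
each feature cluster against each subscore; `p adj` is Holm-corrected
within its cluster × outcome family only. The model-comparison section
then reports each ladder stage in the combined-prediction layout
(estimate, SE, t, Satterthwaite df, p per fixed effect, plus the pooled
likelihood-ratio F against the parent stage), with `No predictors
identified` for stages whose cluster produced no significant
single-predictor model. At n = 10 the screen is dominated by sampling
noise — the library-level simulations in `tests/test_acceptance.py`
run the same machinery at 100–200 participants, where planted slopes of
−0.21 and +0.25 are recovered with |bias| < 0.005 and ~95% CI coverage.

The same stages are available programmatically:

```python
from mobimood import PipelineConfig, run_pipeline
cfg = PipelineConfig(n_participants=10, seed=7,
                     planted_betas={"location_variance": -0.21, "tib": 0.25})
run_pipeline(cfg, "out/")
```

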