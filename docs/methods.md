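# Methods

`mobimood` reimplements a digital-phenotyping analysis: passive smartphone
and wearable sensing plus brief mood self-reports, used to predict symptoms
of depression, anxiety and stress over a 30-day observation window with
symptom questionnaires at baseline (day 1), midpoint (day 16) and endpoint
(day 31).

## Feature extraction

### GPS mobility

Raw location streams (UNIX-ms timestamp, latitude/longitude, accuracy)
are cleaned by removing exact duplicate rows, samples at exactly
(0.0, 0.0) — a known sensing artifact — and samples whose accuracy value
exceeds (strictly) the 80th percentile of the *pooled* accuracies of all
participants. The percentile is the linear-interpolation (type-7)
definition. Because the threshold is a dataset-level statistic,
`clean_trace` is idempotent only when the same accuracy pool is supplied
on re-runs; the pipeline therefore computes the pool once over all raw
samples and records the applied threshold in the removal ledger.

Movement speed at each sample is the haversine distance from the previous
sample divided by elapsed time (sphere radius 6371.0088 km; sub-0.5%
error at city scale with no ellipsoid dependency). Speed strictly above
1 km/h marks a transition state, otherwise stationary. Gaps longer than
15 minutes split the trace into segments: no distance or dwell time is
credited across a gap, and the first sample of a segment inherits the
following interval's speed. Each stationary sample is credited dwell time
equal to the interval to the next within-segment sample.

Stationary samples are clustered per two-week window with K-means
(scikit-learn, `n_init=10`, fixed seed) on a local equirectangular
projection. K-means requires K; since the number of a participant's stay
locations is unknown a priori, K is chosen as the smallest k for which
every stationary sample lies within 500 m of its centroid, capped at 20
(cap flagged). Both thresholds are exposed in the pipeline configuration.

Five features per day set:

- **Total distance** (km): sum of within-segment consecutive-sample
  haversine distances.
- **Location variance**: `ln(var(lat) + var(lon))` over stationary
  samples in raw decimal degrees (population variance); undefined below
  3 stationary samples or at exactly zero variance (undefined, not −inf).
- **Entropy** (nats): `−Σ p_i ln p_i` where `p_i` is the *dwell-time*
  share of cluster i. Time-weighting is robust to irregular sampling;
  sample-count weighting would over-weight bursts.
- **Normalized entropy**: entropy divided by `ln(k)` of the fitted
  cluster count, defined as 0 for a single cluster.
- **Homestay**: dwell seconds in the home cluster divided by 24 h per
  day (clipped to [0, 1]). The home cluster holds the most stationary
  samples with local time in the half-open night window [00:00, 06:00) —
  identification by sample count, as the quantity is a count of night
  fixes. A tracked-time denominator is available behind a config flag;
  the 24-h denominator is the default because it is the literal
  definition of the proportion of a day spent at home.

Daily features are computed against the window-fitted cluster model and
then averaged over days 1–15 (window 1) and 16–30 (window 2), matching
day-level aggregation followed by two-week pooling.

### Phone usage

A usage session runs from an unlock event to the next lock. Consecutive
unlocks without a lock close the earlier session at the next unlock;
a trailing unmatched unlock closes at the stream's last event; sessions
over 12 h are truncated (a guard against lost lock events). Sessions
crossing local midnight are split so each day gets its own minutes.
Daily usage frequency is the raw count of unlock events; daily duration
is the summed attributed session minutes. Midnight splitting conserves
total minutes to within a second.

### Wearable and mood

Wearable data enter as daily ring summaries: steps, 24-h MET average,
total sleep time (TST), sleep onset latency (SOL), wake after sleep
onset (WASO), time in bed (TIB, minutes), nightly RMSSD (ms; treated as
the nightly average). Validation never rejects a record outright: a field
violating an invariant (negative value, TST > TIB, SOL + WASO exceeding
TIB − TST by more than a 30-minute slack, RMSSD > 500 ms) is set
undefined with a reason and the remaining fields survive.

Momentary mood (valence and arousal, integers −4..4, up to three prompts
a day) aggregates to the day by unweighted mean. Untouched default-zero
responses are retained by default (the response scale defaults to zero
and there is no way to distinguish a deliberate zero), with a config
flag to drop them.

### Symptom outcomes

DASS-21 items (0–3) sum into three 7-item subscales on 0–21 — raw sums,
no doubling to the 42-item scale, as the 0–21 range and the cut-offs
imply. Severity categories: depression 0–4 / 5–6 / 7–10 / 11–13 / 14+;
anxiety 0–3 / 4–5 / 6–7 / 8–9 / 10+; stress 0–7 / 8–9 / 10–12 / 13–16 /
17+ (normal / mild / moderate / severe / extremely severe). A missing
item leaves only its own subscale undefined.

## Windowing and standardization

Local calendar dates map to per-participant study days 1–30 (day 1 =
enrollment). Window 1 (days 1–15) pairs with the midpoint assessment,
window 2 (days 16–30) with the endpoint; day 16 itself contributes to
window 2 only. A window feature is defined when at least 5 of its days
are defined — a minimum-coverage guard against one-day "windows".
Predictors *and* outcomes are z-standardized by grand mean/SD over all
observed participant-window rows; grand (not within-person)
standardization of both sides is what makes the fitted intercepts of all
models essentially zero with a nonzero standard error. Transform
parameters are stored for inverse mapping.

## Statistical layer

**Correlations.** Spearman rank correlations (scipy) between each pooled
feature and each subscore, with Holm step-down adjustment applied within
each feature cluster × outcome family (GPS, usage, wearable, EMA).
Cluster-wise families avoid over-correction in an exploratory screen;
the Holm step-down itself is a few lines and is cross-checked in the
tests against statsmodels' implementation and a brute-force enumeration.

**ICC.** ICC(1,1) from one-way random-effects ANOVA variance components
with the unbalanced-design average group size, floored at 0. Hand-rolled
because no installed package computes this form for arbitrary unbalanced
groupings; verified against a hand ANOVA in the tests.

**Mixed models.** Outcome ~ predictors with a per-participant random
intercept and uncorrelated random slopes on each predictor, fitted by
maximum likelihood via statsmodels MixedLM (variance components for the
slopes). With at most two windows per participant a full random-effects
covariance is unidentifiable, hence uncorrelated effects. A slope
variance within 1% of the total variance is treated as a boundary fit:
the model is refitted random-intercept-only and flagged — near-zero
slope variance leaves a flat likelihood direction that would otherwise
poison degrees of freedom. When statsmodels' optimizer fails on
degenerate designs, a fallback optimizes this package's own profiled
marginal likelihood directly.

Fixed-effect tests use Satterthwaite degrees of freedom computed from
the package's own marginal-likelihood evaluator: df = 2·Var(β̂_c)² /
(gᵀ A g), with g the numeric gradient of Var(β̂_c) in the variance
parameters and A the inverse observed information of the profiled ML
log-likelihood (central differences). If the information matrix is
unusable the df falls back to the between-within count
n − p − (groups − 1), and df is capped at n − p.

**Missing data.** Multilevel predictive-mean-matching multiple
imputation, m = 20 chains × 15 sweeps, donor pool 5. Each incomplete
column is regressed on an intercept, the participant's leave-one-out
mean of the column's *observed* values (the carrier of the person random
intercept: a person's other windows are the best predictor of their
missing one), and the participant mean plus within-person deviation of
every other model variable — a two-level surrogate for a random-effects
imputation model. Parameters are drawn from their Bayesian posterior
(normal for coefficients, scaled inverse chi-square for the residual
variance); type-1 matching predicts observed cases with the posterior
mode and missing cases with the draw, and each missing case receives the
observed value of a random donor among the 5 closest predictions.
Chain means/SDs of imputed values are retained for convergence
inspection. Neither a Python nor an R implementation of multilevel PMM
is available in this environment, so the sampler is implemented here and
exercised by property tests (donor membership, no-op on complete data,
reproducibility) and by the MAR recovery simulations.

**Pooling.** Rubin's rules (estimate mean; total variance
W + (1 + 1/m)·B) with Barnard–Rubin adjusted degrees of freedom, using
the mean Satterthwaite df as the complete-data df. Model comparison uses
the multiply-imputed likelihood-ratio statistic (the "D3" recipe):
per-imputation LRT statistics are recalibrated by re-evaluating both
models' likelihoods at their pooled fixed-effect and variance-parameter
values on every completed dataset, giving an F statistic with df1 =
number of constrained fixed effects. With m = 1 the statistic reduces
exactly to the classical chi-square LRT (verified to 1e−6).

**Model ladder.** Single-predictor pooled models screen all 16 features
per outcome; a feature survives at pooled two-sided p < 0.05. Stages:
baseline (intercept only), EMA, GPS, extended digital phenotyping
(GPS + wearable), combined (EMA + GPS + wearable), each containing only
its clusters' surviving features and compared against its parent stage
(falling back past empty parents) by the pooled LRT. Empty stages are
reported as "No predictors identified", never dropped. If any
imputation's fit hits the slope-variance boundary, all m fits for that
stage are refitted random-intercept-only so the pooled quantities come
from a common model.

One conflict in the source material is resolved in favour of the running
text: the combined-model tables label an EMA coefficient "Arousal" where
the text identifies valence as the significant EMA predictor; this
package reports whichever features actually survive its screen, so the
discrepancy does not bind, but the reader should be aware of it when
comparing layouts. Similarly, the correlation table is titled "Pearson"
while the methods prescribe Spearman; Spearman is implemented.

## Synthetic cohort

No participant data are available, so a generator provides study-shaped
data with known ground truth at two levels.

`simulate_model_table` works at the participant × window level. Each
feature has unit variance split into a person component (SD 0.6) and a
within-person residual. Two person-level traits shape the cohort: a
*behavioural* trait loading 0.8 on every feature's person component
(features correlate with each other), and a *psychological* trait
loading 0.85 on the outcome's random intercept. Phone-usage frequency —
the missingness driver — loads on both (0.8 / 0.6), which is exactly
what makes usage-driven missingness informative about the outcome
(complete-case analysis genuinely loses information) while keeping all
other features independent of the random intercept, so the mixed model
estimates planted slopes consistently. The outcome is
y = Σ (β_f + slope_sd·b_fj)·x + b0_j + ε with sd(b0) = 0.7 and
sd(ε) = 0.6 (ICC ≈ 0.58, comfortably above the >0.05 bar that motivates
multilevel modelling).

`generate_cohort` emits full raw streams. Each participant has a home
anchor near Helsinki, 1–4 secondary anchors 0.6–3 km away, and a daily
visit schedule whose outing intensity follows the behavioural trait;
GPS samples are emitted every 60 s (configurable) with 8 m Gaussian
jitter, lognormal accuracies, and injected artifacts (exact duplicates
1%, (0,0) rows 0.4%, accuracy outliers 1% — rates chosen to exercise
every cleaning rule without dominating the stream; each row receives at
most one artifact class so injected counts are exactly recoverable).
Screen events, wearable daily records and EMA responses follow plausible
marginal distributions (e.g. TST ~ 420 min, RMSSD ~ 45 ms, ~25
unlocks/day) shifted by person-level z-scores. The outcome model runs on
the *noiseless* schedule-level features (dwell shares, anchor geometry,
planted usage/wearable/mood levels), standardized across the cohort;
DASS subscores map the standardized latent outcome onto the 0–21 scale
using location/scale (3.78/3.48 depression, 2.73/2.68 anxiety, 6.00/3.82
stress — the severity profile of a general-population cohort under
movement restrictions), are clipped into range (logged), and are then
decomposed into 21 item ratings by largest-remainder allocation so the
subscale sums are exact.

Missingness is MAR by construction: masking probability is
sigmoid(a + 1.5·z_usage) with the offset solved by root-finding on the
realized usage covariate so the marginal rate equals 10% for midpoint/
endpoint assessments and 9.1% for sensing days — a deterministic
function of observed data, so a logistic regression of the missingness
indicator on usage recovers a strongly nonzero coefficient.

What the generator does *not* emulate: circadian or weekday structure,
movement regimes beyond home-plus-anchors (no commuting corridors,
no travel), device-specific accuracy patterns, serially correlated mood,
or item-level DASS response styles. Passing tests therefore demonstrate
that the pipeline recovers what it assumes, not that real populations
satisfy those assumptions.

## Problem sizes in the test suite

The statistical acceptance checks run at sizes chosen to make their
Monte-Carlo error small relative to their tolerances: parameter recovery
uses 200 replicates of 200 participants × 8 windows (planted slopes
−0.21 and +0.25, person-varying with SD 0.1); type-I calibration uses
400 null replicates at 100 participants × 4 windows; the MAR comparison
uses 100 replicates at 100 participants × 4 windows with m = 20
imputations; confidence-interval calibration at the two-window study
scale (55 participants × 2 windows) uses 200 replicates. The end-to-end
smoke test runs 10 participants at a 120 s sampling interval with m = 5
imputations and verifies byte-identical feature artifacts under a fixed
root seed.

## Known limitations

- The Satterthwaite implementation uses finite differences; with nearly
  unidentified variance parameters it falls back to a between-within df
  rather than reproducing lmerTest exactly.
- The D3 statistic pools variance parameters by simple averaging across
  imputations; with heavily skewed variance posteriors this is an
  approximation.
- PMM with a donor pool of 5 slightly attenuates slopes at very small
  sample sizes; the effect is visible (≈0.01 standardized units at
  n = 120 rows) but dominated by sampling error.
- Location variance is computed in squared degrees, so traces at very
  different latitudes are not strictly comparable; the study-scale
  cohort lives at one latitude.
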