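# Methods

## The analysis in one paragraph

Momentary subjective stress is measured by two 7-point items prompted five
times a day; the package predicts its within-person deviations from
passively logged smartphone behavior. Each answered prompt yields a
42-feature vector — per-category app use in the prior hour, sleep proxies
for the prior night, and temporal context — and three regressor families
(LASSO, RBF-SVR, random forest) are trained either across persons with
held-out-person evaluation (nomothetic) or within each person with a
chronological 80/20 split (idiographic). Accuracy is always judged person
by person against a naive person-mean baseline. Shapley attributions then
rank features and, correlated with feature values per person, quantify how
heterogeneous each marker's relation to stress is across people.

## Outcome

`stress_raw = ((8 − relaxed) + stressed) / 2`. The relaxation item is
reverse-keyed before averaging; averaging opposite-valence items
unreversed would cancel the construct. Scores are within-person centered
(each person's own mean subtracted), so models predict deviations from a
personal norm and between-person scale-use differences drop out. Centering
uses the person's full series by default, mirroring common practice; this
leaks a small amount of test-set information into nomothetic training, so
a `centering: train_only` switch recenters on each person's first-80%
rows instead. Unanswered prompts carry no row; stress is never imputed.

## Features

* **App-use windows.** For the 60 minutes before each prompt (window
  length configurable), per category: *duration* = summed overlap of that
  category's sessions with the window, in seconds (so Σ durations ≤ 3600
  for non-overlapping logs), and *frequency* = number of sessions
  intersecting the window. Sessions spanning the window boundary count
  once toward frequency and contribute only their clipped overlap to
  duration. Apps are mapped to 18 core categories by normalized name
  (lowercase, non-alphanumerics stripped); the shipped YAML map seeds each
  category with canonical examples and is meant to be extended. Unmapped
  apps become `other`: retained in the log, excluded from features.
  Overlapping sessions in malformed logs are truncated at the next
  session's start so durations stay additive.
* **Sleep proxies.** For the night anchored at day *d*, consider sessions
  intersecting [d 18:00, d+1 14:00] and take the longest inter-session gap
  that starts in [d 20:00, d+1 12:00] and lasts ≥ 3 h. Onset is the clock
  hour at which the last pre-gap session ended (post-midnight hours coded
  >24, so 01:30 → 25.5); duration is the gap length in hours. These three
  rule parameters are declared package choices from the rule-based
  device-gap family; they are deliberately conservative (a 3 h floor keeps
  late-evening idle periods from masquerading as sleep). A prompt on day
  *d* receives the proxies of night d−1→d; undetected nights are
  person-median imputed and flagged, and persons with zero detected nights
  are dropped with a report.
* **Temporal.** Hour of day 0–23, weekend ∈ {0,1}, day of month, and a
  lockdown indicator that is 1 from the configured lockdown instant onward
  (closed left boundary: a prompt exactly at the boundary counts as
  lockdown).
* **Scaling.** Min-max to [0,1] with bounds from training rows only; test
  values may leave [0,1] and are not clipped. A column constant in
  training maps to 0 for every input, so degenerate features carry no
  information rather than an arbitrary offset.

## Models and tuning

Hyperparameters are selected by inner k-fold search (k = 5, shrinking to
the training size for tiny idiographic sets, never below 2), maximizing
the estimators' default selection score (coefficient of determination),
then refit on all training rows. Default grids are small and standard:
LASSO α ∈ 7 log-spaced points in [1e−4, 10]; SVR C ∈ {0.1, 1, 10},
ε ∈ {0.01, 0.1, 0.5}, γ ∈ {scale, 0.01, 0.1}; RF trees ∈ {100, 300},
depth ∈ {∞, 5, 10}, min leaf ∈ {1, 5, 10}. Idiographic forests use
randomized search with 10 draws (the expensive case); everything else
uses full grid search. All stochastic components — fold shuffling,
randomized search, forest bootstrap, the sampling explainer — derive from
one run seed, which is why a rerun reproduces evaluation artifacts
byte-identically.

The grouped person split assigns whole persons to folds with counts
differing by at most one (224 persons, k=5 → 45/45/45/45/44); scalers and
models inside a fold never see a test person's rows. The idiographic split
takes floor(0.8·n) earliest observations for training; persons with fewer
than 6 observations are excluded, matching the design's inclusion floor.
The naive baseline predicts the person's mean centered stress — over all
their observations in the nomothetic regime (identically 0 under
full-series centering), over training rows only in the idiographic regime
to avoid leakage; its MAE equals the evaluated series' mean absolute
deviation around that constant, a useful exact identity for testing.

## Evaluation

Per person and model: Spearman ρ (average ranks for ties, two-sided
t-approximation p) between out-of-sample predictions and observations, and
MAE. Constant predictions have undefined ρ: they are flagged, excluded
from median-ρ computation, and counted nonsignificant. The headline
"percent significant" counts positive significant correlations only;
negative significant persons are tallied separately, since the two mean
opposite things. Best-model shares (lowest MAE per person, baseline
included) split t-way ties as 1/t so shares sum to 100.

## Shapley explanation

All three explainers satisfy additivity — base value plus row-summed
contributions equals the model prediction:

* **LASSO**: closed form φᵢ = wᵢ(xᵢ − mean(background)ᵢ), exact.
* **Random forest**: the path-dependent polynomial-time tree algorithm,
  computing exact Shapley values of each tree's cover-weighted
  conditional expectation; validated against brute-force subset
  enumeration in the test suite. Rows are cast to float32 before routing
  because sklearn trees predict on float32; without the cast, rows
  straddling a split threshold can take a different leaf than the
  estimator and break additivity.
* **SVR**: permutation sampling over a fixed, seeded background of ≤ 100
  training rows (default 5 permutations). Each sampled ordering
  telescopes from the background mean to the row's prediction, so
  additivity is exact by construction; sampling only affects how credit
  divides among features.

Importance is mean |contribution|, ranked densely (rank 1 = most
important; ties share a rank). Nomothetic importance is computed on
held-out fold rows and aggregated across folds by median; idiographic
importance is computed per person on test rows and aggregated by median,
so the cross-model table's N-median and I-median columns are medians of
medians (the .5 values mark ties). Heterogeneity correlates each feature's
values with its attributions per person on that person's test rows (an
`all-rows` choice is a one-line change in the caller), signing the cell
±1 when p < .05 and 0 otherwise; constant columns are flagged undefined
with sign 0.

**A caveat that matters.** For models whose attributions cannot be exactly
zero — forests and kernel machines — the attribution column is a
deterministic function of the features, so the Spearman p-value tests
whether the *learned response* is monotone, not whether the underlying
association is real. Even on outcome noise, a forest's tiny learned
responses (mean |contribution| < 0.01 stress units) are often monotone
enough to be "significant". Heterogeneity signs from tree models are
therefore best read jointly with attribution magnitudes (the beeswarm
export) or alongside the LASSO, whose L1 zeroing gives exact silence for
dropped features — on pure-noise cohorts the LASSO heterogeneity analysis
signs ~0% of cells, the forest far more.

## The synthetic cohort

The generator emulates the study design so that every downstream stage has
a recoverable target. Per person (independent substream of the global
seed, so growing the cohort preserves earlier persons): nightly sleep
onset ~ N(24.0, 0.75) clock hours and duration ~ N(8.0, 0.75) h; app
sessions fill the waking intervals as a renewal process with circadian
rates (6/8/10 sessions per hour in morning/afternoon/evening — a heavy
student usage level), lognormal session lengths (median 90 s, capped at
30 min), and categories drawn from a prevalence vector putting 77% of
sessions in the 18 core categories (messenger and social network
heaviest) and 23% in unmapped `other` apps. Short anchor sessions pin each
waking interval's ends so the nightly no-use gap equals the drawn sleep to
within seconds. Five prompt times per day are uniform on [08:30, 22:30];
each is answered with probability 0.8.

Latent stress is `intercept (4.0) + Σ βᵢ·x̃ᵢ + N(0, noise_sd)` with
noise_sd = 0.5 on the stress scale, where x̃ are internally standardized
features (duration per 10 min of use, sleep duration/onset per 2 h,
hour and day-of-month spread to unit range) so that coefficient
magnitudes are directly comparable to noise_sd. Ground-truth coefficients
cover the 24-feature truth vector (temporal + per-category duration +
sleep); frequency features carry no effects of their own, since they are
near-duplicates of durations (r ≈ 0.9) and would make sign attribution
ill-posed. Per feature, a coefficient is either fixed (homogeneous
cohorts) or drawn from a negative/zero/positive mixture (default
0.3/0.4/0.3, magnitude 1.0 = 2 noise-SD) — the heterogeneity the
explanation stage must recover. Defaults give temporal features fixed
effects (more stress earlier in the day, on weekdays, later in the month,
under lockdown) and messenger/social/sleep features heterogeneous ones.
Both Likert items derive from the same latent value with independent
N(0, noise_sd/2) item noise, rounding, and clamping to [1,7]; the relaxed
item is generated reverse-keyed.

What the generator does **not** emulate: real app-session length/rate
distributions (no public calibration target exists), autocorrelated or
nonlinear stress dynamics, measurement-burst scheduling, catch-up
surveys, or systematic compliance drift. Passing tests therefore show the
pipeline recovers known linear, independent-noise structure — they do not
certify performance on real behavioral data.

## Problem sizes

The test suite uses a 10-person, 14-day cohort for unit and contract
tests; sign recovery runs at 30 persons × 60 days × 5 prompts (the scale
at which ~190 training observations per person make idiographic forests
meaningful); regime-ordering checks use 15 persons × 20 days over three
seeds; determinism runs the full pipeline twice at 6 persons × 10 days.
The acceptance script's demo pipeline uses 20 persons × 24 days with
trimmed grids (one forest size, two depths). These sizes are the package's
choices for a desk-scale demonstration; all scale up through the config.

## Known limitations

* The shipped category map is a seed, not a complete dictionary; coverage
  on real logs depends on extending it.
* Sleep proxies assume one consolidated nightly gap; split sleep,
  night-shift schedules, or phones left off will be misread.
* The first study day has no prior night and is person-median imputed.
* Heterogeneity signs from tree/kernel models overstate certainty for
  weak markers (see the caveat above).
* Nomothetic full-series centering is mildly optimistic; use
  `train_only` centering for strict leakage control.
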