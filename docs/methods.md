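# Methods

This note documents the models, the synthetic-cohort generator, the
evaluation machinery, the numerical choices, and the limitations of
`respnovel`. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Data model and labeling

A recording is one monitored stay: 5-minute telemetry rows (oxygen flow,
median breathing rate, median inspiratory amplitude, validity flag) plus
metadata (first day, discharge date, exacerbation onset dates). Days are
calendar days; `day_index` is 1-based from the first recorded day. Only
valid rows (spontaneous breathing, good signal quality — an input flag, not
recomputed here) carry respiratory measures; invalid rows still document
oxygen delivery, so daily usage is `5 min × #(rows with flow > 0)`, i.e.
`usage_hours = n_flow_positive / 12`.

Each day is summarized three ways: a summary vector (usage hours, mean rate,
mean amplitude over valid samples), the empirical joint distribution of
valid (rate, amplitude) pairs with uniform weights, and the ordered valid
time series split into segments wherever consecutive valid samples are not
adjacent on the 5-minute grid. A day with fewer than `min_valid_samples`
(default 12, one hour) valid samples counts as *missing* and is dropped from
model fitting and test periods.

Labeling rules:

* **Baseline week** — the 7 calendar days ending at the discharge date
  (inclusive; the boundary convention is fixed here). At least
  `min_baseline_days` (default 4) of them must be non-missing.
* **Eligibility** — recordings lasting ≤ 21 days are excluded (patients can
  take up to ~12 days to return to baseline after an exacerbation, so a
  three-week minimum keeps the final week meaningfully stable); an onset
  inside the baseline week excludes the recording (no week is then a valid
  stable reference); an onset whose preceding 7 days hold no usable data is
  dropped; a with-exacerbation recording with no remaining onset is
  excluded.
* **Pre-exacerbation periods** — the up-to-4 days before each usable onset,
  onset day excluded, missing days dropped.
* **Stable periods** — 4-day windows in control recordings starting on or
  after day 15 and ending strictly before the first baseline day. Start
  days whose window would retain no non-missing day are infeasible (a period
  must hold at least one scoreable day); the sampler draws uniformly over
  the remaining feasible starts.

## Baseline models and novelty scores

All multivariate geometry operates on z-scored variables: breathing rate
(breaths/min) and inspiratory amplitude (arbitrary device units) differ in
scale by a factor of ~20, so each variable is standardized by its baseline
statistics (per-day summaries for single-measure models; pooled baseline
valid samples for the distributional and HMM models). For single-variable
models this is a monotone rescaling and leaves every ROC unchanged; for
multivariate models it is a necessary design choice, documented here.

* **Single measure.** Reference = mean, scale = sample sd (n−1) of the
  non-missing baseline days' values, floored at 1e−8; score = Euclidean
  distance in standardized coordinates. Days missing a required variable
  propagate as "missing day" (no score).
* **Wasserstein barycenter.** The daily distribution is the joint 2-D
  empirical distribution (uniform weights). The reference is the
  free-support barycenter minimizing `Σ_d W₂²(B, P_d)` with uniform weights
  on a support of size `median(n_valid)` capped at 50; optimisation
  alternates exact transport solves with barycentric-projection updates
  (block-coordinate descent; objective non-increasing), seeded
  initialisation from a pooled subsample, max 30 iterations, relative
  tolerance 1e−5. Transport problems are solved exactly as transportation
  LPs (squared-Euclidean cost) with scipy's HiGHS backend — no entropic
  regularisation. The score is `W₂` between the standardized day and the
  barycenter.
* **Hidden Markov model.** Two hidden states, Gaussian emissions with
  diagonal covariances (robust on one week of data) floored at 1e−4 in
  standardized units. Multi-sequence Baum–Welch over all baseline segments,
  each segment restarting from the initial distribution; initialisation by
  seeded 2-means; tolerance 1e−6 on the total log-likelihood, max 200
  iterations; at least 100 training samples required. The novelty score is
  the per-observation negative log-likelihood
  `S = −(1/T) Σ_seg log P(seg | model)` from the scaled forward recursion —
  a length-normalised score invariant to state relabeling. The exact
  normalisation used in prior work being unavailable, per-observation
  normalisation is this package's explicit choice. Baseline days are scored
  in-sample (not leave-one-out), matching how the limits of normality are
  defined.

## Classification and evaluation

Limits of normality per recording/model: `m_b + k·s_b` with `m_b`, `s_b` the
mean and (floored) sample sd of the baseline-day scores. Atypicality is
one-sided (score strictly greater than the limit): every score here is a
deviation magnitude, so only the upper tail signals novelty; the literal
two-sided reading ("outside the limits") was considered and rejected as a
default because distance-based scores cannot be meaningfully *too small*.

A period is pre-exacerbation at rule `n` when ≥ n of its non-missing days
are atypical; a period whose days are all missing is dropped from both ROC
denominators (logged, never silent). Equivalently, the period's operating
statistic is the n-th largest standardized day score `(score − m_b)/s_b`,
with fewer than n scored days giving −∞ (never flagged).

The ROC sweeps the threshold multiplier `k` over −5 … 10 in steps of 0.1
plus ±∞ endpoints; when observed statistics fall outside that range the grid
is extended at the same step so the sweep always runs from everything
flagged to nothing flagged (HMM statistics can legitimately reach z ≈ 20–50
under strong effects, and truncating the sweep would discard real
separation). Points (0,0) and (1,1) are appended; AUC is trapezoidal. Test
sets are resampled 50 times (pre-exacerbation periods fixed — they are what
they are in the data — one fresh stable window per control per repeat), all
seeded from one master seed. The mean ROC is the vertical average on an FPR
grid of step 0.02 with pointwise normal-theory 95% bands (the interval
definition is this package's choice); sensitivity at fixed specificity is
read off the mean ROC by linear interpolation (a per-repeat average is the
documented alternative). Method comparison: one-sided paired t-tests on
per-repeat AUCs for every ordered (method, n) pair, identical columns giving
p = 1 by convention, with Benjamini–Yekutieli adjustment (valid under
arbitrary dependence) applied once over the whole family.

## The synthetic cohort

No public dataset exists for this setting, so the generator emulates the
structure the detection methods assume, with every parameter exposed:

* **Grid and usage.** 288-slot daily grid; the device emits one row per
  slot of oxygen delivery, so a fully used day yields exactly 288 records.
  Usage is one contiguous (nocturnal) session per day, anchored to end at
  08:00 and clipped to the day, of truncated-normal length (default mean
  8 h, sd 0.5 h day-to-day — supervised inpatient therapy is regular; both
  are per-patient parameters).
* **Respiratory dynamics.** Valid samples follow a 2-state Gaussian chain
  stepped per 5-minute slot (default state rate means ~15 vs ~19
  breaths/min, sd 1; amplitudes ~0.85 vs ~0.65 device units, sd 0.08 —
  scales ~20× apart, deliberately exercising the standardization code;
  per-slot stay probabilities 0.90–0.97).
* **Day-level variability.** Each day adds a Gaussian offset to both state
  means (default sd ~0.8 breaths/min, ~0.05 units). This is essential
  realism: without it, within-day averaging makes daily summaries nearly
  deterministic (sd ~0.1 breaths/min over ~100 samples), the baseline
  "scale" degenerates, and limits of normality are meaningless. Real daily
  summaries vary day to day well beyond averaging error.
* **Rehabilitation recovery.** All patients (cases and controls alike — the
  cohort is recruited after an exacerbation-triggered admission) carry a
  rate elevation that decays linearly to zero by the first baseline day
  (slope default 0.02–0.06 breaths/min per day), mirroring improvement
  toward the stable reference.
* **Exacerbation effect.** Over the `ramp_days` (default 4) before the
  onset the state means shift linearly, reaching the full deltas on the eve
  of onset: rate +`delta_rate`, amplitude ×(1 − `delta_amplitude_frac`),
  usage −`delta_usage_hours`. After onset the effect decays to zero before
  the final week (so the baseline stays clean by construction). Default
  delta ranges are placeholders — no published effect sizes exist — and the
  null (all-zero) and strong (rate +4, amplitude −30%, usage −2 h)
  conditions used in tests are always passed explicitly.
* **Missingness.** Whole days drop out with probability 0.05 (baseline-week
  days exempt, preserving trainability by construction; pre-onset days are
  *not* exempt — an earlier draft exempted the onset eve, which made case
  windows retain all 4 days more often than control windows and biased
  high-`n` rules); samples go invalid with probability 0.05.
* **Exchangeability.** Case onsets are drawn uniformly on
  [19, duration − 8], so pre-onset windows occupy the same day range
  (≥ day 15, before baseline) as control stable windows; with all-zero
  deltas the two classes are exchangeable by construction.

What the generator does **not** emulate: oxygen-flow titration, circadian
structure within a session, autocorrelated day-level effects, multi-device
stays, multiple exacerbations per recording, or any validated physiological
model of deterioration. Passing tests on this cohort therefore demonstrate
the pipeline's statistical machinery and its behavior under controlled
signal-to-noise regimes — not clinical performance on real telemetry.

## Numerical choices and degenerate inputs

Sample standard deviations use n−1 and are floored at 1e−8 (limits,
single-measure scales) or 1e−4 (HMM variances, standardized units).
Identical observations drive variances to the floor and stay finite.
Forward/backward recursions are normalised per step; emission densities are
evaluated in log space. The transport LP drops one redundant marginal
constraint for full row rank; 1×m and n×1 problems short-circuit to the
outer-product plan. Barycenter support points get a 1e−9 jitter at
initialisation so coincident points can separate. Score ties at a threshold
classify as normal (strict inequality). All randomness — cohort sampling,
stable-window resampling, k-means and barycenter initialisation — descends
from a single master seed per run.

## Problem sizes

The test suite and the acceptance script run end-to-end evaluations on
cohorts of 10 cases + 14 controls with 50 resampling repeats (the
evaluation-design scale this package targets), forward-recursion oracle
checks on segments of length ≤ 8 (where exhaustive path enumeration is
exact), 1-D transport oracle checks on 2–15-point distributions, and HMM
recovery on baselines of ~1000 valid samples.

## Known limitations

* **Cohort-level variance of mean AUC.** With pre-exacerbation periods
  fixed across repeats, the repeat-mean AUC is the average of the stable
  score distribution's CDF evaluated at the fixed case-period statistics;
  with 10 cases its standard deviation under exchangeability is ≈
  `1/sqrt(12·10)` ≈ 0.09 regardless of simulator noise. Mean-AUC estimates
  at this cohort size therefore carry ±0.1-scale uncertainty between
  cohorts, and narrow calibration bands on a single simulated cohort can
  fail by chance alone; the null-calibration test documents this directly.
* In-sample baseline scoring slightly shrinks baseline scores relative to
  leave-one-out; the limits inherit that bias consistently across methods.
* The free-support barycenter is a local optimiser; different seeds can
  yield different supports (objective differences are checked against
  brute-force oracles on small instances only).
* One baseline model per recording is shared across all of its
  exacerbations; recordings with multiple onsets are supported by the
  telemetry layer but the simulator generates at most one onset per case.
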