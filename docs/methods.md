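# Methods

## The construct

Symptom linkage density (SLD) summarizes, for a single patient, how strongly
their depressive symptoms are coupled from one week to the next during a
12-week course of cognitive therapy (weekly assessments 1–12 plus a
post-treatment assessment as week 13). Nine composite symptom scales in
[0, 1] — mood, interest, energy, guilt, concentration, suicidality, sleep,
psychomotor, appetite — are built by rescaling each instrument item by its
maximum possible score and averaging the items mapped to the same symptom.
For every ordered pair of distinct symptoms (j, k) the package fits, within
the patient,

```
k_t = b0 + b1 k_{t-1} + b2 j_{t-1}
```

by OLS after standardizing each symptom series to mean 0 / sample SD 1 over
that patient's observed weeks. The cross-lag coefficient b2 measures how last
week's level of symptom j predicts this week's level of symptom k beyond k's
own persistence. With nine symptoms there are 9 × 8 = 72 ordered pairs and,
for a fully observed series, 12 one-week lag intervals per regression; SLD is
the unweighted mean of the retained b2. Each patient's grand mean and grand
SD (pooled over all non-missing week × symptom values) are carried alongside
and controlled in every outcome model, so that SLD is evaluated for
*incremental* predictive information.

## Estimator choices

* **No pooling by default.** The per-patient estimator is plain OLS per pair
  — the transparent, exactly reproducible limit of a random-effects-only
  multilevel fit. An empirical-Bayes variant (`shrinkage=True`) shrinks each
  patient's pair coefficient toward the cohort mean for that pair with
  method-of-moments reliability weights; it brackets the shrunken reading of
  the construct.
* **Standardization** is within patient, per symptom, over observed weeks,
  before lagged fitting; this makes SLD unit-free and invariant to positive
  affine rescaling of any raw scale (tested).
* **Lag rows require consecutive calendar weeks**; gaps are not bridged
  (the lag is one week by definition). A pair needs at least
  `min_lag_rows = 4` usable rows (3 parameters + 1 df). A symptom series with
  fewer than 3 observations or zero variance is degenerate and drops the
  8 + 8 pairs it participates in.
* **Data sufficiency.** Patients need ≥ 3 observed weeks (eligibility). An
  SLD built from fewer than `min_coefficients = 48` retained pairs is flagged
  unreliable and reported as missing. Both thresholds are configurable.
* **No detrending by default** (a linear-detrend option exists for
  sensitivity analysis). This matters: see "trend confounding" below.
* **Unboundedness.** Although SLD is often described as ranging from −1 to
  +1, a partial standardized regression coefficient is not mathematically
  bounded by 1 under collinear predictors; the implementation does not clip
  and the estimates can (rarely) leave [−1, 1].
* Pair iteration is lexicographic in (j, k) so logs and outputs are
  deterministic. A vectorized all-pairs solver is used when missingness is
  whole-week (the common case) and is tested to agree with the per-pair path
  to 1e-10.

Cronbach's alpha for SLD treats the 72 pair coefficients as items and
patients as cases, with pairwise-complete covariances.

## Outcome models

* **Response**: no major depressive episode at exit and exit HRSD ≤ 12
  (primary convention) or ≤ 9 (replication convention). ML logistic
  regression of response on grand mean, grand SD and SLD; odds ratios are
  scaled to 1 SD of each predictor, `OR = exp(B · SD)`, an exact identity in
  the results object.
* **Endpoints** (end-of-treatment social adjustment, where higher = poorer,
  and patient/therapist-rated therapy skills): OLS on the endpoint's own
  baseline plus the three summaries; missing endpoints are dropped
  (likelihood-based tolerance with complete predictors); standardized betas
  are `B · SD_x / SD_y`.
* **Follow-up severity**: psychiatric status ratings (PSR, 1–6) averaged
  into 4-month periods (8 periods / 32 months under the primary convention,
  6 / 24 under the replication convention), responders only. Mixed model with
  a patient random intercept (compound symmetry; the covariance structure is
  a config option in principle, only the random intercept is implemented),
  fixed categorical arm and period, grand mean, grand SD, SLD, ML estimation.
  Candidate interactions arm×period, SLD×arm, SLD×period, SLD×arm×period are
  trimmed backward: the three-way family is Wald-tested first and removed at
  p > .05; the two-way families are then each jointly tested in the reduced
  model and the non-significant ones removed together before the final refit.
  Term tests are reported F-style as Wald chi-square / q with denominator
  df = n_patients − n_fixed; p-values are asymptotically equivalent to the
  chi-square version used for trimming. With per-family tests at alpha = .05
  and no generative interactions, the probability that the final model
  retains no SLD interaction is ≈ .95³ ≈ .86, which is what the trimming
  calibration test asserts (with binomial slack).
* **Effect sizes**: Cohen's d with pooled sample SD, and an overlapping
  coefficient computed on a shared histogram binning (for two equal-variance
  normals the population value is 2Φ(−d/2), e.g. 0.617 at d = 1).

## The synthetic cohort generator

The generator is the package's study population. Its latent process is the
estimator's own model class: patient i has a lag-1 matrix A_i with diagonal
`autoreg = 0.25` and off-diagonals drawn around δ_i/8, where the patient
density δ_i ~ N(0.10, 0.45) truncated and rejection-sampled to spectral
radius < 1. **Density is parameterized as the expected total incoming
cross-lag mass per symptom** (not per entry): with nine symptoms a per-entry
mean of 0.2 would force a spectral radius ≈ a + 8 × 0.2 > 1, so the row-mass
convention is what keeps realistic density ranges inside the stability
region.

Weekly latent states follow
`x_t = m_t + A_i (x_{t−1} − m_{t−1}) + ε_t` on the logit scale and are
squashed to [0, 1] levels. The mean path m_t declines linearly on the logit
scale from `trend_start = −0.75` by `trend_change = −1.2` over the 13 weeks
(patient SDs 0.50 and 0.45, per-symptom slope jitter 0.55), emulating
acute-phase improvement. Innovations have SD 0.85 with a 70% common
(general-severity) factor, so symptoms co-fluctuate as they do on real
inventories. Items are emitted as `round(level · max + N(0, 0.15 · max))`
clipped to [0, max] for a 17-item HRSD-like (maxima 2/4), 21-item BDI-like
(max 3) and 30-item IDS-like (max 3) structure (47 mapped items); whole weeks
are removed completely at random at rate 0.09 with week 1 always retained
(expected observed weeks 1 + 12 × 0.91 ≈ 11.9). Response is logistic in δ_i
and final-week severity with exit HRSD and the episode flag generated
consistently with the response definition; endpoints and per-period PSR are
linear in δ_i and the grand mean with Gaussian noise, a patient random
intercept, 4.5%-per-period attrition, and clipping to the 1–6 rating range.
Every patient has an independent RNG substream keyed by patient index, so a
(config, seed) pair regenerates byte-identical files and inserting a patient
does not perturb the others.

These defaults were calibrated once so that the default preset reproduces
the intended study conditions: cohort grand mean ≈ 0.26 (between-patient SD
≈ 0.10), pooled grand SD ≈ 0.17, SLD mean ≈ 0.10, mean observed weeks ≈ 11.9,
median average inter-item correlation ≈ 0.51–0.53 at week 13, response rate
≈ 68–70%. A replication-style preset (threshold 9, 6 periods, two arms,
slightly higher density and lower severity) and a null preset are provided.

## What the generator shows — and what it cannot

* **Trend confounding is real and quantified.** A shared declining mean path
  is forecastable from any symptom's lagged value, so it inflates cross-lag
  coefficients even when the generative cross-lag matrix is zero (≈ +0.07 at
  the default trend). For this reason the *null* preset uses a flat mean path
  (and independent innovations — see next point), realizing "zero linkage"
  as *no shared signal of any kind*; and the density-recovery experiments
  run flat-trend sweeps, because at 13 weekly observations the trend signal
  otherwise dominates patient-level density. On real data, part of any
  positive SLD during effective treatment plausibly reflects the shared
  improvement trajectory; the optional detrend switch exists to probe this.
* **Measurement-error spillover.** With co-fluctuating symptoms and noisy
  item emission, the lagged value of symptom j carries information about the
  (mismeasured) lagged value of symptom k, which genuinely inflates b2 at the
  item level even without coupling — a property of noisy multivariate
  measurement, not a bug in the estimator.
* **Reliability ceiling of the no-pooling estimator.** Each b2 is estimated
  from ~9 residual df, giving a per-coefficient sampling SD ≈ 0.33 and a
  per-patient SLD sampling SD ≈ 0.13 after averaging 72 correlated
  coefficients. Consequently the between-patient SLD SD under the default
  preset is ≈ 0.16–0.17 (not the ≈ 0.08 a shrunken multilevel estimator
  would report), alpha over the 72 coefficients is ≈ 0.85–0.92 rather than
  ≈ 0.95, and the responder/non-responder Cohen's d on *estimated* SLD is
  capped near 0.8–1.0 even when the generative separation is strong. These
  are consequences of 12 lag intervals per patient, not tunable noise.
* The generator does not emulate diagnosis interviews, treatment-arm effects
  on symptom dynamics, informative dropout, or discrete/ordinal symptom
  processes (the latent process is linear-Gaussian so that the null is
  exactly calibrated and recovery is well-posed). Passing tests therefore
  demonstrate estimator correctness and calibrated behavior under the
  linkage model class, not robustness to every real-data pathology.

## Problem sizes used in the test suite

Monte-Carlo checks are sized to run comfortably on one CPU: null p-value
calibration uses 200 replicates of 500-patient series-level cohorts;
density recovery uses three 500-patient cohorts at density 0 / 0.1 / 0.2;
end-to-end directionality uses 50 replicates of 250-patient cohorts
(logistic + trimmed mixed model per replicate); the calibration-anchor check
uses one full item-level cohort of 475 patients. Series-level cohorts skip
item emission; the item-level path is exercised by the anchor, null-centering
and pipeline tests.

## Numerical notes

* Collinear lagged designs are detected by singular-value ratio (cutoff
  1e10) and skipped with the pair's reason recorded.
* Sample SDs (ddof = 1) are used throughout.
* The mixed model tries L-BFGS, then Powell, then CG, and flags
  non-convergence; complete separation in the logistic model falls back to a
  weakly regularized fit flagged `converged = False`.
* Histogram overlap uses a shared `numpy.histogram_bin_edges(..., "auto")`
  binning; overlap of identical samples is exactly 1.
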