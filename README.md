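# sldnet

Idiographic **symptom linkage density** (SLD) for intensive longitudinal
depression data: composite symptom-scale scoring from multi-instrument weekly
item ratings, per-patient time-lagged network density estimation, and a
predictive-validity model suite — plus a synthetic cohort generator with
known ground truth so the whole pipeline is testable without clinical data.

## Who this is for

Researchers studying change processes in treatments for major depressive
disorder (and methodologists working on person-level dynamic measures) who
want a reproducible, tested implementation of the linkage-density construct:
how strongly one patient's depressive symptoms predict each other from week
to week, and whether that density carries incremental information about
treatment outcome.

## The statistic

Nine composite symptom scales (mood, interest, energy, guilt, concentration,
suicidality, sleep, psychomotor, appetite) are scored weekly in [0, 1] by
dividing each inventory item by its maximum possible score and averaging the
items mapped to the same symptom, over 13 weekly assessments (treatment weeks
1–12 plus a post-treatment assessment). For every ordered pair of distinct
symptoms (j, k) the package fits, within patient, the standardized lag-1
regression

```
k_t = β₀ + β₁ k_{t−1} + β₂ j_{t−1}
```

by OLS, over the usable consecutive-week rows, and averages the retained
cross-lag coefficients over all 9 × 8 = 72 ordered pairs:

```
SLD = ( Σ β₂⁽ʲᵏ⁾ ) / 72
```

A positive SLD means that lower levels of one symptom this week predict lower
levels of the other symptoms next week. Each patient's grand mean and grand
SD (pooled over all week × symptom scores) are always controlled in the
outcome models, so SLD is evaluated for *incremental* predictive validity:
a maximum-likelihood logistic model of treatment response (no major
depressive episode and exit HRSD ≤ 12, or ≤ 9 under the replication
convention) with odds ratios scaled per 1 SD of each predictor; linear models
of end-of-treatment social adjustment and therapy skills controlling their
baselines; and a repeated-measures mixed model of post-treatment psychiatric
status ratings (1–6, averaged into 4-month periods) among responders, with a
patient random intercept and backward trimming of non-significant
interactions. See `docs/methods.md` for assumptions, defaults and known
limitations.

## Worked example

```python
import sldnet
from sldnet.simulate import generate_cohort, primary_like
from sldnet.outcomes import ResponseModel, classify_response, effect_size_d

cohort = generate_cohort(primary_like(n_patients=200, seed=1))
results = sldnet.SymptomLinkageModel.from_items(cohort.items).fit()
print(results.summary())

merged = cohort.outcomes.drop(columns=["eligible", "responder"]).merge(
    results.patient_table, on="patient_id")
merged = merged[merged["eligible"] & merged["sld"].notna()].copy()
merged["responder"] = classify_response(
    merged["exit_hrsd"].to_numpy(), merged["mde_at_exit"].to_numpy(), 12)
print(ResponseModel(merged).fit().summary())
d = effect_size_d(merged.loc[merged["responder"], "sld"],
                  merged.loc[~merged["responder"], "sld"])
print(f"Cohen's d (responders vs non-responders): {d:.2f}")
```

prints

```
Symptom linkage density estimation
============================================
patients: 200   eligible (>= 3 weeks): 200
weeks used: mean 11.9 (SD 1.0)
coefficients per patient: median 72 (range 56-72)
SLD: mean 0.089 (SD 0.177)
grand mean: 0.261 (SD 0.095)
grand SD: 0.171 (SD 0.041)
SLD internal consistency (alpha over pairs): 0.897

Logistic regression of treatment response
n = 200, ML estimation, converged = True
term                            B      SE       p   OR/SD
Intercept                    2.00    0.87
grand_mean                  -3.00    3.47   0.387    0.75
grand_sd                    -7.20    8.58   0.401    0.74
sld                          9.24    1.51   0.000    5.16

Cohen's d (responders vs non-responders): 1.15
```

Reading the output: almost every patient contributes the full 72 cross-lag
coefficients (a patient drops to 56 when one symptom is constant over their
observed weeks); the cohort's mean linkage density is ≈ 0.09, i.e. on average
a one-SD lower symptom level this week predicts ≈ 0.09 SD lower levels of
other symptoms next week. In the logistic model, one SD more SLD multiplies
the odds of treatment response by ≈ 5 in this simulated cohort while the mean
and variability terms carry little incremental information, and responders'
SLD sits about one pooled SD above non-responders' — with clearly overlapping
distributions (`sldnet.distribution_overlap`).

The same pipeline runs from the shell:

```
sldnet all --preset primary-like --seed 1 --out runs/demo
```

which writes the scored symptom series, the per-patient linkage table, the
pair-coefficient/edge-matrix exports, and descriptives/response/endpoint/
follow-up tables with a JSON run report (`generate`, `score-scales`,
`estimate-sld`, `fit-models`, `report` run the stages individually).

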