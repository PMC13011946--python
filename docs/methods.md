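# Methods

## Overview

`lbpstrat` stratifies low-back-pain (LBP) cohorts by clustering a
multimodal feature set — lumbar imaging biomarkers (Pfirrmann
disc-degeneration grades and facet-tropism angles at L3/4, L4/5, L5/S1),
smoking status, BMI, sex, and a psychosocial screening-instrument score —
and then characterizes and validates the resulting subgroups. This note
records the model assumptions, the defaults and why they were chosen, and
what the synthetic-data experiments do and do not establish.

## Feature encoding and scaling

Raw variables follow the standard cohort encodings: sex 0/1, smoking
0/1/2 (non/former/current), Pfirrmann grades 2–5, facet tropism in
degrees, LBP frequency 0–4, bothersomeness 0–10. Derived categories:

- disc-degeneration severity: grade 2 mild, 3 moderate, 4–5 severe;
- facet tropism: [0, 10)° normal, [10, 15]° moderately accentuated,
  (15, ∞)° severely accentuated — the boundary at exactly 10° is
  moderate and at exactly 15° still moderate (half-open/closed convention,
  exhaustively boundary-tested);
- bothersomeness: 0–3 low, 4–5 moderate, 6–10 high;
- frequent pain: LBP frequency code 3 or 4 (>30 days/year or daily);
- BMI: WHO bins (<18.5 / 18.5–25 / 25–30 / ≥30).

Risk levels: SBT total ≤3 → low, else psychosocial subscale ≤3 → medium,
≥4 → high; ÖMPSQ-short <40 → low, 40–49 → medium, ≥50 → high. Both
mappings are configurable because published cutoff variants exist; the
defaults here are assumption-bearing and should be overridden if a study
uses different ones.

The clustering matrix holds Pfirrmann grades as ordinal numerics, raw
facet-tropism angles, smoking, raw BMI, sex, and the numerical instrument
score (the coarse 0–2 risk level is available via
`risk_score_column="risk_level"`; the psychosocial column can be excluded
entirely with `include_risk_score=False`). Outcomes never enter the
matrix. Scaling is per-column (x − median)/IQR with linear-interpolation
(type-7) quantiles — the robust-scaler convention — so that ordinal and
continuous columns share a scale without outlier-driven stretch;
zero-IQR columns are centred only and flagged. Stored (median, IQR)
pairs make the transform exactly invertible.

## Consensus clustering

UMAP (defaults: 7 components, 20 neighbours, minimum distance 0.3, fixed
seed, single-threaded and hence deterministic) reduces the scaled matrix.
K-means is then cross-validated five-fold: for each fold, Lloyd's
algorithm with k-means++ initialization (n_init 10, tolerance 1e-6, max
300 iterations) is fit to the other folds, and every held-out point
records the coordinates of its nearest training centroid. A second-pass
k-means over these n × d centroid rows yields final labels that are
provably invariant to per-fold label permutations, because fold labels
never enter the computation. Final labels are canonicalized by descending
cluster size so reports are stable across seeds.

Two genuinely open design points, resolved as follows:

- **Embedding scope.** UMAP is fit once on the full matrix; only k-means
  is cross-validated. Per-fold embeddings would place centroids in
  incomparable coordinate frames, making the stacked centroid matrix
  meaningless. A per-fold-refit mode (`refit_embedding_per_fold`) exists
  for comparison.
- **Model selection.** The grid search ranks configurations by silhouette,
  breaking ties by lower Davies–Bouldin and then higher Calinski–Harabasz,
  and always emits the full metric table for audit. The second-pass k
  equals the fold-level k by default.

## Cluster characterization

Per-cluster summaries report prevalence of frequent pain, the
bothersomeness and risk-level distributions, severe disc degeneration
(grades 4–5) and severe facet tropism (>15°) per level, and the cumulative
FT–DD severity score with its standard error. The cumulative score is
defined as the sum of the three Pfirrmann grades (2–5 each) plus the three
facet-tropism category ordinals (0–2 each), range 6–21; this definition is
a documented assumption (the literature reports cluster means in the 6.9–
9.3 range consistent with it) and is pluggable.

Adjusted odds ratios come from one logistic regression per (cluster,
outcome): the binary outcome (frequent pain, or bothersomeness = high)
against the cluster's robust-scaled features plus the confounders sex,
BMI, and smoking. Wald 95% CIs and two-sided p-values are reported; ORs
are per IQR of the covariate by default (`scale_covariates=False` gives
per-unit ORs). No multiple-testing correction is applied — each feature is
flagged at p < 0.05, matching descriptive forest-plot practice; readers
should treat the flags accordingly. Zero-variance covariates are dropped
with a note; separation or non-convergence is reported per row, not
raised.

## Validation

A multinomial logistic regression (effectively unregularized, ridge 1e-8
for stability) is fit to the cluster labels under stratified five-fold CV,
with scaling parameters estimated inside each training fold. Reported:
per-fold accuracy (mean ± SD), a shuffled-label baseline (labels permuted,
identical CV repeated), one-vs-rest ROC and precision–recall curves with
pointwise 2.5/97.5-percentile bands over 1000 participant-level bootstrap
resamples (precision uses the standard upper-envelope interpolation), and
decision curves: net benefit NB(p_t) = TP/N − (FP/N)·p_t/(1−p_t) on a
0.01–0.99 grid, against treat-all (π − (1−π)p_t/(1−p_t)) and treat-none
(identically 0).

On the chance level of the shuffled baseline: with prediction proportions
q_i and class proportions p_i, E[accuracy] = Σ q_i·p_i. A classifier
trained on permuted labels predicts approximately the training priors, so
argmax prediction drifts toward the majority class and the expectation
approaches max p_i; it equals the often-quoted Σ p_i² exactly when classes
are balanced. The tests pin Σ p_i² on balanced fixtures and the
[Σ p_i², max p_i] bracket otherwise.

## Synthetic cohort generator

The generator emulates a mid-life population cohort with LBP data: three
latent subgroups — *mixed/low* (little degeneration, low psychosocial
risk, relatively accentuated facet tropism), *psychosocial-dominant*
(elevated instrument scores, intermediate moderate-grade degeneration,
more current smokers, more women), and *degenerative-dominant* (severe
degeneration at L4/5 and L5/S1, low psychosocial risk) — mixed with
weights (0.40, 0.25, 0.35). Within a subgroup, grades are categorical per
level (independent across levels by default; a Gaussian-copula shared
severity factor is available via `dd_latent_rho` but ships off because no
calibration target exists for it), facet-tropism angles are zero-truncated
normals, BMI is truncated normal, and the SBT total is a rounded normal
with a binomial psychosocial subscale.

Outcomes are drawn from two proportional-odds (cumulative-logit) models —
LBP frequency over 5 categories, bothersomeness over 11 levels — whose
default coefficients carry effect sizes in the range reported for such
cohorts (risk level OR 2.0, disc degeneration at L4/5 OR 1.87 and L5/S1
OR 1.76 for frequent pain; facet tropism at L3/4 protective). Cutpoints
were set analytically so category frequencies approximate published
baseline tables at the mixture's mean linear predictor. Participants with
frequency 0 receive bothersomeness 0, mirroring the questionnaire's
two-part gating. Percentages in the baseline-characteristics report are
truncated, not rounded, matching the convention of published tables.

**Calibration of subgroup separation.** Mixture marginals approximate the
published baseline characteristics (sex ≈ 53% female; smoking ≈ 51/30/19%;
severe degeneration concentrated at L5/S1 ≈ 44–50%; facet tropism mostly
<10°). The one deliberate deviation: between-subgroup contrasts were set
strong enough that the three subgroups are actually recoverable —
consistent with the high internal validity (silhouette near 0.8) reported
for consensus clusters on real cohort data — which pushes the marginal
prevalence of medium/high psychosocial risk above the published ≈11%.
With weaker contrasts the latent structure is not identifiable by any
method and the generator would not serve its purpose as ground truth.

**What passing tests show, and what they do not.** The generator draws
each subgroup from parametric, conditionally independent distributions;
real cohort data has within-subgroup correlations (e.g. between adjacent
disc levels, BMI and degeneration), measurement error in model-derived
imaging biomarkers, and missingness patterns that are only crudely
emulated (`missingness_rate` blanks fields completely at random).
Recovery of the synthetic subgroups (ARI ≥ 0.8, k = 3 selected) therefore
demonstrates correctness of the machinery, not that three subgroups exist
in any particular real cohort.

## Problem sizes and numerical choices

Default experiment sizes: n = 800 for the recovery experiment (five folds
of 160 comfortably support k ≤ 5), n = 2000 for odds-ratio coverage
simulations, n = 5000–10000 for distributional goodness-of-fit checks,
1000 bootstrap resamples for curve bands. Quality metrics use the standard
definitions; ties in k-means are resolved by best-of-n_init WCSS;
bootstrap resamples that lose a class reuse the point estimate for that
draw; thresholds for decision curves exclude 0 and 1 where net benefit is
undefined.

## Known limitations

- The SBT/ÖMPSQ risk-level cutoffs and the cumulative FT–DD score are
  plausible published conventions, not universal standards; both are
  configurable and flagged.
- Adjusted ORs are associational; no causal adjustment beyond the three
  confounders is attempted.
- UMAP determinism holds for fixed seed and single-threaded execution;
  embeddings (and hence exact metric values) are not comparable across
  UMAP versions.
- The generator's marginals trade fidelity to published psychosocial-risk
  prevalence for subgroup recoverability, as described above.
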