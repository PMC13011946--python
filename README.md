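# lbpstrat

Unsupervised, multimodal stratification of low-back-pain (LBP) cohorts.

Screening questionnaires such as the STarT Back Tool (SBT) and the short
Örebro Musculoskeletal Pain Screening Questionnaire (ÖMPSQ-short) stratify
patients by psychosocial risk but ignore physiology; imaging biomarkers
(disc degeneration, facet tropism) capture physiology but not psychosocial
burden. `lbpstrat` implements a pipeline that combines both: it encodes
demographic, lifestyle, psychosocial, and lumbar-MRI-derived variables,
embeds them with UMAP, and stratifies participants with a cross-validated
**centroid-matrix consensus k-means**, then characterizes and validates the
resulting subgroups. It is aimed at epidemiologists and biostatisticians
working with population-cohort LBP data.

## The algorithm

K-means labels are arbitrary across runs, so naive cross-validation of a
clustering cannot be aggregated. The consensus procedure sidesteps labels
entirely:

1. Robust-scale the feature matrix (Pfirrmann grades and facet-tropism
   angles at L3/4, L4/5, L5/S1; smoking; BMI; sex; psychosocial score):
   x → (x − median)/IQR per column.
2. Embed with UMAP (defaults: 7 components, 20 neighbours, min_dist 0.3).
3. Split points into five folds. For each fold, fit k-means on the other
   four folds and record, for every held-out point, the **coordinates** of
   its nearest training centroid — an n × d centroid matrix.
4. Run a second-pass k-means on the centroid matrix. Because only centroid
   coordinates enter, the result is invariant to each fold's arbitrary
   label numbering.
5. Score the partition (silhouette, Davies–Bouldin, Calinski–Harabasz);
   choose UMAP hyperparameters and k by grid search.

Clusters are then profiled (prevalence of frequent pain — LBP on >30
days/year — and high bothersomeness; cumulative FT–DD severity score;
per-cluster odds ratios adjusted for sex, BMI, and smoking) and validated
(five-fold multinomial logistic regression on the cluster labels vs. a
shuffled-label baseline, 1000-bootstrap ROC/PR bands, and decision-curve
analysis with net benefit NB(p_t) = TP/N − (FP/N)·p_t/(1−p_t)).

A synthetic-cohort generator with three latent subgroups
(psychosocial-dominant, degenerative-dominant, mixed/low) and
proportional-odds outcome models makes the whole pipeline testable without
access to restricted cohort data.

## Worked example

```python
import lbpstrat as L
from sklearn.metrics import adjusted_rand_score

cfg = L.default_config(n_participants=800, seed=0)   # 3 latent subgroups
cohort = L.generate_cohort(cfg)
result = L.stratify(cohort, seed=0)                  # grid search over k
print(result.k, result.quality)
print(round(adjusted_rand_score(cohort["true_subgroup"], result.labels), 3))
```

prints

```
3 {'silhouette': 0.5450352747968789, 'davies_bouldin': 0.6784990302788115,
   'calinski_harabasz': 1951.7516093948357}
0.84
```

i.e. the grid search selects k = 3, the partition is well separated
(silhouette 0.55, low Davies–Bouldin, high Calinski–Harabasz), and the
consensus labels recover the generating subgroups with adjusted Rand index
0.84. The same run from a shell, with all artifacts (labels, centroid
matrix, grid-search table, cluster summaries, odds-ratio tables, ROC/PR and
net-benefit curves, manifest) written to a run directory:

```sh
lbpstrat run --simulate --seed 7 --out runs/demo
```

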