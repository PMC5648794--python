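# histomorph

Nuclear histomorphometry for H&E tissue-microarray (TMA) spots: a tested,
reusable implementation of a quantitative-pathology pipeline that predicts
disease recurrence from the architecture, shape, orientation and chromatin
texture of tumour nuclei, and relates the prediction to recurrence-free
survival.

**Who it is for.** Computational-pathology researchers who want a transparent,
scriptable alternative to opaque end-to-end models: every descriptor has a
closed-form definition, every stage is a plain function on open data
structures, and a synthetic phantom generator makes the whole pipeline
testable without patient material.

## The method

Given a segmented TMA spot (nuclear boundary polygons + centroids), the
package computes a **242-descriptor feature vector** in five families:

| family | count | what it measures |
|---|---|---|
| `graph_global` | 51 | Voronoi / Delaunay / minimum-spanning-tree statistics over nuclear centroids, k-NN distances, neighbour counts in fixed radii |
| `graph_cluster` | 26 | topology of the cell-cluster graph (mean-shift nuclear clusters as nodes) |
| `shape` | 100 | 25 per-nucleus descriptors (area, perimeter, radii, compactness, Fourier shape descriptors FSD1–10, …) × {mean, std, median, min/max ratio} |
| `orientation` | 39 | 13 second-order (Haralick-type) statistics of the per-cluster co-occurrence of quantised nuclear orientations × {mean, median, std} |
| `texture` | 26 | 13 gray-level co-occurrence statistics inside nuclear masks × {mean, std} |

Heterogeneity is summarised throughout by the bounded disorder statistic

```
disorder(x) = 1 − 1 / (1 + σ(x)/μ(x))  ∈ [0, 1)
```

with sample (n−1) standard deviation.  Fourier shape descriptors are
`FSD_k = |F_k| / |F_0|` of the centroid-to-boundary radius signal, resampled
to 128 equal arc-length points — invariant to translation, rotation, scale
and start vertex.

**Feature selection** is a two-stage scheme: minimum-redundancy
maximum-relevance (mRMR, mutual-information difference criterion) keeps the
top 3 features per family (15 candidates), then an exhaustive search over all
C(15,7) = 6435 seven-feature subsets picks the subset with the best quadratic
discriminant (QDA) cross-validated accuracy on shared stratified folds.
**Classifiers**: QDA, LDA and a degree-2 polynomial-kernel SVM on
standardised features.  **Survival analysis**: Kaplan–Meier with log-rank
tests, multivariable Cox proportional-hazards models (Efron ties), Fisher
exact and McNemar tests, and Cox-derived risk scores
`r = Σ β_j z_j` (standardised selected features weighted by Cox
coefficients), stratified at the per-dataset median and tertiles.

Pipeline front end: monotone-spline (PCHIP decile-matching) colour
normalisation and marker-controlled watershed nuclear segmentation on a
colour-deconvolved hematoxylin channel; external segmentations can be
imported from integer label masks.

## Worked example

```python
import numpy as np
from sklearn.model_selection import train_test_split
import histomorph as hm
from histomorph.survival_stats import km_logrank, stratify

# a synthetic cohort: 120 patients, half with the aggressive phenotype
spec = hm.CohortSpec(n_patients=120, seed=7)
images, nuclei, clinical = hm.generate_cohort(spec)
features = hm.extract_cohort_features(images, nuclei)
table = features.merge(clinical, left_on="spot_id", right_on="patient_id")
y = table["recurrence"].to_numpy().astype(int)

idx_tr, idx_te = train_test_split(np.arange(120), test_size=0.5,
                                  stratify=y, random_state=7)
train, test = table.iloc[idx_tr], table.iloc[idx_te]
selection, model, scores, calls = hm.recurrence_pipeline(
    train, y[idx_tr], test, n_iter=10, seed=7)
print("selected:", selection.selected)
report = hm.evaluate(calls, scores, y[idx_te])
print(f"held-out AUC = {report.auc:.3f}, accuracy = {report.accuracy:.3f}")

risk = hm.cox_risk_scores(train, selection.selected,
                          train["rfs_months"], train["event_observed"])
groups = stratify(risk.score(test), np.quantile(risk.score(test), [1/3, 2/3]))
_, chi2, p = km_logrank(test["rfs_months"], test["event_observed"], groups)
print(f"risk-tertile log-rank: chi2 = {chi2:.2f}, p = {p:.2e}")
```

Output:

```
selected: ['graph_global.mst.edge_mean', 'graph_global.density.nuclei_count',
 'graph_global.density.neighbors_r30_std', 'graph_cluster.node_count',
 'graph_cluster.component_count', 'graph_cluster.end_node_pct',
 'shape.perimeter_mean']
held-out AUC = 0.967, accuracy = 0.967
risk-tertile log-rank: chi2 = 35.54, p = 1.92e-08
```

The selection stage found the architectural contrast built into the phantom
presets (clustered vs regularly spaced nuclei); the QDA model trained on 60
patients separates the held-out 60 almost perfectly, and the Cox risk-score
tertiles split the held-out survival curves decisively.

A command-line interface mirrors the library:

```bash
histomorph synth --n-patients 120 --seed 7 --out-dir cohort/
histomorph segment --in cohort/images --out cohort/seg
histomorph features --boundaries cohort/boundaries --images cohort/images --out features.csv
histomorph select --features features.csv --labels cohort/clinical.csv --seed 7 --out sel.json
histomorph train --classifier qda --features features.csv --labels cohort/clinical.csv --selection sel.json --out model.json
histomorph predict --model model.json --features features.csv --out preds.csv
histomorph survival --clinical cohort/clinical.csv --preds preds.csv --out report/
```

## Coordinate and data conventions

Pixel coordinates are 0-based, `x` = column, `y` = row, origin top-left;
polygons are stored counter-clockwise (positive shoelace area) as open rings.
All distances are in pixels; `microns_per_pixel` (default 0.5, the 20×
convention) is metadata only.  Boundaries round-trip through CSV
(`spot_id,nucleus_id,vertex_index,x,y`) and JSON; features through CSV with
`spot_id` + the 242 registry columns; models through JSON.

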