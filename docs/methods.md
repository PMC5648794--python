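# Methods

This note documents the models and procedures implemented in `histomorph`,
the defaults they use, and the design choices made where the literature
leaves the details open.

## 1. Feature families and the registry

The feature registry (`core_io.feature_registry`) fixes 242 descriptor names
in five families (51 global-graph, 26 cluster-graph, 100 shape,
39 orientation, 26 texture) and is the single source of truth for names,
categories and order.  The registry is a declared reconstruction: the family
totals and the anchor descriptors (Voronoi area min/max ratio, mean
neighbour count in a 40 px radius, Fourier descriptors 4 and 8, the three
"Haralick standard deviation" texture statistics) are fixed by the
literature on this pipeline family; the remaining members are chosen to be
the standard descriptors of each family and are enumerated explicitly in the
registry code.

Statistical conventions, used everywhere:

* sample (n−1) standard deviation;
* `minmax_ratio = min/max ∈ (0, 1]`;
* `disorder = 1 − 1/(1 + σ/μ) ∈ [0, 1)` — a bounded transform of the
  coefficient of variation; 0 iff the values are constant, scale-invariant,
  and defined as 0 when μ = 0;
* all entropies in bits (log₂), with 0·log 0 = 0.

### Global graphs (51)

Nodes are nuclear centroids.  Voronoi statistics ({mean, std, min/max ratio,
disorder} × {cell area, cell perimeter, chord length}) use **bounded cells
only**; unbounded hull-adjacent cells are excluded rather than clipped to the
image — simpler and deterministic.  "Chord length" is the edge length between
consecutive Voronoi cell vertices, pooled across bounded cells.  Delaunay
statistics are over unique triangulation edges and triangle areas.  The
Euclidean MST is built with Prim's algorithm; equal-weight frontier edges are
broken by the smallest (tree-node, new-node) index pair, making the tree
deterministic under ties.  Density statistics: distance to the {3,5,7}-th
nearest neighbour, neighbour counts within {10,20,30,40,50} px, nuclei count,
nuclei per 10⁴ px², and the fraction of image pixels within 40 px of a
centroid (computed on the pixel grid by disk rasterisation, so it is a
grid-level approximation).  Fewer than 4 non-collinear centroids make all 51
values NaN with a warning; a k-NN feature with fewer than k+1 nuclei is NaN.

### Cluster graph (26)

Nuclei are clustered by **flat-kernel mean-shift** on centroids (bandwidth
40 px).  The implementation is a synchronous fixed-point iteration with
greedy mode merging by support; it is deterministic and is cross-checked
against scikit-learn's `MeanShift` on separated data in the test suite.
Cluster centroids are member means.  Clusters u, v are linked iff
d(u,v)^(−α) ≥ r (α = 0.5, r = 0.1, i.e. d ≤ r^(−1/α) = 100 px; both in
config).  The 26 descriptors are the standard cell-cluster-graph set; path
metrics (eccentricity, diameter, radius, average path length) use hop counts,
are computed per connected component and averaged with component node counts
as weights, and are 0 by convention for edgeless graphs.  The "core-90"
variants restrict to the ⌈0.9k⌉ largest-degree nodes.  Clustering
coefficients: C = mean local transitivity over all nodes (nodes of degree <2
contribute 0), D = global transitivity (3 × triangles / connected triples),
E = mean local transitivity over nodes of degree ≥ 2.  Central points are
nodes whose eccentricity equals their component's radius.  Edge-length
skewness/kurtosis are the biased moment estimators (Fisher kurtosis), 0 when
there are too few edges.

### Shape (100)

25 per-nucleus descriptors × {mean, std, median, min/max ratio} across
nuclei.  The boundary is resampled to 128 equal arc-length points starting
from the vertex farthest from the area centroid (this canonical start makes
every downstream statistic independent of the stored ring's start vertex).
Radii are distances from the area centroid to the resampled points.  Major
and minor axis derive from the PCA eigenvalues of the resampled boundary
(boundary points of an ellipse have variance a²/2 along the major axis, so
axis length = 2√(2λ)).  Compactness is 4πA/P² (clipped to ≤1), solidity
A/A_hull, extent A/A_bbox, convex-perimeter ratio P_hull/P, and bending
energy the mean squared discrete curvature of the resampled boundary.
FSD_k = |F_k|/|F_0| (k = 1..10) of the radius signal — the real-valued,
rotation- and scale-invariant descriptor family matching the min/max-radius
vocabulary; chosen over complex-coordinate descriptors.  Aggregation needs
≥2 valid nuclei, otherwise NaN; per-nucleus failures skip the nucleus with a
warning.

### Orientation entropy (39)

Each nucleus's direction is the angle of the first principal axis of its
resampled boundary points, folded to [0°, 180°); nuclei with eigenvalue
ratio < 1.05 are flagged low-confidence (the angle is still returned).
Orientations are quantised into B = 10 equal bins over [0°, 180°).  For each
mean-shift cluster with ≥2 members, a symmetric B×B co-occurrence matrix is
accumulated over **all unordered within-cluster pairs** and normalised; the
13 second-order statistics (below) are computed per cluster and aggregated
across clusters by mean, median and std (std is 0 when only one cluster
qualifies, avoiding NaN poisoning).  The pairing rule and B are declared
choices; the cluster definition is shared with the cluster graph.

### The 13 second-order statistics

For a normalised symmetric matrix P with marginals p_x = p_y, difference
distribution p_diff(k) = Σ_{|i−j|=k} P_ij and sum distribution
p_sum(k) = Σ_{i+j=k} P_ij:

* contrast energy Σ (i−j)² P_ij; contrast inverse moment Σ P_ij/(1+(i−j)²);
* contrast average/variance/entropy: mean, variance and entropy of p_diff;
* intensity average/variance/entropy: mean, variance and entropy of p_sum;
* entropy −Σ P log₂ P; energy Σ P²;
* correlation (Σ ij P_ij − μ_x μ_y)/(σ_x σ_y), 0 when a marginal is
  degenerate;
* information measures of correlation IMC1 = (H − H1)/max(H_x, H_y) and
  IMC2 = √(1 − e^{−2(H2 − H)}), with H1 = −Σ P_ij log₂(p_x p_y) and
  H2 = −Σ p_x p_y log₂(p_x p_y).

A termwise independent transcription of these formulas is the oracle in the
test suite (tolerance 1e−10).

### Texture (26)

Luminance (ITU-R 601 grayscale × 255) pixels inside each nuclear polygon are
quantised to 16 levels by equal-width binning over the range of **all**
nuclear pixels in the spot (so levels are comparable across nuclei of one
spot).  A symmetric GLCM per nucleus is accumulated over the four distance-1
offsets (0,1), (1,0), (1,1), (1,−1); the 13 statistics per nucleus are
aggregated across nuclei by mean and std.  Masks under 16 px are skipped
with a warning.

## 2. Preprocessing

**Colour normalisation** maps each RGB channel of a source image onto a
template by a monotone spline through 11 matched quantiles (deciles):
duplicated source knots are collapsed, a PCHIP interpolant (monotone through
monotone data) is evaluated into a 256-entry LUT, clipped and made
non-decreasing.  Constant channels get the identity with a warning.  This is
a variant of spline-based stain normalisation — the published knot scheme is
not fully specified, so the decile scheme here is declared, not a
replication.

**Watershed segmentation**: fixed published H&E colour-deconvolution matrix →
hematoxylin channel → Gaussian smoothing (σ = 1.5 px) → Otsu threshold →
small-component removal → Euclidean distance transform → local-maximum
markers (min separation 5 px) → marker-controlled watershed → per-label
contour tracing → area gate 30–3000 px².  The defaults are matched to the
synthetic-phantom scale (nuclei of roughly 100 px²; at full-resolution 20×
material use ~10 px separation and a 80–3000 px² gate) and meet a ±10%
count accuracy on both phantom presets.  Stain vectors are fixed rather than
estimated per image: simpler, deterministic, and adequate for phantoms.
Imported integer label masks go through the same contour-tracing path
(`mask_to_boundaries`), so downstream code cannot tell segmentation sources
apart.

## 3. Synthetic phantoms

The generator emulates the contrast between an aggressive phenotype
(clustered, disordered, irregular, heterogeneous) and an indolent one
(regular, aligned, smooth, homogeneous):

* **placement**: hard-core dart throwing (uniform proposals rejected within
  `min_spacing_px`) or Neyman–Scott (uniform parents, Gaussian offspring,
  clipped to bounds, same hard-core constraint); bounded retries then error;
* **orientation**: von Mises on the doubled angle (the standard axial-data
  construction), κ = 0 meaning uniform;
* **boundary**: polar ellipse radius × (1 + g(t)) where g is a sum of cosine
  harmonics 2–8 with random phases rescaled to peak amplitude
  `fourier_perturb_amp` < 1 — the polygon stays star-shaped and hence
  simple; per-nucleus size jitter is lognormal (sd 0.12);
* **rendering**: flat eosin-pink background; nuclei coloured by a
  hematoxylin-like linear map of intensity = base + a Gaussian random field
  smoothed at `blob_scale_px` and rescaled to sd `heterogeneity_sd`;
* **survival**: recurrence-free survival is Weibull (shape 1.5; scale 20
  months for the recurrent phenotype, 80 for the non-recurrent — ordering
  enforced) censored by an independent Uniform(0, 120 months); the event
  flag is recurrence-or-death-first semantics, censored at last follow-up.

Defaults: spots are 256×256 px with 70 nuclei — the same order of nuclear
density as a full 1500×1500 spot, scaled down so that a 20-seed end-to-end
experiment runs on one CPU in minutes; cohorts default to n = 120 with a 0.5
recurrence fraction.  All randomness flows through `numpy.random.default_rng`
(PCG64); identical seeds give byte-identical cohorts.

What the phantoms do **not** emulate: stain physics, stromal/immune cells,
segmentation ambiguity at real tissue boundaries, label noise, or any
correlation structure between clinical covariates and morphology.  Passing
the end-to-end tests therefore demonstrates that the pipeline recovers a
built-in morphology–outcome association; it says nothing about effect sizes
on real cohorts.

## 4. Selection and classification

Mutual information uses equal-frequency discretisation into 8 bins.  The
mRMR variant is the difference criterion (relevance − mean redundancy;
quotient form available in config), greedy within each family, ties broken
by registry order; the top 3 per family give 15 candidates.  The subset
search evaluates **all** C(15,7) = 6435 subsets by mean QDA accuracy over
shared stratified 3-fold splits (default 100 repeats; the end-to-end tests
and the acceptance script use 5–10 repeats, which the shared-fold design
makes sufficient at n = 120).  Per fold, class means and covariances are
estimated once in the 15-dimensional candidate space and every subset's QDA
is the corresponding slice, evaluated with batched Cholesky factorisations —
this is what makes the exhaustive search run in seconds.  Ties break by mean
AUC, then mRMR rank-sum, then lexicographic order.  The subset size (7) is a
config knob.

QDA/LDA are Gaussian discriminants with empirical priors; class (or pooled)
covariances are ridge-regularised by 1e−4 · trace/d.  They are implemented
in-package so that models serialise losslessly to JSON and the subset search
can batch them; scikit-learn's discriminants are the independent oracle in
the tests.  The SVM is scikit-learn's SVC with polynomial kernel (degree 2,
coef0 = 1, gamma = "scale"); the bundle stores support vectors, dual
coefficients and intercept, and prediction recomputes the kernel expansion
(verified against `decision_function` to 1e−10).  Features are standardised
by training mean/sd stored in the bundle.  Binary calls threshold the
class-1 posterior at 0.5 (QDA/LDA) or the margin at 0 (SVM).

Evaluation: confusion counts, accuracy, recall (sensitivity), PPV,
specificity, ROC points and the trapezoidal AUC (midrank-equivalent under
ties; constant scores give 0.5).  One-class truth makes the AUC NaN with a
warning.

## 5. Survival statistics

Kaplan–Meier estimates and the standard log-rank test (chi-square with
groups−1 df) come from lifelines; a no-event input short-circuits to
(statistic 0, p 1).  Multivariable Cox models use lifelines' `CoxPHFitter`
with Efron tie handling; covariates are dummy-coded against explicit
reference levels, defaulting to (Female, T1, N0, predicted-non-recurrence);
constant covariates are dropped with a warning, |coef| > 10 triggers a
separation warning.  Note that duplicating all subjects is only
approximately invariant under Efron's correction (exactly invariant under
Breslow).  Cox risk scores standardise the selected features, fit the Cox
model, and define the score as the linear predictor; median and tertile
(1/3, 2/3 sample quantiles, linear interpolation) cutpoints are computed
per dataset, matching the convention of computing cutpoints on training and
validation sets separately.  Zero-variance features get coefficient 0; an
all-constant score vector is flagged degenerate.  Fisher's exact test is the
two-sided conditional test (sum of table probabilities ≤ observed, scipy);
McNemar's test is the exact two-sided binomial on discordant pairs
(p = 1 when there are none).  All tests are two-sided.

## 6. Numerical choices and degenerate inputs

* Polygon validity is enforced at I/O boundaries (shapely `is_valid`);
  internally generated star-shaped polygons are valid by construction.
* Centroids always equal the polygon area-centroid (1e−6 px invariant).
* Near-regular point patterns can produce Voronoi sliver cells from float
  noise; tests therefore pin exact centroids when exercising degenerate
  geometry.
* Correlation and the information measures are defined as 0 for degenerate
  marginals; min/max ratio of an all-zero value list is 1 by convention.
* Quantisation edge cases (constant channels, constant grayscale) map to the
  lowest bin and degenerate GLCMs (energy 1, entropies 0).

## 7. Problem sizes used by tests and the acceptance script

Unit tests run on constructed fixtures (tens of nuclei).  Property suites:
geometric oracles on 100 random 10-point sets; Cox recovery on 20 × n = 500
simulations; the end-to-end suite on 20 cohorts of n = 120 (60/60
train/validate split, 5 CV repeats in the subset search).  The acceptance
script runs one n = 120 cohort with 10 CV repeats.  These sizes keep a full
run in minutes on one CPU while leaving every statistical check
well-powered.

## 8. Known limitations

* The registry reconstruction (section 1) is faithful in counts and anchors
  but not guaranteed to match any particular published supplementary list
  descriptor-for-descriptor.
* The cluster-graph linking parameters (α, r) and the orientation binning
  are declared defaults; published values for this family vary.
* The colour-normalisation variant matches deciles, not full histograms.
* Segmentation is tuned for phantom-scale nuclei; real 20× material needs
  the documented config changes.
* Survival simulation uses independent censoring and exact phenotype-linked
  scales — real cohorts are messier in both respects.
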