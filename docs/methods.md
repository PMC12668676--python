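# Methods

This note documents the models and procedures morpholink implements, the
defaults and why, what the synthetic generator does and does not emulate,
and the numerical choices made where the design was genuinely open.

## Data model

The unit shared between modalities is the **experimental population**: one
cell line at one differentiation day. The default design is 6 lines at day
20 and 4 lines at days 40 and 70, i.e. 14 populations present in both the
imaging and the expression dataset. Imaged cells carry per-cell morphology
features plus QC metadata (areas, channel intensities) and a field
reference; fields carry four per-channel PowerLogLogSlope blur statistics.
Expression is a cells × genes matrix on the log-normalized scale
(`ln(1 + count·10⁴/total)` when starting from counts) with per-cell S and
G2M cell-cycle scores.

## Quality control

Three filters compose in a fixed order (fields → morphology →
intensity/density); each later filter sees only surviving cells.

* **Blur.** A field is retained iff the mean of its four channel slopes is
  *strictly greater* than −2.16 and CellProfiler did not flag it. All cells
  of a discarded field are discarded.
* **Morphology.** Removal at cytoplasm area ≤ 1000 or ≥ 100,000 and nucleus
  area ≤ 10,000 — all bounds inclusive, as printed.
* **Intensity/density.** Removal at nucleus intensity ≤ 0.003 (the mean
  intensity statistic; configurable, since the statistic is not pinned
  down), or when the cell's 2-D density in the (nucleus intensity, summed
  other-channel intensities) plane is ≤ 10⁻⁴. Density uses a product
  uniform (box) kernel of half-width `bandwidth = 1` on the raw coordinate
  scales, self-inclusive, normalized so that k cells sharing one box give
  density k/(n·(2b)²). The normalization constant is a design choice (only
  the kernel and bandwidth are fixed by the procedure); with it, the 10⁻⁴
  cut means "an isolated point among ≥ 2,500 cells is an outlier", which
  matches the intent at study scale but will not transfer to very small
  datasets — the threshold is configurable for that reason.

## Feature regularization

Six distribution families, assigned by deterministic rules on summary
statistics (non-negative and skewness > 1 → log; integer counts → log;
bounded in [0,1] → logit with clamp ε = 10⁻⁶; |skewness| ≤ 0.5 → identity;
excess kurtosis > 3 → signed log `sign(x)·log₂(1+|x|)`; otherwise rank
inverse-normal with Blom-type offset (r−½)/n). All transforms are monotone,
so within-feature rank order is preserved. After transformation each
feature is min–max scaled to [0, 1000]; constant features are dropped with
a warning. When datasets are merged, regularization is applied to the
reunified matrix, so the scale is global, not per batch.

## Subsampling and redundancy selection

Per population at most 2,000 cells are drawn without replacement; if the
capped total still exceeds the 50,000–60,000 target range the cap is
lowered to the largest integer that fits, and below the range nothing is
upsampled. A bootstrap utility reports the Pearson correlation between a
subsample's per-feature mean vector and the full data's, the statistic used
to justify the target range.

Features with |Pearson r| > 0.99 (on regularized values) are joined by an
edge; communities come from greedy modularity maximization
(Clauset–Newman–Moore agglomeration, written in-package so that ties in
modularity gain break deterministically toward the smallest node index);
one feature per community is retained. "Most parsimonious" is
operationalized as fewest underscore-delimited name tokens, then shortest
name, then lexicographic — a proxy for the simplest measurement, since no
formal criterion exists. Spatial x–y, Zernike, and the neighbor-angle
feature are excluded by configurable name patterns. Manual removal of
artifact clusters is config-supplied only, never inferred.

## Clustering, embedding, modules

Cells: Leiden (RB-configuration quality, seeded) on the undirected
Euclidean KNN graph with n_neighbors = 20; resolution defaults to 1.0 and
is configurable since no value is prescribed. UMAP (same n_neighbors,
seeded; random init below 11 cells where spectral init is undefined) is for
reporting only.

Feature modules: distance d = 1 − cov/max|cov| (normalizing by the largest
absolute covariance keeps distances comparable across modules; Pearson
distance available behind a flag), average-linkage hierarchy, cut at k
chosen by the **derivative-loss** rule: with loss(k) the total
within-cluster sum of squared pairwise distances, the gain g(k) =
loss(k−1) − loss(k) is the discrete derivative, and k* maximizes
g(k) / max g(k′>k) — the point after which the loss curve contributes
nothing comparable again. If no candidate reaches a ratio of 3 the module
count falls back to the range minimum with a "no elbow" warning; genuinely
unstructured data occasionally shows an incidental ratio spike, so k is
overridable by config (the reference analysis used 18 on its data).
Activation scores project each module's centered submatrix on its PC1
loading (unit norm, computed by dense eigendecomposition; features already
share the [0,1000] scale, so PCA centers but does not rescale), oriented so
the score correlates positively with the module's mean feature value.
Single-feature modules score as the centered feature. Modules are
auto-named `{dominant statistic}.{dominant channel}` from feature-name
tokens.

## Cross-modal model

Only populations present in both modalities are used. Cells of each
population are randomly split into three balanced metacells (member counts
differ by ≤ 1) and mean-aggregated; which replicate serves as validation is
a seeded random choice per population. With 14 shared populations this
yields two aligned 42-row matrices.

Per image feature, a lasso (objective (1/2n)·Σresid² + α·Σ|β|, α = 0.02,
max_iter = 10,000, tol = 10⁻⁴, coordinate descent with precomputed Gram)
is fit on the 28 training metacells; the 14 validation metacells yield
per-feature Pearson r and R² and never touch the fit. Predictors are not
standardized (a `standardize` flag exposes the known sensitivity);
responses stay on the [0,1000] regularized scale. α = 0 falls back to
least squares via the normal equations. At this α the fit can stop at
max_iter for some features — expected in the p ≫ n regime; a warning lists
it. Per-cell predictions are β₀ + X·β.

"One value per gene" is implemented as the univariate slope
cov(x_g, y_f)/var(x_g) over all 42 metacells (a joint OLS with thousands
of predictors on 42 rows is undefined); zero-variance genes get slope 0
and a flag. Per-module gene rankings are the median of these slopes over
the module's features, sorted descending with stable name tie-breaks —
the `.rnk` input for pre-ranked enrichment tools.

**Support recovery** is evaluated by ranking (gene, feature) pairs by the
*standardized* univariate coefficient |slope|·sd(gene)/sd(feature) (the
gene–feature correlation) against the planted nonzero weights. Raw slopes
are unusable for a pooled ranking: a near-constant gene's slope is inflated
by its tiny variance in the denominator, and lasso coefficients are sparse
with ties at zero (coordinate descent keeps at most n_train of a correlated
gene block), which degenerates a ranking AUROC by construction. The
**negative control** refits the lasso after permuting the rows of the
expression metacell matrix, which destroys the population correspondence
between the modalities; per-feature validation correlations are pooled over
several permutations (a single permutation yields one effectively
correlated draw per feature block and a noisy median). Note that permuting
*population labels* wholesale is not a valid control: it produces a
relabeled but still consistent pairing that the model learns equally well.

## Annotation and transfer

* **Cell-cycle transfer**: two independent lassos (S ~ features,
  G2M ~ features; α reuses 0.02, unstated in the source procedure) trained
  per cell on the predicted feature matrix, then applied to the real
  regularized matrix of imaged cells.
* **Marker scores**: standardized mean difference
  (mean_in − mean_out)/pooled SD (the reference implementation's scoring
  rule is not public; one-vs-rest AUC is available behind a flag). Marker
  matrices from the two modalities are correlated row-by-row over common
  features.
* **Representative features**: contribution = |PC1 loading| normalized by
  the module max; predictability = |Σ_g β(g,f)|/max(|β₀(f)|, 10⁻⁸) from the
  lasso (the ratio involves the lasso intercept, so lasso coefficients are
  used); score = product; top scorer per module, lexicographic ties.
* **Marker genes of a feature**: genes with |slope − mean| > 2.5 SD,
  two-sided. Two-sided is deliberate: for ~17,370 genes the normal
  two-sided 2.5 SD tail is ≈ 1.24 % ≈ 215 genes, consistent with the
  138–270 per-feature range the procedure is known to produce, whereas a
  one-sided rule would give roughly half that.
* **Label transfer**: first nearest neighbor (Euclidean), assigned iff
  distance < 400 strictly, on the shared regularized (and batch-corrected)
  feature space.
* **Batch correction** is a pluggable contract — corrected per-feature
  batch medians must agree — with a median-alignment stand-in as default;
  external tools can replace it through the file interface.
* **Association statistics**: per (line, cluster) log₂ odds ratio from the
  2×2 table with Haldane 0.5 correction on zero cells; adjusted mutual
  information between line and cluster partitions per stratum; the raw
  abundance table is exported for external differential-abundance tools.

## Synthetic generator

Cell state is a population mean plus per-cell Gaussian perturbation
(sd 0.3) in a latent program space; genes load sparsely on programs;
features are linear in programs, so the induced gene × feature weight
matrix W = L·A is exact ground truth and matches the linearity the lasso
assumes. Defaults are the shared-population design: 14 populations × 200
cells per modality, 2,000 genes, 300 features, noise sd 0.1. Ten programs
with ~10 genes each (link density 0.005) plant compact, marker-like
programs; features take one dominant (0.6–1.0) and one weaker (0.3–0.6)
program loading, so planted module blocks are correlated well below the
0.99 redundancy threshold. Redundant features add 3 % jitter to a source
feature (r > 0.99); cell-cycle scores are linear in the programs for both
modalities. Raw feature values apply the *inverse* of each family's
regularization transform (with a fixed offset of 6 in log₂ space keeping
intensity-like values positive), so regularization is testable by round
trip — exactly invertible except for count rounding. QC artifacts are
planted to violate exactly one rule each: slopes −3.0 on blurry fields,
areas in (0, 1000] / [100,000, 150,000], nucleus intensity in (0, 0.003],
and density outliers spaced ≥ 10 units apart far from the intensity cloud
so each sits alone in its kernel box.

What the generator does **not** emulate: pixel data, count-level
sequencing noise, realistic gene–gene covariance beyond programs, batch
effects within a modality, nonlinear gene–morphology links, or ambiguous
borderline QC cases. Passing tests therefore demonstrate correctness of
the machinery and recoverability of planted linear structure, not
performance on real data, where the linearity and noise assumptions are
approximations.

## Problem sizes and determinism

The test-suite study dataset is 14 populations × 200 cells with 2,000 genes
and 300 features — the full lasso setting (42 metacells, 28 training rows);
the pipeline smoke run uses ~5,000 imaged cells with 1,000 genes and 200
features; the negative control uses three permutations over a 50-feature
subset per permutation. Every random draw flows from named integer seeds
through `numpy.random.default_rng`; pipelines write SHA-256 manifests and
identical configs reproduce byte-identical outputs.

## Known limitations

* The exact family definitions, the authors' derivative-loss and marker
  scoring implementations, and the KDE normalization are not published;
  the operationalizations above are explicit and configurable stand-ins.
* The 10⁻⁴ density threshold is scale-coupled (see QC) and should be
  revisited for datasets far from ~50k cells.
* At α = 0.02 on [0,1000]-scale responses the lasso under-regularizes
  (p ≫ n interpolation); validation metacells, not training fit, are the
  meaningful quality signal, and coefficient supports should be read
  per correlated gene block rather than per gene.
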