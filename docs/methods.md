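# Methods

## Model and assumptions

The package models the expression of each highly variable gene (HVG)
within one cell type as a linear function of the spatial presence of
every cell type around each cell:

    u_{c,h} = sum_b f_{c,b} w_{b,h} + eps_{c,h}

- `u_{c,h}`: z-scored expression of HVG *h* in cell *c* (z-scoring per
  gene within the cell type, sample sd).
- `f_{c,b}`: z-scored neighbor score of cell *c* for type *b*.
- `w_{b,h}`: the communication coefficient — its sign is the direction
  of regulation by neighboring type *b*, its magnitude the strength.

The assumptions this encodes: (i) regulation by neighbors is additive
across neighbor types and linear in the score; (ii) the relevant spatial
signal is a single scalar per (cell, type); (iii) residual variation is
homoscedastic after z-scoring. Spatial autocorrelation of the residuals
is not modeled; p-values from the coefficient filter are therefore
calibrated under an exchangeable-cells null, not a spatially correlated
one.

### Neighbor score

    f'_{c,b} = sum over cells m != c with label b of log10(dist_{c,m} / dist0)

`dist0` is the minimum pairwise distance in the dataset, so the nearest
pair contributes log10(1) = 0 and the score is scale-free: multiplying
all coordinates by any s > 0 leaves the z-scored scores unchanged
(verified numerically in the tests). The sum runs over all cells with no
radius cutoff; distances are computed as a full Z x Z matrix.

Note the score *increases* with distance. It is implemented exactly as
stated because it is the quantity the downstream statistics are defined
on; a decaying alternative kernel `exp(-dist/dist0)` is available
(`kernel="exp_decay"`) for users who want proximity-weighted scores.
Coincident cells make `dist0` zero and are a hard error by default; a
deterministic, seeded jitter option displaces coordinates by at most
1e-6 of the bounding box.

### Regression

Per cell type, the multi-response regression U = F W + G is fitted by
NIPALS PLS2: both blocks are mean-centered (a numerical no-op after the
upstream z-scoring), components are extracted by iterating
x-weight/x-score/y-loading/y-score to convergence (tolerance 1e-12 on
the score vector, max 500 iterations) with rank-one deflation of both
blocks. The coefficient matrix decomposes per component,
W = sum_c r_c q_c^T with r_c the rotation of component c, so each
w_{b,h} is the sum of per-component contributions w_{b,h,c} — the
telescoping identity holds to machine precision and is asserted in the
tests. With as many components as the predictor rank the PLS solution
equals ordinary least squares (oracle-checked to 1e-8).

No penalty or extra constraint is placed on the coefficients; the
"constrained/powered" extensions of PLS reduce, with default powers, to
this standard PLS2, and no concrete constraint set was specified to
implement. The component count C is chosen by seeded 10-fold
cross-validation (cells shuffled once, contiguous near-equal folds):
the C in [1, min(A, Z_a - 1, 10)] minimizing the mean out-of-fold
root-mean-squared prediction error, ties toward the smaller count. A
strict argmin is used rather than a one-standard-error parsimony rule;
on pure-noise responses it selects C = 1, while at high signal-to-noise
it may legitimately keep all components, because fold-level predictor
correlations leave a little signal after each component that later
components recover.

### Coefficient filtering

Two stages at FDR threshold delta (default 0.05), per cell type:

1. For each component c, Pearson correlations corr(f_b, t_c) and
   corr(u_h, l_c) against the stored (undeflated) x- and y-scores are
   converted to two-sided t-test p-values (df = n - 2) and BH-adjusted
   within the {predictor x component} and {gene x component} families
   separately. w_{b,h,c} survives only if both adjusted values are
   below delta.
2. The surviving tensor is summed over components; each nonzero pair
   (b, h) is tested by the direct correlation corr(f_b, u_h),
   BH-adjusted over all tested pairs, and zeroed unless the adjusted
   value is below delta.

Degenerate correlations (zero variance) get r = 0, p = 1. Filtering
never alters a surviving value, only zeroes others. Under a simulated
global null (independent F and U, 100 cells, 50 genes, 3 types, 200
replicates) the retained fraction is ~0.1-0.2%, far below delta; the
test suite asserts the bound delta + 3 binomial sd.

### Clustering and the MIMO graph

Genes whose entire filtered coefficient row is zero are dropped. The
remaining genes' A-length coefficient vectors are clustered with
k-means (k-means++ init, 10 restarts, seeded) for each k in
[2, min(15, n_genes - 1)]; the k with the largest mean silhouette wins,
ties toward the smaller k. Silhouette uses Euclidean distance with the
conventions: singleton clusters contribute 0, and 0/0 is defined as 0
(hand-implemented for these conventions; cross-checked against
scikit-learn on non-degenerate inputs). Cluster indices are 0-based.

Per receiver type the cluster-mean coefficient vectors form a k_a x A
matrix. So that unequal cluster counts cannot bias the comparison
between receivers, every receiver keeps only its k_min largest-L2-norm
clusters, with k_min the minimum cluster count over receivers (or an
explicit override). The directed weight from sender b to receiver a is
the Euclidean norm over kept clusters of their mean coefficients toward
b. The A x A matrix is thresholded at the mean of its off-diagonal
entries (diagonal excluded from graph semantics and zeroed); the same
mean is the attenuation constant — the accompanying narrative mentions
a median, but the printed aggregation uses the mean and one constant is
used for both roles.

Indirect communication: for every ordered pair, all simple directed
paths (no repeated nodes, at most A - 1 edges) through the thresholded
graph are enumerated; a path's contribution is the sum over its edges of
weight(e_s) - mean * 10^(1 - s), where s is the edge position from the
source. Because thresholding guarantees every surviving weight >= mean
and the subtracted term never exceeds mean, every contribution is
nonnegative. The simple-path restriction makes the path sum finite; an
exhaustive recursive enumerator in the tests reproduces the
implementation exactly on all graphs with up to 6 types.

### HVG selection

Per cell type: genes with zero expression across the type's cells are
dropped; the rest are ranked by variance-stabilized standardized
variance — a lowess regression (span 0.3) of log10(variance) on
log10(mean) across genes predicts each gene's expected sd, expression
is standardized by it, standardized values are clipped above at
sqrt(n_cells), and genes are ranked by the variance of the clipped
values, keeping the top n_top (default 2000). Selection is per type
rather than global because the per-type HVG sets, and their overlap,
are themselves quantities of interest; global selection is available by
passing the whole dataset. The overlap ratio between per-type HVG sets
is the mean over ordered pairs (i, j) of |H_i ∩ H_j| / |H_i|
(`min_fraction` uses the smaller set as denominator instead).

### Gene labeling and classification

Communication-relevance labels come from offline annotation text: a
gene is labeled 1 when any strong keyword (receptor(s), ligand(s),
cell–cell adhesion, intercellular interaction) occurs as a
case-insensitive substring after normalizing hyphen/en-dash/space;
weak keywords (pathway, regulation, signal transduction, ...) are
recorded but never set the label. Classifier features per gene are its
filtered coefficient toward each neighbor type averaged over cell types
where it is a retained HVG, plus mean expression, log1p variance and
dropout fraction (length A + 3); the coefficients are the method's own
measure of communication involvement, and the summaries let the
classifier separate structurally inactive genes. The MLP has one
hidden layer of 64 rectified units, early stopping on a 10% validation
split, at most 500 epochs, and is evaluated by stratified seeded
k-fold cross-validation (accuracy, precision, recall, F1, AUROC per
fold and mean).

## Synthetic data

The generator emulates the structure of sequencing-resolution spatial
datasets: spatially clustered cell types, per-type HVGs, and genes
whose expression is linear in neighbor-type scores plus Gaussian noise.
Cells of each type occupy contiguous unit patches tiled over a
near-square 2-D grid (a triangle for 3 types). A single-axis stripe
arrangement was rejected: with all spatial structure on one axis the
within-type score columns become collinear (condition number ~30) and
coefficient magnitudes are unrecoverable even in the OLS limit; the
2-D tiling keeps the within-type design well conditioned (condition
number < 4) while remaining contiguous blocks. A Poisson-scatter layout
with region labels is also available.

A fraction `frac_responsive` (default 0.2) of genes each receive one
sender type and sign, with coefficient ±`effect_size` (default 2) on
the z-scored score, plus Gaussian noise (`noise_sd`, default 0.5);
expression is shifted per gene to be nonnegative (an exponential
transform is optional), which leaves all downstream z-scoring
untouched. Defaults follow the recovery study conditions (600 cells, 3
types, 200 genes). The generator uses the package's own neighbor
scorer so the generative and inference models agree by construction;
the tests therefore keep an independent brute-force scorer to break
that circularity.

What the simulation does not emulate: count noise (negative binomial,
library-size effects), within-type substructure, label noise, and
spatially autocorrelated residuals. Passing the recovery tests shows
the estimator chain is correct and calibrated under its own model, not
that real tissues satisfy the model.

Parameter recovery is assessed in consistent units: the pipeline
estimates coefficients on per-type z-scored expression, so estimates
are multiplied back by each gene's within-type sd before comparison
with the planted raw-unit coefficients; sign recovery is unit-free.
Under the default conditions, all 120 responsive (gene, type) pairs
survive the filter, 100% of signs are recovered, and the
planted-vs-estimated correlation is ~0.99.

## Numerical choices and degenerate inputs

- z-scoring uses the sample sd (ddof = 1); constant columns map to all
  zeros rather than NaN.
- All tabular output is written with 6 significant digits; round trips
  are relatively accurate to ~1e-5.
- BH adjustment delegates to statsmodels (`fdr_bh`); p-values outside
  [0, 1] are rejected.
- k-means ties and restarts are controlled by a single seed; repeated
  runs are bit-identical.
- Types with fewer than `min_cells_per_type` (default 10) cells are
  skipped with a warning; an error is raised only if no type remains.
- CV folds are reduced (with a warning) when a type has fewer cells
  than folds.

## Known limitations

- The score's growth with distance means far-away cells of a type
  dominate its raw score; interpret coefficients as responses to the
  type's overall spatial configuration, not to touching neighbors.
  The `exp_decay` kernel inverts this behavior if desired.
- O(Z^2) distance and score computation; datasets beyond ~50k cells
  need blocking or subsampling upstream.
- The filter's error control assumes exchangeable cells; spatially
  autocorrelated expression inflates the effective false-positive rate.
- Keyword labeling is only as good as the supplied annotation text;
  it replaces interactive database queries to keep labeling
  reproducible and offline.
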