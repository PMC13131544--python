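# Methods

This note documents the model, the estimation procedure, the synthetic-data
generator, the numerical choices, and the limitations of `coprog`.  Nothing
here reports an empirical number that the test suite or
`scripts/acceptance.py` does not itself compute.

## Model and estimation

**Preprocessing.**  Expression is centered and (by default) unit-variance
scaled within each cell type, then reduced by PCA.  Genes with zero
within-type variance are excluded before scaling and re-enter with zero
loadings whenever weights are decoded to gene space, so gene-weight vectors
always span the full panel.  PC scores are whitened (per-column unit
variance) by default: with whitened scores the normalization constraint
`W'X'XW = I` of the multi-column objective reduces to unit-norm weight
columns, which is what the sequential algorithm enforces.  Default dimension
is 40 components, clipped to `min(n_t − 1, m)`.  Whether expression should be
log-normalized beforehand is data-dependent (raw counts are fine because of
the internal centering/scaling; log-normalized input is equally valid) and is
left to the caller — the loader takes whatever matrix it is given.

PC sign indeterminacy is fixed by orienting every component so its
largest-|loading| gene has a positive loading; this makes weights
reproducible across runs and transferable across fits.  For multi-sample
fits, cells of a type are pooled across slides and embedded on one common
basis; per-slide scores are the row blocks.  A shared basis is what makes a
single weight vector per type meaningful across slides.

**Objective.**  One canonical axis maximizes
`Σ_q Σ_{s<t} w_s' X_s,q' K_st,q(σ) X_t,q w_t` over unit-norm weight vectors,
one per cell type.  Two solvers are provided: block power iteration (default)
— each free type's weights are replaced by the normalized sum of its
kernel-weighted partner projections, cycling until the largest weight change
drops below `tol` (default 1e−6) or 500 iterations — and a damped
coordinate-descent variant that mixes the current weights with the power
direction (step `alpha`, default 0.5), useful when plain power iteration
oscillates.  The objective is non-convex in general, so the solver restarts
from 5 seeded random initializations and keeps the best objective; a fit with
a single free type is a linear problem and uses one start.  With identity
kernels, matched cells and whitened embeddings the procedure reduces exactly
to classical two-view CCA (verified against the SVD solution in the tests).

**Components beyond the first** come from deflation: each type's score
direction `v = Xw` is projected out of its embedding
(`X ← X − v v'X / v'v`), and the objective is re-optimized on the residual.
Deflation acts on embeddings only; kernels are reused.  Scores of successive
components are therefore orthogonal within each sample.  The joint sign of a
component's weight tuple is arbitrary; it is oriented so the first cell
type's scores correlate positively with that type's first principal
component.

**Within-type mode.**  For a single population the objective is the quadratic
form `w'X'KXw`; the optimum is the leading eigenvector of the symmetrized
matrix, computed directly.  Degenerate top eigenspaces (e.g. identity
kernels on whitened scores, where every direction ties) are resolved by
projecting the first coordinate axis onto the tied eigenspace — a
deterministic, basis-independent tie-break.

**Supervised mode.**  A known ordinal axis (e.g. an anatomical segment
ordering) is turned into a reference weight vector by OLS regression of the
labels on the PC scores, normalized to unit length.  Fixed types are never
updated; the conditional optimum for the free types is then unique up to
convergence of the block updates.  Fixing *all* types turns `fit` into a pure
evaluation of scores and metrics.

## Kernels

The default kernel is isotropic Gaussian on Euclidean distance,
`K_ij = exp(−d_ij²/2σ²)`, in the input coordinate units — no internal
rescaling, so bandwidth grids must be expressed in those units.  An optional
upper-quantile distance cutoff zeroes far pairs; kernels below 25% density
are stored sparse.  Two variants:

- **Morphology-aware filter.**  Geodesic distances on a k-nearest-neighbor
  graph (k = 10 by default, Euclidean edge weights) are compared with a
  linear Euclidean→geodesic fit estimated on the graph's own edges; pairs
  whose geodesic distance exceeds `reclassify_factor` (default 2.0, our
  choice — no canonical value exists) times the fitted prediction are set to
  a sentinel distance (1e6 × the maximum observed distance), forcing their
  kernel weight to zero.  Pairs in disconnected components are always
  non-local.  This prevents leakage across lumens, folds, and tears.
- **Directional kernel.**  Separate bandwidths along and perpendicular to a
  user-chosen unit axis:
  `exp(−[(Δ∥/σ∥)² + (Δ⊥/σ⊥)²]/2)`.  This is our concrete parameterization of
  axis-specific spatial weighting (two bandwidths plus an axis); it reduces
  to the isotropic kernel when the bandwidths agree and lets overlapping
  gradients along different anatomical directions be separated by refitting
  with different axes.

## Coordination metrics and bandwidth selection

`NCorr = w_i'X_i'K X_j w_j / (‖X_i w_i‖ ‖X_j w_j‖ ‖K‖_s)` is bounded in
[−1, 1] (Cauchy–Schwarz with the spectral norm) and comparable across
bandwidths, which is why it drives bandwidth selection: the first component
is fit at every σ of a grid (identically seeded) and the σ maximizing the
mean NCorr over all (type pair, sample) entries wins, ties toward smaller σ.
The default grid is geometric with 8 points spanning 1%–30% of the
coordinate-range diagonal.  Spectral norms are computed by power iteration
(≤100 iterations, tolerance 1e−7), which also serves sparse kernels.

NCorr is not an interpretable correlation, so coordination strength is
reported as **BSC**: the average of the Pearson correlations between each
population's scores and the kernel-weighted *mean* of the partner's scores.
The weighted-mean normalization makes BSC invariant to affine score
transforms (`v → a·v + b`, `a > 0`), exactly like an ordinary correlation,
and antisymmetric under negating one side; `bsc(v_i, v_j, K) =
bsc(v_j, v_i, K')`.  Cells whose kernel row/column sum falls below 5e−2 are
excluded first — near-isolated cells otherwise destabilize the smoothed
scores.

A caveat on bandwidth selection: the NCorr profile identifies the planted
smoothing scale only when the candidate bandwidths are *resolvable* at the
data's sampling density.  When cells are so dense that the smallest grid
value still captures many cross-type neighbors, bandwidths below the true
scale are statistically adequate and can win the argmax — while recovery of
the gradient at the selected bandwidth remains essentially unchanged.  The
scale-recovery test therefore runs at a density where the smallest candidate
is below the typical cross-type neighbor spacing.

## Significance testing

The observed statistic is the re-optimized NCorr of the tested component and
type pair.  The null is built by patch permutation: the tissue is gridded
into axis-aligned square bins (side 2σ by default, grid anchored at the
bounding-box corner), a seeded random permutation maps bins to bins, and for
each tested type the expression profiles occupying a bin's coordinate slots
are replaced by same-type profiles from the mapped bin — without replacement
when counts match, with replacement otherwise.  Coordinates, other types,
and per-bin counts never change.  The model is re-estimated on every
replicate (the per-type PCA basis is fixed: permutation moves whole
profiles, so the pooled PCA is unchanged up to row order when counts match).
P-values use the add-one rule `(1 + #{null ≥ obs})/(1 + n_perm)`, so they
are never zero.  By default all types except the first listed (or except the
supervised anchors) are permuted, each with its own seeded stream.

**Limitation.**  Bin shuffling preserves within-type autocorrelation only
*below* the bin scale.  Because the observed statistic is a supremum over
weight vectors, it can exploit cross-bin smoothness of the tested type's
field that the shuffled null lacks, so the conditional null is somewhat too
narrow and the test is anti-conservative under the simulated null: across
sampling densities the measured rejection rate at nominal α = 0.05 ranges
from roughly 0.10 at sparse density (300 cells) to 0.2–0.3 at benchmark
densities, as computed by the calibration suite.  Changing the patch side,
permuting both types, or altering the count-mismatch resampling policy does
not repair this; an autocorrelation-preserving mapping (e.g. a random torus
translation of bins) narrows the gap but departs from the plain bin-shuffle
design and is not the default.  P-values from this test should therefore be
read as a strong-effect screen rather than an exact level-α guarantee —
under genuine co-progression the observed statistic sits far outside the
null (power ≈ 1 at p ≤ 0.01 in the alternative scenario).  A naive null
that shuffles cell positions outright ignores within-type autocorrelation
entirely and rejects about half the time under the null — it is included in
the tests only as a cautionary comparator.

## Gene programs and transfer

Because PCA and the canonical objective are linear, a PC-space weight vector
equals an exact gene-space functional on standardized expression:
`g = V diag(1/s) w` with loadings `V` and raw PC-score standard deviations
`s` (back-projection).  Weights are defined on *standardized* expression;
the reference per-gene mean/sd are carried with the program.  An alternative
regression route — the per-gene slope of standardized expression on the
standardized score, i.e. the per-gene Pearson correlation — avoids PC
collinearity and tends to travel better across replicates.  For deflated
(k > 1) components, back-projection uses the weight vector in the original
basis; the regression route on the actual component scores is exact in all
cases.

Transfer standardizes the target's genes with the reference statistics,
optionally after per-gene quantile normalization (midpoint ranks, ties
averaged, linear interpolation into the sorted reference values), and
projects.  Quantile normalization makes the projected scores invariant to
any strictly monotone per-gene distortion of the target.  Genes missing from
the target are imputed at the reference mean (their weight effectively
drops, logged); a fit fails if less than half the informative genes overlap.
Scores can also be propagated across cell types through a cross-type kernel
as a kernel-weighted mean, with low-support targets flagged NaN.  A generic
quantile summary (default 90th percentile) aggregates per-sample scores for
severity-style comparisons.

## Synthetic-data generator

The generator emulates the core structure of a dissociated single-cell
atlas feeding a spatial simulation:

1. **Pool** — `softplus(F L' + shift + ε)` with standard-normal factors `F`
   (10 latent dimensions by default), loadings scaled to unit per-gene latent
   variance, per-type mean shifts of norm 2 (types separable but
   overlapping), and Gaussian noise of sd 0.3; 200 genes by default.  This
   reproduces low-rank gene–gene correlation and nonnegative, skewed
   expression; it does **not** model count noise (Poisson/NB), dropout,
   batch effects, or realistic mean–variance relationships — conclusions
   about those regimes cannot be drawn from these tests.  Any user-supplied
   expression table with type labels can replace the synthetic pool.
2. **Fields** — uniform positions on the unit square, multinomial types,
   standard-normal initial scores smoothed with a Gaussian of
   `σ_sim = 0.1` (our choice of smoothing scale and tissue size; both
   config-exposed), either within each type only (null: autocorrelation
   without co-progression) or across all cells (alternative: one shared
   gradient).  For two axes, two independent fields are smoothed and the
   second is residualized against the first, giving exactly uncorrelated
   ground-truth axes.
3. **Planting and assignment** — per type, a random unit weight vector on
   the pool's top PCs defines the planted program (orthonormal vectors for
   multiple axes; a dedicated program seed lets replicate slides share
   programs); pool scores and field values are quantile-transformed and
   coupled by rank matching — the exact 1-D optimal-transport solution — or,
   for two axes, by an exact linear-assignment solve on summed squared
   quantile distances.  For multi-axis instances the achievable ground truth
   is re-derived by regressing the field on the placed cells' PC scores,
   since the 2-D coupling cannot follow both fields exactly.
4. **Ceiling** — the correlation between the placed cells' own program
   scores and the ground-truth field bounds what any method can recover on
   that instance; it is reported with every scenario and asserted against
   fitted recoveries in the tests.

Default scenario sizes are 2,000–3,000 cells (pool twice the sample size);
the permutation-calibration suite uses 300-cell instances and the
bandwidth-recovery suite 800-cell instances, for the statistical reasons
given above — both choices are properties of the experiments, documented
here, not tuning knobs.  Recovery is measured as |Pearson r| between fitted
scores and ground truth, z-scored within type and pooled across types
(the axis orientation is arbitrary, hence the absolute value).

## Numerical choices and degenerate inputs

- Convergence: max per-type weight-vector change < 1e−6; 500 iterations;
  objective ascent is monotone for plain power iteration and asserted in
  tests.
- Whitening tolerance: score columns satisfy `scores'scores = n·I` to 1e−6;
  rank-deficient embeddings are clipped with a warning.
- Zero-norm score directions skip deflation with a warning; all-fixed
  supervised fits skip optimization; constant supervision labels, empty
  samples, non-square within-type kernels, and zero-norm metric inputs raise
  typed errors.
- Sparse kernels: density < 25% stored CSR; sentinel distance 1e6 × max
  observed distance.
- All randomness flows through seeded NumPy generators; fits, simulations,
  and CLI commands are bit-reproducible given their seeds.

## Known limitations

- Linear model: strongly nonlinear co-progression is out of reach by design.
- Kernel cost is quadratic in cells per type pair; very large slides need
  subsampling or the quantile cutoff + sparse storage.
- The permutation test's density-dependent anti-conservatism (above).
- Axis transfer imposes the reference program on the target; target-specific
  axes that deviate from the reference are invisible to transferred scores.
- Quality of the axes depends on the input cell-type labels; mislabeled
  cells blur the cross-type coupling.
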