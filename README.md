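# coprog

Coordinated spatial progression analysis for single-cell-resolution spatial
transcriptomics.

Tissues are organized along continuous gradients — liver lobular zonation,
the intestinal crypt–luminal axis, the renal corticomedullary axis — and
different cell types progress along these gradients *together*: a hepatocyte's
metabolic state co-varies with the angiocrine program of the endothelial
cells beside it.  `coprog` finds such shared axes directly.  Given per-cell
expression, 2-D coordinates, and broad cell-type labels, it estimates one
gene program per cell type such that the programs' per-cell scores are
maximally correlated *between spatially neighboring cells of different
types*.

## The model

For cell types `t = 1..T`, let `X_t` be the whitened PC scores of type *t*'s
(centered, scaled) expression, and let `K_st(σ)` be a Gaussian spatial kernel
between the cells of types *s* and *t*,
`K_ij = exp(-d_ij² / 2σ²)`.  One canonical axis solves

    max_{w_1..w_T}  Σ_q Σ_{s<t}  w_s' X_s,q' K_st,q(σ) X_t,q w_t
    s.t. ‖w_t‖ = 1,

summing over samples *q* (weights are shared across slides; scores are
per-slide).  This is classical CCA with the cross-type covariance re-weighted
by spatial proximity — the kernel acts on *coordinates*, not on expression,
so the model stays linear and the weights remain interpretable gene programs.
`v_t = X_t w_t` is the **cell progression score**: each cell's position along
the inferred axis.  Further axes come from sequential deflation and are
orthogonal within each sample.  A single cell type reduces to an eigenproblem
on `X'KX` (within-type mode); fixing one type's weights to a known axis (for
example an ordinal anatomical ordering regressed onto PC scores) gives the
supervised mode.

Supporting machinery, all included:

- **Bandwidth selection** — σ maximizing the mean first-component
  kernel-normalized correlation `NCorr = w_i'X_i'K X_j w_j /
  (‖X_i w_i‖‖X_j w_j‖‖K‖_s)` over a grid.
- **BSC** (bidirectional spatial correlation) — the symmetric average of the
  Pearson correlations between each population's scores and the
  kernel-weighted mean of the partner's; an interpretable coordination
  strength in [−1, 1].
- **Significance** — a patch-based permutation test: square spatial bins
  (side 2σ) of the tested type are randomly shuffled, expression moves while
  coordinates stay, the model is re-estimated per replicate.  This preserves
  within-type spatial autocorrelation, which naive coordinate shuffling
  destroys (and which makes naive permutation wildly anti-conservative).
- **Transfer** — back-projected (or regression-based) gene weights applied to
  another slide after per-gene quantile normalization onto the reference
  distribution, for cross-sample comparison on one biological axis.
- **Simulation benchmark** — spatial samples built by optimal-transport
  assignment of synthetic single-cell profiles onto smoothed score fields,
  with exactly known ground truth and a per-instance performance ceiling.

## Worked example

```python
import coprog
from coprog import simulate as sim

# a two-type tissue with one shared, spatially smooth gradient
sample, truth = sim.simulate_scenario("alt2", n_cells=2000, seed=1)

fit = coprog.fit(sample, seed=1)          # bandwidth selected automatically
print(f"sigma = {fit.sigma:.3f}")
print(f"mean NCorr = {fit.mean_ncorr():.3f}")
r = sim.recovery_correlation(fit, truth, sample)
print(f"recovery r = {r:.3f}  (ceiling {truth.ceiling[0]:.3f})")
```

prints

```
sigma = 0.061
mean NCorr = 0.725
recovery r = 0.979  (ceiling 0.979)
```

The fitted component-1 progression scores correlate at r = 0.979 with the
planted gradient — at the instance's ceiling, the best any method could do
given which cells were sampled.  Significance of the coordination:

```python
res = coprog.permutation_test(sample, sigma=fit.sigma, n_perm=99, seed=1)
print(f"observed NCorr = {res.observed:.3f}, p = {res.p_value:.2f}")
# observed NCorr = 0.725, p = 0.01
```

The same pipeline is available from the shell: `coprog simulate`,
`coprog fit`, `coprog permute`, `coprog transfer`, and `coprog benchmark`
(see `coprog --help`).

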