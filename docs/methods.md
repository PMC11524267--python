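# Methods

## Model

For a response `y` and standardized predictors `X`, Huber–Berhu (HB)
regression minimizes

```
f(β) = Σ_i H_M(y_i − β₀ − x_iᵀβ) + λ Σ_j B_M(β_j)
```

with the Huber loss `H_M(z) = z²` for `|z| ≤ M`, `2M|z| − M²` otherwise, and
the Berhu penalty `B_M(z) = |z|` for `|z| ≤ M`, `(z² + M²)/(2M)` otherwise.
Both pieces are convex; the objective is minimized by an accelerated proximal
gradient method.  The Berhu proximal operator decomposes into soft
thresholding followed by a quadratic-tail shrinkage
`sign(x)·min{|x|, (M/(M+tλ))(|x| + tλ)}`, so every iteration is closed-form.

HB-PLS applies the same loss/penalty pair to the PLS inner problem.  On
standardized `X` (n×p) and `Y` (n×q) it forms the cross-product `S = XᵀY`
and seeks a penalized rank-one approximation `S ≈ δ u vᵀ`, alternating one
backtracked proximal step on `u` and one on `v` from an SVD warm start until
both weight vectors stabilize.  Each component contributes a score
`ξ = Xu`, loadings `c = Xᵀξ/(ξᵀξ)`, `d = Yᵀξ/(ξᵀξ)`; `X` and `Y` are
deflated by `ξcᵀ` and `ξdᵀ` and a coefficient matrix `A` accumulates the
per-component regression contributions.  TFs are ranked by connectivity, the
row-wise L1 norm of `A` (a nonzero-count alternative is available).

## Assumptions

- Samples are exchangeable rows shared between `X` and `Y`; columns are
  standardized internally (constant columns are dropped with a warning).
- Errors may be heavy-tailed or contain a minority of gross outliers; the
  Huber loss targets exactly this regime. It does not address high-leverage
  outliers in `X` (no row reweighting is performed).
- Regulatory signal is low-dimensional: a few latent components relate `X`
  to `Y`, with only a subset of TFs carrying nonzero weight.

## Parameters and defaults

- **Shape parameter `M`** — `IQR/10` of the current working values (response
  residual scale for regression; the entries of the deflated cross-product
  for each PLS component, recomputed per component). Quantiles use linear
  interpolation. A tiny floor guards degenerate zero-IQR inputs.
- **Penalty weight λ** — chosen by k-fold cross-validation (5 folds;
  leave-one-out below 30 samples; contiguous blocks of a seeded permutation)
  over a descending log grid from `λ_max` (the smallest λ that zeroes the
  weight vectors, computed from the gradient at zero) down to `λ_max/1000`,
  20 values by default. Ties prefer the larger (sparser) λ; folds whose fit
  is fully shrunk fall back to a train-mean null model and are flagged.
- **Number of components `K`** — the `Q²` criterion:
  `Q²_h = 1 − ΣPRESS_h / ΣRSS_h` with PRESS from held-out folds and RSS from
  the all-data model with the same number of components. Components are kept
  while `Q²_h ≥ 1 − 0.95² = 0.0975` (prefix rule, minimum one, cap 5). Using
  the same-`h` RSS in the denominator is conservative: it compares held-out
  against in-sample error of the *same* model size, so marginal late
  components are rejected readily and selected models stay small.
- **CV model size `K_cv = 2`** — λ is tuned under a small fixed component
  budget for speed; the final `K` is chosen separately by `Q²`.
- **Simulation defaults** — `snr = 2` (noise variance calibrated to signal
  variance), Student-t noise with `df = 3` rescaled to unit variance,
  outlier fraction 0.1 at 10× the noise scale, block correlation `ρ = 0.7`.

## What the generator does and does not emulate

The synthetic generator produces equicorrelated TF blocks through a shared
latent factor, a sparse coefficient matrix with effects of random sign, and
three noise families (Gaussian, heavy-tailed t₃, Gaussian plus gross
outliers). This reproduces the collinearity and tail behaviour that motivate
the method, but not: nonlinear regulation, count-based measurement noise
(the data are Gaussian-scale, as after a variance-stabilizing transform),
network feedback, or batch structure. One consequence worth knowing:
scattered gross outliers in individual response *entries* largely average
out inside the `XᵀY` cross-product, so on the outlier-noise generator plain
PLS and HB-PLS both sit near the AuROC ceiling and robustness gains are
easier to see under heavy-tailed (t₃) noise or in the regression setting,
where the acceptance script quantifies them directly.

## Numerical choices

- Accelerated proximal gradient with momentum `k/(k+3)`, step size starting
  at 1 and only ever halved (no reset), backtracking on the standard
  linearized sufficient-decrease bound with a small numerical slack.
- SVD initialization of `(u, v)` with a sign convention (largest-magnitude
  entry of `u` positive) applied jointly to `u` and `v`.
- Deflation recomputes loadings from the current matrices (projection form),
  making repeated deflation idempotent and successive scores orthogonal.
- Components whose weight vector is fully shrunk, or whose score has zero
  norm, stop extraction; the model is truncated with a warning.
- AuROC uses midranks, so ties contribute ½; ROC curves keep all thresholds.

## Limitations

- The alternating one-step inner problem is biconvex, not jointly convex;
  the SVD warm start works well in practice but global optimality is not
  guaranteed (the convex single-vector regression solver *is* verified
  against an independent oracle to ~1e-16 relative).
- Useful λ values for the PLS inner problem sit well below the analytic
  `λ_max`; the default grid spans this but single-λ fits near `λ_max` can
  yield no usable components (raised as an error).
- Connectivity ranking aggregates absolute coefficients; it does not
  distinguish activation from repression (see the signed `edges.tsv` for
  direction) and inherits the grouping behaviour of the Berhu penalty:
  correlated block-mates of a true regulator rank high together.
- Cross-validation folds are contiguous blocks of one seeded permutation;
  no stratification is attempted.
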