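# Methods

## Model

Each sample i contributes a curve observed at m discretization points
t_1 < … < t_m (wavelengths in nm for hyperspectral reflectance):

    x_i(t_j) = f_i(t_j) + ε_ij,     ε_ij ~ N(0, σ_ε²) i.i.d.,

where f_i is a smooth underlying function, and a scalar response generated
by the functional linear model

    y_i = ∫ x_i(t) β(t) dt + e_i,   e_i ~ N(0, σ²).

Both the curves and the coefficient function are expanded on truncated
bases: x_i(t) ≈ Σ_l c_il φ_l(t) and β(t) = Σ_s d_s ψ_s(t), with S = L and
ψ = φ by default.  Per-curve coefficients are the least-squares projection
ĉ_i = (ΦᵀΦ)⁻¹Φᵀx_i, computed via a QR/SVD factorization (an optional flag
cross-checks the explicit normal-equations solve when ΦᵀΦ is well
conditioned).

## Basis systems

**B-splines.** Degree q ≥ 1, K interior knots, clamped boundary knots at the
domain endpoints with multiplicity q + 1, giving L = q + 1 + K functions, a
partition of unity on [lo, hi], and compact support.  Knots are placed
uniformly in (lo, hi) or at empirical quantiles of the grid at probabilities
k/(K + 1) (linear interpolation) — the quantile rule reduces to uniform
spacing on equispaced grids.  Evaluation is delegated to scipy's B-spline
design-matrix routine on the clamped knot vector.

**Fourier.** The ordered system {1, sin(2πrt/T), cos(2πrt/T)}, r = 1, 2, …,
unnormalized, evaluated at raw t (no rescaling of the abscissa; a different
convention would only shift phases, not the span).  An even L truncates the
sequence after the final sine and warns, since the sin/cos pair structure is
broken.  T = "auto" resolves to hi − lo, the span of the measured domain.
Duplicate grid points are rejected at construction: they would duplicate
rows of Φ and silently over-weight those locations in the smoother.

## Knot-number selection

For candidate knot counts K the selector scores the B-spline fit of all
curves jointly, summing over curves:

* GCV(K) = (RSS/m) / (1 − L/m)², minimized;
* R² = 1 − RSS/TSS, smallest K attaining a threshold (default 0.99); if the
  threshold is unattainable the largest candidate is returned with a
  warning.

Ties break toward smaller K, and the full per-candidate score table is
returned so alternative criteria can be applied externally.  Selection can
equally be run on a single curve (pass a length-m vector); the dataset-level
sum is the default because one shared basis smooths all curves.

## Design constructions (M1–M7)

| method | design | basis | columns |
|---|---|---|---|
| M1 | Z = X | none | m |
| M2 / M3 | W = XΦ(ΦᵀΦ)⁻¹J | B-spline / Fourier | S |
| M4 / M5 | X\* = XΦ(ΦᵀΦ)⁻¹Φᵀ | B-spline / Fourier | m (rank L) |
| M6 / M7 | X\*\* = XΦ | B-spline / Fourier | L |

J_ls = ∫φ_l ψ_s dt is computed under one of two quadrature conventions:

* `grid_sum` (default): J_ls = Σ_j φ_l(t_j)ψ_s(t_j), i.e. J = ΦᵀΨ exactly.
  With identical bases this realizes J = ΦᵀΦ as an identity rather than an
  approximation, and W collapses to X\*\* exactly.  Fits are invariant to
  the missing dt factor (it is absorbed by the coefficients).
* `trapezoid`: composite trapezoid on the grid refined 10-fold (each grid
  interval split into 10), carrying physical dt units — for when the
  integrals themselves matter.

X\* and X\*\* span the same prediction space (X\*Φ = X\*\*); the reduced
X\*\* is preferred in practice because it has only L columns and full column
rank.  Design bundles store the m×p mapping matrix and (when centering is
on, the default) the training column means, so held-out curves are mapped
into exactly the training coordinate system — the no-leakage identity
`design_for(X_new) == rows of a jointly built design` holds to machine
precision.

## Shrinkage priors and the Gibbs sampler

The regression y = μ1 + Zθ + e is sampled by blocked Gibbs: flat-prior
intercept, single-site coefficient updates in fixed column order,
scaled-inv-χ² variance updates.  Families:

* **BRR**: θ_j ~ N(0, σ_b²), σ_b² ~ χ⁻²(df_b, S_b);
* **BayesA**: per-coefficient σ_j² ~ χ⁻²(df_b, S_b);
* **BayesB**: spike at 0 with probability 1 − π, BayesA-type slab otherwise;
  π ~ Beta(p₀π₀, p₀(1 − π₀)) with π₀ = 0.5, p₀ = 10;
* **BayesC**: spike plus common-variance Gaussian slab, same π prior;
* **BL**: θ_j | σ², τ_j² ~ N(0, σ²τ_j²), τ_j² ~ Exp(λ²/2),
  λ² ~ Gamma(0.55, rate), with 1/τ_j² updated by inverse-Gaussian draws.

Hyperparameter scales follow the variance-partition rule standard in
whole-genome regression software: a proportion r2 (default 0.5) of var(y)
is assigned a priori to the linear term.  With the scaled-inv-χ² mode at
S/(df + 2): S_e = (1 − r2)·var(y)·(df_e + 2) for the residual (df_e = 5);
S_b = r2·var(y)/MSx·(df_b + 2) for coefficients (df_b = 5), where MSx is the
sum over columns of the mean squared design entries, divided additionally by
π₀ for the spike families; for BL the Gamma rate is set so the prior mean of
λ² equals 2(1 − r2)·MSx/r2, the value matching the partition.  All scales,
degrees of freedom and π hyperparameters are overridable, and any part of
the hierarchy can be pinned at a point mass — pinning everything reduces
every family to the conjugate ridge conditional, which the tests exploit
against the closed-form posterior mean.

MCMC defaults are n_iter = 6000, burn_in = 1000, thin = 5.  One RNG stream
per fit is keyed by the seed and coefficients are updated in fixed order, so
runs are bitwise reproducible.  Numerical guards: inverse-Gaussian means are
clipped at 1e8 when a BL coefficient is numerically zero, and zero-variance
design columns receive a floor of 1e-12 on zᵀz.

β(t) reconstruction (β̂ = Ψθ̂ with draw-wise credible bands) is defined for
the basis-space fits M2/M3/M6/M7; M1/M4/M5 coefficients are
per-measurement-point and exposed as-is.

## Cross-validation protocol

`make_folds` draws a balanced random partition into k folds (sizes differ by
at most one; k = 3 by default, so two folds train and one is predicted —
a third of the lines held out at a time).  For every (method, prior, basis)
cell and fold, the design is built on the training curves (bases depend only
on the grid, so Φ is fold-invariant; centering means come from the training
fold), the sampler is run with a per-cell seed derived from the base seed
via a SeedSequence spawn key, the held-out curves are mapped through the
training bundle, and Pearson r between observed and predicted responses is
recorded.  Aggregation reports mean and SE = sd/√k over folds.  A failing
cell is recorded as NaN with a warning rather than aborting the sweep.  A
single CV partition is used by default; replication is a matter of calling
`run_cv` with new plans.

## Synthetic data: what it emulates and what it does not

* **Sine testbed**: f(t) = sin(1 + t), t ~ U(10, 20) (100 points by
  default, stored sorted with the draw order kept as metadata), noise sd
  0.5.  This reproduces the classic demonstration that Fourier smoothing is
  sharp at the matched period (T = 6) and poor at T = 4 or 8, and that cubic
  splines with L ≈ 11 fit well while L = 5 underfits and linear splines lag.
* **Curve panels**: truth curves f_i = Φ_truth c_i with a cubic B-spline
  truth basis (L = 15 by default) and c_i ~ N(0, coef_sd²I); coef_sd
  defaults to the value making the average pointwise curve variance ≈ 1
  (unit-scale curves, akin to centered reflectance panels).  Measurement
  noise is i.i.d. Gaussian, default sd 0.1 — i.e. 10% of the curve scale,
  a realistic error level for averaged reflectance values.  The default
  grid is 250 equispaced points on [392, 851] nm, the geometry of a typical
  wheat hyperspectral panel.
* **Phenotypes**: y_i = trapezoid quadrature of f_i·β over the grid plus
  N(0, residual_sd²).  The integral uses the *noise-free* truth curves, so
  the target signal is exactly the functional model.  The default study
  β(t) = sin(2πt/459) spans one period over the wheat domain.  For
  experiments about the effect of the basis count, a three-cycle
  β(t) = sin(2πt/153) is used instead: a one-period β is already
  representable by an L = 5 spline, so only a β with structure between
  L = 5 and L = 23 resolution can exhibit the accuracy drop at small L.
  For the accuracy-regime demonstration the residual sd is set to √3 times
  the signal sd, so the curves explain 25% of the phenotypic variance —
  the regime in which field panels of this kind sit (held-out r ≈ 0.5 at
  best).

The generators do not emulate genetic relatedness, field-design effects,
band-to-band correlated measurement error, or the BLUE pre-adjustment that
produces real panels; passing tests therefore certify the statistical
machinery, not robustness to those real-data features.

## Problem sizes and numerical choices

Recovery experiments use n = 500 curves on m = 250 bands with L = 23 and
3:1 signal-to-noise (sd ratio); the coefficient-recovery experiment draws
its truth curves from an L = 30 basis so that the fitted 23-basis design is
well conditioned (identifiability of d requires the curves to span the
fitted basis).  CV demonstrations use n = 120–300 with chains of 600–2000
iterations, and the full 7-method × 9-basis sweep runs n = 150 with short
chains (150 iterations) since it checks completion and table shape rather
than posterior accuracy.  Sampler cross-checks against the ridge closed form
use 20,000 retained draws and batch-means Monte-Carlo standard errors (50
batches).

Conditioning: basis matrices with cond(Φ) > 1e10 raise a conditioning error
naming the offending configuration (e.g. Fourier aliasing on a coarse grid);
L > m raises a dimension error.  Degenerate inputs — duplicate grid points,
non-finite data, zero-variance vectors in Pearson correlation — are rejected
with specific errors rather than propagated as NaN.

## Known limitations

* Roughness-penalty (P-spline) smoothing and mixed-model spline
  reformulations are not implemented; smoothing is pure regression on a
  truncated basis.
* Only Gaussian responses; no binary/ordinal likelihoods, no multi-trait
  models, no environment or genotype×environment terms, and no genomic or
  pedigree kernels.
* Function-on-scalar and function-on-function regression are out of scope.
* The BayesA/B slab scale S_b is fixed at its variance-partition value
  rather than given its own hyperprior; sensitivity can be explored through
  the exposed `scale_coef`.
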