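# Methods

## Model

`bisreg` fits a group-level image-on-scalar regression. For participant
i = 1…N with covariate vector x_i (first entry 1) and an image response
y_i(s_v) observed at V spatial locations s_v:

    y_i(s_v) = Σ_j x_ij α_j + Σ_j x_ij β_j(s_v) + η_i(s_v) + ε_i(s_v)

- α_j — global (spatially constant) effect of covariate j, prior N(0, σ²_α);
- β_j(·) — spatially varying effect, prior GP(0, σ²_β K);
- η_i(·) — participant-specific deviation field, prior GP(0, σ²_η K);
- ε_i(·) — spatially correlated noise, GP(0, σ²_ε K).

All four components share one stationary Matérn correlation kernel K with a
fixed length scale; only their variances differ. Each standard deviation
carries a half-Cauchy(A = 100) prior expressed as a scale mixture of
inverse-gammas (σ² ~ IG(1/2, 1/a), a ~ IG(1/2, 1/A²)), preserving
conjugacy. Identifiability is imposed by Σ_i η_i(s_v) = 0 and
Σ_v β_j(s_v) = 0; the reported quantity is the combined voxel effect
α_j + β_j(s_v).

## Low-rank computation

A dense V×V kernel is intractable, so K is replaced by a rank-L Nyström
approximation anchored at L inducing locations (k-means centroids snapped
to the mask, seeded): K ≈ Ψ Λ Ψᵀ with orthonormal Ψ. Writing
β_j = Ψ Λ^{1/2} θ_{βj} (Karhunen–Loève form) and projecting responses by
Φ = Ψ Λ^{-1/2} turns the model into an L-dimensional regression with iid
N(0, σ²_ε) errors:

    ỹ_i = (x_iᵀα)·1ᵀΦ + x_iᵀθ_β + θ_{ηi}ᵀΦ_η + ε̃_i .

The participant field uses a coarser independent basis of rank
L_η = ⌈0.1·L⌉ to limit overfitting. Per-iteration inference cost is
O(N·L·L_η + L_η³) after the one-off projection.

Identifiability recentering exploits an exact invariance: shifting
(α_j, θ_{βj}) by (δ, −δ·Λ^{-1/2}Ψᵀ1) leaves every fitted value unchanged,
so the voxel mean of each reconstructed β_j can be moved into α_j without
breaking conjugacy; likewise the participant mean of θ_η is absorbed into
the spatial intercept. The Gibbs sampler recenters every iteration; the
variational fit recenters once after convergence so that each sweep remains
exact coordinate ascent (the ELBO is asserted to be nondecreasing).

## Inference engines

**Gibbs.** All blocks have closed-form conditionals: Gaussian for α, for
each basis column of θ_β (one shared (J+1)×(J+1) precision), and for each
θ_{ηi} (one shared L_η×L_η precision); inverse-gamma for variances and
auxiliaries. Defaults: 3 chains, 4,000 burn-in, 1,000 kept draws, chains
overdispersed by scaling initial variances ×{0.5, 1, 2}; convergence judged
by the Gelman–Rubin factor on the conditional log-likelihood trace
(threshold 1.1).

**Mean-field CAVI.** Same blocks as variational factors, with conditioning
moments replaced by variational expectations (E[1/σ²] = shape/rate).
Initialization is a deterministic least-squares/method-of-moments warm
start; iteration stops when the relative ELBO change falls below 1e-8
(cap 500 sweeps). Variance-factor rates are floored at shape×1e-10 so that
degenerate, perfectly fitting inputs cannot drive E[1/σ²] into
catastrophic cancellation. A `free`-blocks argument supports conditional
fits; on a toy with a single free conjugate block the converged bound
equals the exact conditional log marginal, which the tests exploit as an
oracle.

## Kernel choice

The Matérn scaling follows the √(2ν) convention; length scales are
unit-free fractions of the largest mask extent (coordinates are mapped
into [0,1]^d preserving aspect ratio). The default smoothness is ν = 1/2
(exponential kernel). This was a deliberate design decision: the rank
window prescribed for basis selection — the L range explaining 80–98% of
the truncated spectrum's variance — collapses to a few dozen functions for
ν ≥ 3/2 at ρ = 0.3, while for ν = 1/2 it spans roughly 10–400 on a
~5,000-voxel mask, matching the ranks that leave-one-out selection actually
favors. ν remains configurable. The default length scale is ρ = 0.3
(normalized units); `estimate_length_scale` recovers ρ empirically from
pairwise spatial correlations of residual images when no value is given.

## Basis-rank selection

Likelihoods are not comparable across L (each L defines a different
projected data space), so WAIC/DIC are not offered. Instead: decompose at
L_max = min(V, 2000), keep candidates in the 80–98% cumulative-variance
window, and grid-search by leave-one-participant-out predictive MSE with
the VI engine (prediction uses η = 0 for the held-out participant). The
PMSE differences inside the window are small relative to per-image noise,
so enough folds are needed to resolve the minimum; the package default is
all N folds, and the bundled study scripts use 40 subsampled folds as a
compute compromise (below ~20 folds the argmin is dominated by fold noise).

## Synthetic-data generator

The generator emulates a single-slice group study:

- **Mask** — an ellipse with a sinusoidally perturbed boundary on a regular
  grid, solved to hit a target voxel count (default ~5,000) within 5%, kept
  4-connected.
- **Truth maps** — per coefficient, two disjoint regions (a disk and a
  rounded rectangle), one positive and one negative so the map is roughly
  mean-zero, each with a flat core at the peak amplitude and a
  truncated-Gaussian shoulder decaying to exactly zero at the boundary
  (zero outside). The shoulder makes the maps essentially representable
  (<2% relative error) in the rank-~300 kernel basis, which is what keeps
  the spatial model's bias — and hence its false-discovery behavior —
  comparable to its posterior spread.
- **Amplitude calibration** — maps are rescaled so the active-voxel
  mean-square effect equals SNR·σ²_ε. SNR is defined on active voxels
  (not total signal variance) because the two study settings
  (σ_ε = 2, SNR = 0.3) and (σ_ε = 5, SNR = 0.05) then imply one common map
  scale (1.2 vs 1.25) and reproduce the mass-univariate detection pattern —
  most active voxels detectable per-voxel at σ_ε = 2, almost none at
  σ_ε = 5 — which pins the scale via OLS theory alone.
- **Noise** — participant deviations are iid N(0,1) per voxel (deliberately
  rougher than the smooth η the fitted model assumes — a structured
  model-misspecification kept on purpose), and ε is drawn from the Matérn
  GP through a rank-500 basis (a dense-Cholesky option exists for small-V
  oracle tests).
- **Scenarios** — {N ∈ {50, 200}} × {σ_ε ∈ {2, 5}}, presets
  `n50-s2 … n200-s5`.

What passing tests on this generator do *not* show: robustness to
realistic fMRI artifacts (motion, physiological noise, nonstationary
smoothness, site effects), to non-Gaussian heavy-tailed responses, or to
masks with disconnected or highly anisotropic geometry.

## Baselines and metrics

- **GLM** — per-voxel OLS with t-based two-sided inference and
  Benjamini–Hochberg adjustment at q = 0.05 across voxels (per covariate).
- **BML** — a voxelwise Bayesian multilevel model with iid N(0, σ²_{βj})
  voxel effects per covariate, a scalar participant deviation, iid noise,
  and the same half-Cauchy hierarchy; conjugate Gibbs, vectorized across
  voxels. It pools information but carries no spatial correlation.
- **Metrics** — MSE of estimated vs true voxel effects (pooled over
  covariates), TPR/FDR of |Es| > 0.95 selection against the exactly-zero
  truth region (FDR guard: FP/max(TP+FP, 1)), and 95% interval coverage.
  Evidence is unified as Es = 2(P+ − ½) for Bayesian fits and ±(1 − p_adj)
  for the GLM. Activation defaults to the two-sided rule |Es| > 0.95.

## Numerical choices

- Gram matrices get jitter 1e-8 on the diagonal, escalated ×10 up to 1e-4
  on Cholesky failure; trailing eigenvalues below 1e-10·λ₁ are trimmed.
- Gibbs variance draws are floored at 1e-12.
- P+ counts ties at zero as ½, so an exactly null effect has Es = 0.
- Posterior-predictive density overlays use a shared 512-point grid over
  the pooled range and Gaussian KDE with Silverman bandwidth (subsampled to
  5,000 points per replicate); degenerate constant samples fall back to a
  histogram.
- The Gelman–Rubin statistic uses the classic between/within formula
  √(((K−1)/K·W + B/K)/W); identical chains give √((K−1)/K), i.e. ~1 to
  three decimals rather than exactly 1.

## Problem sizes used in the bundled checks

The acceptance script and study-level tests run at the generator's native
conditions (~5,000-voxel mask, rank selected from the 80–98% window at
L_max = 2000) with 100 replicates for the OLS-calibration checks and 20
replicates for the spatial-model checks; the method-comparison ordering run
uses the two N = 200 scenarios with 20 replicates and a single-chain,
300-iteration BML configuration. Unit tests use ~300–600-voxel masks.

## Known limitations

- The length scale is fixed before fitting; no kernel hyperparameter
  inference.
- Mean-field VI underestimates marginal variances in principle; on the
  bundled simulations its intervals are nevertheless conservative because
  the dominant uncertainty enters through the conjugate per-block
  posteriors.
- The iid-η generator mismatch makes the projected noise mildly
  heteroscedastic across basis indices while the model assumes
  homoscedasticity; with the LOOCV-selected rank this shows up as a small
  false-discovery inflation at mid-window ranks.
- Surface data are handled through vertex coordinates only; no mesh
  topology or geodesic distances.
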