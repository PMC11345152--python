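# Methods

This note documents the statistical model implemented by `cpfosr`, the
conventions and defaults that matter, what the synthetic-data generator does
and does not emulate, and the numerical choices made where the design was
genuinely open.

## Model

### Tensor conventions

A mode-`m` unfolding places the mode-`m` index along columns; the remaining
indices are linearized along rows with the first remaining mode varying
fastest (column-major). All voxel linearization in the package follows the
same first-index-fastest rule, so a flattened voxel index is
`v = j1 + p1*j2 + p1*p2*j3`, and every map written to NIfTI is re-folded
with the identical rule (round-trip exact). The subjects-by-voxels matrix
used by the regression is the transpose of the mode-4 unfolding.

### CP basis

The 4D contrast tensor is approximated by a rank-R CP decomposition fitted
with alternating least squares (ALS). Conventions:

- **Normalization.** The scale split among the four factor matrices of a CP
  model is indeterminate, so the canonical convention is used: every factor
  column (spatial modes and subject scores alike) has unit Euclidean norm
  and the nonnegative weights λ carry the full component magnitudes.
  Components are sorted by descending weight; spatial columns are
  sign-canonicalized (largest-magnitude entry positive) with the
  accumulated flip pushed into the score column.
- **Basis.** `L = Λ(A⁽³⁾ ⊙ A⁽²⁾ ⊙ A⁽¹⁾)ᵀ` has shape R × Nv (the Khatri-Rao
  row order matches the column-major voxel order), so the mode-4 subject
  matrix satisfies `Y = G·L`. `P = pinv(L)` projects voxel data to scores;
  when `L` has full row rank, `L·P = I_R`.
- **ALS details.** Initialization is HOSVD-style (leading left singular
  vectors of each unfolding); further restarts (default 3) are random and
  seeded; the best run by reconstruction error wins. Iterations stop when
  the *relative improvement* of the relative Frobenius error falls below
  `tol` (default 1e-8) or at `max_iter` (default 500); improvement-based
  stopping lets exactly low-rank tensors run down to the numerical floor
  instead of halting mid-decay. The reported `fit_rel_error` is computed
  from an explicit residual, because the Gram-based shortcut loses accuracy
  below ~1e-8. Non-convergence raises a warning, never an exception.
- **Degeneracies.** Voxels that are zero across subjects simply produce
  zero basis entries. If the score matrix of an exactly low-rank tensor is
  itself rank-deficient (fewer independent covariate directions than
  components, with no subject noise), the CP solution is non-unique and ALS
  stalls near — not at — zero error; this situation does not arise with
  noisy data. An optional 3D mask restricts the voxel linearization
  (out-of-mask voxels are zeroed for fitting and excluded from L, P and all
  maps); the default is the full grid.

### Basis-space regression

Projected scores follow `G = Zγ* + E*` with i.i.d. matrix-normal rows and
conjugate Matrix-Normal/Inverse-Wishart prior `(g₀, L₀, V₀, ν₀)`. The
posterior is available in closed form:

```
Ln = Z'Z + L0                       nun = nu0 + N
gn = Ln^{-1} (Z'G + L0 g0)
Vn = V0 + (G - Z gn)'(G - Z gn) + (gn - g0)' L0 (gn - g0)
```

Sampling is exact two-block composition — Σ_ε from W⁻¹(Vₙ, νₙ), then γ*
from MN(gₙ, Lₙ⁻¹, Σ_ε) via Cholesky factors — so the M draws are i.i.d. and
no burn-in is required (burn-in/thinning arguments exist for interface
compatibility and default to 0/1). A jitter of 1e-10 guards Cholesky
factorizations of near-singular matrices.

### Default prior (and why it is data-scaled)

`g₀ = 0` and `L₀ = 1e-6·I` (near-flat on the coefficients; `gn` is then the
ridge-stabilized OLS fit). For `V₀` and `ν₀` the package deliberately does
*not* use a fixed identity scale:

- Because the CP normalization puts all magnitude into λ, the score columns
  are unit norm; any fixed V₀ would be strongly informative on that scale.
- The conjugate update counts all N rows toward the Σ_ε degrees of freedom
  (νₙ = ν₀ + N) although p of them are spent estimating γ*. With a small
  V₀, the posterior for Σ_ε therefore sits a factor ≈ (N−p−R−1)/(ν₀+N−R−1)
  below the unbiased residual covariance — a few percent that the
  max-over-voxels statistic amplifies into substantial under-coverage of
  the joint bands (≈9% exclusion at nominal 5% in null simulations with
  N = 40).

When no explicit prior is given, `CPTensorFOSR.fit` uses ν₀ = R + 2 (the
smallest integer giving the prior a finite mean) and

```
V0 = (nu0 + p) / (N - p - R - 1) * S,     S = OLS residual Gram,
```

which re-centers the posterior mean of Σ_ε on `S/(N−p−R−1)`. Null
simulations with this default measure a 5.75% (N=40, 400 replicates) and
5.0% (N=100, 200 replicates) simultaneous exclusion rate at α = 0.05.
The posterior mean gₙ never depends on V₀, so rank selection and point
estimates are unaffected by this choice. Explicit `FOSRPrior` objects are
honored verbatim.

### Voxel-space inference

For a contrast c, per-draw voxel values `C⁽ᵐ⁾ = (c'γ*⁽ᵐ⁾)L` are streamed
over voxel chunks (default 8192), so no M × Nv array is materialized. The
posterior sd uses denominator M−1. The quantile for the joint band is the
`ceil((1−α)M)`-th ascending order statistic of the max statistics z⁽ᵐ⁾,
computed as `M − floor(αM)` with integer snapping so that for α on the 1/M
grid the band inversion reproduces P_SimBaS *exactly* (this identity is
asserted in the tests for every voxel and every grid α). Zero-variance
voxels cannot be standardized: they are excluded from the max, reported,
and assigned P_SimBaS = 1 so they are never flagged. If every voxel is
degenerate (e.g. identical draws) the result carries a degenerate flag.
Clusters are connected components of {P_SimBaS < α} under 6-, 18- or
26-connectivity (default 26, the common choice for 3D fMRI cluster
reporting), thresholded at a minimum extent (default 125 voxels) and
reported with size and peak |Ĉ|/sd.

Defaults mirror the intended use: α = 0.01 and 125-voxel extent for
activation reporting; M = 2000 draws (i.i.d. exact sampling makes modest M
sufficient; M only needs to resolve the α-quantile of the max statistic).

### Rank cross-validation

Subjects are partitioned into K random seeded folds (default 10). Per fold
and candidate rank: CP factors from training subjects only; γ* estimated by
the closed-form posterior mean on training scores (fast and deterministic —
draws add nothing to a point prediction); held-out scores predicted as
`Z_test·gn`; the held-out tensor reconstructed with the *training* λ and
spatial factors. The per-fold Frobenius residual norms are averaged per
rank (insensitive to fold-size imbalance; the norm-of-averaged-residual
variant is available via `aggregate="norm_of_mean"`), and the argmin is
selected with ties broken toward the smaller rank. Candidate ranks at or
above the training-fold size are skipped with a warning. Because the
reconstruction uses covariate-predicted scores, CV measures the rank of the
*covariate-predictable* structure; components carrying no covariate signal
cannot reduce the CV error.

### Subject-level GLM

A deliberately minimal stage to produce per-subject contrast maps from 4D
time series: stimulus boxcars convolved (at 16× oversampling) with a
canonical double-gamma hemodynamic response (gamma-pdf peak at 6 s,
undershoot at 16 s, ratio 1/6, peak-normalized; all configurable), then
voxelwise OLS and a contrast `c'B`. Errors are treated as i.i.d. — no
prewhitening, drift, or motion regressors. This is a stated limitation:
the stage exists so the full pipeline runs file-to-file, not as a
competitive single-subject model.

## Synthetic data

`simulate.gen_multisubject` emulates exactly the structure the model fits:

- Spatial components are outer products of smooth 1D Gaussian bumps with
  distinct (jittered) peak locations and widths ≈ dim/(R+2), normalized to
  unit columns — blob-like "activation" topography with exact CP rank.
- Weights λ decline linearly (1.6 → 0.9 before scaling), giving components
  of unequal but comparable energy.
- The design holds an intercept, one binary covariate, and (for p > 3)
  standardized continuous covariates. Coefficients γ* are drawn with scales
  `effect_scales` (default (1.0, 0.5)); intercept loadings are signed
  magnitudes Uniform(0.75, 1.25), because components extracted from task
  activation data all carry population-mean signal — a component with no
  mean and no covariate loading would be pure noise structure.
- Subject scores are `G = Zγ* + σ_subject·noise` with σ_subject = 1 (unit
  subject heterogeneity, the scale on which "weakly informative" priors are
  meaningful), and the tensor is `fold(G·L) + σ_voxel·noise`. σ_voxel is
  set from a target SNR = ‖signal‖_F/‖noise‖_F (default 5) unless given
  explicitly; the realized SNR is reported with every draw.
- `gen_null` zeroes every covariate effect except the intercept, for
  family-wise-error and coverage simulations.

Everything regenerates bit-identically from the seed.

What the generator does **not** emulate: spatially autocorrelated or
heavy-tailed noise, physiological drift, registration error, inter-subject
anatomical variability, or surface-based (CIFTI) geometry. Passing tests
therefore demonstrate correctness and calibration *under the model's own
assumptions* plus i.i.d. voxel noise — not robustness to realistic fMRI
artifacts.

## Problem sizes used in the checks

The automated checks run at desk scale, chosen to exercise every code path
with comfortable margins: exact CP recovery on a 20³×15 noiseless tensor;
sampler accuracy with 50,000 draws on an (N=40, p=2, R=5) fixture;
SimBaS/band duality on a 500-voxel, M=1000 fit; end-to-end recovery and
family-wise error on 30³×50 tensors (R_true=4, SNR 5, 20 null replicates);
rank selection on 12³×60 tensors over the grid {2,3,4,5,6,8} with 5 folds
(10 replicates); and null simultaneous coverage over 200 replicates of
10³×40 tensors. Measured behavior at these sizes: intercept-map recovery
correlation ≈ 0.98, rank-4 selection in ≥ 9/10 replicates, null exclusion
rate ≈ 5-6% at α = 0.05, zero duality violations.

## Known limitations

- The basis is estimated on the same data used for inference; the posterior
  does not propagate CP estimation uncertainty. Null simulations show the
  calibrated default prior compensates adequately at these problem sizes,
  but very small N or very weak components may reintroduce optimism.
- ALS finds local optima; restarts mitigate but do not guarantee global
  fits, and exactly rank-deficient score structure makes the decomposition
  non-unique.
- Prediction-based rank CV is blind to covariate-orthogonal components (see
  above); a descriptive analysis wanting those components should choose R
  by reconstruction error instead.
- Volumetric grids only; no Tucker or other decompositions; no
  surface/CIFTI support.
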