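# Methods

## The model

`voxlica` factorizes K feature-by-voxel matrices that share their voxel
axis — in the motivating application, Allen-atlas gene-expression energy
(3318 coronal genes) and axonal projection density (498 tract-tracing
injections) registered to a common 200 µm template — as

    Y^k = X^k diag(W^k) H + E^k,        k = 1..K

* `H` (L × N): shared spatial sources over the N in-mask voxels. Each
  element carries a zero-mean mixture-of-Gaussians (MoG) prior with
  `mog_components` (default 3) components shared across sources; the
  mixture weights and variances are adapted during inference. A
  super-Gaussian source prior is what makes the factorization an ICA:
  Gaussian priors would leave the component basis rotation-invariant.
* `X^k` (R_k × L): feature coefficients. Columns carry Gaussian priors
  with per-component, per-modality precisions under Gamma (ARD)
  hyperpriors, so components a modality does not need are shut off and
  the effective model order is data-driven.
* `W^k` (diagonal, ≥ 0): modality weights. Point parameters with a
  half-normal shrinkage prior whose precision has its own Gamma
  hyperprior. The adaptive shrinkage matters: with a flat prior, a
  component absent from one modality keeps a lingering small weight
  there and slowly rotates its spatial map into a blend of sources;
  the shrinkage pulls such weights cleanly to zero.
* `E^k`: i.i.d. Gaussian noise per modality, precision `beta_k` with a
  broad Gamma prior. The likelihood of modality k can be tempered by
  `dof_scale` (default 1.0 = no correction) — a scalar stand-in for a
  spatial degrees-of-freedom correction; an estimator from residual
  autocorrelation is deliberately not built in, since no principled
  formula is available for these data.

Each feature row is z-scored before fitting (`standardize=True`); the
constants are retained so reconstructions can be reported in original
units. Whether the modalities should additionally be variance-normalized
relative to each other is an open choice; z-scoring every row makes the
two modalities enter on a common per-feature scale and is the default.

## Inference

Mean-field variational Bayes with blocks q(X^k) (Gaussian, row-shared
covariance), q(H) (Gaussian per voxel, full L × L covariance), MoG
assignment responsibilities, Gamma factors for the ARD, weight-shrinkage
and noise precisions, and point updates for W^k and the MoG
hyperparameters. Every update is an exact conditional maximiser of the
free energy, so the free-energy trace is non-decreasing — asserted in
the test suite with a 1e-8 relative slack for floating-point noise, and
the primary correctness oracle for the inference code. Convergence is
declared when the relative free-energy change falls below `rel_tol`
(default 1e-6, a machine-precision-order change per parameter) within
`max_iter` (default 3000) iterations; otherwise the decomposition is
returned with `converged=False`.

**Initialization.** The default `init="svd"` takes a deterministic full
SVD of the row-stacked z-scored modalities and then applies a symmetric
fixed-point ICA rotation (tanh contrast, identity start) to the whitened
scores. The rotation is required, not cosmetic: mean-field coordinate
ascent cannot perform global rotations of the component basis, and from
an unrotated SVD it reliably converges to a mixed local optimum
(matched |rho| ≈ 0.6–0.8 instead of ≥ 0.99 on the reference fixture).
Both steps touch only sample averages, so the initialization — and hence
the whole fit — is equivariant under voxel permutation and deterministic
given the seed. `init="random"` is available for robustness checks.

**Identifiability conventions.** Scale: rows of `H` and columns of
`X^k` are normalized to unit Euclidean norm after fitting, with all
scale absorbed into `W^k`, making the weights the canonical per-modality
component magnitudes (this resolves the three-way scale degeneracy the
raw parametrization has). Sign: each `H` row is flipped to positive
skewness, with `X^k` columns flipped along. Order: components are sorted
by total explained variance, descending, so component indices are
comparable across analyses.

**Numerical floors.** Precisions used in updates are clipped to
[1e-10, 1e12]; MoG responsibilities are floored at 1e-12 and
renormalized; MoG variances are floored at 1e-8.

## Post-hoc analysis

Spatial maps and coefficient vectors are thresholded at percentiles 1
and 99 (linear-interpolation convention between order statistics; values
inside the band are treated as zero). Components of interest are those
whose relative explained-variance contribution exceeds a floor (default
1%) in every modality. Per-voxel dominance compares the two modalities'
reconstruction energies e_k(j) = Σ_r (X^k_ri W^k_i H_ij)²; a voxel is
labelled for a modality when its energy exceeds the other's by more than
`ratio_cut` (default 2.0), else "shared". Because the per-component
reconstruction is rank one, this ratio is constant across a component's
voxels; the rule is kept voxel-wise so it extends to multi-component
summaries. Cross-factorization similarity uses Pearson's rho with
two-sided p-values (exact beta-distribution null), flagged at p < 0.004.
Region summaries count thresholded voxels per parcellation region.

## DLSC comparison

Dictionary learning and sparse coding minimizes
½‖Y − C·A‖² + λ‖C‖₁ with unit-norm spatial atoms A, alternating exact
coordinate-descent Lasso for the codes with exact per-atom updates on
the unit sphere — both exact conditional minimizers, so the objective is
non-increasing (tested). "Exclusive" fits decompose each modality alone;
"concat" stacks the z-scored feature rows of all modalities over the
shared voxel axis. Defaults: `penalty=5.0` (median exact-zero code
fraction ≈ 0.6–0.7 at 5–10 atoms on ~10³ voxels — raising the penalty
toward 90% sparsity at these small atom counts collapses the codes
entirely) and atom count equal to the linked model order for r²
comparability. For source-matching experiments the harness uses 2L
atoms: at L atoms the DLSC global optimum itself blends correlated
sources (verified by refitting from SVD, ICA-rotated, true-source and
random initializations, which all reach the same objective), so extra
capacity rather than more optimization is what isolates them. DLSC has
no independence objective, so how many planted sources its atoms match
at |rho| ≥ 0.8 varies with the dataset draw (typically 1–5 of 5); the
mean best-match correlation is the stabler summary.

## Synthetic data

The generator emits data exactly from the model: L unit-norm sparse
sources (sums of 1–3 Gaussian blobs on the grid, hard-thresholded to the
top `source_sparsity` fraction of in-mask voxels — sparse, contiguous
and super-Gaussian), standard-normal feature coefficients, log-uniform
modality weights on [0.5, 2] with selected weights zeroed to plant
modality-unique sources, and Gaussian noise scaled to a per-modality
target SNR (total signal variance over noise variance). Blob
configurations are redrawn (up to 100 attempts, deterministically)
until each source's spatial correlation with every earlier source stays
below 0.3: sources stacking on the same voxels are not mutually
independent, so no factorization could tell them apart, and the fixtures
must stay identifiable to serve as a recovery harness. The mask is a
filled ellipsoid covering `mask_fill` of the grid (background −1), the
parcellation a Voronoi tessellation of in-mask voxels around random
seeds, and a stated fraction of in-mask modality-1 entries is set to the
sentinel to emulate the ~0.8% missing values of the real expression
volumes. Matrices are not forced non-negative (the factorization is
unconstrained); a `shift` knob exists for realism.

Reference conditions used throughout the tests and the acceptance
script: 12 × 10 × 10 grid, 80% fill (N = 960 voxels), L = 5 sources of
which one is gene-only, R = (60, 30) features, SNR 10, sparsity 0.1,
0.8% missing, 6 regions. These sizes keep a full VB fit under a second
while exercising every code path; they are ~65× fewer voxels and ~10×
fewer features than the motivating datasets.

**What passing does and does not show.** The generator draws data from
the fitted model's own family with spatially distinct sources; passing
recovery tests therefore demonstrates correct inference, identifiability
handling and pipeline plumbing — not that real expression energy follows
a MoG-source linear model, not robustness to registration error,
injection-volume heterogeneity or hemispheric asymmetry (none of which
are simulated), and not performance when sources overlap heavily. At the
reference conditions, recovery of all five sources at matched
|rho| ≥ 0.95 holds on 19 of 21 dataset seeds measured; on the other two,
one source converges to a blend (|rho| ≈ 0.66) whose variational free
energy — and gene-modality likelihood — is genuinely higher than the
planted configuration's (the truth, used as initialization, remains a
stable fixed point with a lower bound). At this size and noise level the
planted configuration is occasionally not the model-evidence optimum;
that is a property of the statistical problem, not of the optimizer.

## Preprocessing conventions

Downsampling is trilinear interpolation at coarse-cell centres with
output dims ⌈dim/factor⌉; background (−1) voxels are excluded from the
interpolation support (weights renormalized over non-sentinel corners;
all-background support stays sentinel), so mask borders are averages of
in-mask values only. The mask marks voxels where *any* feature is
non-sentinel, matching a single shared brain mask across genes.
Flattening is row-major (C order; the Right–Left axis moves fastest)
over in-mask cells and is exactly invertible. Missing in-mask entries
are imputed per feature with the mean over expressed voxels of the same
parcellation region; a region with no expressed voxel for a feature
falls back to the feature's global in-mask mean (logged) — the fallback
is this package's addition, since the region-mean rule alone is
undefined there.

## Enrichment

Over-representation only: hypergeometric upper tail P[X ≥ k] per term
(exact, via the log-stable survival function), Benjamini–Hochberg
q-values across tested terms, and two significance modes — a fixed raw-p
cutoff (default 3.8e-5, the family-wide FDR-derived convention of the
motivating analysis) or BH at a stated level across the tested family.
Ontology DAG propagation is out of scope; term sets are flat, read and
written as GMT text.

## Limitations

* Mean-field VB widens posteriors, so noise precision is systematically
  underestimated (≈ 6.9 fitted vs ≈ 11 true at SNR 10 on the reference
  fixture); reconstruction and recovery are unaffected, but `beta_k`
  should not be read as a calibrated noise estimate.
* The MoG source prior is shared across components; sources with very
  different sparsity profiles would be better served by per-component
  priors at the cost of more hyperparameters.
* The spatial degrees-of-freedom correction is a manual scalar, not
  estimated from the data.
* No registration, hemisphere handling or ISH imaging physics; inputs
  are assumed pre-registered volumes with a −1 background convention.
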