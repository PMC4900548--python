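# Methods

`cdtmorph` implements a complete diffusion-MRI morphometry chain: voxel-wise
ensemble-average-propagator (EAP) estimation as Gaussian-mixture fields,
unbiased "sharp" template construction by groupwise diffeomorphic
registration, Cauchy-deformation-tensor (CDT) morphometry on the SPD(3)
manifold, principal geodesic analysis (PGA), and leave-one-out ν-SVM
classification — validated end to end on synthetic HARDI phantoms.

## Signal model and EAP representation

Under the narrow-pulse assumption the EAP `P(r)` is the Fourier transform of
the normalized attenuation `E(q) = S(q)/S0`.  We model each voxel as a
multi-compartment Gaussian system over a *shared dictionary* of axially
symmetric diffusivity tensors

    D_k = (λ∥ − λ⊥) u_k u_kᵀ + λ⊥ I,          k = 1 … K,

plus one isotropic atom, giving the forward model
`E(q) = Σ_k w̃_k exp(−b gᵀ D_k g)` and the closed-form propagator
`P(r) = Σ_k w̃_k N(r; 0, 2τ D_k)`.  Defaults (units mm²/s): λ∥ = 1.7e−3,
λ⊥ = 3e−4, isotropic diffusivity 2e−3 — typical white-matter values.  The
effective diffusion time is τ = Δ − δ/3 = 42.4 − 10/3 ≈ 39.07 ms, from the
emulated gradient timing Δ/δ = 42.4/10 ms.  Dictionary orientations are a
spherical-Fibonacci hemisphere lattice (antipodally distinct by
construction); the reference dictionary uses 46 orientations, while
registration-heavy experiments use 12 (see *Problem sizes* below).

Weights are fit per voxel by nonnegative least squares with a small ridge
(default 1e−3) on the attenuations, then renormalized to sum 1 so `P` is a
probability density.  The fit depends only on attenuations, hence is exactly
invariant to global signal scale.  Voxels whose fit degenerates fall back to
the isotropic atom and are counted.

The *estimation basis is a design choice*: the representation requirement is
only that every subject's EAP field live on one shared mixture dictionary;
a fixed dictionary + NNLS is the simplest fully specified estimator with
that property.

## Mixture distance and PPD re-orientation

The image dissimilarity is the voxel-wise L2 distance between mixture
densities.  For zero-mean Gaussians it is closed-form:
∫N(·;0,A)N(·;0,B) = (2π)^{−3/2}|A+B|^{−1/2}, so the squared distance is a
quadratic form in the two weight vectors with Gram entries of that type.
Tests verify the closed form against brute-force 3D quadrature on a 61³
grid (relative error < 1e−2 on random 3-component mixtures).

Warping a mixture field re-orients each component by **preservation of
principal direction (PPD)**: the principal eigenvector e₁ maps to
F e₁/‖F e₁‖, the secondary axis is Gram–Schmidt corrected, eigenvalues are
kept exactly.  Because dictionary atoms are axially symmetric (two equal
minor eigenvalues), PPD reduces to rotating the principal axis alone:
`C′ = a₁ u′u′ᵀ + a₂ I` with `u′ = J u/‖J u‖`.  This makes re-orientation and
the re-oriented Gram matrices closed-form in the registration inner loop
(determinant of a sum of two rank-1-plus-isotropic matrices:
`det = γ³ + γ²(a₁+b₁) + γ a₁ b₁ (1−t)`, γ = a₂+b₂, t = (u·v)²) — no per-voxel
eigendecompositions.  `F = J` by default (forward push of the moving frame);
`F = J^{−T}` is available behind a flag.

A warped field carries per-voxel rotated axes.  Where a field must return to
the canonical dictionary (template averaging, population storage), each
rotated atom's weight is reassigned to the angularly nearest canonical atom
("snapping"); the quantization error is bounded by half the dictionary's
angular spacing (~12° at 46 orientations, ~25° at 12).

Partial-volume handling: interpolated weight vectors are *capped* at total
1 rather than renormalized up, so tissue fades at boundaries instead of
hallucinating full-weight voxels — renormalizing tiny interpolated totals
to 1 creates a spurious tissue halo that corrupts every energy comparison.

## Diffeomorphic registration

The deformation is T(x) = x + d(x), built greedily from small velocity
steps (a tractable stand-in for full time-varying velocity-field
integration; geodesic shooting is out of scope).  Each iteration:

1. a demons-like force from central finite differences (step 0.25 voxel) of
   the voxel distance with re-orientation frozen at the current Jacobian —
   PPD is non-smooth at eigenvalue crossings, so analytic differentiation
   through it is avoided;
2. Gaussian smoothing of the force (σ = 2 voxels), the standard fluid proxy
   for applying (L†L)^{-1} with L a discrete Laplacian;
3. demons-style per-voxel step normalization capped at 0.4 voxel,
   composition with the current map, and a mild elastic smoothing of the
   accumulated field (σ = 1 voxel);
4. accept only if det J > 0 everywhere *and* the total energy decreases
   (line search over step factors 1, 0.5, 0.25, 0.1) — the energy trace is
   monotone non-increasing by construction.

The tracked energy is the re-oriented data term plus λ Σ log(det J)(det J−1)
(λ = 0.05).  The volume-change penalty as usually printed,
λ log(det Φ)(1−det Φ), is ≤ 0 for all det ≠ 1 and cannot act as a penalty
under minimization; we negate it, which preserves the evident intent
(nonnegative, zero iff det ≡ 1).  It is asymmetric under det → 1/det; a test
documents this.  Gram entries are globally rescaled by the canonical Gram's
maximum so voxel distances are O(1); this uniform rescaling changes no
minimizer.

Multiresolution: up to 3 levels, 2× block-average downsampling.  Similarity
pre-alignment (3 translations, 3 rotations, 1 scale) maximizes normalized
cross-correlation of the b=0 images, FFT-initialized for translation and
Powell-refined; applying it to a mixture field uses rotation-only PPD (the
scale normalizes away).

Deformation inversion is fixed-point iteration on
d⁻¹(x) ← −d(x + d⁻¹(x)), with a composition-residual check (< 0.1 voxel on
smooth warps).

## Template construction

Stage 1 (intermediate): initialize with the voxel-wise average of weight
fields (closed under averaging — the blur this introduces is what stage 2
removes); then alternate register-all → re-average warped fields → *unbias*
by composing every deformation (and warping the template) with the inverse
of the mean displacement, so the template sits at the population barycenter.
Default 2–3 outer iterations with an energy-decrease stopping rule; the
iteration count is a free design choice, and the population energy trace is
monitored rather than assumed.

Stage 2 (projection): register every subject to the intermediate and keep
the (subject, warp) pair of least residual data energy (ties → smallest
index).  The final template is that subject warped and PPD-re-oriented —
an element of a data orbit, hence "sharp".  Both the warp and the
re-orientation convention are applied consistently (warp by T*, PPD by its
Jacobian).  Each stage costs exactly N registrations per pass — O(N)
overall, asserted by a registration-call counter in tests.

## CDT morphometry and SPD statistics

The morphometric feature is the Cauchy deformation tensor √(J Jᵀ) (left
stretch; the √(JᵀJ) variant is behind a flag), computed by batched
symmetric eigendecomposition.  Identities: CDT(Id) = Id, CDT(R) = Id for any
rotation, eigenvalues = singular values of J, and invariance under right
rotation J → JR.

CDTs live on SPD(3); statistics default to the affine-invariant metric
(Log_M(X) = M^{1/2} log(M^{−1/2} X M^{−1/2}) M^{1/2}), with Log-Euclidean as
a fast alternative (under which PGA provably equals PCA on matrix logs — a
test asserts this equivalence).  Fréchet means use the fixed-point
iteration M ← Exp_M(mean Log_M(X_i)), batched over voxels, tolerance 1e−10
on the gradient norm.

PGA operates on the *concatenated* product manifold: each subject maps to a
6V-dimensional tangent vector at the voxel-wise means (whitened logs;
off-diagonals scaled by √2 so the Euclidean inner product matches the
metric), followed by SVD.  A 362-voxel ROI gives 6 × 362 = 2172 features,
and N generic subjects give N − 1 positive-variance components (68 → 67).
The concatenated reading (one joint PGA rather than voxel-wise PGAs) is
chosen because the published analysis reports a single 2172 → 67 reduction.

The voxel-wise group test is a tangent-space Hotelling T² at the pooled
Fréchet mean, calibrated by permutation of group labels (default 1000
shuffles, mandatory seed, add-one p-value estimator); the underlying
manifold t-test statistic is not uniquely pinned down in the source
analysis, and the permutation calibration makes the choice
distribution-free.  Thresholds 0.05 / 0.01 are uncorrected, matching the
reference protocol; Benjamini–Hochberg is available as an option.  Type-I
error is verified by simulation (rejection fraction within [0.02, 0.08] at
α = 0.05).

## Classification

ν-SVM with RBF kernel exp(−g‖x−y‖²) (scikit-learn's NuSVC), leave-one-out.
Grid: g ∈ [0.001, 1] step 0.001, ν ∈ [0.001, 0.90] step 0.001,
r ∈ {5, …, 65} step 5; `stride_factor` coarsens the g and ν grids (default
10 for desk-scale runs; 1 reproduces the printed protocol).  Selection uses
the LOO accuracy itself, as in the reference protocol — this is
optimistically biased, which is why per-fold standardization is still done
strictly on the training fold, and the bias is documented rather than
hidden.  Ties break toward smaller r, then g, then ν; the scan visits cells
in that order, so it can stop at the first perfect cell without changing
the result.  Infeasible ν cells (class-balance bound) are invalid, not
errors.  The positive class is the patient group.  An independent ν-SVM
implementation (R `e1071`) cross-checks LOO predictions in the test suite.

FA baseline: single-tensor fit by weighted linear least squares on
log-attenuations (weights E²), FA = √(3/2)·‖λ−λ̄‖/‖λ‖ clamped to [0, 1],
features = FA at ROI voxels, identical protocol.  FA is rotation-invariant,
so a group effect that only re-orients fibers is invisible to it by
construction — the synthetic study plants exactly such an effect to
demonstrate the CDT feature's advantage.

## Synthetic phantoms

The generator emulates the target acquisition exactly — 64 spread gradient
directions at b = 1000 s/mm² plus one b = 0, Δ/δ = 42.4/10 ms, 2 mm
voxels — on a desk-scale grid.  The phantom is an ellipsoidal "brain" with:
a smoothly rotating fiber direction (in-plane rotation plus a z-dependent
tilt, snapped to the nearest dictionary atom so noise-free recovery is
exact); a central 90° crossing slab; an isotropic fraction that varies
smoothly with radius plus smooth seeded texture (tissue heterogeneity,
giving the registration scalar contrast everywhere); Rician magnitude
noise at a configurable b = 0 SNR (default 20).  Populations are
independently warped (Gaussian-smoothed random displacements, zero at a
boundary band, det J > 0 enforced by rescaling) and independently noised.

The two-class generator plants, for patients only, (i) a fixed localized
contraction toward the center of a 6×6×4 block (~144 voxels, the same order
as the published 362-voxel ROI), and/or (ii) an in-place rotation of fiber
orientations in that block (FA-invariant by construction), and/or (iii) an
anisotropy drop (fiber weight moved to the isotropic atom).  Every
generator is a pure function of (spec, seed).

What the phantoms do *not* model: real brain anatomy and its
inter-individual topology, scanner artifacts (eddy currents, ghosting,
distortion), spatially varying noise, partial voluming with CSF, or
multi-shell acquisitions.  Passing tests therefore demonstrate internal
consistency and sensitivity of the method under controlled conditions, not
clinical performance.

## Problem sizes and numerical choices

Desk-scale experiments keep the acquisition faithful (64 directions,
b = 1000) but shrink the spatial grid and dictionary so the full pipeline
runs in minutes on one core: grids of 24–32 voxels per axis (vs 112×112×60),
12 dictionary orientations for registration-heavy studies (46 for
estimation accuracy checks), 12+12 or 8+8 subjects (vs 22 controls + 46
patients), 1–2 template outer iterations, and grid stride 10.  These sizes
are stated here as the package's own defaults for its validation studies.

Other numerical choices: attenuation clamp (1e−6, 1]; mean of multiple b=0
volumes as the normalization divisor; NNLS ridge 1e−3; Fréchet tolerance
1e−10; PGA variance floor 1e−12 of total variance; permutation p-values use
the add-one estimator; energy comparisons treat empty (zero-weight) voxels
as zero-distance pairs.

## Known limitations

- Single-shell acquisitions (one b-value) do not uniquely identify the
  mixture: distinct weight vectors on a coherent dictionary can produce
  nearly identical 64-direction signals while remaining well separated in
  mixture L2 distance.  NNLS estimates are therefore stable and
  deterministic (noise moves them very little) but sit at a systematic
  offset from the generating weights.  Within-channel comparisons
  (estimate vs estimate) are meaningful; comparisons that cross the
  estimation channel (e.g. a warped estimate against a direct estimate of
  the same anatomy) carry that offset.  The template-sharpness validation
  consequently runs on the generators' emitted mixture fields, and the
  estimation stage is validated by its own recovery tests.
- The greedy registration is not symmetric/inverse-consistent and recovers
  only the data-visible part of a warp (aperture problem in homogeneous
  regions); the elastic smoothing biases toward smooth solutions.
- Dictionary snapping quantizes orientation at the dictionary's angular
  resolution; coarse dictionaries trade angular fidelity for speed.
- LOO-accuracy-based grid selection is optimistically biased; nested
  selection is available but not the default, to match the reference
  protocol.
- The manifold t-test is uncorrected for multiple comparisons by default,
  again matching the reference protocol.
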