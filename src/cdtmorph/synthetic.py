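"""Synthetic HARDI phantoms and populations with known ground truth.

Emulates the target acquisition — 64 spread gradient directions at
b = 1000 s/mm^2 plus one b = 0 volume, DELTA/delta = 42.4/10 ms — on a
desk-scale grid (default 32 x 32 x 16, 2 mm isotropic).  The phantom is an
ellipsoidal "brain" containing a smoothly rotating single-fiber region
and a 90-degree crossing slab over an isotropic background; magnitude
(Rician) noise is added at a configurable b=0 SNR.  Populations are
diffeomorphically warped, independently noised copies; a two-class
population plants a localized group effect (extra deformation and/or an
anisotropy drop) inside a small block standing in for the substantia
nigra ROI.

Every generator is a pure function of (spec, seed), and ground truth is
returned alongside the data so each downstream stage has an oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .gmf import (
    DiffusionDictionary,
    GMField,
    build_dictionary,
    hemisphere_orientations,
)
from .io_formats import DWIVolume, GradientTable, ROIMask, ValidationError
from .registration import DeformationField, apply_warp, jacobian_field, snap_to_dictionary

__all__ = [
    "PhantomSpec",
    "EffectSpec",
    "spread_gradients",
    "default_gradient_table",
    "make_phantom",
    "make_random_diffeo",
    "make_population",
    "make_two_class_population",
    "synthesize_dwi",
]


def spread_gradients(n: int) -> np.ndarray:
    """n unit vectors evenly spread over the sphere (Fibonacci lattice)."""
    i = np.arange(n)
    z = 1.0 - (2 * i + 1.0) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    rho = np.sqrt(1.0 - z**2)
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def default_gradient_table(n_dirs: int = 64, bval: float = 1000.0) -> GradientTable:
    """One b=0 volume followed by ``n_dirs`` directions at ``bval`` s/mm^2."""
    bvecs = np.vstack([np.zeros(3), spread_gradients(n_dirs)])
    bvals = np.concatenate([[0.0], np.full(n_dirs, bval)])
    return GradientTable(bvals=bvals, bvecs=bvecs)


@dataclass
class PhantomSpec:
    """Geometry and acquisition of the synthetic HARDI phantom.

    snr is the Rician signal-to-noise ratio at b=0 (np.inf = noise-free);
    n_orient sets the shared dictionary's orientation count.
    """

    shape: tuple = (32, 32, 16)
    snr: float = 20.0
    seed: int = 0
    n_dirs: int = 64
    bval: float = 1000.0
    s0: float = 100.0
    n_orient: int = 46
    iso_fraction: float = 0.3        # isotropic weight in fiber voxels
    crossing: bool = True

    def dictionary(self) -> DiffusionDictionary:
        return build_dictionary(n_orient=self.n_orient)

    def gradient_table(self) -> GradientTable:
        return default_gradient_table(self.n_dirs, self.bval)


@dataclass
class EffectSpec:
    """Planted localized group effect (synthetic substantia-nigra analog)."""

    roi_block: tuple = ((13, 19), (13, 19), (6, 10))  # 6x6x4 = 144 voxels
    warp_amplitude: float = 1.5   # voxels
    anisotropy_delta: float = 0.0  # fraction of fiber weight moved to isotropic
    rotation_angle_deg: float = 0.0  # in-place fiber re-orientation (FA-blind)

    def __post_init__(self):
        if self.warp_amplitude < 0:
            raise ValidationError("warp amplitude must be >= 0")

    def block_slices(self):
        return tuple(slice(lo, hi) for lo, hi in self.roi_block)

    def center(self) -> np.ndarray:
        return np.array([(lo + hi - 1) / 2.0 for lo, hi in self.roi_block])

    def mask(self, shape) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[self.block_slices()] = True
        return m

    def roi(self, shape, affine=None) -> ROIMask:
        return ROIMask(mask=self.mask(shape),
                       affine=np.eye(4) if affine is None else affine)


def _ellipsoid_mask(shape) -> np.ndarray:
    grid = np.stack(np.meshgrid(*[np.arange(s, dtype=float) for s in shape],
                                indexing="ij"), axis=-1)
    c = (np.array(shape) - 1) / 2.0
    ax = np.array(shape) * 0.46
    return (((grid - c) / ax) ** 2).sum(-1) <= 1.0


def _truth_weights(spec: PhantomSpec, dictionary: DiffusionDictionary) -> np.ndarray:
    """Ground-truth mixture weights built from dictionary atoms.

    Fiber orientations are continuous in-plane directions snapped to the
    nearest dictionary atom, which makes noise-free recovery exact.
    """
    X, Y, Z = spec.shape
    K = dictionary.n_atoms
    aniso = np.flatnonzero(dictionary.a1 > 0)
    iso = np.flatnonzero(dictionary.a1 == 0)
    iso_idx = iso[0] if len(iso) else aniso[0]
    w = np.zeros(spec.shape + (K,))
    brain = _ellipsoid_mask(spec.shape)

    xs, ys, zs = np.meshgrid(np.arange(X), np.arange(Y), np.arange(Z), indexing="ij")
    # smoothly rotating fiber direction with a z-dependent out-of-plane tilt
    theta = np.pi * (0.9 * xs / max(X - 1, 1) + 0.5 * ys / max(Y - 1, 1))
    psi = 0.35 * np.pi * (zs / max(Z - 1, 1) - 0.5)
    dirs = np.stack(
        [np.cos(theta) * np.cos(psi), np.sin(theta) * np.cos(psi), np.sin(psi)],
        axis=-1,
    )
    dots = np.abs(np.einsum("...p,kp->...k", dirs, dictionary.axes[aniso]))
    nearest = aniso[np.argmax(dots, axis=-1)]

    # isotropic fraction varies smoothly with radius plus smooth random
    # texture (tissue heterogeneity), giving the field scalar contrast on
    # top of orientation contrast; texture is part of the anatomy and is a
    # pure function of the spec seed
    c = (np.array(spec.shape) - 1) / 2.0
    ax_len = np.array(spec.shape) * 0.46
    grid = np.stack([xs, ys, zs], axis=-1).astype(float)
    r2 = (((grid - c) / ax_len) ** 2).sum(-1)
    rng = np.random.default_rng(spec.seed + 17)
    tex = ndimage.gaussian_filter(rng.standard_normal(spec.shape), 2.5)
    tex /= max(tex.std(), 1e-12)
    iso_f = np.clip(spec.iso_fraction * (0.5 + 1.3 * r2) + 0.12 * tex, 0.05, 0.85)

    flat = w.reshape(-1, K)
    bm = brain.ravel()
    rows = np.flatnonzero(bm)
    iso_flat = iso_f.ravel()
    flat[rows, nearest.ravel()[rows]] = 1.0 - iso_flat[rows]
    flat[rows, iso_idx] += iso_flat[rows]

    if spec.crossing:
        # central slab where two near-orthogonal populations cross at 90 deg
        cx = slice(int(X * 0.35), int(X * 0.65))
        cy = slice(int(Y * 0.30), int(Y * 0.70))
        kx = aniso[np.argmax(np.abs(dictionary.axes[aniso] @ np.array([1.0, 0, 0])))]
        ky = aniso[np.argmax(np.abs(dictionary.axes[aniso] @ np.array([0, 1.0, 0])))]
        cross = np.zeros(spec.shape, bool)
        cross[cx, cy, :] = True
        cross &= brain
        rows = np.flatnonzero(cross.ravel())
        flat[rows] = 0.0
        flat[rows, kx] = (1.0 - iso_flat[rows]) / 2
        flat[rows, ky] = (1.0 - iso_flat[rows]) / 2
        flat[rows, iso_idx] += iso_flat[rows]
    return w


def synthesize_dwi(field: GMField, gradients: GradientTable, s0: float = 100.0,
                   snr: float = np.inf, rng: np.random.Generator | None = None,
                   background_s0_frac: float = 0.05) -> DWIVolume:
    """Simulate the HARDI signal of a GMF under the mixture forward model.

    Handles fields carrying per-voxel re-oriented axes.  Rician noise:
    S = sqrt((S + n1)^2 + n2^2) with n ~ N(0, (s0/snr)^2).
    """
    d = field.dictionary
    w = field.weights_grid
    shape = field.shape
    K = d.n_atoms
    axes_grid = getattr(field, "axes_grid", None)
    scale = 1.0 / (2e-3 * d.tau)  # covariance (mm^2) -> diffusivity (mm^2/s)
    lam_delta = d.a1 * scale
    lam_perp = d.a2 * scale
    n_meas = len(gradients)
    tissue = w.sum(-1) > 0
    wn = np.where(tissue[..., None], w, 0.0)
    total = np.maximum(wn.sum(-1, keepdims=True), 1e-12)
    wn = wn / total

    E = np.empty(shape + (n_meas,))
    g = gradients.bvecs
    b = gradients.bvals
    if axes_grid is None:
        quad = np.einsum("ip,kpq,iq->ik", g, d.tensors, g)
        A = np.exp(-b[:, None] * quad)  # (n_meas, K)
        E = np.einsum("...k,ik->...i", wn, A)
    else:
        for i in range(n_meas):
            dot2 = np.einsum("...kp,p->...k", axes_grid, g[i]) ** 2
            quad = lam_delta * dot2 + lam_perp * (g[i] @ g[i])
            E[..., i] = np.einsum("...k,...k->...", wn, np.exp(-b[i] * quad))
    S = s0 * E
    S[~tissue] = background_s0_frac * s0
    if np.isfinite(snr):
        if rng is None:
            rng = np.random.default_rng(0)
        sigma = s0 / snr
        n1 = rng.normal(0, sigma, S.shape)
        n2 = rng.normal(0, sigma, S.shape)
        S = np.sqrt((S + n1) ** 2 + n2**2)
    return DWIVolume(data=S, affine=np.eye(4), gradients=gradients)


def make_phantom(spec: PhantomSpec,
                 dictionary: DiffusionDictionary | None = None):
    """Build the base phantom: (noisy DWIVolume, ground-truth GMField)."""
    if dictionary is None:
        dictionary = spec.dictionary()
    w = _truth_weights(spec, dictionary)
    truth = GMField(weights_grid=w, dictionary=dictionary, affine=np.eye(4))
    rng = np.random.default_rng(spec.seed)
    dwi = synthesize_dwi(truth, spec.gradient_table(), s0=spec.s0,
                         snr=spec.snr, rng=rng)
    return dwi, truth


def make_random_diffeo(shape, amplitude: float, smoothness: float = 4.0,
                       seed: int = 0, boundary: int = 3) -> DeformationField:
    """Random smooth displacement, zero near the boundary, det J > 0.

    Gaussian-smoothed white noise scaled to the requested maximum
    displacement; rescaled (up to 20 times) until det(Id + grad d) > 0
    everywhere.
    """
    rng = np.random.default_rng(seed)
    if amplitude == 0:
        return DeformationField(disp=np.zeros(tuple(shape) + (3,)), affine=np.eye(4))
    d = rng.normal(size=tuple(shape) + (3,))
    for i in range(3):
        d[..., i] = ndimage.gaussian_filter(d[..., i], smoothness)
    # cosine taper to zero in a boundary band
    for ax, s in enumerate(shape):
        t = np.ones(s)
        bb = min(boundary, s // 2)
        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(bb) / bb))
        t[:bb] = ramp
        t[s - bb:] = ramp[::-1]
        d *= t.reshape([-1 if a == ax else 1 for a in range(3)] + [1])
    norms = np.linalg.norm(d, axis=-1)
    d *= amplitude / norms.max()
    for _ in range(20):
        T = DeformationField(disp=d, affine=np.eye(4))
        if jacobian_field(T).det.min() > 0.05:
            return T
        d *= 0.8
    raise ValidationError("could not build a diffeomorphic displacement; "
                          "amplitude too large for this smoothness")


def _effect_deformation(shape, effect: EffectSpec) -> DeformationField:
    """Deterministic localized contraction toward the effect-block center."""
    grid = np.stack(np.meshgrid(*[np.arange(s, dtype=float) for s in shape],
                                indexing="ij"), axis=-1)
    c = effect.center()
    widths = np.array([(hi - lo) for lo, hi in effect.roi_block], float) / 2.0
    rel = (grid - c) / widths
    bump = np.exp(-1.5 * (rel**2).sum(-1))
    raw = -bump[..., None] * (grid - c) / np.maximum(widths.max(), 1.0)
    norms = np.linalg.norm(raw, axis=-1)
    if norms.max() > 0 and effect.warp_amplitude > 0:
        raw *= effect.warp_amplitude / norms.max()
    else:
        raw[:] = 0.0
    d = raw
    for _ in range(20):
        T = DeformationField(disp=d, affine=np.eye(4))
        if jacobian_field(T).det.min() > 0.05:
            return T
        d = d * 0.8
    raise ValidationError("effect deformation is not diffeomorphic")


def _warped_subject(truth: GMField, T: DeformationField, gradients: GradientTable,
                    spec: PhantomSpec, rng: np.random.Generator):
    # the emitted ground truth (snapped to the shared dictionary) is exactly
    # the field the signal is synthesized from, so it is a true oracle for
    # every downstream stage
    gmf_truth = snap_to_dictionary(apply_warp(truth, T))
    dwi = synthesize_dwi(gmf_truth, gradients, s0=spec.s0, snr=spec.snr, rng=rng)
    return dwi, gmf_truth


def make_population(n: int, spec: PhantomSpec, warp_amplitude: float = 1.0,
                    smoothness: float = 4.0, seed: int = 0,
                    dictionary: DiffusionDictionary | None = None):
    """n independently warped + noised copies of the base phantom.

    Returns a list of (DWIVolume, ground-truth GMField) pairs; the truth
    fields are snapped back to the shared dictionary.
    """
    if n < 2:
        raise ValidationError("population needs n >= 2")
    if dictionary is None:
        dictionary = spec.dictionary()
    _, truth = make_phantom(spec, dictionary=dictionary)
    gt = spec.gradient_table()
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        T = make_random_diffeo(spec.shape, warp_amplitude, smoothness,
                               seed=seed * 100003 + 7919 * i + 1)
        out.append(_warped_subject(truth, T, gt, spec, rng))
    return out


def make_two_class_population(n_ctrl: int, n_pat: int, spec: PhantomSpec,
                              effect: EffectSpec, seed: int = 0,
                              warp_amplitude: float = 1.0,
                              smoothness: float = 4.0,
                              dictionary: DiffusionDictionary | None = None):
    """Labeled control/patient population with a planted localized effect.

    Patients receive, on top of the shared inter-subject variability, a
    fixed localized contraction inside ``effect.roi_block`` (the same
    pattern for every patient) and optionally an anisotropy drop there.
    Returns (subjects, labels): labels are 0 = control, 1 = patient.
    """
    if n_ctrl < 2 or n_pat < 2:
        raise ValidationError("both classes need n >= 2")
    if dictionary is None:
        dictionary = spec.dictionary()
    _, truth = make_phantom(spec, dictionary=dictionary)
    gt = spec.gradient_table()
    rng = np.random.default_rng(seed)
    T_eff = _effect_deformation(spec.shape, effect)

    patient_truth = truth
    if effect.rotation_angle_deg != 0.0:
        # rotate fiber orientations in place inside the block: eigenvalues
        # (hence FA) are exactly unchanged, only directions move
        from scipy.spatial.transform import Rotation

        R = Rotation.from_rotvec(
            np.deg2rad(effect.rotation_angle_deg) * np.array([0.0, 0.0, 1.0])
        ).as_matrix()
        d = dictionary
        aniso_idx = np.flatnonzero(d.a1 > 0)
        rotated = (R @ d.axes[aniso_idx].T).T
        dots = np.abs(rotated @ d.axes[aniso_idx].T)
        target = aniso_idx[np.argmax(dots, axis=1)]  # nearest canonical atom
        w = patient_truth.weights_grid.copy()
        block = effect.mask(spec.shape)
        wb = w[block]
        moved = wb[:, aniso_idx].copy()
        wb[:, aniso_idx] = 0.0
        for src, dst in zip(range(len(aniso_idx)), target):
            wb[:, dst] += moved[:, src]
        w[block] = wb
        patient_truth = GMField(weights_grid=w, dictionary=dictionary,
                                affine=truth.affine)
    if effect.anisotropy_delta > 0:
        w = patient_truth.weights_grid.copy()
        d = dictionary
        iso = np.flatnonzero(d.a1 == 0)
        if len(iso) == 0:
            raise ValidationError("anisotropy_delta requires an isotropic atom")
        block = effect.mask(spec.shape)
        aniso = d.a1 > 0
        moved = w[block][:, aniso] * effect.anisotropy_delta
        w[block, iso[0]] += moved.sum(axis=-1)
        wb = w[block]
        wb[:, aniso] *= 1.0 - effect.anisotropy_delta
        w[block] = wb
        patient_truth = GMField(weights_grid=w, dictionary=d, affine=truth.affine)

    subjects, labels = [], []
    for i in range(n_ctrl + n_pat):
        is_pat = i >= n_ctrl
        T_i = make_random_diffeo(spec.shape, warp_amplitude, smoothness,
                                 seed=seed * 100003 + 7919 * i + 3)
        base = patient_truth if is_pat else truth
        if is_pat and effect.warp_amplitude > 0:
            from .registration import compose_deformations

            T_i = compose_deformations(T_i, T_eff)
        subjects.append(_warped_subject(base, T_i, gt, spec, rng))
        labels.append(1 if is_pat else 0)
    return subjects, np.array(labels)
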