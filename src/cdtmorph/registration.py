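"""Similarity and diffeomorphic registration of Gaussian-mixture fields.

The deformation model is a diffeomorphism T(x) = x + d(x) built greedily
from small velocity steps: each iteration computes a demons-like force
from the voxel-wise mixture L2 distance, smooths it (a Gaussian proxy for
the inverse of the regularizing operator L), caps the step length and
composes it with the current map.  Steps are accepted only if they keep
det(J) > 0 everywhere and decrease the total energy

    E = sum_x dist^2( reorient(moving o T)(x), fixed(x) )
        + lam * sum_x log(det J(x)) (det J(x) - 1),

so the energy trace is monotone non-increasing.  The log-det term is
nonnegative and zero iff det J = 1; its printed sign in the source
formulation makes the term nonpositive, which cannot act as a penalty
under minimization, so the negated form is used.

Mixture components are re-oriented by preservation of principal
direction (PPD); because dictionary atoms are axially symmetric this
reduces to rotating each atom's principal axis to J u / ||J u||, which
keeps the inner loop free of per-voxel eigendecompositions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from .gmf import DiffusionDictionary, GMField, ppd_rotate_axes
from .io_formats import ValidationError

__all__ = [
    "DeformationField",
    "JacobianField",
    "RegistrationConfig",
    "SimilarityTransform",
    "identity_deformation",
    "jacobian_field",
    "apply_warp",
    "warp_scalar",
    "compose_deformations",
    "invert_deformation",
    "data_energy",
    "smoothness_penalty",
    "nonrigid_register",
    "similarity_register",
    "apply_similarity_to_gmf",
    "registration_call_count",
    "reset_registration_counter",
]

#: module-level counter of nonrigid registration calls (template bookkeeping)
_REGISTRATION_CALLS = [0]


def registration_call_count() -> int:
    return _REGISTRATION_CALLS[0]


def reset_registration_counter() -> None:
    _REGISTRATION_CALLS[0] = 0


@dataclass
class DeformationField:
    """Dense displacement d(x) in voxel units; T(x) = x + d(x)."""

    disp: np.ndarray  # (X, Y, Z, 3)
    affine: np.ndarray

    def __post_init__(self):
        self.disp = np.asarray(self.disp, dtype=float)
        if self.disp.ndim != 4 or self.disp.shape[-1] != 3:
            raise ValidationError("displacement must be (X, Y, Z, 3)")
        if not np.all(np.isfinite(self.disp)):
            raise ValidationError("non-finite displacement")
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape(self):
        return self.disp.shape[:3]


@dataclass
class JacobianField:
    """Per-voxel 3x3 Jacobian of T (dimensionless)."""

    J: np.ndarray  # (X, Y, Z, 3, 3)

    @property
    def det(self) -> np.ndarray:
        return np.linalg.det(self.J)


@dataclass
class RegistrationConfig:
    """Knobs of the greedy diffeomorphic registration.

    lam          weight of the log-det volume-change penalty
    smooth_sigma Gaussian width (voxels) standing in for (L^dag L)^{-1}
    max_step     per-iteration displacement cap (voxels)
    n_iter       iterations per pyramid level
    n_levels     multiresolution depth (downsampling by 2, block averages)
    tol          relative energy-decrease stopping threshold
    fd_step      finite-difference step (voxels) for the distance gradient
    """

    lam: float = 0.05
    smooth_sigma: float = 2.0
    max_step: float = 0.4
    n_iter: int = 50
    n_levels: int = 3
    tol: float = 1e-5
    fd_step: float = 0.25
    elastic_sigma: float = 1.0
    use_inverse_transpose: bool = False


def identity_deformation(shape, affine=None) -> DeformationField:
    if affine is None:
        affine = np.eye(4)
    return DeformationField(disp=np.zeros(tuple(shape) + (3,)), affine=affine)


# ---------------------------------------------------------------------------
# warping primitives


def _grid_coords(shape):
    return np.stack(
        np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij"),
        axis=-1,
    )


def _sample(vol: np.ndarray, coords: np.ndarray, order=1, cval=0.0) -> np.ndarray:
    """Trilinear sampling of a 3D scalar volume at (..., 3) voxel coords."""
    pts = coords.reshape(-1, 3).T
    out = ndimage.map_coordinates(vol, pts, order=order, mode="constant", cval=cval)
    return out.reshape(coords.shape[:-1])


def _sample_channels(vol4: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Sample every channel of a (X, Y, Z, K) volume; returns (..., K)."""
    K = vol4.shape[-1]
    out = np.empty(coords.shape[:-1] + (K,))
    for k in range(K):
        out[..., k] = _sample(vol4[..., k], coords)
    return out


def _renormalize_weights(w: np.ndarray) -> np.ndarray:
    """Renormalize interpolated weights without hallucinating tissue.

    Interior voxels (interpolated total ~1) are renormalized to sum
    exactly 1; partial-volume boundary voxels (total < 1) keep their
    fractional total, so tissue fades out instead of snapping to full
    weight.
    """
    w = np.clip(w, 0.0, None)
    total = w.sum(axis=-1, keepdims=True)
    scale = np.where(total > 1.0, 1.0 / np.maximum(total, 1e-12), 1.0)
    return w * scale


def jacobian_field(T: DeformationField) -> JacobianField:
    """J = Id + grad(d): central differences interior, one-sided at edges."""
    d = T.disp
    J = np.zeros(T.shape + (3, 3))
    for i in range(3):
        grads = np.gradient(d[..., i], axis=(0, 1, 2))
        for j in range(3):
            J[..., i, j] = grads[j]
        J[..., i, i] += 1.0
    return JacobianField(J=J)


def compose_deformations(outer: DeformationField, inner: DeformationField) -> DeformationField:
    """Deformation of T_outer o T_inner: d(x) = d_in(x) + d_out(x + d_in(x))."""
    coords = _grid_coords(inner.shape) + inner.disp
    d_out = np.stack(
        [_sample(outer.disp[..., i], coords) for i in range(3)], axis=-1
    )
    return DeformationField(disp=inner.disp + d_out, affine=inner.affine)


def invert_deformation(T: DeformationField, n_iter: int = 50, tol: float = 0.05) -> DeformationField:
    """Fixed-point inversion: d_inv(x) <- -d(x + d_inv(x))."""
    grid = _grid_coords(T.shape)
    d_inv = np.zeros_like(T.disp)
    for _ in range(n_iter):
        coords = grid + d_inv
        d_at = np.stack([_sample(T.disp[..., i], coords) for i in range(3)], axis=-1)
        new = -d_at
        delta = np.abs(new - d_inv).max()
        d_inv = new
        if delta < tol * 0.1:
            break
    # composition residual check
    inv = DeformationField(disp=d_inv, affine=T.affine)
    comp = compose_deformations(T, inv)
    core = tuple(slice(2, -2) for _ in range(3))
    resid = np.abs(comp.disp[core]).max() if min(T.shape) > 4 else np.abs(comp.disp).max()
    if resid > 1.0:
        raise ValidationError(f"deformation inversion failed: residual {resid:.3f} voxels")
    return inv


def warp_scalar(vol: np.ndarray, T: DeformationField) -> np.ndarray:
    return _sample(vol, _grid_coords(T.shape) + T.disp)


def apply_warp(img: GMField, T: DeformationField, reorient: bool = True,
               use_inverse_transpose: bool = False) -> GMField:
    """Warp a GMF: sample weights at T(x), PPD-reorient by the local Jacobian.

    The input must live on canonical dictionary axes (snap a previously
    warped field first).  The output carries a per-voxel ``axes_grid``
    holding each atom's rotated principal axis; weights are renormalized
    to sum 1 on tissue voxels.
    """
    if getattr(img, "axes_grid", None) is not None:
        raise ValidationError("apply_warp expects a field on canonical dictionary axes")
    coords = _grid_coords(T.shape) + T.disp
    w = _sample_channels(img.weights_grid, coords)
    w = _renormalize_weights(w)
    out = GMField(weights_grid=w, dictionary=img.dictionary, affine=img.affine)
    if reorient:
        J = jacobian_field(T).J
        F = np.linalg.inv(J).transpose(0, 1, 2, 4, 3) if use_inverse_transpose else J
        out.axes_grid = ppd_rotate_axes(img.dictionary.axes, F)
    else:
        out.axes_grid = None
    return out


def snap_to_dictionary(field: GMField) -> GMField:
    """Re-express a re-oriented field on canonical atoms.

    Each rotated atom's weight moves to the dictionary atom whose axis is
    angularly closest (antipodally symmetric).  Quantization error is at
    most half the dictionary's angular spacing.
    """
    axes_grid = getattr(field, "axes_grid", None)
    if axes_grid is None:
        return field
    d = field.dictionary
    aniso = d.a1 > 0
    dots = np.abs(np.einsum("...kp,mp->...km", axes_grid, d.axes))
    # forbid moving anisotropic weight onto differently-shaped atoms
    shape_ok = (d.a1[:, None] > 0) == (d.a1[None, :] > 0)
    dots = np.where(shape_ok[None, None, None], dots, -1.0)
    nearest = np.argmax(dots, axis=-1)  # (X, Y, Z, K)
    K = d.n_atoms
    w = field.weights_grid
    new_w = np.zeros_like(w)
    flat_w = w.reshape(-1, K)
    flat_n = nearest.reshape(-1, K)
    rows = np.repeat(np.arange(flat_w.shape[0]), K)
    np.add.at(new_w.reshape(-1, K), (rows, flat_n.ravel()), flat_w.ravel())
    out = GMField(weights_grid=new_w, dictionary=d, affine=field.affine,
                  mask=field.mask)
    out.axes_grid = None
    return out


# ---------------------------------------------------------------------------
# mixture-field energies


class _EnergyMachine:
    """Vectorized voxel-wise squared L2 mixture distances for one dictionary.

    All Gram entries are rescaled by the canonical Gram's maximum so
    voxel distances are O(1); this is a uniform global rescale (every
    cross term scales identically) and does not change any minimizer.
    """

    def __init__(self, dictionary: DiffusionDictionary):
        self.d = dictionary
        self.axes = dictionary.axes
        self.a1 = dictionary.a1
        self.a2 = dictionary.a2
        G = self._gram_canonical()
        self.scale = 1.0 / G.max()
        self.G = G * self.scale
        self._chunk = 8192

    def _cross_gram(self, axes_a, a1_a, a2_a, axes_b, a1_b, a2_b):
        """Gram for axially symmetric covariances a1 u u^T + a2 I.

        det(C_a + C_b) = g^3 + g^2 (a1_a + a1_b) + g a1_a a1_b (1 - t),
        g = a2_a + a2_b, t = (u_a . u_b)^2; broadcast over leading dims.
        """
        t = np.einsum("...ip,...jp->...ij", axes_a, axes_b) ** 2
        g = a2_a[..., :, None] + a2_b[..., None, :]
        s1 = a1_a[..., :, None] + a1_b[..., None, :]
        p = a1_a[..., :, None] * a1_b[..., None, :]
        det = g**3 + g**2 * s1 + g * p * (1.0 - t)
        return (2.0 * np.pi) ** (-1.5) / np.sqrt(det)

    def _gram_canonical(self):
        return self._cross_gram(self.axes, self.a1, self.a2,
                                self.axes, self.a1, self.a2)

    def dist_sq_map(self, w_m, axes_m, w_f):
        """Per-voxel dist^2 between a (possibly re-oriented) moving field
        and a canonical fixed field.

        w_m, w_f: (V, K) weights; axes_m: (V, K, 3) or None (canonical).
        """
        V, K = w_m.shape
        out = np.empty(V)
        ff = np.einsum("vk,kl,vl->v", w_f, self.G, w_f)
        if axes_m is None:
            mm = np.einsum("vk,kl,vl->v", w_m, self.G, w_m)
            mf = np.einsum("vk,kl,vl->v", w_m, self.G, w_f)
            return np.maximum(mm - 2 * mf + ff, 0.0)
        for lo in range(0, V, self._chunk):
            sl = slice(lo, min(lo + self._chunk, V))
            ax = axes_m[sl]
            Gmm = self._cross_gram(ax, self.a1, self.a2, ax, self.a1, self.a2) * self.scale
            Gmf = self._cross_gram(ax, self.a1, self.a2,
                                   self.axes[None], self.a1, self.a2) * self.scale
            mm = np.einsum("vk,vkl,vl->v", w_m[sl], Gmm, w_m[sl])
            mf = np.einsum("vk,vkl,vl->v", w_m[sl], Gmf, w_f[sl])
            out[sl] = mm - 2 * mf + ff[sl]
        return np.maximum(out, 0.0)


def _field_flat(field: GMField):
    w = field.weights_grid.reshape(-1, field.dictionary.n_atoms)
    axes = getattr(field, "axes_grid", None)
    if axes is not None:
        axes = axes.reshape(-1, field.dictionary.n_atoms, 3)
    return w, axes


def data_energy(moving: GMField, fixed: GMField, T: DeformationField | None = None,
                machine: _EnergyMachine | None = None) -> float:
    """Sum over voxels of squared mixture L2 distance (Eq-1-style data term).

    If a deformation is given, the moving field is warped and PPD
    re-oriented first; otherwise it is compared as-is.
    """
    if moving.shape != fixed.shape:
        raise ValidationError(f"grid mismatch {moving.shape} vs {fixed.shape}")
    if moving.dictionary.n_atoms != fixed.dictionary.n_atoms:
        raise ValidationError("dictionary mismatch between fields")
    if T is not None:
        moving = apply_warp(moving, T)
    if machine is None:
        machine = _EnergyMachine(fixed.dictionary)
    w_m, axes_m = _field_flat(moving)
    w_f, axes_f = _field_flat(fixed)
    if axes_f is not None:
        raise ValidationError("fixed field must live on canonical dictionary axes")
    return float(machine.dist_sq_map(w_m, axes_m, w_f).sum())


def _detj_penalty(detJ: np.ndarray, lam: float) -> float:
    if np.any(detJ <= 0):
        return np.inf
    return float(lam * np.sum(np.log(detJ) * (detJ - 1.0)))


def smoothness_penalty(T: DeformationField, config: RegistrationConfig,
                       velocity_steps=None) -> float:
    """Deformation regularity: lam * sum log(det J)(det J - 1) (+ sum ||L v||^2).

    ``velocity_steps`` is an optional list of (velocity field, step) pairs
    accumulated during greedy optimization; L is a discrete Laplacian.
    """
    detJ = jacobian_field(T).det
    pen = _detj_penalty(detJ, config.lam)
    if not np.isfinite(pen):
        return np.inf
    if velocity_steps:
        for v, step in velocity_steps:
            lv = np.stack([ndimage.laplace(v[..., i]) for i in range(3)], axis=-1)
            pen += float(np.sum(lv**2) * step)
    return pen


# ---------------------------------------------------------------------------
# greedy diffeomorphic registration


def _downsample_weights(w: np.ndarray) -> np.ndarray:
    """Block-average 2x2x2 downsampling of a (X, Y, Z, K) array."""
    sx, sy, sz = (s // 2 for s in w.shape[:3])
    w = w[: 2 * sx, : 2 * sy, : 2 * sz]
    return w.reshape(sx, 2, sy, 2, sz, 2, -1).mean(axis=(1, 3, 5))


def _downsample_field(field: GMField) -> GMField:
    # block averages keep partial-volume totals (<= 1) unrenormalized
    w = _downsample_weights(field.weights_grid)
    return GMField(weights_grid=w, dictionary=field.dictionary, affine=field.affine)


def _upsample_disp(disp: np.ndarray, target_shape) -> np.ndarray:
    zoom = [t / s for t, s in zip(target_shape, disp.shape[:3])]
    out = np.stack(
        [ndimage.zoom(disp[..., i], zoom, order=1) * zoom[i] for i in range(3)],
        axis=-1,
    )
    return out


def _register_single_level(moving: GMField, fixed: GMField, disp: np.ndarray,
                           config: RegistrationConfig, machine: _EnergyMachine):
    shape = fixed.shape
    grid = _grid_coords(shape)
    w_f = fixed.weights_grid.reshape(-1, fixed.dictionary.n_atoms)
    G = machine.G
    Gwf = w_f @ G
    h = config.fd_step

    def total_energy(d):
        T = DeformationField(disp=d, affine=fixed.affine)
        detJ = jacobian_field(T).det
        pen = _detj_penalty(detJ, config.lam)
        if not np.isfinite(pen):
            return np.inf, np.inf
        e = data_energy(moving, fixed, T, machine=machine)
        return e + pen, e

    energy, data_e = total_energy(disp)
    trace = [energy]
    converged = False
    for _ in range(config.n_iter):
        coords = grid + disp
        # demons-like force: finite differences of the voxel distance,
        # reorientation frozen within the iteration (shared Gram)
        force = np.empty(shape + (3,))
        for dim in range(3):
            q = []
            for sgn in (+1.0, -1.0):
                c = coords.copy()
                c[..., dim] += sgn * h
                wm = _renormalize_weights(
                    _sample_channels(moving.weights_grid, c)
                ).reshape(-1, moving.dictionary.n_atoms)
                q.append(np.einsum("vk,vk->v", wm @ G, wm) - 2 * np.einsum("vk,vk->v", wm, Gwf))
            force[..., dim] = -((q[0] - q[1]) / (2 * h)).reshape(shape)
        for dim in range(3):
            force[..., dim] = ndimage.gaussian_filter(force[..., dim], config.smooth_sigma)
        norms = np.linalg.norm(force, axis=-1)
        if norms.max() == 0:
            converged = True
            break
        # demons-style per-voxel normalization: voxels saturate toward
        # max_step where the force is strong, move proportionally where weak
        q = np.percentile(norms[norms > 0], 75)
        step_dir = force / (norms + q + 1e-30)[..., None]
        accepted = False
        for factor in (1.0, 0.5, 0.25, 0.1):
            s = step_dir * (config.max_step * factor)
            trial = s + np.stack(
                [_sample(disp[..., i], grid + s) for i in range(3)], axis=-1
            )
            if config.elastic_sigma > 0:
                # mild elastic regularization of the accumulated field
                for i in range(3):
                    trial[..., i] = ndimage.gaussian_filter(
                        trial[..., i], config.elastic_sigma
                    )
            e_new, d_new = total_energy(trial)
            if e_new < energy:
                disp = trial
                prev = energy
                energy, data_e = e_new, d_new
                trace.append(energy)
                accepted = True
                break
        if not accepted:
            break
        if prev - energy < config.tol * max(abs(prev), 1e-12):
            converged = True
            break
    return disp, trace, converged, data_e


def nonrigid_register(moving: GMField, fixed: GMField,
                      config: RegistrationConfig | None = None):
    """Greedy multiresolution diffeomorphic registration of two GMFs.

    Returns (DeformationField, info) where info carries the energy trace
    (monotone non-increasing within each level), per-level traces, the
    final data energy and a convergence flag.  det J > 0 everywhere is
    enforced by step rejection.
    """
    if config is None:
        config = RegistrationConfig()
    if moving.shape != fixed.shape:
        raise ValidationError("moving and fixed grids differ")
    _REGISTRATION_CALLS[0] += 1
    machine = _EnergyMachine(fixed.dictionary)

    # pyramid (coarsest last in build order)
    pyramid = [(moving, fixed)]
    for _ in range(config.n_levels - 1):
        m, f = pyramid[-1]
        if min(m.shape) < 12:
            break
        pyramid.append((_downsample_field(m), _downsample_field(f)))

    disp = None
    traces = []
    converged = True
    data_e = None
    for level in range(len(pyramid) - 1, -1, -1):
        m, f = pyramid[level]
        if disp is None:
            disp = np.zeros(f.shape + (3,))
        else:
            disp = _upsample_disp(disp, f.shape)
        lvl_cfg = replace(config, smooth_sigma=config.smooth_sigma)
        disp, trace, conv, data_e = _register_single_level(m, f, disp, lvl_cfg, machine)
        traces.append(trace)
        converged = conv
    T = DeformationField(disp=disp, affine=fixed.affine)
    detJ = jacobian_field(T).det
    info = {
        "energy_trace": traces[-1],
        "level_traces": traces,
        "data_energy": data_e,
        "converged": bool(converged),
        "min_detj": float(detJ.min()),
    }
    return T, info


# ---------------------------------------------------------------------------
# similarity (7-dof) pre-alignment


@dataclass
class SimilarityTransform:
    """x_moving = c + s R (x_fixed - c) + t, all in voxel coordinates."""

    translation: np.ndarray
    rotation: np.ndarray  # 3x3
    scale: float
    center: np.ndarray

    @property
    def magnification(self) -> float:
        """Size of fixed-image structures relative to the moving image.

        ``scale`` parameterizes the resampling map (fixed -> moving
        coordinates), so a fixed image whose objects are 1.1x larger
        yields scale ~ 1/1.1 and magnification ~ 1.1.
        """
        return 1.0 / self.scale

    def coords(self, shape) -> np.ndarray:
        grid = _grid_coords(shape)
        rel = grid - self.center
        return self.center + self.scale * np.einsum("pq,...q->...p", self.rotation, rel) \
            + self.translation


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a.ravel() - a.mean()
    b = b.ravel() - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


def similarity_register(moving_s0: np.ndarray, fixed_s0: np.ndarray,
                        smooth: float = 1.0) -> SimilarityTransform:
    """7-dof (translation, rotation, isotropic scale) alignment by NCC.

    Translation is initialized by FFT cross-correlation, then all seven
    parameters are refined with Powell's method.  On optimizer failure the
    identity transform is returned with a warning.
    """
    mv = ndimage.gaussian_filter(np.asarray(moving_s0, float), smooth)
    fx = ndimage.gaussian_filter(np.asarray(fixed_s0, float), smooth)
    center = (np.array(fx.shape) - 1) / 2.0

    # FFT-based translation init
    fa = np.fft.fftn(fx - fx.mean())
    fb = np.fft.fftn(mv - mv.mean())
    cc = np.real(np.fft.ifftn(fa.conj() * fb))
    shift = np.array(np.unravel_index(np.argmax(cc), cc.shape), float)
    shift = np.where(shift > np.array(cc.shape) / 2, shift - np.array(cc.shape), shift)

    def params_to_tf(p):
        t = p[:3]
        R = Rotation.from_rotvec(p[3:6]).as_matrix()
        s = float(np.exp(p[6]))
        return SimilarityTransform(translation=np.asarray(t, float), rotation=R,
                                   scale=s, center=center)

    def loss(p):
        tf = params_to_tf(p)
        resampled = _sample(mv, tf.coords(fx.shape))
        return -_ncc(resampled, fx)

    x0 = np.concatenate([shift, np.zeros(4)])
    try:
        res = minimize(loss, x0, method="Powell",
                       options={"xtol": 1e-3, "ftol": 1e-6, "maxiter": 4000})
        if not res.success and loss(res.x) > loss(x0):
            raise RuntimeError(res.message)
        p = res.x
    except Exception as exc:  # pragma: no cover - defensive
        warnings.warn(f"similarity registration did not converge ({exc}); "
                      "returning identity")
        p = np.zeros(7)
    return params_to_tf(p)


def apply_similarity_to_gmf(img: GMField, tf: SimilarityTransform,
                            snap: bool = True) -> GMField:
    """Resample a GMF under a similarity transform with rotation-only PPD.

    PPD of a similarity map reduces to conjugation by its rotation (the
    scale normalizes away).  With ``snap`` the rotated atoms are
    re-expressed on the canonical dictionary.
    """
    coords = tf.coords(img.shape)
    w = _sample_channels(img.weights_grid, coords)
    w = _renormalize_weights(w)
    out = GMField(weights_grid=w, dictionary=img.dictionary, affine=img.affine)
    rotated = (tf.rotation @ img.dictionary.axes.T).T
    out.axes_grid = np.broadcast_to(
        rotated, out.shape + rotated.shape
    ).copy()
    if snap:
        out = snap_to_dictionary(out)
    return out
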