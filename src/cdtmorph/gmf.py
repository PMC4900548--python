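"""Gaussian-mixture representation of ensemble average propagators (EAPs).

The EAP P(r) at a voxel is the Fourier transform of the normalized
diffusion signal E(q).  Under a multi-compartment Gaussian model the
signal is E(q) = sum_k w_k exp(-b g^T D_k g) and the propagator is the
zero-mean Gaussian mixture

    P(r) = sum_k w_k N(r; 0, 2 tau D_k),

with tau the effective diffusion time.  A whole image of such mixtures
over one shared dictionary of diffusivity tensors D_k is a Gaussian
mixture field (GMF): only the nonnegative weights vary across voxels.
This module builds the dictionary, fits weights to attenuations by
nonnegative least squares, evaluates the closed-form L2 distance between
mixture densities, and re-orients mixtures under a local Jacobian by
preservation of principal direction (PPD).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy.optimize import nnls

from .io_formats import GradientTable, DWIVolume, ValidationError, attenuation

__all__ = [
    "DEFAULT_TAU",
    "DiffusionDictionary",
    "GaussianMixture",
    "GMField",
    "build_dictionary",
    "hemisphere_orientations",
    "design_matrix",
    "predict_attenuation",
    "estimate_gmf",
    "eap_value",
    "gm_l2_distance",
    "gm_l2_distance_sq",
    "reorient_ppd",
    "ppd_rotate_axes",
    "gram_matrix",
]

#: effective diffusion time DELTA - delta/3 for DELTA/delta = 42.4/10 ms
DEFAULT_TAU = 42.4 - 10.0 / 3.0

_NORM3 = (2.0 * np.pi) ** (-1.5)


def hemisphere_orientations(n: int) -> np.ndarray:
    """n unit vectors spread over a hemisphere (spherical Fibonacci lattice).

    Antipodally distinct by construction (all have z > 0).
    """
    if n < 1:
        raise ValidationError("need at least one orientation")
    i = np.arange(n)
    z = (i + 0.5) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    rho = np.sqrt(1.0 - z**2)
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


@dataclass(frozen=True)
class DiffusionDictionary:
    """Shared dictionary of axially symmetric diffusivity tensors.

    Each atom is D_k = (lambda_par - lambda_perp) u_k u_k^T + lambda_perp I
    (mm^2/s) for a unit orientation u_k; an optional isotropic atom has
    D = d_iso I.  The mixture covariance of atom k is C_k = 2 tau D_k with
    tau in ms and an ms->s conversion, so C is in mm^2 (displacement scale
    of a few microns).

    Atoms are stored in the uniform axially-symmetric form
    C_k = a1_k u_k u_k^T + a2_k I  (a1 = 0 for the isotropic atom), which
    registration exploits for fast vectorized distances.
    """

    axes: np.ndarray        # (K, 3) unit principal axes
    a1: np.ndarray          # (K,) c_par - c_perp  (mm^2)
    a2: np.ndarray          # (K,) c_perp          (mm^2)
    tau: float = DEFAULT_TAU  # ms
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        axes = np.asarray(self.axes, dtype=float)
        a1 = np.asarray(self.a1, dtype=float)
        a2 = np.asarray(self.a2, dtype=float)
        if self.tau <= 0:
            raise ValidationError("tau must be positive")
        if np.any(a2 <= 0) or np.any(a1 < 0):
            raise ValidationError("atom covariances must be SPD (a2 > 0, a1 >= 0)")
        object.__setattr__(self, "axes", axes)
        object.__setattr__(self, "a1", a1)
        object.__setattr__(self, "a2", a2)

    @property
    def n_atoms(self) -> int:
        return len(self.a1)

    @property
    def covariances(self) -> np.ndarray:
        """(K, 3, 3) mixture covariances C_k = a1 u u^T + a2 I (mm^2)."""
        uu = self.axes[:, :, None] * self.axes[:, None, :]
        return self.a1[:, None, None] * uu + self.a2[:, None, None] * np.eye(3)

    @property
    def tensors(self) -> np.ndarray:
        """(K, 3, 3) diffusivity tensors D_k (mm^2/s)."""
        return self.covariances / (2e-3 * self.tau)

    def to_json(self) -> str:
        return json.dumps(
            {
                "axes": self.axes.tolist(),
                "a1": self.a1.tolist(),
                "a2": self.a2.tolist(),
                "tau": self.tau,
                "meta": self.meta,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "DiffusionDictionary":
        d = json.loads(text)
        return cls(
            axes=np.asarray(d["axes"]),
            a1=np.asarray(d["a1"]),
            a2=np.asarray(d["a2"]),
            tau=d["tau"],
            meta=d.get("meta", {}),
        )


def build_dictionary(
    n_orient: int = 46,
    lambda_par: float = 1.7e-3,
    lambda_perp: float = 3.0e-4,
    tau: float = DEFAULT_TAU,
    include_isotropic: bool = True,
    iso_diffusivity: float = 2.0e-3,
    orientations: np.ndarray | None = None,
) -> DiffusionDictionary:
    """Build the shared diffusion dictionary.

    Defaults are typical white-matter diffusivities: lambda_par = 1.7e-3,
    lambda_perp = 3e-4 mm^2/s, isotropic atom 2e-3 mm^2/s.  Orientations
    default to a hemisphere Fibonacci lattice; pass ``orientations``
    explicitly to pin specific axes.
    """
    if lambda_perp <= 0 or lambda_par < lambda_perp:
        raise ValidationError("need lambda_par >= lambda_perp > 0")
    if orientations is None:
        orientations = hemisphere_orientations(n_orient)
    else:
        orientations = np.atleast_2d(np.asarray(orientations, dtype=float))
        orientations = orientations / np.linalg.norm(orientations, axis=1, keepdims=True)
    scale = 2e-3 * tau  # ms * mm^2/s -> mm^2
    axes = [orientations]
    a1 = [np.full(len(orientations), scale * (lambda_par - lambda_perp))]
    a2 = [np.full(len(orientations), scale * lambda_perp)]
    if include_isotropic:
        if iso_diffusivity <= 0:
            raise ValidationError("iso_diffusivity must be positive")
        axes.append(np.array([[0.0, 0.0, 1.0]]))
        a1.append(np.array([0.0]))
        a2.append(np.array([scale * iso_diffusivity]))
    return DiffusionDictionary(
        axes=np.concatenate(axes),
        a1=np.concatenate(a1),
        a2=np.concatenate(a2),
        tau=tau,
        meta={
            "lambda_par": lambda_par,
            "lambda_perp": lambda_perp,
            "iso_diffusivity": iso_diffusivity if include_isotropic else None,
            "n_orient": len(orientations),
        },
    )


@dataclass
class GaussianMixture:
    """One voxel's zero-mean Gaussian mixture.

    ``covariances`` is None for a mixture living on the dictionary atoms;
    re-orientation materializes per-component covariances.
    """

    weights: np.ndarray
    covariances: np.ndarray | None = None

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < 0) or not np.all(np.isfinite(w)):
            raise ValidationError("mixture weights must be finite and >= 0")
        self.weights = w

    def resolved_covariances(self, dictionary: DiffusionDictionary) -> np.ndarray:
        if self.covariances is not None:
            return np.asarray(self.covariances, dtype=float)
        return dictionary.covariances


@dataclass
class GMField:
    """A 3D field of Gaussian mixtures over one shared dictionary."""

    weights_grid: np.ndarray  # (X, Y, Z, K)
    dictionary: DiffusionDictionary
    affine: np.ndarray
    mask: np.ndarray | None = None  # tissue support

    def __post_init__(self):
        self.weights_grid = np.asarray(self.weights_grid, dtype=float)
        if self.weights_grid.ndim != 4:
            raise ValidationError("weights_grid must be (X, Y, Z, K)")
        if self.weights_grid.shape[-1] != self.dictionary.n_atoms:
            raise ValidationError("weights channel count does not match dictionary")
        if np.any(self.weights_grid < 0):
            raise ValidationError("negative mixture weights")
        if self.mask is None:
            self.mask = self.weights_grid.sum(axis=-1) > 0
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape(self) -> tuple:
        return self.weights_grid.shape[:3]

    def voxel(self, idx) -> GaussianMixture:
        return GaussianMixture(weights=self.weights_grid[tuple(idx)])

    def save(self, nifti_path, sidecar_path=None) -> None:
        nib.save(nib.Nifti1Image(self.weights_grid.astype(np.float32), self.affine),
                 str(nifti_path))
        if sidecar_path is None:
            p = str(nifti_path)
            for suf in (".nii.gz", ".nii"):
                if p.endswith(suf):
                    p = p[: -len(suf)]
                    break
            sidecar_path = p + ".json"
        Path(sidecar_path).write_text(self.dictionary.to_json())

    @classmethod
    def load(cls, nifti_path, sidecar_path=None) -> "GMField":
        img = nib.load(str(nifti_path))
        if sidecar_path is None:
            p = str(nifti_path)
            for suf in (".nii.gz", ".nii"):
                if p.endswith(suf):
                    p = p[: -len(suf)]
                    break
            sidecar_path = p + ".json"
        dictionary = DiffusionDictionary.from_json(Path(sidecar_path).read_text())
        return cls(
            weights_grid=np.asarray(img.get_fdata(), dtype=float),
            dictionary=dictionary,
            affine=img.affine,
        )


# ---------------------------------------------------------------------------
# forward model and estimation


def design_matrix(dictionary: DiffusionDictionary, gradients: GradientTable) -> np.ndarray:
    """A[i, k] = exp(-b_i g_i^T D_k g_i) for every measurement i and atom k."""
    g = gradients.bvecs
    b = gradients.bvals
    D = dictionary.tensors
    quad = np.einsum("ip,kpq,iq->ik", g, D, g)
    return np.exp(-b[:, None] * quad)


def predict_attenuation(
    dictionary: DiffusionDictionary, weights, gradients: GradientTable
) -> np.ndarray:
    """Forward model E(q) = sum_k w~_k exp(-b g^T D_k g), w~ normalized to 1."""
    w = np.asarray(weights, dtype=float)
    total = w.sum()
    if total <= 0:
        raise ValidationError("all-zero mixture weights: attenuation undefined")
    return design_matrix(dictionary, gradients) @ (w / total)


def estimate_gmf(
    dwi: DWIVolume,
    dictionary: DiffusionDictionary,
    mask: np.ndarray | None = None,
    ridge: float = 1e-3,
) -> GMField:
    """Fit per-voxel nonnegative mixture weights to attenuations.

    Solves min_{w >= 0} ||A w - E||^2 + ridge ||w||^2 voxel-wise (NNLS on
    the ridge-augmented design) and rescales weights to sum 1 so P(r) is a
    probability density.  Voxels where the fit fails or returns all zeros
    fall back to the most isotropic atom; the count is reported on the
    returned field's ``n_fallback`` attribute.
    """
    E = attenuation(dwi)
    if mask is None:
        b0 = dwi.gradients.b0_mask
        s0 = dwi.data[..., b0].mean(axis=-1)
        # tissue support: exclude air/background with negligible signal
        mask = s0 > 0.2 * np.percentile(s0, 99)
    A = design_matrix(dictionary, dwi.gradients)
    K = dictionary.n_atoms
    if ridge > 0:
        A_fit = np.vstack([A, np.sqrt(ridge) * np.eye(K)])
    else:
        A_fit = A
    pad = np.zeros(K)
    shape = dwi.shape
    weights = np.zeros(shape + (K,), dtype=float)
    # fallback: most isotropic atom (smallest anisotropy a1/a2)
    iso_idx = int(np.argmin(dictionary.a1 / dictionary.a2))
    n_fallback = 0
    idx = np.argwhere(mask)
    for ix, iy, iz in idx:
        y = E[ix, iy, iz]
        rhs = np.concatenate([y, pad]) if ridge > 0 else y
        try:
            w, _ = nnls(A_fit, rhs)
        except RuntimeError:
            w = None
        if w is None or w.sum() <= 0:
            n_fallback += 1
            w = np.zeros(K)
            w[iso_idx] = 1.0
        weights[ix, iy, iz] = w / w.sum()
    field = GMField(weights_grid=weights, dictionary=dictionary,
                    affine=dwi.affine, mask=np.asarray(mask, bool))
    field.n_fallback = n_fallback
    return field


# ---------------------------------------------------------------------------
# density evaluation and L2 distance


def eap_value(gm: GaussianMixture, dictionary: DiffusionDictionary, r) -> np.ndarray:
    """Evaluate the mixture propagator density P(r) at displacement(s) r (mm)."""
    r = np.atleast_2d(np.asarray(r, dtype=float))
    C = gm.resolved_covariances(dictionary)
    w = gm.weights
    total = w.sum()
    if total <= 0:
        raise ValidationError("all-zero mixture weights")
    w = w / total
    dets = np.linalg.det(C)
    inv = np.linalg.inv(C)
    quad = np.einsum("np,kpq,nq->nk", r, inv, r)
    vals = (_NORM3 / np.sqrt(dets))[None, :] * np.exp(-0.5 * quad)
    out = vals @ w
    return out[0] if out.shape == (1,) else out


def gram_matrix(covs_a: np.ndarray, covs_b: np.ndarray) -> np.ndarray:
    """Cross-correlation matrix of zero-mean Gaussians.

    Entry (i, j) is the integral of N(.; 0, A_i) N(.; 0, B_j) over R^3,
    i.e. (2 pi)^{-3/2} det(A_i + B_j)^{-1/2}.
    """
    S = covs_a[:, None, :, :] + covs_b[None, :, :, :]
    dets = np.linalg.det(S)
    if np.any(dets <= 0):
        raise ValidationError("non-SPD covariance in mixture distance")
    return _NORM3 / np.sqrt(dets)


def gm_l2_distance_sq(
    gm1: GaussianMixture, gm2: GaussianMixture, dictionary: DiffusionDictionary
) -> float:
    """Squared L2 distance between two mixture densities (closed form)."""
    C1 = gm1.resolved_covariances(dictionary)
    C2 = gm2.resolved_covariances(dictionary)
    a = gm1.weights / gm1.weights.sum() if gm1.weights.sum() > 0 else gm1.weights
    b = gm2.weights / gm2.weights.sum() if gm2.weights.sum() > 0 else gm2.weights
    d2 = (
        a @ gram_matrix(C1, C1) @ a
        - 2.0 * (a @ gram_matrix(C1, C2) @ b)
        + b @ gram_matrix(C2, C2) @ b
    )
    return float(max(d2, 0.0))


def gm_l2_distance(
    gm1: GaussianMixture, gm2: GaussianMixture, dictionary: DiffusionDictionary
) -> float:
    return float(np.sqrt(gm_l2_distance_sq(gm1, gm2, dictionary)))


# ---------------------------------------------------------------------------
# PPD re-orientation


def _ppd_frame(F: np.ndarray, e1: np.ndarray, e2: np.ndarray) -> np.ndarray:
    """Rotated orthonormal frame under the PPD rule for one matrix F."""
    f1 = F @ e1
    n1 = np.linalg.norm(f1)
    if n1 == 0:
        raise ValidationError("singular Jacobian collapses principal direction")
    e1p = f1 / n1
    f2 = F @ e2
    f2 = f2 - (f2 @ e1p) * e1p
    n2 = np.linalg.norm(f2)
    if n2 == 0:
        raise ValidationError("singular Jacobian collapses secondary direction")
    e2p = f2 / n2
    e3p = np.cross(e1p, e2p)
    return np.column_stack([e1p, e2p, e3p])


def reorient_ppd(
    gm: GaussianMixture,
    dictionary: DiffusionDictionary,
    J: np.ndarray,
    use_inverse_transpose: bool = False,
) -> GaussianMixture:
    """Re-orient every mixture component by the local Jacobian J.

    Preservation of principal direction: each covariance C = V diag(s) V^T
    keeps its eigenvalues (shape) while its eigenframe is rotated — the
    principal axis follows F e1, the secondary axis is Gram-Schmidt
    corrected in the rotated frame, with F = J (or J^{-T} when
    ``use_inverse_transpose``).
    """
    J = np.asarray(J, dtype=float)
    det = np.linalg.det(J)
    if det <= 0:
        raise ValidationError(f"Jacobian determinant must be positive, got {det:.3g}")
    F = np.linalg.inv(J).T if use_inverse_transpose else J
    C = gm.resolved_covariances(dictionary)
    out = np.empty_like(C)
    for k in range(len(C)):
        evals, evecs = np.linalg.eigh(C[k])
        # descending: e1 = principal
        e1, e2 = evecs[:, 2], evecs[:, 1]
        Vp = _ppd_frame(F, e1, e2)
        out[k] = (Vp * evals[::-1][None, :]) @ Vp.T
    return GaussianMixture(weights=gm.weights.copy(), covariances=out)


def ppd_rotate_axes(axes: np.ndarray, J: np.ndarray) -> np.ndarray:
    """Vectorized PPD for axially symmetric atoms: only the principal axis moves.

    ``axes`` is (K, 3); ``J`` is (..., 3, 3).  Returns (..., K, 3) unit axes
    J u / ||J u||.  For a covariance a1 u u^T + a2 I the PPD image is
    a1 u' u'^T + a2 I, because the two minor eigenvalues are equal.
    """
    v = np.einsum("...pq,kq->...kp", J, axes)
    n = np.linalg.norm(v, axis=-1, keepdims=True)
    if np.any(n == 0):
        raise ValidationError("singular Jacobian in PPD")
    return v / n
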