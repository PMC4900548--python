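"""Reading, writing and normalizing diffusion-weighted MRI data.

Volumes and masks travel as NIfTI-1 files; gradient tables as FSL-style
whitespace-delimited ``bval``/``bvec`` text files (3xN layout for bvecs).
Raw signal is normalized to attenuations E(q) = S(q)/S0 before any
propagator estimation.

Conventions: voxel indices are 0-based, deformations are stored in voxel
units, and world (mm) coordinates exist only through the affine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "GradientTable",
    "DWIVolume",
    "ROIMask",
    "FormatError",
    "ValidationError",
    "read_dwi",
    "write_dwi",
    "read_mask",
    "write_mask",
    "attenuation",
]

#: attenuations are clamped to (EPS_ATTENUATION, 1]
EPS_ATTENUATION = 1e-6


class FormatError(ValueError):
    """A file's layout does not match its declared format."""


class ValidationError(ValueError):
    """Inputs are well-formed but mutually inconsistent or degenerate."""


@dataclass(frozen=True)
class GradientTable:
    """Per-volume b-values (s/mm^2) and unit gradient directions.

    ``big_delta``/``small_delta`` are the gradient separation and duration
    (ms); the effective diffusion time tau = DELTA - delta/3 follows from
    them.
    """

    bvals: np.ndarray
    bvecs: np.ndarray  # (N, 3)
    big_delta: float = 42.4
    small_delta: float = 10.0

    def __post_init__(self):
        bvals = np.asarray(self.bvals, dtype=float).ravel()
        bvecs = np.asarray(self.bvecs, dtype=float)
        if bvecs.ndim != 2 or bvecs.shape[1] != 3:
            raise FormatError(f"bvecs must be (N, 3), got {bvecs.shape}")
        if len(bvals) != len(bvecs):
            raise FormatError(
                f"{len(bvals)} b-values but {len(bvecs)} gradient directions"
            )
        if not np.any(bvals == 0):
            raise ValidationError("gradient table contains no b=0 volume")
        nz = bvals > 0
        norms = np.linalg.norm(bvecs[nz], axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-3):
            raise ValidationError(
                "non-unit gradient direction(s) at nonzero b "
                f"(worst norm {norms[np.argmax(np.abs(norms - 1))]:.6f})"
            )
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)

    def __len__(self) -> int:
        return len(self.bvals)

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals == 0

    @property
    def tau(self) -> float:
        """Effective diffusion time DELTA - delta/3 (ms)."""
        return self.big_delta - self.small_delta / 3.0


@dataclass
class DWIVolume:
    """4D diffusion-weighted signal with its affine and gradient table."""

    data: np.ndarray  # (X, Y, Z, N), signal >= 0
    affine: np.ndarray  # 4x4
    gradients: GradientTable

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 4:
            raise FormatError(f"DWI data must be 4D, got {self.data.ndim}D")
        if self.affine.shape != (4, 4):
            raise FormatError("affine must be 4x4")
        if self.data.shape[3] != len(self.gradients):
            raise FormatError(
                f"{self.data.shape[3]} volumes but "
                f"{len(self.gradients)} gradient entries"
            )
        if np.any(self.data < 0):
            raise ValidationError("negative signal values")

    @property
    def shape(self) -> tuple:
        return self.data.shape[:3]


@dataclass
class ROIMask:
    """Boolean region-of-interest on a reference grid."""

    mask: np.ndarray
    affine: np.ndarray

    def __post_init__(self):
        self.mask = np.asarray(self.mask).astype(bool)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.mask.ndim != 3:
            raise FormatError("mask must be 3D")
        if self.n_voxels == 0:
            raise ValidationError("empty ROI mask")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def _read_bvals_bvecs(bval_path, bvec_path):
    bvals = np.loadtxt(bval_path, dtype=float).ravel()
    bvecs = np.loadtxt(bvec_path, dtype=float)
    if bvecs.ndim != 2:
        raise FormatError(f"bvec file {bvec_path} is not a 2D table")
    if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
        bvecs = bvecs.T  # FSL 3xN layout
    elif bvecs.shape[1] != 3:
        raise FormatError(f"bvec table has shape {bvecs.shape}, expected 3xN")
    return bvals, bvecs


def read_dwi(nifti_path, bval_path, bvec_path,
             big_delta: float = 42.4, small_delta: float = 10.0) -> DWIVolume:
    """Load a 4D NIfTI plus FSL bval/bvec files into a validated DWIVolume."""
    img = nib.load(str(nifti_path))
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim != 4:
        raise FormatError(f"{nifti_path}: expected 4D volume, got {data.ndim}D")
    bvals, bvecs = _read_bvals_bvecs(bval_path, bvec_path)
    if data.shape[3] != len(bvals):
        raise FormatError(
            f"{data.shape[3]} volumes in {nifti_path} but {len(bvals)} b-values"
        )
    gt = GradientTable(bvals, bvecs, big_delta=big_delta, small_delta=small_delta)
    return DWIVolume(data=data, affine=img.affine, gradients=gt)


def write_dwi(dwi: DWIVolume, nifti_path, bval_path=None, bvec_path=None) -> None:
    """Write a DWIVolume back to NIfTI (+ optional bval/bvec text files)."""
    img = nib.Nifti1Image(dwi.data.astype(np.float32), dwi.affine)
    nib.save(img, str(nifti_path))
    if bval_path is not None:
        np.savetxt(str(bval_path), dwi.gradients.bvals[None, :], fmt="%.6g")
    if bvec_path is not None:
        np.savetxt(str(bvec_path), dwi.gradients.bvecs.T, fmt="%.8f")


def read_mask(nifti_path, reference) -> ROIMask:
    """Load a binary NIfTI mask and check it against a reference grid.

    ``reference`` is a DWIVolume or anything with ``shape`` / ``affine``.
    """
    img = nib.load(str(nifti_path))
    mask = np.asarray(img.get_fdata()) > 0.5
    ref_shape = tuple(reference.shape[:3])
    if mask.shape != ref_shape:
        raise ValidationError(
            f"mask grid {mask.shape} does not match reference {ref_shape}"
        )
    return ROIMask(mask=mask, affine=img.affine)


def write_mask(roi: ROIMask, nifti_path) -> None:
    img = nib.Nifti1Image(roi.mask.astype(np.uint8), roi.affine)
    nib.save(img, str(nifti_path))


def attenuation(dwi: DWIVolume) -> np.ndarray:
    """Normalize raw signal to attenuations E(q) = S(q) / mean(S0).

    Multiple b=0 volumes are averaged before division.  E is clamped to
    (EPS_ATTENUATION, 1]: noisy S > S0 is physically impossible attenuation.
    Voxels with S0 <= 0 get E = EPS_ATTENUATION everywhere (and should be
    excluded by the tissue mask).
    """
    b0 = dwi.gradients.b0_mask
    s0 = dwi.data[..., b0].mean(axis=-1)
    bad = s0 <= 0
    safe_s0 = np.where(bad, 1.0, s0)
    E = dwi.data / safe_s0[..., None]
    E[bad] = EPS_ATTENUATION
    return np.clip(E, EPS_ATTENUATION, 1.0)
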