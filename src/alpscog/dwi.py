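"""Diffusion-weighted image container and NIfTI / FSL bval-bvec IO.

The package works in *subject axes*: x = left-right, y = anterior-posterior,
z = superior-inferior. Every volume container carries an ``axes`` tag
asserting this convention; nothing in the package reorients data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import nibabel as nib
import numpy as np

SUBJECT_AXES = "x=LR,y=AP,z=SI"


def default_directions() -> np.ndarray:
    """The packaged 64-direction electrostatic-repulsion gradient table.

    Returns a (64, 3) array of unit vectors, antipodally well spread
    (minimum pair angle about 17 degrees, counting antipodes).
    """
    with resources.files("alpscog.data").joinpath("directions64.txt").open() as fh:
        dirs = np.loadtxt(fh)
    return dirs / np.linalg.norm(dirs, axis=1, keepdims=True)


@dataclass
class DWIVolume:
    """A 4D diffusion acquisition in subject axes.

    Parameters
    ----------
    signal : (nx, ny, nz, nvol) array, arbitrary units, non-negative.
    voxel_size : (3,) voxel edge lengths in mm.
    bvals : (nvol,) b-values in s/mm^2.
    bvecs : (nvol, 3) unit gradient directions (rows for b=0 may be zero).
    """

    signal: np.ndarray
    voxel_size: np.ndarray
    bvals: np.ndarray
    bvecs: np.ndarray
    axes: str = SUBJECT_AXES

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.voxel_size = np.asarray(self.voxel_size, dtype=float).reshape(3)
        self.bvals = np.asarray(self.bvals, dtype=float).ravel()
        self.bvecs = np.asarray(self.bvecs, dtype=float).reshape(-1, 3)
        if self.signal.ndim != 4:
            raise ValueError("signal must be 4D (x, y, z, volume)")
        nvol = self.signal.shape[3]
        if len(self.bvals) != nvol or len(self.bvecs) != nvol:
            raise ValueError(
                f"got {nvol} volumes but {len(self.bvals)} b-values and "
                f"{len(self.bvecs)} directions"
            )
        if np.any(self.signal < 0):
            raise ValueError("signals must be non-negative")
        if not np.any(self.bvals == 0):
            raise ValueError("at least one b=0 volume is required")
        dw = self.bvals > 0
        norms = np.linalg.norm(self.bvecs[dw], axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("diffusion-weighted directions must be unit norm")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.signal.shape[:3]

    @property
    def n_volumes(self) -> int:
        return self.signal.shape[3]


def _affine(voxel_size: np.ndarray) -> np.ndarray:
    aff = np.diag([*voxel_size, 1.0])
    return aff


def save_dwi(dwi: DWIVolume, nifti_path: str | Path) -> None:
    """Write signal as NIfTI-1 plus FSL-style .bval/.bvec siblings."""
    nifti_path = Path(nifti_path)
    img = nib.Nifti1Image(dwi.signal.astype(np.float32), _affine(dwi.voxel_size))
    nib.save(img, nifti_path)
    stem = nifti_path.with_suffix("")
    if stem.suffix == ".nii":  # strip .nii.gz double suffix
        stem = stem.with_suffix("")
    np.savetxt(str(stem) + ".bval", dwi.bvals[None, :], fmt="%g")
    np.savetxt(str(stem) + ".bvec", dwi.bvecs.T, fmt="%.8f")


def load_dwi(
    nifti_path: str | Path,
    bval_path: str | Path | None = None,
    bvec_path: str | Path | None = None,
) -> DWIVolume:
    """Read a DWI NIfTI with FSL-style bval/bvec text files.

    When ``bval_path``/``bvec_path`` are omitted, siblings with the same
    stem and ``.bval``/``.bvec`` suffixes are used.
    """
    nifti_path = Path(nifti_path)
    stem = nifti_path.with_suffix("")
    if stem.suffix == ".nii":
        stem = stem.with_suffix("")
    bval_path = Path(bval_path) if bval_path else Path(str(stem) + ".bval")
    bvec_path = Path(bvec_path) if bvec_path else Path(str(stem) + ".bvec")
    img = nib.load(str(nifti_path))
    voxel_size = np.asarray(img.header.get_zooms()[:3], dtype=float)
    bvals = np.loadtxt(bval_path).ravel()
    bvecs = np.loadtxt(bvec_path)
    if bvecs.shape[0] == 3 and bvecs.shape != (3, 3):
        bvecs = bvecs.T
    return DWIVolume(np.asarray(img.dataobj, dtype=float), voxel_size, bvals, bvecs)


def save_volume(data: np.ndarray, voxel_size: np.ndarray, path: str | Path) -> None:
    """Write a 3D scalar or mask volume as NIfTI-1."""
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), _affine(np.asarray(voxel_size, float))), Path(path))


def load_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a 3D NIfTI volume; returns (data, voxel_size)."""
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=float), np.asarray(img.header.get_zooms()[:3], float)
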