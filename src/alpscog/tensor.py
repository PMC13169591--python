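"""Diffusion tensor estimation and scalar maps.

The tensor is fitted voxelwise by unweighted log-linear least squares on
ln(S) against the standard monoexponential model

    S(g, b) = S0 * exp(-b * g^T D g),

which linearises to ln S = ln S0 - b * (gx^2 Dxx + gy^2 Dyy + gz^2 Dzz
+ 2 gx gy Dxy + 2 gx gz Dxz + 2 gy gz Dyz). A weighted fit is available
behind a flag for completeness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dwi import SUBJECT_AXES, DWIVolume

#: index order of the six unique tensor components
TENSOR_COMPONENTS = ("Dxx", "Dxy", "Dxz", "Dyy", "Dyz", "Dzz")

#: eigenvalue clamp applied to non-positive-definite fits, mm^2/s
EIG_CLAMP = 1e-7


@dataclass
class TensorVolume:
    """Per-voxel symmetric diffusion tensors in subject axes.

    ``components`` holds (nx, ny, nz, 6) in :data:`TENSOR_COMPONENTS` order,
    mm^2/s. ``valid`` marks voxels with a usable fit; ``clamped`` marks
    voxels whose eigenvalues were clipped to :data:`EIG_CLAMP`.
    """

    components: np.ndarray
    valid: np.ndarray
    voxel_size: np.ndarray
    clamped: np.ndarray | None = None
    axes: str = SUBJECT_AXES

    def __post_init__(self) -> None:
        self.components = np.asarray(self.components, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        self.voxel_size = np.asarray(self.voxel_size, dtype=float).reshape(3)
        if self.components.ndim != 4 or self.components.shape[3] != 6:
            raise ValueError("components must be (nx, ny, nz, 6)")
        if self.valid.shape != self.components.shape[:3]:
            raise ValueError("valid mask shape mismatch")
        if self.clamped is None:
            self.clamped = np.zeros_like(self.valid)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.components.shape[:3]

    def as_matrices(self) -> np.ndarray:
        """Full (nx, ny, nz, 3, 3) symmetric tensor array."""
        c = self.components
        m = np.empty(c.shape[:3] + (3, 3), dtype=float)
        m[..., 0, 0] = c[..., 0]
        m[..., 0, 1] = m[..., 1, 0] = c[..., 1]
        m[..., 0, 2] = m[..., 2, 0] = c[..., 2]
        m[..., 1, 1] = c[..., 3]
        m[..., 1, 2] = m[..., 2, 1] = c[..., 4]
        m[..., 2, 2] = c[..., 5]
        return m

    @property
    def diagonal(self) -> np.ndarray:
        """(nx, ny, nz, 3) array of (Dxx, Dyy, Dzz) — the directional
        diffusivities the ALPS index is built from."""
        return self.components[..., [0, 3, 5]]


@dataclass
class ScalarMap:
    """A 3D scalar diffusion map (FA dimensionless; MD/AD/RD in mm^2/s)."""

    data: np.ndarray
    quantity: str
    voxel_size: np.ndarray
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.voxel_size = np.asarray(self.voxel_size, dtype=float).reshape(3)
        if self.valid is None:
            self.valid = np.isfinite(self.data)


def design_matrix(bvals: np.ndarray, bvecs: np.ndarray) -> np.ndarray:
    """Log-linear design: columns [1, -b gx^2, -b gy^2, -b gz^2,
    -2b gx gy, -2b gx gz, -2b gy gz] matching [ln S0, D components]."""
    b = np.asarray(bvals, float)[:, None]
    g = np.asarray(bvecs, float)
    cols = np.stack(
        [
            g[:, 0] ** 2,
            g[:, 1] ** 2,
            g[:, 2] ** 2,
            2 * g[:, 0] * g[:, 1],
            2 * g[:, 0] * g[:, 2],
            2 * g[:, 1] * g[:, 2],
        ],
        axis=1,
    )
    return np.hstack([np.ones_like(b), -b * cols])


def fit_tensor(
    dwi: DWIVolume,
    mask: np.ndarray | None = None,
    weighted: bool = False,
) -> TensorVolume:
    """Fit per-voxel diffusion tensors by (optionally weighted) log-linear LLS.

    Parameters
    ----------
    dwi : acquisition with at least 7 volumes spanning 6 independent
        direction outer products.
    mask : optional boolean volume; unmasked voxels are left invalid.
    weighted : if True, weight the log-linear fit by the predicted signal
        (one IRLS pass), reducing the low-SNR log-transform bias.

    Notes
    -----
    Voxels with a non-positive b=0 signal are flagged invalid rather than
    raising. Negative eigenvalues are clamped to ``EIG_CLAMP`` and flagged.
    """
    X = design_matrix(dwi.bvals, dwi.bvecs)
    if X.shape[0] < 7:
        raise ValueError("tensor fit needs at least 7 volumes (1 b0 + 6 DWI)")
    rank = np.linalg.matrix_rank(X[:, 1:])
    if rank < 6:
        raise ValueError(
            f"rank-deficient diffusion design: directions span rank {rank} < 6 "
            "independent outer products"
        )
    nx, ny, nz, nvol = dwi.signal.shape
    if mask is None:
        mask = np.ones((nx, ny, nz), dtype=bool)
    mask = np.asarray(mask, dtype=bool)

    sig = dwi.signal[mask]  # (nvox, nvol)
    b0 = dwi.bvals == 0
    ok = np.all(sig[:, b0] > 0, axis=1) & np.all(sig > 0, axis=1)

    comps = np.zeros((nx, ny, nz, 6), dtype=float)
    valid = np.zeros((nx, ny, nz), dtype=bool)
    clamped = np.zeros((nx, ny, nz), dtype=bool)
    if np.any(ok):
        y = np.log(sig[ok])  # (ngood, nvol)
        pinv = np.linalg.pinv(X)
        beta = y @ pinv.T  # (ngood, 7)
        if weighted:
            w = np.exp(X @ beta.T).T  # predicted signals as weights
            beta = _weighted_solve(X, y, w)
        # design order (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz) -> container order
        d6 = beta[:, 1:][:, [0, 3, 4, 1, 5, 2]]
        d6, was_clamped = _clamp_spd(d6)
        idx = np.zeros(mask.sum(), dtype=bool)
        idx[ok] = True
        full_idx = np.where(mask)
        good = tuple(ax[idx] for ax in full_idx)
        comps[good] = d6
        valid[good] = True
        clamped[good] = was_clamped
    return TensorVolume(comps, valid, dwi.voxel_size, clamped)


def _weighted_solve(X: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    beta = np.empty((y.shape[0], X.shape[1]))
    for i in range(y.shape[0]):
        Wx = X * w[i][:, None]
        beta[i] = np.linalg.lstsq(Wx, w[i] * y[i], rcond=None)[0]
    return beta


def _clamp_spd(d6: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Clamp eigenvalues of (n, 6) component rows to >= EIG_CLAMP."""
    m = np.empty((len(d6), 3, 3))
    m[:, 0, 0] = d6[:, 0]
    m[:, 0, 1] = m[:, 1, 0] = d6[:, 1]
    m[:, 0, 2] = m[:, 2, 0] = d6[:, 2]
    m[:, 1, 1] = d6[:, 3]
    m[:, 1, 2] = m[:, 2, 1] = d6[:, 4]
    m[:, 2, 2] = d6[:, 5]
    vals, vecs = np.linalg.eigh(m)
    bad = np.any(vals < 0, axis=1)
    if np.any(bad):
        vals_c = np.clip(vals[bad], EIG_CLAMP, None)
        fixed = np.einsum("nij,nj,nkj->nik", vecs[bad], vals_c, vecs[bad])
        out = d6.copy()
        out[bad, 0] = fixed[:, 0, 0]
        out[bad, 1] = fixed[:, 0, 1]
        out[bad, 2] = fixed[:, 0, 2]
        out[bad, 3] = fixed[:, 1, 1]
        out[bad, 4] = fixed[:, 1, 2]
        out[bad, 5] = fixed[:, 2, 2]
        return out, bad
    return d6, bad


def tensor_scalars(
    tensors: TensorVolume,
) -> tuple[ScalarMap, ScalarMap, ScalarMap, ScalarMap]:
    """Eigenvalue scalar maps (FA, MD, AD, RD) from a tensor volume.

    With eigenvalues l1 >= l2 >= l3: MD = mean(l), AD = l1, RD = (l2+l3)/2,
    FA = sqrt(3/2) * ||l - MD|| / ||l|| (0 for an all-zero tensor, flagged
    by the validity mask). MD/AD/RD are in mm^2/s.
    """
    m = tensors.as_matrices()
    vals = np.linalg.eigvalsh(m)[..., ::-1]  # descending l1 >= l2 >= l3
    md = vals.mean(axis=-1)
    ad = vals[..., 0]
    rd = vals[..., 1:].mean(axis=-1)
    norm = np.sqrt((vals**2).sum(axis=-1))
    dev = np.sqrt(((vals - md[..., None]) ** 2).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * dev / norm
    fa = np.where(norm > 0, fa, 0.0)
    fa = np.clip(fa, 0.0, 1.0)
    vs = tensors.voxel_size
    valid = tensors.valid
    return (
        ScalarMap(fa, "FA", vs, valid),
        ScalarMap(md, "MD", vs, valid),
        ScalarMap(ad, "AD", vs, valid),
        ScalarMap(rd, "RD", vs, valid),
    )
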