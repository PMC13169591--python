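"""Non-ALPS imaging covariates: normalized tissue volumes, white-matter
diffusion summaries, and lesion burden metrics."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .simulate import MM3_PER_ML
from .tensor import ScalarMap


@dataclass
class VolumetricsInput:
    """Precomputed segmentation volumetrics (ml) plus cortical thickness (mm)."""

    csfv: float
    gmv: float
    wmv: float
    tiv: float
    cth: float | None = None
    flags: list[str] = None

    def __post_init__(self) -> None:
        self.flags = self.flags or []
        for name in ("csfv", "gmv", "wmv", "tiv"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.csfv + self.gmv + self.wmv > 1.05 * self.tiv:
            self.flags.append("tissue volumes exceed TIV by more than 5%")


@dataclass
class LesionMetrics:
    wmlv_ml: float
    wmln: int


def normalize_volumes(v: VolumetricsInput) -> tuple[float, float, float]:
    """TIV-normalized tissue volumes on the percent scale:
    (nCSFV, nGMV, nWMV) = 100 * (CSFV, GMV, WMV) / TIV."""
    if v.tiv <= 0:
        raise ValueError("TIV must be > 0")
    return tuple(100.0 * x / v.tiv for x in (v.csfv, v.gmv, v.wmv))


def wm_mask_stats(
    fa: ScalarMap,
    md: ScalarMap,
    ad: ScalarMap,
    rd: ScalarMap,
    fa_threshold: float = 0.2,
) -> dict[str, float]:
    """Global white-matter diffusion summary: means of FA/MD/AD/RD over the
    FA > threshold mask, with MD/AD/RD reported in 1e-3 mm^2/s.

    This is a whole-mask summary of the anisotropic white-matter
    compartment; it deliberately replaces template-registered skeleton
    projection with a registration-free mask mean.
    """
    if not 0 < fa_threshold < 1:
        raise ValueError("fa_threshold must be in (0, 1)")
    maps = (fa, md, ad, rd)
    shapes = {m.data.shape for m in maps}
    if len(shapes) != 1:
        raise ValueError(f"maps are not co-registered: shapes {shapes}")
    mask = (fa.data > fa_threshold) & fa.valid
    if not np.any(mask):
        raise ValueError(f"no voxels with FA > {fa_threshold}")
    return {
        "fa": float(fa.data[mask].mean()),
        "md": float(md.data[mask].mean() * 1e3),
        "ad": float(ad.data[mask].mean() * 1e3),
        "rd": float(rd.data[mask].mean() * 1e3),
    }


def lesion_metrics(mask: np.ndarray, voxel_size) -> LesionMetrics:
    """Lesion burden from a binary mask: WMLV = voxel count x voxel volume
    (ml); WMLN = number of 26-connected components."""
    mask = np.asarray(mask)
    values = np.unique(mask)
    if not set(values.tolist()) <= {0, 1, False, True}:
        raise ValueError(f"mask is not binary (values {values})")
    mask = mask.astype(bool)
    vs = np.asarray(voxel_size, dtype=float)
    wmlv = float(mask.sum() * vs.prod() / MM3_PER_ML)
    wmln = int(ndimage.label(mask, structure=np.ones((3, 3, 3)))[1])
    return LesionMetrics(wmlv_ml=wmlv, wmln=wmln)
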