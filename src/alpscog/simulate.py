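"""Synthetic data with known ground truth.

Three generators cover the pipeline's inputs end to end:

* :func:`make_phantom` — a DWI phantom containing periventricular
  projection (superior-inferior, Dz-dominant) and association
  (anterior-posterior, Dy-dominant) fiber blocks with prescribed diagonal
  diffusivities, so the true ALPS index is analytic.
* :func:`make_lesion_volume` — spherical lesion masks with known count and
  volume.
* :func:`make_cohort` — a two-group cohort table in which cognitive raw
  scores depend linearly on age/sex/education plus planted ALPS and nWMV
  effects, and a planted impairment label follows a stated log-odds model.

All generators are deterministic under a fixed spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .alps import alps_index
from .dwi import DWIVolume, default_directions
from .tensor import TensorVolume

MM3_PER_ML = 1000.0


# --------------------------------------------------------------------------
# DWI phantom
# --------------------------------------------------------------------------

@dataclass
class BlockSpec:
    """A rectangular fiber block with diagonal diffusivities (mm^2/s)."""

    center: tuple[int, int, int]
    extent: tuple[int, int, int] = (5, 5, 5)
    diffusivities: tuple[float, float, float] = (1.2e-3, 0.8e-3, 1.6e-3)


@dataclass
class PhantomSpec:
    """Geometry, diffusivities, acquisition and noise of a DWI phantom.

    Left-hemisphere projection/association blocks are specified; the right
    hemisphere is their exact x-mirror, which makes left and right truth
    ALPS identical by construction. Defaults place the blocks in a
    mid-axial band flanking the midline, mimicking the periventricular
    level where the ALPS ROIs sit, and give truth ALPS = 1.5.
    """

    shape: tuple[int, int, int] = (64, 64, 32)
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)
    background_diffusivity: float = 0.8e-3
    proj_left: BlockSpec = field(
        default_factory=lambda: BlockSpec((24, 32, 16), (5, 5, 5), (1.2e-3, 0.8e-3, 1.6e-3))
    )
    assoc_left: BlockSpec = field(
        default_factory=lambda: BlockSpec((14, 32, 16), (5, 5, 5), (1.2e-3, 1.6e-3, 0.8e-3))
    )
    b_values: tuple[float, ...] = (0.0, 1000.0)
    n_directions: int = 64
    s0: float = 1000.0
    noise: str = "rician"  # none | gaussian | rician
    sigma: float | None = None  # default s0/30 (b0 SNR ~ 30)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise not in ("none", "gaussian", "rician"):
            raise ValueError(f"unknown noise model {self.noise!r}")
        for name, blk, dominant in (
            ("projection", self.proj_left, 2),
            ("association", self.assoc_left, 1),
        ):
            d = np.asarray(blk.diffusivities, float)
            if np.any(d <= 0):
                raise ValueError(
                    f"{name} block: requested tensor is not positive definite "
                    f"(diffusivities {tuple(d)})"
                )
            isotropic = d.min() == d.max()  # degenerate analytic case, ALPS = 1
            if not isotropic and (np.argmax(d) != dominant or np.sum(d == d.max()) > 1):
                axis = "Dz" if dominant == 2 else "Dy"
                raise ValueError(f"{name} block: {axis} must be strictly dominant")
        if self.background_diffusivity <= 0:
            raise ValueError("background diffusivity must be > 0")

    @property
    def noise_sigma(self) -> float:
        return self.s0 / 30.0 if self.sigma is None else self.sigma

    def mirror_x(self, center: tuple[int, int, int]) -> tuple[int, int, int]:
        return (self.shape[0] - 1 - center[0], center[1], center[2])


@dataclass
class PhantomTruth:
    """Ground-truth carrier for a phantom: the noise-free tensor field, the
    four ROI centers, their diffusivity triplets, the analytic ALPS values,
    and the (y, z) search band that covers the blocks."""

    tensors: TensorVolume
    roi_centers: dict[str, tuple[int, int, int]]
    roi_diffusivities: dict[str, tuple[float, float, float]]
    alps_left: float
    alps_right: float
    alps_bilateral: float
    search_band: tuple[np.ndarray, np.ndarray]


def _block_slices(blk: BlockSpec, shape: tuple[int, int, int]):
    sl = []
    for c, e, n in zip(blk.center, blk.extent, shape):
        lo, hi = c - e // 2, c + e // 2 + 1
        if lo < 0 or hi > n:
            raise ValueError(f"block at {blk.center} extends outside grid {shape}")
        sl.append(slice(lo, hi))
    return tuple(sl)


def make_phantom(spec: PhantomSpec) -> tuple[DWIVolume, PhantomTruth]:
    """Simulate a DWI acquisition of the block phantom.

    The signal follows S(g, b) = S0 exp(-b g^T D g) voxelwise with the
    spec's noise model applied; the returned truth carries the analytic
    ALPS computed from the block diffusivity triplets.
    """
    nx, ny, nz = spec.shape
    diag = np.full((nx, ny, nz, 3), spec.background_diffusivity, dtype=float)

    blocks = {
        "left_projection": spec.proj_left,
        "left_association": spec.assoc_left,
        "right_projection": replace(spec.proj_left, center=spec.mirror_x(spec.proj_left.center)),
        "right_association": replace(spec.assoc_left, center=spec.mirror_x(spec.assoc_left.center)),
    }
    centers, triplets = {}, {}
    for name, blk in blocks.items():
        diag[_block_slices(blk, spec.shape)] = blk.diffusivities
        centers[name] = blk.center
        triplets[name] = tuple(blk.diffusivities)

    comps = np.zeros((nx, ny, nz, 6), dtype=float)
    comps[..., [0, 3, 5]] = diag
    tensors = TensorVolume(comps, np.ones((nx, ny, nz), bool), np.asarray(spec.voxel_size))

    dirs = default_directions()[: spec.n_directions]
    if len(dirs) < spec.n_directions:
        raise ValueError("packaged direction table has only 64 directions")
    bvals = [b for b in spec.b_values if b == 0] + [
        b for b in spec.b_values if b > 0 for _ in range(spec.n_directions)
    ]
    bvecs = [np.zeros(3) for b in spec.b_values if b == 0] + [
        g for b in spec.b_values if b > 0 for g in dirs
    ]
    bvals = np.asarray(bvals, float)
    bvecs = np.asarray(bvecs, float)

    # quadratic form for diagonal tensors: g^T D g = sum_i g_i^2 D_ii
    g2 = bvecs**2  # (nvol, 3)
    atten = np.einsum("xyzc,vc->xyzv", diag, g2 * bvals[:, None])
    signal = spec.s0 * np.exp(-atten)

    rng = np.random.default_rng(spec.seed)
    sigma = spec.noise_sigma
    if spec.noise == "gaussian" and sigma > 0:
        signal = np.clip(signal + rng.normal(0, sigma, signal.shape), 0, None)
    elif spec.noise == "rician" and sigma > 0:
        re = signal + rng.normal(0, sigma, signal.shape)
        im = rng.normal(0, sigma, signal.shape)
        signal = np.hypot(re, im)

    dwi = DWIVolume(signal, np.asarray(spec.voxel_size), bvals, bvecs)

    alps_l = alps_index(triplets["left_projection"], triplets["left_association"])
    alps_r = alps_index(triplets["right_projection"], triplets["right_association"])
    ys = np.arange(spec.proj_left.center[1] - 2, spec.proj_left.center[1] + 3)
    zs = np.arange(spec.proj_left.center[2] - 1, spec.proj_left.center[2] + 2)
    truth = PhantomTruth(
        tensors=tensors,
        roi_centers=centers,
        roi_diffusivities=triplets,
        alps_left=alps_l,
        alps_right=alps_r,
        alps_bilateral=(alps_l + alps_r) / 2.0,
        search_band=(ys, zs),
    )
    return dwi, truth


# --------------------------------------------------------------------------
# Lesion masks
# --------------------------------------------------------------------------

def make_lesion_volume(
    shape: tuple[int, int, int],
    voxel_size: tuple[float, float, float],
    lesions: list[tuple[tuple[float, float, float], float]],
    seed: int = 0,
) -> tuple[np.ndarray, dict]:
    """Binary lesion mask from spheres given as (center voxel, radius mm).

    Overlapping spheres merge; the truth count reflects 26-connected
    components of the final mask, and the truth volume is voxel count times
    voxel volume in ml.
    """
    shape = tuple(int(n) for n in shape)
    vs = np.asarray(voxel_size, float)
    mask = np.zeros(shape, dtype=bool)
    for center, radius in lesions:
        c = np.asarray(center, float)
        if np.any(c * vs - radius < -vs / 2) or np.any(
            (c * vs + radius) > (np.asarray(shape) - 0.5) * vs
        ):
            raise ValueError(f"lesion sphere at {tuple(center)} (r={radius} mm) leaves the grid")
        grids = np.meshgrid(*(np.arange(n) for n in shape), indexing="ij")
        dist = np.sqrt(sum(((g - ci) * vi) ** 2 for g, ci, vi in zip(grids, c, vs)))
        mask |= dist <= radius
    n_components = int(ndimage.label(mask, structure=np.ones((3, 3, 3)))[1])
    volume_ml = float(mask.sum() * vs.prod() / MM3_PER_ML)
    return mask, {"count": n_components, "volume_ml": volume_ml}


# --------------------------------------------------------------------------
# Cohort tables
# --------------------------------------------------------------------------

@dataclass
class TestSpec:
    """Generating model of one cognitive test.

    Raw score = hc_mean + b_age (age-43) + b_sex sex + b_edu (edu-10)
    [+ for the patient group: rrms_shift + planted ALPS / nWMV terms]
    + N(0, resid_sd). Planted effects are *standardized* betas (per SD of
    predictor, in units of the patient-group outcome SD) and are converted
    to raw-scale coefficients analytically inside the generator.
    """

    hc_mean: float
    resid_sd: float
    b_age: float = 0.0
    b_sex: float = 0.0
    b_edu: float = 0.0
    rrms_shift: float = 0.0
    beta_alps: float = 0.0
    beta_nwmv: float = 0.0


#: canonical cognitive battery column names
COGNITIVE_TESTS = (
    "sdmt", "cvlt2", "bvmt_r", "pasat3", "pasat2",
    "stroop_w", "stroop_c", "stroop_d", "cowa", "mmse", "moca",
)


def _default_tests() -> dict[str, TestSpec]:
    # HC means and SDs follow the magnitudes of a typical RRMS/HC battery
    # (SDs on the raw-score scale); covariate slopes are conventional
    # normative directions (age costs speed, education helps).
    return {
        "sdmt": TestSpec(53.96, 7.0, b_age=-0.35, b_edu=0.9, rrms_shift=-10.98, beta_alps=0.40),
        "cvlt2": TestSpec(57.0, 8.0, b_age=-0.25, b_sex=-2.0, b_edu=0.7, rrms_shift=-15.0),
        "bvmt_r": TestSpec(26.2, 3.5, b_age=-0.15, b_edu=0.3, rrms_shift=-3.4),
        "pasat3": TestSpec(74.63, 14.0, b_age=-0.30, b_edu=1.0, rrms_shift=-9.67, beta_alps=0.30),
        "pasat2": TestSpec(63.99, 12.0, b_age=-0.30, b_edu=1.0, rrms_shift=-11.57, beta_alps=0.43),
        "stroop_w": TestSpec(17.13, 4.5, b_age=0.15, b_edu=-0.3, rrms_shift=8.0),
        "stroop_c": TestSpec(23.75, 6.0, b_age=0.15, b_edu=-0.3, rrms_shift=16.3),
        "stroop_d": TestSpec(14.0, 3.0, b_age=0.10, b_edu=-0.2, rrms_shift=2.0),
        "cowa": TestSpec(44.94, 4.0, b_age=-0.10, b_edu=0.8, rrms_shift=-5.45, beta_alps=0.30),
        "mmse": TestSpec(28.6, 1.3, b_age=-0.03, b_edu=0.1, rrms_shift=-1.8),
        "moca": TestSpec(26.44, 2.1, b_age=-0.05, b_edu=0.15, rrms_shift=-1.9),
    }


@dataclass
class EffectSpec:
    """Generating model of a two-group cohort table.

    Group sizes, covariate distributions and biomarker means/SDs default to
    an RRMS/HC study of 45 + 41 participants; planted impairment log-odds
    (per SD of ALPS and nWMV in the patient group) default to about -0.9
    and -0.8, the per-SD scale of reported cognitive-impairment models.
    Sex is coded 0 = female, 1 = male.
    """

    n_rrms: int = 45
    n_hc: int = 41
    age_mean: float = 43.0
    age_sd: float = 11.0
    p_male: float = 0.33
    edu_mean: float = 10.0
    edu_sd: float = 3.0
    alps_hc: tuple[float, float] = (1.53, 0.19)
    alps_rrms: tuple[float, float] = (1.42, 0.27)
    nwmv_hc: tuple[float, float] = (36.0, 1.7)
    nwmv_rrms: tuple[float, float] = (35.2, 3.2)
    tests: dict[str, TestSpec] = field(default_factory=_default_tests)
    impair_intercept: float = 0.0
    impair_b_alps: float = -0.93
    impair_b_nwmv: float = -0.81
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rrms < 2 or self.n_hc < 2:
            raise ValueError("group sizes must be >= 2")
        if any(t.resid_sd < 0 for t in self.tests.values()):
            raise ValueError("residual SDs must be >= 0")


def _standardized_to_raw(t: TestSpec, spec: EffectSpec) -> tuple[float, float]:
    """Raw-scale ALPS/nWMV coefficients giving the requested standardized
    betas, from the independent-covariate variance decomposition."""
    var_cov = (
        (t.b_age * spec.age_sd) ** 2
        + t.b_sex**2 * spec.p_male * (1 - spec.p_male)
        + (t.b_edu * spec.edu_sd) ** 2
    )
    a = var_cov + t.resid_sd**2
    denom = 1.0 - t.beta_alps**2 - t.beta_nwmv**2
    if denom <= 0:
        raise ValueError("planted standardized betas imply non-positive residual variance")
    var_y = a / denom
    sd_y = np.sqrt(var_y)
    return (
        t.beta_alps * sd_y / spec.alps_rrms[1],
        t.beta_nwmv * sd_y / spec.nwmv_rrms[1],
    )


def make_cohort(spec: EffectSpec) -> pd.DataFrame:
    """One row per participant with demographics, clinical fields, imaging
    features, raw cognitive scores and the planted impairment label.

    The ``impaired_true`` column (patients only) is Bernoulli with
    log-odds ``impair_intercept + b_alps z(ALPS) + b_nwmv z(nWMV)`` where z
    standardizes by the patient-group generating mean/SD.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_rrms + spec.n_hc
    group = np.array(["RRMS"] * spec.n_rrms + ["HC"] * spec.n_hc)
    is_rrms = group == "RRMS"

    age = np.clip(rng.normal(spec.age_mean, spec.age_sd, n), 18, 70)
    sex = (rng.random(n) < spec.p_male).astype(int)
    edu = np.clip(rng.normal(spec.edu_mean, spec.edu_sd, n), 6, 18)

    alps = np.where(
        is_rrms,
        rng.normal(*spec.alps_rrms, n),
        rng.normal(*spec.alps_hc, n),
    )
    alps = np.clip(alps, 0.3, None)
    nwmv = np.where(
        is_rrms,
        rng.normal(*spec.nwmv_rrms, n),
        rng.normal(*spec.nwmv_hc, n),
    )

    df = pd.DataFrame(
        {
            "id": [f"S{i:04d}" for i in range(n)],
            "group": group,
            "sex": sex,
            "age": age,
            "education": edu,
            "alps": alps,
            "nwmv": nwmv,
        }
    )
    # clinical fields, patients only
    df["disease_duration"] = np.where(is_rrms, np.round(rng.gamma(2.0, 3.2, n), 1), np.nan)
    df["edss"] = np.where(is_rrms, np.round(np.clip(rng.gamma(2.5, 0.67, n), 0, 7) * 2) / 2, np.nan)
    dmt = np.where(rng.random(n) < 37 / 45, "regular", "untreated")
    df["dmt"] = np.where(is_rrms, dmt, "")

    # context imaging columns (group-shifted normals at published magnitudes)
    def gshift(hc, rr, sd_hc, sd_rr):
        return np.where(is_rrms, rng.normal(rr, sd_rr, n), rng.normal(hc, sd_hc, n))

    df["ncsfv"] = gshift(18.9, 20.5, 2.5, 5.0)
    df["ngmv"] = gshift(47.77, 45.18, 3.8, 2.0)
    df["tiv"] = gshift(1443.0, 1385.0, 146.0, 160.0)
    df["cth"] = gshift(2.33, 2.30, 0.06, 0.09)
    df["fa"] = gshift(0.30, 0.26, 0.025, 0.04)
    df["md"] = gshift(0.50, 0.49, 0.012, 0.03)
    df["ad"] = gshift(0.76, 0.74, 0.015, 0.025)
    df["rd"] = gshift(0.36, 0.38, 0.015, 0.04)
    df["wmlv"] = np.where(is_rrms, rng.gamma(1.2, 8.0, n), 0.0)
    df["wmln"] = np.where(is_rrms, rng.poisson(18.6, n), 0)

    z_alps = (alps - spec.alps_rrms[0]) / spec.alps_rrms[1]
    z_nwmv = (nwmv - spec.nwmv_rrms[0]) / spec.nwmv_rrms[1]

    for name, t in spec.tests.items():
        b_alps_raw, b_nwmv_raw = _standardized_to_raw(t, spec)
        raw = (
            t.hc_mean
            + t.b_age * (age - spec.age_mean)
            + t.b_sex * sex
            + t.b_edu * (edu - spec.edu_mean)
        )
        raw = raw + is_rrms * (
            t.rrms_shift
            + b_alps_raw * (alps - spec.alps_rrms[0])
            + b_nwmv_raw * (nwmv - spec.nwmv_rrms[0])
        )
        if t.resid_sd > 0:
            raw = raw + rng.normal(0, t.resid_sd, n)
        df[name] = raw

    logodds = spec.impair_intercept + spec.impair_b_alps * z_alps + spec.impair_b_nwmv * z_nwmv
    p_imp = 1.0 / (1.0 + np.exp(-logodds))
    impaired = rng.random(n) < p_imp
    df["impaired_true"] = np.where(is_rrms, impaired, np.nan)
    return df
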