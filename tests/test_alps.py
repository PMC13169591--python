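"""ALPS index, directional profiles, and automated ROI localization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from alpscog import (
    ALPSConfig,
    BlockSpec,
    PhantomSpec,
    ROILocalizationError,
    alps_index,
    directional_profile,
    locate_alps_rois,
    make_phantom,
    roi_mean_diffusivities,
    subject_alps,
    tensor_scalars,
)
from alpscog.alps import ROISpec
from alpscog.tensor import TensorVolume


def _uniform_field(diag, shape=(10, 10, 6), voxel=(2, 2, 2)):
    comps = np.zeros(shape + (6,))
    comps[..., [0, 3, 5]] = diag
    return TensorVolume(comps, np.ones(shape, bool), np.asarray(voxel, float))


# -- alps_index -------------------------------------------------------------

@pytest.mark.parametrize(
    "proj, assoc, expected",
    [
        ((1.0, 1.0, 1.0), (1.0, 1.0, 1.0), 1.0),
        ((1.2e-3, 0.8e-3, 1.6e-3), (1.2e-3, 1.6e-3, 0.8e-3), 1.5),
        ((1.0, 0.6, 1.4), (1.1, 1.5, 0.5), 1.9091),
    ],
)
def test_alps_index_direct_arithmetic(proj, assoc, expected):
    assert alps_index(proj, assoc) == pytest.approx(expected, abs=1e-4)


def test_alps_index_rejects_nonpositive_denominator():
    with pytest.raises(ValueError, match="denominator"):
        alps_index((1.0, 0.0, 1.0), (1.0, 1.0, 0.5))


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    vals=st.lists(st.floats(0.1, 3.0), min_size=6, max_size=6),
    c=st.floats(0.01, 100.0),
)
def test_alps_scale_invariance_and_reciprocity(vals, c):
    proj, assoc = tuple(vals[:3]), tuple(vals[3:])
    base = alps_index(proj, assoc)
    scaled = alps_index(tuple(c * v for v in proj), tuple(c * v for v in assoc))
    assert scaled == pytest.approx(base, rel=1e-9)
    # swapping numerator/denominator roles: proj (Dy<->Dx), assoc (Dz<->Dx)
    swapped = alps_index((proj[1], proj[0], proj[2]), (assoc[2], assoc[1], assoc[0]))
    assert swapped == pytest.approx(1.0 / base, rel=1e-9)


# -- directional profiles ---------------------------------------------------

def test_profile_constant_on_uniform_field():
    diag = (1.1e-3, 0.9e-3, 0.7e-3)
    tv = _uniform_field(diag)
    prof = directional_profile(tv, y=5, z=3, radius_mm=5.0)
    np.testing.assert_allclose(prof.dxx, diag[0], rtol=1e-12)
    np.testing.assert_allclose(prof.dyy, diag[1], rtol=1e-12)
    np.testing.assert_allclose(prof.dzz, diag[2], rtol=1e-12)


def test_profile_degenerate_radius_reads_single_voxel_line():
    tv = _uniform_field((1e-3, 1e-3, 1e-3))
    tv.components[:, 5, 3, 5] = np.linspace(1, 10, 10) * 1e-4  # vary Dzz along x
    prof = directional_profile(tv, y=5, z=3, radius_mm=0.9)  # < half a voxel
    np.testing.assert_allclose(prof.dzz, tv.components[:, 5, 3, 5], rtol=1e-12)


def test_profile_peak_at_block_center(clean_phantom):
    truth = clean_phantom["truth"]
    cx, cy, cz = truth.roi_centers["left_projection"]
    prof = directional_profile(clean_phantom["tensors"], y=cy, z=cz, radius_mm=5.0)
    left_half = prof.dzz[:32]
    assert abs(int(np.nanargmax(left_half)) - cx) <= 1


def test_profile_missing_circle_is_nan():
    tv = _uniform_field((1e-3, 1e-3, 1e-3))
    tv.valid[:, :, :] = False
    prof = directional_profile(tv, y=5, z=3, radius_mm=1.0)
    assert np.isnan(prof.dzz).all()


# -- ROI extraction ---------------------------------------------------------

def _roi(center_vox, radius, voxel=(2.0, 2.0, 2.0)):
    c_mm = tuple(np.asarray(center_vox) * np.asarray(voxel))
    return ROISpec("left", "projection", tuple(center_vox), c_mm, radius)


def test_roi_mean_on_uniform_field_is_exact():
    diag = (1.3e-3, 0.9e-3, 0.5e-3)
    tv = _uniform_field(diag)
    got = roi_mean_diffusivities(tv, _roi((5, 5, 3), 3.0))
    assert got == pytest.approx(diag, rel=1e-12)


def test_sphere_membership_on_2mm_grid():
    """Enumerate voxel-center distances: radius 1.5 mm admits only the
    center voxel; radius 2.0 mm adds exactly the 6 face neighbors."""
    tv = _uniform_field((1e-3, 1e-3, 1e-3))
    tv.components[5, 5, 3, :] = 2e-3  # distinct center voxel
    only_center = roi_mean_diffusivities(tv, _roi((5, 5, 3), 1.5))
    assert only_center == pytest.approx((2e-3,) * 3, rel=1e-12)
    with_neighbors = roi_mean_diffusivities(tv, _roi((5, 5, 3), 2.0))
    assert with_neighbors == pytest.approx(((2e-3 + 6e-3) / 7,) * 3, rel=1e-12)


def test_roi_mean_two_voxel_average():
    tv = _uniform_field((0.0, 0.0, 0.0), shape=(2, 1, 1), voxel=(1, 1, 1))
    tv.components[0, 0, 0, 0] = 1.0  # Dxx
    tv.components[1, 0, 0, 3] = 1.0  # Dyy
    got = roi_mean_diffusivities(tv, ROISpec("left", "projection", (0, 0, 0), (0.5, 0, 0), 1.0))
    assert got[0] == pytest.approx(0.5) and got[1] == pytest.approx(0.5)


def test_empty_roi_errors():
    tv = _uniform_field((1e-3, 1e-3, 1e-3))
    tv.valid[:] = False
    with pytest.raises(ValueError, match="no valid voxel"):
        roi_mean_diffusivities(tv, _roi((5, 5, 3), 1.5))


# -- localization and subject-level ALPS ------------------------------------

def test_locate_rois_on_clean_phantom_matches_truth(clean_phantom):
    truth = clean_phantom["truth"]
    rois = locate_alps_rois(
        clean_phantom["tensors"], clean_phantom["fa"], truth.search_band
    )
    assert len(rois) == 4
    for roi in rois:
        truth_c = truth.roi_centers[f"{roi.hemisphere}_{roi.fiber}"]
        assert np.abs(np.subtract(roi.center_voxel, truth_c)).max() <= 1
        assert roi.qc["peak_prominence"] > 0


def test_uniform_isotropic_field_has_no_peak():
    tv = _uniform_field((0.8e-3, 0.8e-3, 0.8e-3), shape=(16, 16, 8))
    fa = tensor_scalars(tv)[0]
    with pytest.raises(ROILocalizationError, match="prominence"):
        locate_alps_rois(tv, fa, (np.arange(6, 10), np.arange(3, 5)))


def test_subject_alps_recovers_truth_noise_free(clean_phantom):
    res = subject_alps(
        clean_phantom["tensors"], clean_phantom["fa"], clean_phantom["truth"].search_band
    )
    assert res.bilateral_alps == pytest.approx(1.5, abs=1e-6)
    assert res.bilateral_alps == pytest.approx((res.left.alps + res.right.alps) / 2, abs=1e-12)


def test_subject_alps_scale_invariant(clean_phantom):
    t = clean_phantom["tensors"]
    scaled = TensorVolume(2.0 * t.components, t.valid, t.voxel_size)
    fa = tensor_scalars(scaled)[0]
    res = subject_alps(scaled, fa, clean_phantom["truth"].search_band)
    base = subject_alps(t, clean_phantom["fa"], clean_phantom["truth"].search_band)
    assert res.bilateral_alps == pytest.approx(base.bilateral_alps, rel=1e-9)


def test_forced_truth_rois_reproduce_analytic_alps(clean_phantom):
    """Oracle equivalence: ROIs pinned to the truth centers give the
    analytic ALPS exactly (noise-free)."""
    truth = clean_phantom["truth"]
    vs = clean_phantom["tensors"].voxel_size
    rois = [
        ROISpec(
            h, f, truth.roi_centers[f"{h}_{f}"],
            tuple(np.array(truth.roi_centers[f"{h}_{f}"]) * vs), 1.5,
        )
        for h in ("left", "right")
        for f in ("projection", "association")
    ]
    res = subject_alps(
        clean_phantom["tensors"], clean_phantom["fa"], truth.search_band, rois=rois
    )
    assert res.bilateral_alps == pytest.approx(truth.alps_bilateral, abs=1e-6)


def test_alps_result_json_roundtrip(clean_phantom, tmp_path):
    import json

    res = subject_alps(
        clean_phantom["tensors"], clean_phantom["fa"], clean_phantom["truth"].search_band
    )
    path = tmp_path / "alps.json"
    res.to_json(path)
    loaded = json.loads(path.read_text())
    assert loaded["bilateral_alps"] == pytest.approx(1.5, abs=1e-6)
    assert len(loaded["rois"]) == 4
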