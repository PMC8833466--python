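import numpy as np
import pytest
from hypothesis import given, strategies as st

import pancdwi as p
from pancdwi import (
    GeometryError,
    ROISpec,
    ROIStats,
    UndefinedMetricError,
    compute_metrics,
    propagate_roi,
    roi_stats,
)
from pancdwi.roi import correct_roi_placement, pool_stats


def test_identity_propagation_is_direct_rasterization():
    roi = ROISpec("t", "tumor", center_mm=(0.0, 0.0, 0.0), diameter_mm=5.0)
    vox = propagate_roi(roi, p.RFOV, p.RFOV)
    vox2 = propagate_roi(roi, p.RFOV, p.RFOV)
    np.testing.assert_array_equal(vox, vox2)
    assert len(vox) >= 1


def test_5mm_roi_on_25mm_grid_is_the_4_connected_disc(small_rfov):
    """Centred on a voxel centre, a 5 mm ROI covers the centre voxel and its
    4 in-plane neighbours (centres at 2.5 mm)."""
    xs = small_rfov.axis_coords(0)
    ys = small_rfov.axis_coords(1)
    center = (float(xs[20]), float(ys[20]), 0.0)
    roi = ROISpec("t", "tumor", center_mm=center, diameter_mm=5.0)
    vox = propagate_roi(roi, small_rfov, small_rfov)
    assert len(vox) == 5
    offs = sorted((int(i - 20), int(j - 20)) for i, j, _ in vox)
    assert offs == [(-1, 0), (0, -1), (0, 0), (0, 1), (1, 0)]


def test_roi_center_never_lost_on_coarse_grid():
    # a tiny ROI between voxel centres still returns the nearest voxel
    roi = ROISpec("t", "tumor", center_mm=(1.2, 1.2, 0.0), diameter_mm=0.5)
    vox = propagate_roi(roi, p.FFOV, p.FFOV)
    assert len(vox) == 1


def test_outside_fov_rejected():
    roi = ROISpec("t", "tumor", center_mm=(400.0, 0.0, 0.0))
    with pytest.raises(GeometryError):
        propagate_roi(roi, p.FFOV, p.RFOV)


@given(st.integers(0, 999))
def test_propagated_centroid_stays_near_roi_center(i):
    """fFOV -> rFOV transfer keeps the voxel-set centroid within half a
    target voxel of the ROI centre (brute-force geometric check)."""
    rng = np.random.default_rng(i)
    center = (float(rng.uniform(-40, 40)), float(rng.uniform(-40, 40)), float(rng.uniform(-8, 8)))
    roi = ROISpec("t", "tumor", center_mm=center, diameter_mm=5.0)
    vox = propagate_roi(roi, p.FFOV, p.RFOV)
    world = p.RFOV.voxel_to_world(vox)
    centroid = world[:, :2].mean(axis=0)
    dist = np.linalg.norm(centroid - np.asarray(center[:2]))
    assert dist <= max(p.RFOV.voxel_size_mm[:2]) / 2 + 1e-9


def test_roi_stats_constant_field():
    vol = np.full((4, 4, 2), 7.0)
    s = roi_stats(vol, np.array([[0, 0, 0], [1, 1, 1], [2, 3, 0]]))
    assert s.mean_si == 7.0 and s.sd_si == 0.0 and s.n_voxels == 3


def test_roi_stats_two_point_population_sd():
    vol = np.zeros((2, 1, 1))
    vol[0, 0, 0], vol[1, 0, 0] = 10.0, 20.0
    s = roi_stats(vol, np.array([[0, 0, 0], [1, 0, 0]]))
    assert s.mean_si == 15.0 and s.sd_si == 5.0


def test_roi_stats_errors():
    vol = np.zeros((2, 2, 2))
    with pytest.raises(ValueError):
        roi_stats(vol, np.empty((0, 3)))
    with pytest.raises(IndexError):
        roi_stats(vol, np.array([[5, 0, 0]]))


def test_metric_formula_arithmetic():
    tumor = ROIStats(80.0, 4.0, 9)
    par = ROIStats(50.0, 5.0, 9)
    rec = compute_metrics(tumor, par, par)
    assert rec.asnr == 10.0
    assert rec.acnr == 6.0
    assert rec.cr_proximal == rec.cr_distal == 1.6


def test_equal_signal_gives_zero_acnr_and_unit_cr():
    s = ROIStats(120.0, 6.0, 5)
    rec = compute_metrics(s, s, s)
    assert rec.acnr == 0.0 and rec.cr_proximal == 1.0


def test_zero_parenchyma_sd_is_explicit_error():
    with pytest.raises(UndefinedMetricError):
        compute_metrics(ROIStats(10, 1, 4), ROIStats(10, 0, 4), ROIStats(10, 1, 4))


def test_nonpositive_parenchyma_mean_is_explicit_error():
    with pytest.raises(UndefinedMetricError):
        compute_metrics(ROIStats(10, 1, 4), ROIStats(0.0, 1, 4), ROIStats(10, 1, 4))


def test_pooled_reference_matches_concatenated_sample():
    rng = np.random.default_rng(0)
    a, b = rng.normal(50, 5, 7), rng.normal(60, 8, 12)
    sa = ROIStats(a.mean(), a.std(), len(a))
    sb = ROIStats(b.mean(), b.std(), len(b))
    pooled = pool_stats(sa, sb)
    both = np.concatenate([a, b])
    np.testing.assert_allclose(pooled.mean_si, both.mean())
    np.testing.assert_allclose(pooled.sd_si, both.std())
    rec = compute_metrics(ROIStats(80, 1, 4), sa, sb, reference="pooled")
    np.testing.assert_allclose(rec.asnr, both.mean() / both.std())


@given(st.floats(min_value=1e-3, max_value=1e3))
def test_metrics_scale_invariant(c):
    """Multiplying the whole volume by c > 0 leaves aSNR, aCNR and CR fixed."""
    tumor = ROIStats(80.0 * c, 4.0 * c, 9)
    par = ROIStats(50.0 * c, 5.0 * c, 9)
    rec = compute_metrics(tumor, par, par)
    np.testing.assert_allclose(rec.asnr, 10.0, rtol=1e-9)
    np.testing.assert_allclose(rec.acnr, 6.0, rtol=1e-9)
    np.testing.assert_allclose(rec.cr_proximal, 1.6, rtol=1e-9)


def test_manual_correction_recenters_to_pure_tissue(noiseless_phantom):
    """An ROI dropped on the lesion boundary moves to a pure-parenchyma spot."""
    geom = noiseless_phantom.geometry
    edge = noiseless_phantom.lesion_center_mm + np.array([noiseless_phantom.lesion_diameter_mm / 2, 0, 0])
    roi = ROISpec("pp", "parenchyma_distal", center_mm=tuple(edge), diameter_mm=5.0)
    fixed = correct_roi_placement(roi, noiseless_phantom.label_map, geom,
                                  [p.LABELS["parenchyma_distal"]])
    vox = propagate_roi(fixed, geom, geom)
    labs = noiseless_phantom.label_map[vox[:, 0], vox[:, 1], vox[:, 2]]
    assert set(labs) == {p.LABELS["parenchyma_distal"]}


def test_closed_form_cr_through_full_pipeline(noiseless_phantom, noiseless_stack):
    """Noiseless defaults: CR(b) = exp((ADC_p - ADC_l) b) exactly, so
    CR(1000)/CR(600) = exp(0.6e-3 * 400)."""
    from pancdwi.cohort import place_study_rois
    fit = p.fit_monoexponential(noiseless_stack)
    rois = place_study_rois(noiseless_phantom)
    geom = noiseless_phantom.geometry

    def cr(vol):
        s = {k: roi_stats(vol, propagate_roi(r, geom, geom)) for k, r in rois.items()}
        return s["tumor"].mean_si / s["parenchyma_proximal"].mean_si

    cr600 = cr(noiseless_stack.volume(600.0))
    cr1000 = cr(p.compute_dwi(fit, 1000.0).signal)
    np.testing.assert_allclose(cr600, np.exp(0.36), rtol=1e-9)
    np.testing.assert_allclose(cr1000, np.exp(0.6), rtol=1e-9)
    np.testing.assert_allclose(cr1000 / cr600, np.exp(0.24), rtol=1e-9)
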