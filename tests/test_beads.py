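"""Bead detection, registration, PSF extraction and drift tracking."""

import numpy as np
import pytest

from spimscreen import (
    AffineTransform3D,
    BeadDetections,
    OpticsParams,
    PSFModel,
    VolumeStack,
    detect_beads,
    estimate_registration,
    extract_psf,
    render_bead_calibration,
    track_drift,
    nominal_view_rotation,
)
from spimscreen._util import fwhm_1d


def _detections(points, view="A", t=0):
    pts = np.asarray(points, dtype=float)
    return BeadDetections(pts, np.ones(len(pts)), np.full(len(pts), 50.0), view, t)


# --------------------------------------------------------------------- detect


def test_blank_stack_yields_no_detections():
    rng = np.random.default_rng(0)
    stack = VolumeStack(rng.normal(100, 2, (32, 32, 32)), (0.5, 0.5, 0.5))
    assert len(detect_beads(stack)) == 0


def test_rendered_beads_are_recovered_subvoxel():
    op = OpticsParams(psf_sigma_lateral={"A": 0.3, "B": 0.3},
                      psf_sigma_axial={"A": 0.8, "B": 0.8})
    cal = render_bead_calibration(5, op, n_frames=1, seed=8, grid_shape=(64, 64, 64))
    det = detect_beads(cal["stacks"][0][0])
    assert len(det) == 5
    truth = cal["positions"][0]
    for p in det.centroids:
        assert np.linalg.norm(truth - p, axis=1).min() < 0.3 * op.voxel


def test_close_pair_suppressed_to_brighter():
    v = 0.5
    img = np.zeros((32, 32, 32))
    zz, yy, xx = np.meshgrid(*([np.arange(32)] * 3), indexing="ij")
    for (cz, cy, cx), amp in [((16, 16, 14), 2000.0), ((16, 16, 18), 900.0)]:
        img += amp * np.exp(-((zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2) / (2 * 1.2**2))
    stack = VolumeStack(img + 10, (v, v, v))
    det = detect_beads(stack, min_separation=4.0)  # beads 2 µm apart = 0.5*min_sep
    assert len(det) == 1
    assert det.centroids[0][0] == pytest.approx(14 * v, abs=2 * v)  # brighter one


# ------------------------------------------------------------------- register


def test_identity_registration_on_identical_sets():
    rng = np.random.default_rng(2)
    pts = rng.uniform(5, 25, (8, 3))
    t = estimate_registration(_detections(pts), _detections(pts, "B"),
                              init=AffineTransform3D.identity())
    np.testing.assert_allclose(t.matrix, np.eye(3), atol=1e-9)
    np.testing.assert_allclose(t.translation, 0, atol=1e-9)
    assert t.residual_rms < 1e-12


def test_known_rotation_translation_recovered_exactly():
    rng = np.random.default_rng(3)
    pts_a = rng.uniform(5, 27, (8, 3))
    true = nominal_view_rotation(np.array([16.0, 16.0, 16.0]))
    true.translation = true.translation + np.array([0.4, -0.2, 0.3])
    pts_b = true.inverse().apply(pts_a)
    t = estimate_registration(_detections(pts_a), _detections(pts_b, "B"))
    np.testing.assert_allclose(t.matrix, true.matrix, atol=1e-9)
    np.testing.assert_allclose(t.translation, true.translation, atol=1e-6)
    assert t.residual_rms < 1e-9


def test_noisy_registration_within_tolerance():
    """0.1 µm localization noise, 12 beads: residual ≤ 0.2 µm RMS and the
    translation component — measured at the bead-cloud centroid, where the
    affine's intercept is identified — recovered to ≤ 0.05 µm (Monte-Carlo
    over seeds)."""
    true = nominal_view_rotation(np.array([16.0, 16.0, 16.0]))
    true.translation = true.translation + np.array([0.3, 0.1, -0.2])
    resids, terrs = [], []
    for seed in range(8):
        rng = np.random.default_rng(seed)
        pts_a = rng.uniform(4, 28, (12, 3))
        pts_b = true.inverse().apply(pts_a)
        det_a = _detections(pts_a + rng.normal(0, 0.1 / np.sqrt(3), (12, 3)))
        det_b = _detections(pts_b + rng.normal(0, 0.1 / np.sqrt(3), (12, 3)), "B")
        t = estimate_registration(det_a, det_b)
        resids.append(t.residual_rms)
        c = pts_b.mean(axis=0)
        terrs.append(np.linalg.norm(t.apply(c) - true.apply(c)))
    assert np.mean(resids) <= 0.2
    assert np.mean(terrs) <= 0.05


def test_registration_residual_is_rms_of_mapped_beads():
    rng = np.random.default_rng(7)
    pts_a = rng.uniform(4, 28, (10, 3))
    pts_b = pts_a + rng.normal(0, 0.05, (10, 3))
    t = estimate_registration(_detections(pts_a), _detections(pts_b, "B"),
                              init=AffineTransform3D.identity())
    mapped = t.apply(pts_b)
    rms = np.sqrt(((mapped - pts_a) ** 2).sum(axis=1).mean())
    assert rms == pytest.approx(t.residual_rms, abs=1e-9)


def test_degenerate_registration_rejected():
    rng = np.random.default_rng(1)
    few = rng.uniform(0, 10, (3, 3))
    with pytest.raises(ValueError):
        estimate_registration(_detections(few), _detections(few, "B"))
    coplanar = rng.uniform(0, 10, (8, 3))
    coplanar[:, 2] = 5.0
    with pytest.raises(ValueError):
        estimate_registration(_detections(coplanar), _detections(coplanar, "B"),
                              init=AffineTransform3D.identity())


def test_calibration_transfers_to_sample_positions():
    """A transform estimated at the bead position aligns sample points
    rendered with the same true transform to within twice the bead residual."""
    op = OpticsParams()
    cal = render_bead_calibration(16, op, n_frames=1, seed=21, grid_shape=(64, 64, 64))
    det_a = detect_beads(cal["stacks"][0][0])
    det_b = detect_beads(cal["stacks"][0][1])
    est = estimate_registration(det_a, det_b)
    true = cal["transform"]
    rng = np.random.default_rng(0)
    sample_a = rng.uniform(8, 24, (50, 3))
    sample_b = true.inverse().apply(sample_a)
    err = np.linalg.norm(est.apply(sample_b) - sample_a, axis=1)
    assert err.mean() <= 2 * max(est.residual_rms, 1e-3)


# ------------------------------------------------------------------------ psf


def _gaussian_bead_stack(sigmas_vox=(2.5, 1.0, 1.0), center=(16.2, 15.7, 16.4),
                         shape=(33, 33, 33), amp=5000.0, voxel=0.5):
    zz, yy, xx = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    img = amp * np.exp(
        -((zz - center[0]) ** 2) / (2 * sigmas_vox[0] ** 2)
        - ((yy - center[1]) ** 2) / (2 * sigmas_vox[1] ** 2)
        - ((xx - center[2]) ** 2) / (2 * sigmas_vox[2] ** 2)
    )
    return VolumeStack(img + 20.0, (voxel, voxel, voxel))


def test_psf_extraction_recovers_gaussian_widths():
    stack = _gaussian_bead_stack()
    cx, cy, cz = 16.4 * 0.5, 15.7 * 0.5, 16.2 * 0.5
    det = _detections([[cx, cy, cz]])
    psf = extract_psf(stack, det, radius=4.0)
    assert psf.kernel.sum() == pytest.approx(1.0, abs=1e-6)
    assert np.abs(psf.centroid_offset_vox()).max() < 0.5
    k = psf.kernel
    mid = np.array(k.shape) // 2
    fz = fwhm_1d(k[:, mid[1], mid[2]])
    fx = fwhm_1d(k[mid[0], mid[1], :])
    assert fz == pytest.approx(2.355 * 2.5, rel=0.10)
    assert fx == pytest.approx(2.355 * 1.0, rel=0.10)


def test_psf_extraction_is_intensity_scale_invariant():
    stack = _gaussian_bead_stack(amp=5000.0)
    scaled = VolumeStack(stack.data * 4.2, stack.voxel_size)
    det = _detections([[16.4 * 0.5, 15.7 * 0.5, 16.2 * 0.5]])
    k1 = extract_psf(stack, det, radius=4.0).kernel
    k2 = extract_psf(scaled, det, radius=4.0).kernel
    np.testing.assert_allclose(k1, k2, atol=1e-3)


def test_psf_requires_isolated_bead():
    stack = _gaussian_bead_stack()
    det = _detections([[8.0, 8.0, 8.0], [9.0, 8.5, 8.0]])  # 1.1 µm apart
    with pytest.raises(ValueError):
        extract_psf(stack, det, radius=3.0)


# ---------------------------------------------------------------------- drift


def test_static_beads_give_zero_drift():
    pts = np.array([[5.0, 6.0, 7.0], [10.0, 12.0, 9.0], [20.0, 5.0, 15.0]])
    series = track_drift([_detections(pts, t=t) for t in range(6)])
    np.testing.assert_allclose(series.offsets, 0.0, atol=1e-12)


def test_linear_drift_recovered():
    pts = np.random.default_rng(5).uniform(5, 25, (5, 3))
    dets = [_detections(pts + [0.2 * t, 0.0, 0.0], t=t) for t in range(10)]
    series = track_drift(dets)
    np.testing.assert_allclose(series.offsets[9], [1.8, 0.0, 0.0], atol=0.05)


def test_outlier_bead_does_not_move_the_median():
    pts = np.random.default_rng(6).uniform(5, 25, (5, 3))
    moved = pts.copy()
    moved[0] += [3.0, 0.0, 0.0]  # one rogue bead drifts alone
    series = track_drift([_detections(pts), _detections(moved, t=1)], max_gate=5.0)
    np.testing.assert_allclose(series.offsets[1], [0.0, 0.0, 0.0], atol=1e-9)


def test_drift_requires_input():
    with pytest.raises(ValueError):
        track_drift([])


# ---------------------------------------------------------- transform algebra


def test_transform_inverse_roundtrip():
    t = nominal_view_rotation(np.array([10.0, 12.0, 8.0]))
    t.translation = t.translation + [0.5, -0.1, 0.2]
    comp = t.compose(t.inverse())
    np.testing.assert_allclose(comp.matrix, np.eye(3), atol=1e-9)
    np.testing.assert_allclose(comp.translation, 0, atol=1e-9)


def test_transform_json_roundtrip(tmp_path):
    t = nominal_view_rotation(np.array([10.0, 12.0, 8.0]))
    t.residual_rms = 0.123
    t.n_correspondences = 9
    t.write_json(tmp_path / "t.json")
    back = AffineTransform3D.read_json(tmp_path / "t.json")
    np.testing.assert_allclose(back.matrix, t.matrix)
    np.testing.assert_allclose(back.translation, t.translation)
    assert back.residual_rms == t.residual_rms


def test_psf_model_validation():
    with pytest.raises(ValueError):
        PSFModel(np.zeros((3, 3, 3)), 0.5)
    with pytest.raises(ValueError):
        PSFModel(-np.ones((3, 3, 3)), 0.5)
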