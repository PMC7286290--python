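"""Nuclei segmentation, geometry and Haralick texture features."""

import numpy as np
import pytest
from scipy import ndimage

from spimscreen import (
    FusedVolume,
    LabelVolume,
    compute_geometry,
    compute_haralick,
    segment_nuclei,
)
from spimscreen.haralick import (
    OFFSETS_3D,
    glcm_3d,
    haralick_features,
    haralick_from_glcm,
    quantize,
)

V = 0.5


def _sphere_volume(centers_vox, radius_vox=6.0, shape=(64, 64, 64), amp=200.0,
                   blur=0.8, bg=10.0, noise=0.0, seed=0):
    zz, yy, xx = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    img = np.zeros(shape)
    for cz, cy, cx in centers_vox:
        d = np.sqrt((zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2)
        img += amp * np.clip(radius_vox - d + 0.5, 0, 1)
    if blur:
        img = ndimage.gaussian_filter(img, blur)
    if noise:
        img += np.random.default_rng(seed).normal(0, noise, shape)
    return FusedVolume(img + bg, voxel_size=V)


# --------------------------------------------------------------- segmentation


def test_noise_only_volume_yields_no_labels():
    rng = np.random.default_rng(3)
    vol = FusedVolume(rng.normal(100, 3, (48, 48, 48)), voxel_size=V)
    labels = segment_nuclei(vol, min_size=30.0)
    assert labels.n_labels == 0


def test_constant_volume_rejected():
    with pytest.raises(ValueError, match="no foreground"):
        segment_nuclei(FusedVolume(np.full((16, 16, 16), 7.0), voxel_size=V))


def test_well_separated_nuclei_recovered_with_centroids():
    rng = np.random.default_rng(1)
    centers = []
    while len(centers) < 10:
        c = rng.uniform(10, 54, 3)
        if all(np.linalg.norm(c - np.array(o)) > 16 for o in centers):
            centers.append(tuple(c))
    vol = _sphere_volume(centers, radius_vox=5.0, noise=2.0)
    labels = segment_nuclei(vol)
    assert labels.n_labels == 10
    recs = compute_geometry(labels, vol)
    got = np.array([r.centroid for r in recs]) / V  # voxel units (x, y, z)
    truth = np.array(centers)[:, ::-1]  # zyx -> xyz
    for t in truth:
        assert np.linalg.norm(got - t, axis=1).min() < 1.0


def test_touching_pair_is_split_by_erosion():
    # two spheres overlapping by ~20% of the radius
    r = 7.0
    c1 = (32, 32, 25.5)
    c2 = (32, 32, 25.5 + 1.8 * r)
    vol = _sphere_volume([c1, c2], radius_vox=r, blur=0.6)
    # a 20%-of-radius overlap leaves a thick neck: allow a deeper erosion
    # search than the spheroid default (which must spare anaphase dumbbells)
    labels = segment_nuclei(vol, min_size=30.0, split_erosion_radius=3.0)
    assert labels.n_labels == 2


def test_label_partition_covers_volume():
    vol = _sphere_volume([(20, 20, 20), (40, 40, 40)], radius_vox=5.0)
    labels = segment_nuclei(vol)
    counts = np.bincount(labels.labels.ravel())
    assert counts.sum() == labels.labels.size


# ------------------------------------------------------------------- geometry


def test_cube_volume_arithmetic():
    lab = np.zeros((16, 16, 16), dtype=int)
    lab[4:9, 4:9, 4:9] = 1  # 5x5x5 voxels
    vol = FusedVolume(np.ones((16, 16, 16)), voxel_size=V)
    rec = compute_geometry(LabelVolume(lab, V), vol)[0]
    assert rec.volume_um3 == pytest.approx(125 * 0.125)  # 15.625 µm³
    np.testing.assert_allclose(rec.centroid, [6 * V, 6 * V, 6 * V])


def test_centroid_is_intensity_weighted():
    lab = np.zeros((10, 10, 10), dtype=int)
    lab[2:5, 2:5, 2:5] = 1
    data = np.ones((10, 10, 10))
    data[2, 2, 2] = 100.0  # drag the centroid toward one corner
    rec = compute_geometry(LabelVolume(lab, V), FusedVolume(data, voxel_size=V))[0]
    assert rec.centroid[0] < 3 * V


# ------------------------------------------------------------------- haralick


def test_constant_segment_has_trivial_texture():
    img = np.full((6, 6, 6), 42.0)
    mask = np.ones((6, 6, 6), bool)
    f = haralick_features(img, mask)
    asm, contrast, *_ = f
    entropy = f[8]
    assert asm == pytest.approx(1.0)
    assert contrast == pytest.approx(0.0)
    assert entropy == pytest.approx(0.0)


def test_stripe_pattern_matches_hand_computed_glcm():
    """Alternating 2-level stripes along X with a (0,0,1) offset: every
    co-occurring pair differs by one level, so contrast = 1 and ASM = 1/2."""
    img = np.zeros((4, 4, 8))
    img[:, :, 1::2] = 1.0
    mask = np.ones(img.shape, bool)
    q = quantize(img, 2)
    P = glcm_3d(q, mask, (0, 0, 1), 2)
    np.testing.assert_allclose(P, [[0.0, 0.5], [0.5, 0.0]])
    f = haralick_from_glcm(P)
    assert f[1] == pytest.approx(1.0)  # contrast
    assert f[0] == pytest.approx(0.5)  # angular second moment


def _brute_force_glcm(q, mask, offset, n_levels):
    P = np.zeros((n_levels, n_levels))
    dz, dy, dx = offset
    nz, ny, nx = q.shape
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                z2, y2, x2 = z + dz, y + dy, x + dx
                if 0 <= z2 < nz and 0 <= y2 < ny and 0 <= x2 < nx:
                    if mask[z, y, x] and mask[z2, y2, x2]:
                        P[q[z, y, x], q[z2, y2, x2]] += 1
                        P[q[z2, y2, x2], q[z, y, x]] += 1
    return P / P.sum() if P.sum() else P


@pytest.mark.parametrize("offset", [(0, 0, 1), (1, 0, 0), (1, 1, -1)])
def test_glcm_matches_brute_force_enumeration(offset):
    rng = np.random.default_rng(4)
    img = rng.uniform(0, 100, (7, 8, 6))
    mask = rng.uniform(0, 1, (7, 8, 6)) > 0.3
    q = np.zeros(img.shape, dtype=np.int32)
    q[mask] = quantize(img[mask], 8)
    np.testing.assert_allclose(glcm_3d(q, mask, offset, 8),
                               _brute_force_glcm(q, mask, offset, 8), atol=1e-12)


def test_haralick_statistics_match_independent_2d_implementation():
    """Cross-check ASM, contrast and correlation against scikit-image's
    graycomatrix/graycoprops on a 2D texture."""
    from skimage.feature import graycomatrix, graycoprops

    rng = np.random.default_rng(9)
    img2d = rng.integers(0, 8, (24, 24))
    P_sk = graycomatrix(img2d.astype(np.uint8), [1], [0], levels=8,
                        symmetric=True, normed=True)[:, :, 0, 0]
    q = img2d[None].astype(np.int32)
    P = glcm_3d(q, np.ones_like(q, bool), (0, 0, 1), 8)
    np.testing.assert_allclose(P, P_sk, atol=1e-12)
    f = haralick_from_glcm(P)
    assert f[0] == pytest.approx(graycoprops(P_sk[:, :, None, None], "ASM")[0, 0])
    assert f[1] == pytest.approx(graycoprops(P_sk[:, :, None, None], "contrast")[0, 0])
    assert f[2] == pytest.approx(graycoprops(P_sk[:, :, None, None], "correlation")[0, 0],
                                 abs=1e-9)


def test_features_invariant_to_affine_intensity_rescale():
    rng = np.random.default_rng(5)
    img = ndimage.gaussian_filter(rng.uniform(0, 1, (10, 10, 10)), 1.0)
    mask = np.ones(img.shape, bool)
    f1 = haralick_features(img, mask)
    f2 = haralick_features(3.7 * img + 11.0, mask)
    np.testing.assert_allclose(f1, f2, atol=1e-9)


def test_haralick_per_segment_and_small_segment_policy():
    vol = _sphere_volume([(20, 20, 20)], radius_vox=5.0, noise=1.0)
    labels = segment_nuclei(vol)
    feats = compute_haralick(labels, vol)
    assert set(feats) == {1}
    assert np.isfinite(feats[1]).all()
    # a 4-voxel fragment gets NaN features
    lab = np.zeros((8, 8, 8), dtype=int)
    lab[2, 2, 2:6] = 1
    small = compute_haralick(LabelVolume(lab, V), FusedVolume(np.ones((8, 8, 8)), V))
    assert np.isnan(small[1]).all()


def test_glcm_normalization_sums_to_one():
    rng = np.random.default_rng(6)
    q = rng.integers(0, 5, (6, 6, 6)).astype(np.int32)
    mask = np.ones((6, 6, 6), bool)
    for off in OFFSETS_3D:
        P = glcm_3d(q, mask, off, 5)
        assert P.sum() == pytest.approx(1.0)


def test_default_spheroid_recall_precision():
    """On a rendered frame of the default control spheroid, segmentation
    recovers ≥95% of nuclei (recall) with ≥95% precision, matching segments
    to ground truth by centroid distance below one nucleus radius."""
    from scipy.spatial import cKDTree

    from spimscreen import (OpticsParams, SceneParams, fuse_mean,
                            resample_to_reference, simulate_timelapse,
                            render_dual_view)

    params = SceneParams(n_initial_cells=40, n_frames=1, divisions=False, seed=6)
    scene = simulate_timelapse(params)
    op = OpticsParams()
    va, vb = render_dual_view(scene, op, 0, seed=9, grid_shape=(128, 128, 128))
    vb_reg = resample_to_reference(vb, scene.true_transform,
                                   grid_shape=(128, 128, 128))
    fused = fuse_mean(va, vb_reg)
    labels = segment_nuclei(fused)
    recs = compute_geometry(labels, fused)
    got = np.array([r.centroid for r in recs])
    truth = np.array([n.centroid for n in scene.frames[0]])
    radius = params.nucleus_radius_mean

    d_truth, _ = cKDTree(got).query(truth)
    recall = (d_truth < radius).mean()
    d_got, _ = cKDTree(truth).query(got)
    precision = (d_got < radius).mean()
    assert recall >= 0.95
    assert precision >= 0.95
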