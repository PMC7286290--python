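"""Spheroid clustering, tracking, speeds, transitions, growth, shape."""

import numpy as np
import pandas as pd
import pytest

from spimscreen import (
    GrowthRateParams,
    NucleusRecord,
    SceneParams,
    cluster_into_spheroids,
    detect_transitions,
    growth_rate,
    migration_speed,
    phase_fractions,
    radial_distances,
    shape_descriptors,
    simulate_timelapse,
    track_nuclei,
)


def _rec(nid, xyz, t=0, sph=None):
    return NucleusRecord(nucleus_id=nid, timepoint=t,
                         centroid=np.asarray(xyz, dtype=float), spheroid_id=sph)


# ----------------------------------------------------------------- clustering


def test_two_distant_groups_form_two_spheroids():
    pts = np.vstack([np.random.default_rng(0).normal(0, 2, (5, 3)),
                     np.random.default_rng(1).normal(75, 2, (5, 3))])
    ids = cluster_into_spheroids([pts], cutoff=25.0)[0]
    assert len(set(ids)) == 2
    assert len(set(ids[:5])) == 1 and len(set(ids[5:])) == 1


def test_single_nucleus_is_one_spheroid():
    ids = cluster_into_spheroids([np.array([[1.0, 2.0, 3.0]])], cutoff=25.0)[0]
    assert list(ids) == [0]


def _brute_single_linkage(pts, cutoff):
    n = len(pts)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if np.linalg.norm(pts[i] - pts[j]) <= cutoff:
                parent[find(i)] = find(j)
    return [find(i) for i in range(n)]


def test_chain_merges_under_single_linkage():
    cutoff = 20.0
    pts = np.array([[i * 0.9 * cutoff, 0.0, 0.0] for i in range(8)])
    ids = cluster_into_spheroids([pts], cutoff=cutoff)[0]
    brute = _brute_single_linkage(pts, cutoff)
    assert len(set(ids)) == len(set(brute)) == 1


def test_spheroid_ids_stable_across_frames():
    f0 = np.vstack([np.zeros((4, 3)), np.full((4, 3), 80.0)])
    f1 = f0 + 1.0  # both clusters drift slightly
    ids = cluster_into_spheroids([f0, f1], cutoff=25.0)
    np.testing.assert_array_equal(ids[0], ids[1])


# ------------------------------------------------------------------- tracking


def test_static_nuclei_one_track_each_zero_displacement():
    frames = [[_rec(i, [10 * i, 0, 0], t) for i in range(4)] for t in range(5)]
    tracks = track_nuclei(frames, max_gate=5.0)
    assert len(tracks) == 4
    for tr in tracks:
        assert len(tr.steps) == 5
        assert all(d == 0 for d in tr.displacements)


def test_constant_velocity_tracks_recover_speed():
    vel = np.array([2.0, 0.0, 0.0])  # 0.5 × gate per frame
    frames = [[_rec(i, np.array([0, 20 * i, 0]) + t * vel, t) for i in range(3)]
              for t in range(10)]
    tracks = track_nuclei(frames, max_gate=4.0)
    assert len(tracks) == 3
    for tr in tracks:
        assert len(tr.steps) == 10
        speed = np.mean(tr.displacements)
        assert speed == pytest.approx(2.0, rel=0.05)


def test_division_links_both_children_to_parent():
    frames = [
        [_rec(1, [50, 50, 50], 0)],
        [_rec(1, [50, 50, 50], 1)],
        [_rec(2, [46, 50, 50], 2), _rec(3, [54, 50, 50], 2)],
    ]
    tracks = track_nuclei(frames, max_gate=8.0)
    parents = [tr.parent_track_id for tr in tracks if tr.parent_track_id is not None]
    assert len(parents) >= 1  # at least the non-matched child records the parent
    root = [tr for tr in tracks if tr.parent_track_id is None][0]
    assert all(p == root.track_id for p in parents)


def test_generator_divisions_are_recovered_by_tracker():
    p = SceneParams(n_initial_cells=10, n_frames=120, cycle_length=300.0,
                    divisions=True, random_walk_sd=0.05, seed=8)
    scene = simulate_timelapse(p)
    frames = [[_rec(n.id, n.centroid, t, sph=n.spheroid_id) for n in fr]
              for t, fr in enumerate(scene.frames)]
    tracks = track_nuclei(frames, max_gate=8.0)
    with_parent = [tr for tr in tracks if tr.parent_track_id is not None]
    assert len(with_parent) >= 2
    # partition: every nucleus-frame belongs to at most one track
    seen = [s for tr in tracks for s in tr.steps]
    assert len(seen) == len(set(seen))


# ------------------------------------------------------ speeds and distances


def test_migration_speed_arithmetic_and_median_robustness():
    frames = [[_rec(0, [t * 1.0, 0, 0], t, sph=0)] for t in range(6)]
    tracks = track_nuclei(frames, max_gate=5.0)
    speeds = migration_speed(tracks, frame_interval=5.0)
    assert speeds[0] == pytest.approx(0.2)  # 1 µm / 5 min

    static = [[_rec(0, [0, 0, 0], t, sph=0)] for t in range(4)]
    assert migration_speed(track_nuclei(static, 5.0), 5.0)[0] == 0.0

    # outlier step: one huge jump among many unit steps leaves the median at 1
    xs = [0, 1, 2, 3, 4, 9, 10, 11, 12, 13, 14]
    frames = [[_rec(0, [x, 0, 0], t, sph=0)] for t, x in enumerate(xs)]
    tracks = track_nuclei(frames, max_gate=6.0)
    assert migration_speed(tracks, 1.0)[0] == pytest.approx(1.0)


def test_radial_distances_center_shell_translation():
    center = [_rec(0, [10, 10, 10], sph=0)]
    radial_distances([center])
    assert center[0].radial_distance_um == 0.0

    shell = [_rec(i, 10 + 5 * u, sph=0) for i, u in enumerate(
        [np.array(v) for v in [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                               (0, 0, 1), (0, 0, -1)]])]
    radial_distances([shell])
    for r in shell:
        assert r.radial_distance_um == pytest.approx(5.0)

    shifted = [_rec(r.nucleus_id, r.centroid + 100.0, sph=0) for r in shell]
    radial_distances([shifted])
    for a, b in zip(shell, shifted):
        assert a.radial_distance_um == pytest.approx(b.radial_distance_um)


# ------------------------------------------------------- fractions/transitions


def test_phase_fraction_arithmetic():
    phases = ["interphase"] * 94 + ["prophase"] + ["metaphase"] + ["anaphase"] * 4
    f = phase_fractions(phases)
    assert f == {"interphase": 0.94, "prophase": 0.01, "metaphase": 0.01,
                 "anaphase": 0.04}
    assert sum(f.values()) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        phase_fractions([])


def _track_with_phases(phases):
    frames = [[_rec(1, [0, 0, 0], t)] for t in range(len(phases))]
    tracks = track_nuclei(frames, max_gate=5.0)
    phase_by = {(t, 1): p for t, p in enumerate(phases)}
    return detect_transitions(tracks, phase_by)


def test_full_cycle_transitions_all_valid():
    events, summary = _track_with_phases(
        ["interphase", "prophase", "metaphase", "anaphase", "interphase"])
    assert summary["n_transitions"] == 4
    assert summary["n_improper"] == 0


def test_prophase_to_interphase_is_improper():
    events, summary = _track_with_phases(["prophase", "interphase"])
    assert summary["n_transitions"] == 1
    assert summary["n_improper"] == 1
    assert events.iloc[0]["from_phase"] == "prophase"


def test_flicker_yields_one_improper_event():
    events, summary = _track_with_phases(["prophase", "metaphase", "prophase"])
    assert summary["n_transitions"] == 2
    improper = events[~events["valid"]]
    assert len(improper) == 1
    assert (improper.iloc[0]["from_phase"], improper.iloc[0]["to_phase"]) == (
        "metaphase", "prophase")


# ---------------------------------------------------------------- growth rate


def test_growth_rate_constant_series_is_zero():
    rates = growth_rate(np.full(20, 7.0))
    np.testing.assert_allclose(rates, 0.0, atol=1e-9)


def test_growth_rate_reproduces_line_slope():
    y = 3.0 + 0.5 * np.arange(30)
    rates = growth_rate(y)
    np.testing.assert_allclose(rates, 0.5, atol=1e-6)


def test_growth_rate_tracks_noisy_exponential():
    rng = np.random.default_rng(3)
    t = np.arange(120, dtype=float)
    y = 20 * np.exp(t / 60.0)
    noisy = y + rng.normal(0, 1.5, len(t))
    rates = growth_rate(noisy, GrowthRateParams())
    true = np.diff(y)
    assert (rates > 0).mean() > 0.95
    assert np.corrcoef(rates, true)[0, 1] > 0.9


def test_growth_rate_needs_four_points():
    with pytest.raises(ValueError):
        growth_rate([1.0, 2.0, 3.0])


def test_doubling_time_recovered_from_simulated_expansion():
    """Lowess growth rates on a clonal expansion recover the cycle length
    (= doubling time when every cell divides) within 15%."""
    p = SceneParams(n_initial_cells=30, n_frames=250, cycle_length=300.0,
                    frame_interval=5.0, divisions=True, random_walk_sd=0.0, seed=2)
    scene = simulate_timelapse(p)
    counts = np.array([len(fr) for fr in scene.frames], dtype=float)
    rates = growth_rate(counts)
    rel = rates / counts[1:]  # per-frame relative growth
    doubling_frames = np.log(2) / np.median(rel)
    doubling_min = doubling_frames * p.frame_interval
    assert doubling_min == pytest.approx(300.0, rel=0.15)


# ---------------------------------------------------------------------- shape


def _ball_mask(r_vox, shape=None):
    shape = shape or (int(2 * r_vox + 7),) * 3
    zz, yy, xx = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    c = (np.array(shape) - 1) / 2
    return ((zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2) <= r_vox**2


def test_ball_is_spherical_convex_compact():
    d = shape_descriptors(_ball_mask(9.0), voxel_size=0.5)
    assert d["sphericity"] == pytest.approx(1.0, abs=0.08)
    assert d["convexity"] == pytest.approx(1.0, abs=0.05)
    assert d["compactness"] == pytest.approx(1.0, abs=0.25)


def test_two_disjoint_balls_are_not_convex():
    m = np.zeros((20, 20, 44), bool)
    m[:, :, :20] |= _ball_mask(6.0, (20, 20, 20))
    m[:, :, 24:] |= _ball_mask(6.0, (20, 20, 20))
    d = shape_descriptors(m, voxel_size=0.5)
    assert d["convexity"] < 0.8


def test_shape_descriptors_scale_invariant():
    small = shape_descriptors(_ball_mask(6.0), voxel_size=0.5)
    big = shape_descriptors(_ball_mask(12.0), voxel_size=0.5)
    rescaled = shape_descriptors(_ball_mask(6.0), voxel_size=2.0)
    for k in ("compactness", "convexity", "sphericity"):
        assert small[k] == pytest.approx(big[k], abs=0.07)
        assert small[k] == pytest.approx(rescaled[k], abs=1e-9)
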