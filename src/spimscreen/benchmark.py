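"""Default synthetic benchmarks and the end-to-end control-population run.

Two standard experiments are defined here so tests, scripts and users all
run the same thing:

* :func:`default_benchmark` — the 4-class nucleus-morphology benchmark:
  single nuclei of each phase rendered through the dual-view optics,
  fused, segmented, and turned into CNN slice patches and per-nucleus
  Haralick feature vectors.
* :func:`control_population_run` — the full pipeline on a simulated
  asynchronous control population (bead calibration → registration →
  render → resample/fuse → segment → slice CNN with summed-likelihood
  voting → phase fractions).

The control population is simulated in constant-population renewal mode
(``divisions=False``): with uniform random initial cycle ages the expected
phase occupancy is then exactly duration/cycle, which is the stationary
accounting the screen's control fractions correspond to.  (In a growing
population the age structure skews toward newborn interphase cells and the
mitotic fractions fall below duration/cycle; see docs/methods.md.)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .beads import detect_beads, estimate_registration
from .classify import (
    PHASE_CLASSES_4,
    classify_segment,
    extract_slices,
    predict_slices,
    train_cnn,
    train_rf,
)
from .fusion import fuse_mean, resample_to_reference
from .haralick import haralick_features
from .scene import (
    NucleusState,
    OpticsParams,
    SceneParams,
    render_bead_calibration,
    render_density,
    render_dual_view,
    simulate_timelapse,
)
from .segmentation import segment_nuclei
from .volume import FusedVolume

#: patches per nucleus: this many central planes per orientation
BENCHMARK_SLICES_PER_ORIENTATION = 3
BENCHMARK_PATCH_SIZE = 32


def render_fused_nucleus(nuc: NucleusState, optics: OpticsParams, seed: int,
                         grid_shape=(36, 36, 36), noise: bool = True) -> FusedVolume:
    """Render one nucleus as it appears after registered dual-view fusion.

    View A is blurred axially along Z; view B, once resampled into the A
    frame, carries its axial blur along X.  Averaging the two noisy views
    emulates the fused volume without the per-nucleus resampling cost.
    """
    rng = np.random.default_rng(seed)
    v = optics.voxel
    dens = render_density([nuc], grid_shape, v) * optics.photon_scale
    lat_a = optics.psf_sigma_lateral["A"] / v
    ax_a = optics.psf_sigma_axial["A"] / v
    lat_b = optics.psf_sigma_lateral["B"] / v
    ax_b = optics.psf_sigma_axial["B"] / v
    views = []
    for sig in ((ax_a, lat_a, lat_a), (lat_b, lat_b, ax_b)):
        img = ndimage.gaussian_filter(dens, sig, mode="constant") + optics.background
        if noise:
            img = rng.poisson(np.clip(img, 0, None)).astype(float)
            img = img + rng.normal(0, optics.read_noise_sd, img.shape)
        views.append(np.clip(img, 0, None))
    fused = 0.5 * (views[0] + views[1])
    return FusedVolume(fused, voxel_size=v)


def _random_nucleus(phase: str, rng, params: SceneParams, center) -> NucleusState:
    r = float(np.clip(rng.normal(params.nucleus_radius_mean, params.nucleus_radius_sd),
                      0.5 * params.nucleus_radius_mean, 1.5 * params.nucleus_radius_mean))
    ax = rng.normal(size=3)
    ax /= np.linalg.norm(ax)
    return NucleusState(
        id=0, parent_id=None, spheroid_id=0, centroid=np.asarray(center, dtype=float),
        radius=r, phase=phase, phase_frac=float(rng.uniform(0.05, 0.95)),
        axis=ax, texture_seed=int(rng.integers(0, 2**31 - 1)),
    )


@dataclass
class Benchmark:
    """The default 4-class morphology benchmark, ready for training."""

    patches: np.ndarray  # (n_slices_total, p, p)
    slice_labels: np.ndarray  # phase name per patch
    slice_groups: np.ndarray  # nucleus uid per patch (for leakage-free splits)
    features: np.ndarray  # (n_nuclei, 13) Haralick
    nucleus_labels: np.ndarray  # phase name per nucleus
    class_order: tuple = PHASE_CLASSES_4


def default_benchmark(n_per_class: int = 800, seed: int = 0,
                      optics: OpticsParams | None = None,
                      patch_size: int = BENCHMARK_PATCH_SIZE,
                      n_slices: int = BENCHMARK_SLICES_PER_ORIENTATION) -> Benchmark:
    """Render the default synthetic 4-class nucleus-morphology benchmark.

    ``n_per_class`` nuclei per phase are rendered individually through the
    fused dual-view optics, segmented with the standard recipe, and turned
    into per-orientation central slice patches plus 13 Haralick features.
    """
    optics = optics or OpticsParams()
    params = SceneParams(n_initial_cells=1, n_frames=1)
    rng = np.random.default_rng(seed)
    grid = (36, 36, 36)
    center = np.array(grid[::-1]) * optics.voxel / 2.0

    patches, slice_labels, groups = [], [], []
    feats, nuc_labels = [], []
    uid = 0
    for phase in PHASE_CLASSES_4:
        made = 0
        attempts = 0
        while made < n_per_class and attempts < n_per_class * 2:
            attempts += 1
            nuc = _random_nucleus(phase, rng, params, center)
            fused = render_fused_nucleus(nuc, optics, seed=int(rng.integers(2**31 - 1)),
                                         grid_shape=grid)
            try:
                labels = segment_nuclei(fused)
            except ValueError:
                continue
            if labels.n_labels == 0:
                continue
            counts = np.bincount(labels.labels.ravel())[1:]
            nid = int(counts.argmax()) + 1
            sl = extract_slices(fused, labels, nid, patch_size=patch_size,
                                n_slices=n_slices)
            mask = labels.labels == nid
            f = haralick_features(fused.data, mask)
            if not np.isfinite(f).all():
                continue
            patches.append(sl.patches)
            slice_labels += [phase] * len(sl)
            groups += [uid] * len(sl)
            feats.append(f)
            nuc_labels.append(phase)
            uid += 1
            made += 1
    return Benchmark(
        patches=np.concatenate(patches, axis=0),
        slice_labels=np.array(slice_labels),
        slice_groups=np.array(groups),
        features=np.array(feats),
        nucleus_labels=np.array(nuc_labels),
    )


def train_benchmark_classifiers(bench: Benchmark, seed: int = 0, epochs: int = 8):
    """Train the slice CNN and the Haralick random forest on a benchmark."""
    cnn = train_cnn(bench.patches, bench.slice_labels, seed=seed,
                    class_order=bench.class_order, groups=bench.slice_groups,
                    epochs=epochs)
    rf = train_rf(bench.features, bench.nucleus_labels, seed=seed,
                  class_order=bench.class_order)
    return cnn, rf


# --------------------------------------------------------------------------
# end-to-end control population
# --------------------------------------------------------------------------


def control_scene_params(n_cells: int = 64, n_frames: int = 150, seed: int = 0) -> SceneParams:
    """Study conditions of the asynchronous control population."""
    return SceneParams(
        n_initial_cells=n_cells,
        n_frames=n_frames,
        divisions=False,
        seed=seed,
    )


def control_population_run(
    cnn_bundle,
    n_cells: int = 64,
    n_frames: int = 150,
    seed: int = 0,
    optics: OpticsParams | None = None,
    grid_shape=(128, 128, 128),
    n_slices: int = BENCHMARK_SLICES_PER_ORIENTATION,
    patch_size: int = BENCHMARK_PATCH_SIZE,
):
    """Full pipeline on a simulated asynchronous control population.

    Simulates the ground truth, estimates the view registration from a
    rendered bead calibration stack, then for every frame renders both
    views, resamples view B through the *estimated* transform, fuses,
    segments and classifies every nucleus with summed-likelihood slice
    voting.  Returns a dict with classified and ground-truth phase
    fractions and bookkeeping counts.
    """
    optics = optics or OpticsParams()
    params = control_scene_params(n_cells, n_frames, seed)
    scene = simulate_timelapse(params)

    calib = render_bead_calibration(
        12, optics, n_frames=1, seed=seed + 101,
        grid_shape=grid_shape, true_transform=scene.true_transform,
    )
    a0, b0 = calib["stacks"][0]
    det_a = detect_beads(a0)
    det_b = detect_beads(b0)
    transform = estimate_registration(det_a, det_b)

    counts = {c: 0 for c in cnn_bundle.class_order}
    truth_counts = {c: 0 for c in cnn_bundle.class_order}
    n_segments = 0
    validity = None
    for t in range(scene.n_frames):
        va, vb = render_dual_view(scene, optics, t, seed=seed + 7919 * (t + 1),
                                  grid_shape=grid_shape)
        vb_reg = resample_to_reference(vb, transform, grid_shape=grid_shape,
                                       validity=validity)
        validity = vb_reg.validity
        fused = fuse_mean(va, vb_reg)
        labels = segment_nuclei(fused)
        for nid in range(1, labels.n_labels + 1):
            try:
                sl = extract_slices(fused, labels, nid, patch_size=patch_size,
                                    n_slices=n_slices)
            except ValueError:
                continue
            probs = predict_slices(cnn_bundle, sl.patches)
            call, _ = classify_segment(probs, cnn_bundle.class_order)
            counts[call] += 1
            n_segments += 1
        for nuc in scene.frames[t]:
            truth_counts[nuc.phase] += 1

    total = max(sum(counts.values()), 1)
    total_truth = max(sum(truth_counts.values()), 1)
    return {
        "fractions": {c: counts[c] / total for c in cnn_bundle.class_order},
        "truth_fractions": {c: truth_counts[c] / total_truth
                            for c in cnn_bundle.class_order},
        "expected_fractions": params.expected_phase_fractions(),
        "counts": counts,
        "n_nucleus_frames": total,
        "registration_residual_um": transform.residual_rms,
    }
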