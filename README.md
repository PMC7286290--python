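# spimscreen

A reusable implementation of an automated dual-view light-sheet
high-content screening pipeline for 3D cell culture: from raw dual-view
stacks through bead-based registration, fusion/deconvolution, 3D nuclei
segmentation and cell-cycle phase classification, to spheroid time-lapse
quantification and phenotype clustering. A synthetic scene generator with
full ground truth drives and verifies every stage, so the whole pipeline
is testable without microscope data.

**Who it is for.** Groups running (or simulating) diSPIM-style screens of
H2B-labelled spheroids who need the image-analysis half of the experiment:
registration/fusion of orthogonal views, per-nucleus features, mitotic
phase calls, spheroid growth statistics, and siRNA/perturbation phenotype
clustering.

## The core models

* **Calibration**: beads at a dedicated position give the affine
  registration matrix *T* (view B → view A, fit by iterated
  nearest-neighbour + least squares), an empirical PSF per view, and the
  global stage drift (per-axis median of bead displacements).
* **Fusion**: alternating joint Richardson–Lucy deconvolution with the two
  per-view PSFs, initialized with the mean of the registered views —
  multiplicative updates `est ← est · ((view / (est ⊛ psf)) ⊛ psf*)`
  alternating between views, yielding near-isotropic resolution.
* **Phase classification**: a random forest on 13 Haralick GLCM texture
  features per nucleus, versus a compact VGG-style CNN on 2D slices
  (XY/XZ/YZ) of each segmented nucleus whose per-slice probabilities are
  summed — the class with the highest summed likelihood becomes the
  nucleus' phase.
* **Occupancy**: for an asynchronous, constant-size population the
  expected fraction of nucleus-frames in phase *p* is duration(*p*) /
  cycle length; with a 1260-min cycle and prophase/metaphase/anaphase
  durations of 11.3/15.1/40.3 min this gives 94.7% interphase, 0.9%
  prophase, 1.2% metaphase, 3.2% anaphase.
* **Phenotypes**: per-sample feature matrices are centred/scaled, each
  feature is replaced by its ranks, and samples are clustered with
  complete-linkage hierarchical clustering on rank distances — invariant
  to any monotone feature distortion.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

Simulate a small dividing spheroid, image one frame through both views,
calibrate from beads, fuse, segment and measure:

```python
import numpy as np
from spimscreen import (SceneParams, OpticsParams, simulate_timelapse,
                        render_dual_view, render_bead_calibration,
                        detect_beads, estimate_registration,
                        resample_to_reference, fuse_mean, segment_nuclei,
                        compute_geometry)

params = SceneParams(n_initial_cells=8, n_frames=5, seed=4,
                     fov_um=(31.5, 31.5, 31.5))
scene = simulate_timelapse(params)
optics = OpticsParams()

cal = render_bead_calibration(12, optics, seed=4,
                              true_transform=scene.true_transform)
a0, b0 = cal["stacks"][0]
T = estimate_registration(detect_beads(a0), detect_beads(b0))
print(f"registration residual {T.residual_rms:.3f} um "
      f"from {T.n_correspondences} beads")

va, vb = render_dual_view(scene, optics, frame=0, seed=7,
                          grid_shape=(64, 64, 64))
fused = fuse_mean(va, resample_to_reference(vb, T, grid_shape=(64, 64, 64)))
labels = segment_nuclei(fused)
recs = compute_geometry(labels, fused)
print(f"{labels.n_labels} nuclei segmented (truth: {len(scene.frames[0])})")
print(f"mean nucleus volume {np.mean([r.volume_um3 for r in recs]):.0f} um^3")
```

which prints

```
registration residual 0.076 um from 12 beads
8 nuclei segmented (truth: 8)
mean nucleus volume 277 um^3
```

— the bead calibration recovers the true 90° view transform to well under
a tenth of a micrometre, all 8 nuclei are found, and the measured volumes
sit near the generator's 4-µm-radius nuclei (4/3·π·4³ ≈ 268 µm³).

A command-line interface wraps the same functionality:
`spimscreen simulate|register|fuse|segment|classify|cluster|prescreen`
(see `spimscreen --help`).

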