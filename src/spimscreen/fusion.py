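"""View fusion and joint deconvolution.

View B is pulled back onto the view-A reference grid through the bead
calibration transform; the two registered views are then combined either by
simple averaging (``n_iter=0``) or by alternating joint Richardson–Lucy
deconvolution with the two per-view PSFs, which restores near-isotropic
resolution from the complementary axial blur directions.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.signal import fftconvolve

from .beads import DriftSeries, PSFModel
from .transform import AffineTransform3D
from .volume import FusedVolume, VolumeStack


def resample_to_reference(
    stack: VolumeStack,
    transform: AffineTransform3D,
    grid_shape=None,
    voxel_size: float | None = None,
    validity: np.ndarray | None = None,
) -> VolumeStack:
    """Resample a (view-B) stack onto the isotropic reference grid.

    ``transform`` maps the stack's own world coordinates into the reference
    frame; resampling is the pull-back with trilinear interpolation.
    Out-of-view voxels are zero; a boolean validity mask is attached as
    ``.validity``.  When resampling a series with one fixed transform, pass
    a previously computed ``validity`` mask to skip recomputing it.
    """
    if voxel_size is None:
        voxel_size = stack.voxel_size[0] if stack.is_isotropic else min(stack.voxel_size)
    if grid_shape is None:
        grid_shape = stack.data.shape

    inv = transform.inverse()
    # output voxel (z,y,x) -> world_A (x,y,z) -> world_B -> input voxel (z,y,x)
    vx, vy, vz = stack.voxel_size
    S_out = np.diag([voxel_size] * 3)  # index (z,y,x) -> world (z,y,x)
    P = np.array([[0, 0, 1], [0, 1, 0], [1, 0, 0]], dtype=float)  # zyx <-> xyz swap
    M_xyz = inv.matrix
    t_xyz = inv.translation
    S_in = np.diag([1.0 / vz, 1.0 / vy, 1.0 / vx])
    full = S_in @ P @ M_xyz @ P @ S_out
    offset = S_in @ P @ t_xyz

    out = ndimage.affine_transform(
        np.asarray(stack.data, dtype=np.float32), full, offset=offset,
        output_shape=tuple(grid_shape), order=1, mode="constant", cval=0.0,
    )
    if validity is None:
        ones = ndimage.affine_transform(
            np.ones(stack.data.shape, dtype=np.float32), full, offset=offset,
            output_shape=tuple(grid_shape), order=1, mode="constant", cval=0.0,
        )
        validity = ones > 0.999
    res = VolumeStack(out, (voxel_size,) * 3, view=stack.view, timepoint=stack.timepoint)
    res.validity = validity  # type: ignore[attr-defined]
    return res


def _conv(a: np.ndarray, k: np.ndarray) -> np.ndarray:
    return fftconvolve(a, k, mode="same")


def joint_deconvolve(
    view_a: VolumeStack,
    view_b: VolumeStack,
    psf_a: PSFModel,
    psf_b: PSFModel,
    n_iter: int = 10,
    epsilon: float = 1e-6,
    background: float = 0.0,
) -> FusedVolume:
    """Alternating joint Richardson–Lucy fusion of two registered views.

    The estimate starts as the mean of the two views; each iteration
    applies the multiplicative RL update for view A, then for view B
    (``ratio = view / (estimate ⊛ psf + eps)``, estimate multiplied by
    ``ratio ⊛ psf-flipped``), each restricted to that view's validity
    mask.  The per-view Poisson data-fit terms are logged per iteration.

    ``n_iter=0`` returns the plain mean of the views (registration-only
    fusion).
    """
    if view_a.data.shape != view_b.data.shape:
        raise ValueError("views must share a common grid")
    if abs(view_a.voxel_size[0] - view_b.voxel_size[0]) > 1e-9:
        raise ValueError("views must share a common grid")
    a = np.clip(np.asarray(view_a.data, dtype=float) - background, 0, None)
    b = np.clip(np.asarray(view_b.data, dtype=float) - background, 0, None)
    mask_a = getattr(view_a, "validity", None)
    mask_b = getattr(view_b, "validity", None)
    mask_a = np.ones(a.shape, bool) if mask_a is None else mask_a
    mask_b = np.ones(b.shape, bool) if mask_b is None else mask_b

    est = 0.5 * (a + b)
    ka = psf_a.kernel
    kb = psf_b.kernel
    ka_f = ka[::-1, ::-1, ::-1]
    kb_f = kb[::-1, ::-1, ::-1]

    def poisson_fit(view, mask, kern):
        mu = np.clip(_conv(est, kern), epsilon, None)
        return float((mu[mask] - view[mask] * np.log(mu[mask])).sum())

    log = []
    for _ in range(int(n_iter)):
        for view, mask, kern, kern_f in ((a, mask_a, ka, ka_f), (b, mask_b, kb, kb_f)):
            blur = _conv(est, kern)
            ratio = np.where(mask, view / np.clip(blur, epsilon, None), 1.0)
            corr = _conv(ratio, kern_f)
            est = np.clip(est * np.where(mask, corr, 1.0), 0, None)
        log.append({"fit_a": poisson_fit(a, mask_a, ka), "fit_b": poisson_fit(b, mask_b, kb)})

    fused = FusedVolume(
        np.clip(est, 0, None), voxel_size=float(view_a.voxel_size[0]),
        iterations=int(n_iter), fit_log=log,
    )
    fused.validity = mask_a & mask_b  # type: ignore[attr-defined]
    return fused


def fuse_mean(view_a: VolumeStack, view_b: VolumeStack) -> FusedVolume:
    """Registration-only fusion: per-voxel mean of the registered views."""
    psf = PSFModel.delta(view_a.voxel_size[0])
    return joint_deconvolve(view_a, view_b, psf, psf, n_iter=0)


def crop_to_content(fused: FusedVolume, threshold: float | None = None,
                    margin: int = 4) -> FusedVolume:
    """Crop a fused volume to the bounding box of its content.

    ``threshold`` defaults to the 99.5th percentile of the border voxels
    (a background estimate); ``margin`` voxels are kept around the box.
    """
    data = fused.data
    if threshold is None:
        border = np.concatenate([data[0].ravel(), data[-1].ravel(),
                                 data[:, 0].ravel(), data[:, -1].ravel()])
        threshold = float(np.percentile(border, 99.5))
    fg = np.argwhere(data > threshold)
    if len(fg) == 0:
        return fused
    lo = np.maximum(fg.min(axis=0) - margin, 0)
    hi = np.minimum(fg.max(axis=0) + margin + 1, data.shape)
    out = FusedVolume(data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]],
                      voxel_size=fused.voxel_size,
                      iterations=fused.iterations, fit_log=fused.fit_log)
    return out


def downsample(fused: FusedVolume, factor: int = 2) -> FusedVolume:
    """Block-mean downsampling by an integer factor (reduces data depth)."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return fused
    d = fused.data
    shape = [s - s % factor for s in d.shape]
    d = d[: shape[0], : shape[1], : shape[2]]
    d = d.reshape(shape[0] // factor, factor, shape[1] // factor, factor,
                  shape[2] // factor, factor).mean(axis=(1, 3, 5))
    return FusedVolume(d, voxel_size=fused.voxel_size * factor,
                       iterations=fused.iterations, fit_log=fused.fit_log)


def apply_drift_correction(volumes: list[VolumeStack], drift: DriftSeries) -> list[VolumeStack]:
    """Translate each frame by minus its global stage offset.

    Frame 0 is unchanged; every other frame is shifted (trilinear) so that
    stationary structures stay in place.  Raises if an offset is missing
    for any frame.
    """
    if len(volumes) > len(drift):
        raise ValueError("drift series does not cover all frames")
    out = []
    for i, vol in enumerate(volumes):
        off_xyz = drift.offsets[i]
        if np.abs(off_xyz).max() == 0:
            out.append(vol.copy_with(vol.data.copy()))
            continue
        vx, vy, vz = vol.voxel_size
        shift_zyx = [off_xyz[2] / vz, off_xyz[1] / vy, off_xyz[0] / vx]
        data = ndimage.shift(np.asarray(vol.data, dtype=float), shift=[-s for s in shift_zyx],
                             order=1, mode="constant", cval=0.0)
        out.append(vol.copy_with(data))
    return out
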