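"""Synthetic dual-view light-sheet scenes with known ground truth.

The generator emulates the imaging situation of a dual-view (diSPIM-style)
time-lapse screen of H2B-labelled spheroids: nuclei progress asynchronously
through the cell cycle (interphase → prophase → metaphase → anaphase →
division), sit packed in a roughly ball-shaped spheroid, and are imaged as
two orthogonal views related by a rigid/affine transform, each blurred by
its own anisotropic PSF and corrupted by Poisson shot noise plus Gaussian
read noise.  Fluorescent beads and slow stage drift are available for
calibration work.  Every stochastic operation takes an explicit seed.

Phase morphology encoding (chromatin appearance under an H2B label):

* interphase — smooth sphere with mild large-scale texture;
* prophase   — same envelope, high-contrast condensed speckles;
* metaphase  — dense flattened plate perpendicular to the division axis,
  fine striated texture (aligned chromosomes);
* anaphase   — two dense lobes separating along the division axis, joined
  by a dim midzone bridge.

These are minimal geometric encodings a texture or CNN classifier can
separate; they are not photorealistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import json

import numpy as np
from scipy import ndimage

from .transform import AffineTransform3D, nominal_view_rotation
from .volume import VolumeStack

PHASES = ("interphase", "prophase", "metaphase", "anaphase")

#: Appearance constants per phase: relative chromatin density, texture
#: amplitude (multiplicative, relative to 1) and texture length scale (µm).
PHASE_MORPHOLOGY = {
    "interphase": dict(density=1.0, tex_amp=0.15, tex_scale=2.2),
    "prophase": dict(density=1.05, tex_amp=1.5, tex_scale=1.1),
    "metaphase": dict(density=1.7, tex_amp=0.25, tex_scale=0.6),
    "anaphase": dict(density=1.5, tex_amp=0.4, tex_scale=1.8),
}
# metaphase plate geometry (relative to nucleus radius)
_META_HALF_THICKNESS = 0.35
_META_PLATE_RADIUS = 1.15
# anaphase lobe geometry: centre separation grows from 0.35 r to 0.8 r
_ANA_LOBE_RADIUS = 0.72
_ANA_SEP_START, _ANA_SEP_END = 0.35, 0.80
_ANA_BRIDGE_RADIUS = 0.25
_ANA_BRIDGE_DENSITY = 0.35
_EDGE_SOFTNESS_UM = 0.4  # soft-edge width of all envelopes


@dataclass
class SceneParams:
    """Study conditions for a simulated time lapse.

    Defaults follow the screen this package models: MCF10A-like ~21 h cell
    cycle (1260 min) with mitotic phase durations back-derived from the
    observed control phase fractions, imaged every 5 minutes.
    """

    n_initial_cells: int = 8
    cycle_length: float = 1260.0
    phase_durations: dict = field(
        default_factory=lambda: {"prophase": 11.3, "metaphase": 15.1, "anaphase": 40.3}
    )
    frame_interval: float = 5.0
    n_frames: int = 289
    nucleus_radius_mean: float = 4.0
    nucleus_radius_sd: float = 0.4
    spheroid_packing_distance: float = 12.0
    drift_per_frame: tuple[float, float, float] = (0.0, 0.0, 0.0)
    random_walk_sd: float = 0.1
    fov_um: tuple[float, float, float] = (63.5, 63.5, 63.5)
    divisions: bool = True
    n_initial_spheroids: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("need at least one frame")
        if self.n_initial_cells < 1:
            raise ValueError("need at least one cell")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        for k, v in self.phase_durations.items():
            if k not in PHASES[1:]:
                raise ValueError(f"unknown mitotic phase {k!r}")
            if v <= 0:
                raise ValueError("all phase durations must be positive")
        if self.mitotic_duration >= self.cycle_length:
            raise ValueError("mitotic phases must be shorter than the cycle")

    @property
    def mitotic_duration(self) -> float:
        return float(sum(self.phase_durations.values()))

    @property
    def interphase_duration(self) -> float:
        return self.cycle_length - self.mitotic_duration

    def expected_phase_fractions(self) -> dict[str, float]:
        """Stationary occupancy duration(p)/cycle for a constant population."""
        out = {"interphase": self.interphase_duration / self.cycle_length}
        for p in PHASES[1:]:
            out[p] = self.phase_durations[p] / self.cycle_length
        return out

    def phase_at_age(self, age: float) -> tuple[str, float]:
        """Phase and within-phase progress (0..1) at cycle age ``age`` min."""
        a = age % self.cycle_length
        edges = [self.interphase_duration]
        for p in PHASES[1:]:
            edges.append(edges[-1] + self.phase_durations[p])
        lo = 0.0
        for phase, hi in zip(PHASES, edges):
            if a < hi:
                return phase, (a - lo) / (hi - lo)
            lo = hi
        return "anaphase", 1.0


@dataclass
class OpticsParams:
    """Camera and optics description for rendering.

    ``voxel_size_xy``/``slice_spacing`` describe the native acquisition
    (0.1625 µm/px, 0.5 µm slice interval).  Synthesis happens on an
    isotropic grid with edge ``render_voxel_size`` (defaults to the slice
    spacing — the "isotropic-equivalent" desk scale).
    """

    voxel_size_xy: float = 0.1625
    slice_spacing: float = 0.5
    render_voxel_size: float | None = None
    psf_sigma_lateral: dict = field(default_factory=lambda: {"A": 0.3, "B": 0.3})
    psf_sigma_axial: dict = field(default_factory=lambda: {"A": 1.0, "B": 1.0})
    photon_scale: float = 200.0
    background: float = 5.0
    read_noise_sd: float = 2.0
    bit_depth: int = 16

    def __post_init__(self) -> None:
        if self.photon_scale < 0:
            raise ValueError("photon_scale must be nonnegative")
        if self.voxel_size_xy <= 0 or self.slice_spacing <= 0:
            raise ValueError("voxel sizes must be positive")
        for v in self.psf_sigma_lateral.values():
            if v < 0:
                raise ValueError("PSF sigma must be nonnegative")
        for view in self.psf_sigma_axial:
            if self.psf_sigma_axial[view] < self.psf_sigma_lateral.get(view, 0.0):
                raise ValueError("axial PSF sigma must be >= lateral sigma")

    @property
    def voxel(self) -> float:
        return float(self.render_voxel_size or self.slice_spacing)

    def sigmas_vox(self, view: str) -> tuple[float, float, float]:
        """PSF sigmas in voxels, (z, y, x) order, axial along the view's z."""
        lat = self.psf_sigma_lateral[view] / self.voxel
        ax = self.psf_sigma_axial[view] / self.voxel
        return (ax, lat, lat)


@dataclass
class NucleusState:
    id: int
    parent_id: int | None
    spheroid_id: int
    centroid: np.ndarray  # (x, y, z) µm, drift included
    radius: float
    phase: str
    phase_frac: float
    axis: np.ndarray  # division axis, unit (x, y, z)
    texture_seed: int


@dataclass
class GroundTruthScene:
    params: SceneParams
    frames: list  # list (per frame) of list[NucleusState]
    bead_positions: list  # per frame: (n_beads, 3) array, drift included
    drift: np.ndarray  # (n_frames, 3) cumulative offset µm
    true_transform: AffineTransform3D

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def nuclei_table(self):
        """Flat per-nucleus-frame table (pandas DataFrame)."""
        import pandas as pd

        rows = []
        for t, frame in enumerate(self.frames):
            for n in frame:
                rows.append(
                    dict(
                        timepoint=t,
                        nucleus_id=n.id,
                        parent_id=-1 if n.parent_id is None else n.parent_id,
                        spheroid_id=n.spheroid_id,
                        x_um=n.centroid[0],
                        y_um=n.centroid[1],
                        z_um=n.centroid[2],
                        radius_um=n.radius,
                        phase=n.phase,
                    )
                )
        return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# time-lapse simulation
# --------------------------------------------------------------------------


def _random_unit(rng) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _relax_positions(pos, spheroid_of, packing, centers, n_iter=40, step=0.3):
    """Soft-sphere relaxation: repel pairs closer than ``packing``, pull each
    nucleus weakly toward its spheroid centre so the cluster stays ball-like."""
    pos = pos.copy()
    for _ in range(n_iter):
        disp = np.zeros_like(pos)
        d = pos[:, None, :] - pos[None, :, :]
        dist = np.linalg.norm(d, axis=-1)
        np.fill_diagonal(dist, np.inf)
        close = dist < packing
        if close.any():
            ii, jj = np.nonzero(close)
            push = (packing - dist[ii, jj])[:, None] * d[ii, jj] / dist[ii, jj][:, None]
            np.add.at(disp, ii, 0.5 * push)
        # weak centring
        for s, c in centers.items():
            m = spheroid_of == s
            disp[m] += 0.02 * (c - pos[m])
        if np.abs(disp).max() < 1e-3:
            break
        pos += step * disp
    return pos


def simulate_timelapse(params: SceneParams) -> GroundTruthScene:
    """Simulate nucleus ground truth for a full time lapse.

    Each nucleus carries an asynchronous cycle clock (initial ages uniform
    over the cycle).  When the clock wraps, either the nucleus divides into
    two children placed apart along its division axis (``divisions=True``)
    or it re-enters interphase in place, keeping the population constant
    and the age structure exactly uniform (``divisions=False`` — the mode
    whose time-averaged phase occupancy equals duration/cycle).
    """
    rng = np.random.default_rng(params.seed)
    fov = np.asarray(params.fov_um, dtype=float)
    center = fov / 2.0
    n = params.n_initial_cells
    n_sph = max(1, min(params.n_initial_spheroids, n))

    # spheroid seed centres, then cells packed around them
    if n_sph == 1:
        sph_centers = {0: center.copy()}
    else:
        sph_centers = {}
        for s in range(n_sph):
            sph_centers[s] = center + rng.uniform(-0.25, 0.25, 3) * fov

    per = [n // n_sph + (1 if i < n % n_sph else 0) for i in range(n_sph)]
    pos, sph_of = [], []
    for s, k in enumerate(per):
        r0 = params.spheroid_packing_distance * max(1.0, k ** (1 / 3)) * 0.6
        u = rng.normal(size=(k, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        rad = r0 * rng.uniform(0, 1, k) ** (1 / 3)
        pos.append(sph_centers[s] + u * rad[:, None])
        sph_of += [s] * k
    pos = np.vstack(pos)
    sph_of = np.array(sph_of)
    pos = _relax_positions(pos, sph_of, params.spheroid_packing_distance, sph_centers)

    ages = rng.uniform(0, params.cycle_length, n)
    radii = np.clip(
        rng.normal(params.nucleus_radius_mean, params.nucleus_radius_sd, n),
        0.5 * params.nucleus_radius_mean,
        1.5 * params.nucleus_radius_mean,
    )
    ids = list(range(n))
    parents: list[int | None] = [None] * n
    axes = [_random_unit(rng) for _ in range(n)]
    tex_seeds = [int(rng.integers(0, 2**31 - 1)) for _ in range(n)]
    next_id = n

    drift_step = np.asarray(params.drift_per_frame, dtype=float)
    drift = np.outer(np.arange(params.n_frames), drift_step)

    frames = []
    for t in range(params.n_frames):
        if t > 0:
            ages = ages + params.frame_interval
            if params.random_walk_sd > 0:
                pos = pos + rng.normal(0, params.random_walk_sd, pos.shape)
            # divisions / renewals at clock wrap
            wrapped = np.nonzero(ages >= params.cycle_length)[0]
            if params.divisions and len(wrapped):
                keep = np.ones(len(ids), dtype=bool)
                new_pos, new_sph, new_age, new_rad = [], [], [], []
                new_ids, new_par, new_axes, new_tex = [], [], [], []
                for i in wrapped:
                    keep[i] = False
                    sep = 0.45 * params.spheroid_packing_distance
                    for sgn in (-1.0, 1.0):
                        new_pos.append(pos[i] + sgn * sep * axes[i])
                        new_sph.append(sph_of[i])
                        new_age.append(ages[i] - params.cycle_length)
                        new_rad.append(
                            float(
                                np.clip(
                                    rng.normal(
                                        params.nucleus_radius_mean,
                                        params.nucleus_radius_sd,
                                    ),
                                    0.5 * params.nucleus_radius_mean,
                                    1.5 * params.nucleus_radius_mean,
                                )
                            )
                        )
                        new_ids.append(next_id)
                        new_par.append(ids[i])
                        new_axes.append(_random_unit(rng))
                        new_tex.append(int(rng.integers(0, 2**31 - 1)))
                        next_id += 1
                pos = np.vstack([pos[keep]] + [np.asarray(new_pos)])
                sph_of = np.concatenate([sph_of[keep], np.asarray(new_sph)])
                ages = np.concatenate([ages[keep], np.asarray(new_age)])
                radii = np.concatenate([radii[keep], np.asarray(new_rad)])
                ids = [x for x, k in zip(ids, keep) if k] + new_ids
                parents = [x for x, k in zip(parents, keep) if k] + new_par
                axes = [x for x, k in zip(axes, keep) if k] + new_axes
                tex_seeds = [x for x, k in zip(tex_seeds, keep) if k] + new_tex
            elif len(wrapped):
                ages[wrapped] -= params.cycle_length
                for i in wrapped:
                    axes[i] = _random_unit(rng)
            if len(wrapped) or params.random_walk_sd > 0:
                pos = _relax_positions(
                    pos, sph_of, params.spheroid_packing_distance, sph_centers, n_iter=8
                )

        frame = []
        for k in range(len(ids)):
            phase, frac = params.phase_at_age(ages[k])
            frame.append(
                NucleusState(
                    id=ids[k],
                    parent_id=parents[k],
                    spheroid_id=int(sph_of[k]),
                    centroid=pos[k] + drift[t],
                    radius=float(radii[k]),
                    phase=phase,
                    phase_frac=float(frac),
                    axis=axes[k].copy(),
                    texture_seed=tex_seeds[k],
                )
            )
        frames.append(frame)

    true = nominal_view_rotation(center)
    true.translation = true.translation + rng.normal(0, 0.5, 3)
    return GroundTruthScene(
        params=params,
        frames=frames,
        bead_positions=[np.zeros((0, 3))] * params.n_frames,
        drift=drift,
        true_transform=true,
    )


# --------------------------------------------------------------------------
# rendering
# --------------------------------------------------------------------------


_TEXTURE_CACHE: dict = {}


def _texture_field(nuc: NucleusState, half_um: float, spacing: float = 0.5):
    """Deterministic per-nucleus texture on a world-axis-aligned local grid.

    Sampled in world space so both views see the same chromatin pattern.
    Cached by (seed, phase, extent) — nuclei persist across frames and
    views, so re-generation would dominate rendering time.
    """
    key = (nuc.texture_seed, nuc.phase, round(half_um, 3))
    hit = _TEXTURE_CACHE.get(key)
    if hit is not None:
        return hit
    m = PHASE_MORPHOLOGY[nuc.phase]
    npts = int(np.ceil(2 * half_um / spacing)) + 1
    rng = np.random.default_rng(nuc.texture_seed + {"interphase": 0, "prophase": 1,
                                                    "metaphase": 2, "anaphase": 3}[nuc.phase])
    raw = rng.normal(size=(npts, npts, npts))
    smooth = ndimage.gaussian_filter(raw, m["tex_scale"] / spacing).astype(np.float32)
    sd = smooth.std()
    if sd > 0:
        smooth /= sd
    if len(_TEXTURE_CACHE) > 4096:
        _TEXTURE_CACHE.clear()
    _TEXTURE_CACHE[key] = (smooth, spacing)
    return smooth, spacing


def _nucleus_density(points_xyz: np.ndarray, nuc: NucleusState) -> np.ndarray:
    """Chromatin density of one nucleus evaluated at world points (N, 3)."""
    m = PHASE_MORPHOLOGY[nuc.phase]
    q = points_xyz - nuc.centroid
    r = nuc.radius
    w = _EDGE_SOFTNESS_UM

    def soft(dist_inside):
        return np.clip(dist_inside / w + 0.5, 0.0, 1.0)

    if nuc.phase == "interphase" or nuc.phase == "prophase":
        env = soft(r - np.linalg.norm(q, axis=1))
        base = env * m["density"]
    elif nuc.phase == "metaphase":
        along = q @ nuc.axis
        perp = np.linalg.norm(q - np.outer(along, nuc.axis), axis=1)
        env = soft(_META_HALF_THICKNESS * r - np.abs(along)) * soft(
            _META_PLATE_RADIUS * r - perp
        )
        base = env * m["density"]
    else:  # anaphase: two lobes + midzone bridge
        sep = (_ANA_SEP_START + (_ANA_SEP_END - _ANA_SEP_START) * nuc.phase_frac) * r
        lobe_r = _ANA_LOBE_RADIUS * r
        d1 = np.linalg.norm(q - (sep / 2) * nuc.axis, axis=1)
        d2 = np.linalg.norm(q + (sep / 2) * nuc.axis, axis=1)
        env = np.maximum(soft(lobe_r - d1), soft(lobe_r - d2))
        along = q @ nuc.axis
        perp = np.linalg.norm(q - np.outer(along, nuc.axis), axis=1)
        bridge = soft(_ANA_BRIDGE_RADIUS * r - perp) * soft(sep / 2 - np.abs(along))
        base = m["density"] * np.maximum(env, _ANA_BRIDGE_DENSITY * bridge)

    if m["tex_amp"] > 0 and base.any():
        half = 1.7 * r
        field, spacing = _texture_field(nuc, half)
        # world offset -> field indices (z, y, x)
        coords = np.stack(
            [(q[:, 2] + half) / spacing, (q[:, 1] + half) / spacing, (q[:, 0] + half) / spacing]
        )
        tex = ndimage.map_coordinates(field, coords, order=1, mode="nearest")
        base = base * np.clip(1.0 + m["tex_amp"] * tex, 0.05, None)
    return base


def _splat_points(canvas: np.ndarray, idx_zyx: np.ndarray, weights: np.ndarray) -> None:
    """Trilinear splat of point intensities into a (Z, Y, X) canvas."""
    base = np.floor(idx_zyx).astype(int)
    frac = idx_zyx - base
    for dz in (0, 1):
        for dy in (0, 1):
            for dx in (0, 1):
                w = (
                    (frac[:, 0] if dz else 1 - frac[:, 0])
                    * (frac[:, 1] if dy else 1 - frac[:, 1])
                    * (frac[:, 2] if dx else 1 - frac[:, 2])
                )
                z, y, x = base[:, 0] + dz, base[:, 1] + dy, base[:, 2] + dx
                ok = (
                    (z >= 0) & (z < canvas.shape[0])
                    & (y >= 0) & (y < canvas.shape[1])
                    & (x >= 0) & (x < canvas.shape[2])
                )
                np.add.at(canvas, (z[ok], y[ok], x[ok]), weights[ok] * w[ok])


def render_density(
    nuclei,
    grid_shape,
    voxel: float,
    grid_to_world: AffineTransform3D | None = None,
    bead_positions=None,
    bead_photons: float = 0.0,
):
    """Noise-free chromatin density raster on a view grid.

    ``grid_to_world`` maps the grid's own world coordinates into the frame
    the nuclei are expressed in (identity for view A, the true B→A
    transform for view B).
    """
    canvas = np.zeros(grid_shape, dtype=np.float32)
    T = grid_to_world or AffineTransform3D.identity()
    Tinv = T.inverse()
    nz, ny, nx = grid_shape
    for nuc in nuclei:
        c_grid = Tinv.apply(nuc.centroid)
        # envelopes never reach past ~1.25 r (+ soft edge)
        half = 1.25 * nuc.radius + 1.0 + voxel
        lo = np.maximum(np.floor((c_grid - half) / voxel).astype(int), 0)
        hi_lim = np.array([nx - 1, ny - 1, nz - 1])
        hi = np.minimum(np.ceil((c_grid + half) / voxel).astype(int), hi_lim)
        if np.any(hi < lo):
            continue
        xs = np.arange(lo[0], hi[0] + 1, dtype=np.float32) * voxel
        ys = np.arange(lo[1], hi[1] + 1, dtype=np.float32) * voxel
        zs = np.arange(lo[2], hi[2] + 1, dtype=np.float32) * voxel
        Z, Y, X = np.meshgrid(zs, ys, xs, indexing="ij")
        pts_grid = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
        vals = _nucleus_density(T.apply(pts_grid), nuc)
        canvas[lo[2]: hi[2] + 1, lo[1]: hi[1] + 1, lo[0]: hi[0] + 1] += (
            vals.reshape(Z.shape).astype(np.float32))

    if bead_positions is not None and len(bead_positions) and bead_photons > 0:
        p_grid = Tinv.apply(np.asarray(bead_positions, dtype=float))
        idx = np.column_stack([p_grid[:, 2], p_grid[:, 1], p_grid[:, 0]]) / voxel
        _splat_points(canvas, idx, np.full(len(idx), bead_photons))
    return canvas


def _apply_optics(density, optics: OpticsParams, view: str, rng, bead_field=None):
    sig = optics.sigmas_vox(view)
    img = density * optics.photon_scale
    if bead_field is not None:
        img = img + bead_field
    if max(sig) > 0:
        img = ndimage.gaussian_filter(img, sig, mode="constant")
    img = img + optics.background
    if optics.photon_scale > 0 or optics.background > 0:
        img = rng.poisson(np.clip(img, 0, None)).astype(np.float64)
    if optics.read_noise_sd > 0:
        img = img + rng.normal(0, optics.read_noise_sd, img.shape)
    hi = 2**optics.bit_depth - 1
    return np.clip(np.round(img), 0, hi).astype(np.uint16)


def render_dual_view(
    scene: GroundTruthScene,
    optics: OpticsParams,
    frame: int,
    seed: int,
    grid_shape=(128, 128, 128),
    noise: bool = True,
):
    """Render one timepoint as the (view A, view B) stack pair.

    View A lies on the reference grid; view B is rendered on its own grid
    whose coordinates map into the A frame through the scene's true
    transform, then blurred by its own anisotropic PSF.
    """
    if not 0 <= frame < scene.n_frames:
        raise IndexError(f"frame {frame} outside scene")
    rng = np.random.default_rng(seed)
    nuclei = scene.frames[frame]
    beads = scene.bead_positions[frame]
    v = optics.voxel
    bead_photons = getattr(scene, "bead_photons", 0.0)

    stacks = []
    for view, T in (("A", None), ("B", scene.true_transform)):
        dens = render_density(nuclei, grid_shape, v, grid_to_world=T)
        bead_field = None
        if len(beads) and bead_photons > 0:
            bead_field = render_density(
                [], grid_shape, v, grid_to_world=T,
                bead_positions=beads, bead_photons=bead_photons,
            )
        if noise:
            img = _apply_optics(dens, optics, view, rng, bead_field)
        else:
            sig = optics.sigmas_vox(view)
            img = dens * optics.photon_scale
            if bead_field is not None:
                img = img + bead_field
            if max(sig) > 0:
                img = ndimage.gaussian_filter(img, sig, mode="constant")
            img = img + optics.background
        stacks.append(VolumeStack(img, (v, v, v), view=view, timepoint=frame))
    return stacks[0], stacks[1]


def render_bead_calibration(
    n_beads: int,
    optics: OpticsParams,
    drift=(0.0, 0.0, 0.0),
    n_frames: int = 1,
    seed: int = 0,
    grid_shape=(64, 64, 64),
    bead_photons: float = 20000.0,
    min_separation: float = 5.0,
    true_transform: AffineTransform3D | None = None,
):
    """Render the dedicated bead position used for registration and drift.

    Beads are isolated sub-voxel point sources at random non-coplanar
    positions inside the central part of the field of view; frame ``t``
    positions equal frame-0 positions plus ``t * drift``.

    Returns a dict with ``stacks`` (per frame (A, B) pairs), ``positions``
    (per frame (n, 3) arrays, A frame) and ``transform`` (true B→A).
    """
    if n_beads < 1:
        raise ValueError("need at least one bead")
    rng = np.random.default_rng(seed)
    v = optics.voxel
    fov = np.array([grid_shape[2], grid_shape[1], grid_shape[0]]) * v
    if true_transform is None:
        true_transform = nominal_view_rotation(fov / 2.0)
        true_transform.translation = true_transform.translation + rng.normal(0, 0.3, 3)

    pts: list[np.ndarray] = []
    tries = 0
    while len(pts) < n_beads and tries < 20000:
        cand = fov * rng.uniform(0.18, 0.82, 3)
        if all(np.linalg.norm(cand - p) >= min_separation for p in pts):
            pts.append(cand)
        tries += 1
    if len(pts) < n_beads:
        raise ValueError("could not place beads with requested separation")
    base = np.array(pts)

    drift = np.asarray(drift, dtype=float)
    positions, stacks = [], []
    for t in range(n_frames):
        p = base + t * drift
        positions.append(p)
        pair = []
        for view, T in (("A", None), ("B", true_transform)):
            field = render_density(
                [], grid_shape, v, grid_to_world=T,
                bead_positions=p, bead_photons=bead_photons,
            )
            img = _apply_optics(
                np.zeros(grid_shape, np.float32), optics, view,
                np.random.default_rng(seed + 1000 + 17 * t + (0 if view == "A" else 1)),
                bead_field=field,
            )
            pair.append(VolumeStack(img, (v, v, v), view=view, timepoint=t))
        stacks.append(tuple(pair))
    return {"stacks": stacks, "positions": positions, "transform": true_transform}


# --------------------------------------------------------------------------
# export
# --------------------------------------------------------------------------


def export_scene(
    scene: GroundTruthScene,
    optics: OpticsParams,
    outdir: str | Path,
    position: int = 0,
    grid_shape=(128, 128, 128),
    seed: int = 0,
    frames=None,
):
    """Write per-frame per-view TIFFs plus ground truth (CSV + JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    frames = range(scene.n_frames) if frames is None else frames
    for t in frames:
        a, b = render_dual_view(scene, optics, t, seed=seed + t, grid_shape=grid_shape)
        a.write_tiff(outdir / f"pos{position}_t{t}_viewA.tif")
        b.write_tiff(outdir / f"pos{position}_t{t}_viewB.tif")
    scene.nuclei_table().to_csv(outdir / f"pos{position}_ground_truth.csv", index=False)
    meta = {
        "true_transform": scene.true_transform.to_dict(),
        "drift_per_frame_um": list(map(float, scene.params.drift_per_frame)),
        "psf_sigma_lateral_um": optics.psf_sigma_lateral,
        "psf_sigma_axial_um": optics.psf_sigma_axial,
        "render_voxel_size_um": optics.voxel,
    }
    (outdir / f"pos{position}_ground_truth.json").write_text(json.dumps(meta, indent=2))
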