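"""Bead-based calibration: detection, view registration, PSF, drift.

The screen dedicates one sample position to fluorescent beads in gel.  From
those stacks this module localizes beads with sub-voxel precision, fits the
affine transform that maps view-B coordinates into the view-A frame,
extracts an empirical PSF per view, and tracks the slow global stage drift
over the time lapse.  The calibration estimated at the bead position is
then transferred to every sample stack acquired at the same timepoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import json

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .transform import AffineTransform3D, nominal_view_rotation
from .volume import VolumeStack


@dataclass
class BeadDetections:
    """Sub-voxel bead localizations from one stack."""

    centroids: np.ndarray  # (n, 3) world (x, y, z) µm
    intensities: np.ndarray  # (n,) background-subtracted peak
    quality: np.ndarray  # (n,) peak SNR
    view: str = "A"
    timepoint: int = 0

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float).reshape(-1, 3)
        self.intensities = np.asarray(self.intensities, dtype=float).reshape(-1)
        self.quality = np.asarray(self.quality, dtype=float).reshape(-1)

    def __len__(self) -> int:
        return len(self.centroids)


@dataclass
class PSFModel:
    """Empirical point spread function on an isotropic kernel grid."""

    kernel: np.ndarray  # (Z, Y, X), nonnegative, sums to 1
    voxel_size: float
    view: str = "A"

    def __post_init__(self) -> None:
        self.kernel = np.asarray(self.kernel, dtype=float)
        if self.kernel.ndim != 3:
            raise ValueError("PSF kernel must be 3D")
        if (self.kernel < -1e-12).any():
            raise ValueError("PSF kernel must be nonnegative")
        s = self.kernel.sum()
        if s <= 0:
            raise ValueError("PSF kernel must have positive mass")
        self.kernel = np.clip(self.kernel, 0, None) / self.kernel.sum()

    @classmethod
    def gaussian(cls, sigmas_um, voxel_size: float, view: str = "A",
                 radius_sigmas: float = 4.0) -> "PSFModel":
        """Analytic Gaussian PSF; ``sigmas_um`` is (axial_z, lat_y, lat_x)."""
        sig = np.asarray(sigmas_um, dtype=float) / voxel_size
        half = np.maximum(np.ceil(radius_sigmas * np.maximum(sig, 0.5)).astype(int), 1)
        zz, yy, xx = np.meshgrid(*(np.arange(-h, h + 1) for h in half), indexing="ij")
        k = np.exp(-0.5 * ((zz / max(sig[0], 1e-6)) ** 2
                           + (yy / max(sig[1], 1e-6)) ** 2
                           + (xx / max(sig[2], 1e-6)) ** 2))
        return cls(k, voxel_size, view)

    @classmethod
    def delta(cls, voxel_size: float, view: str = "A") -> "PSFModel":
        k = np.zeros((3, 3, 3))
        k[1, 1, 1] = 1.0
        return cls(k, voxel_size, view)

    def centroid_offset_vox(self) -> np.ndarray:
        """Centroid minus geometric centre, in voxels (z, y, x)."""
        grids = np.meshgrid(*(np.arange(s) for s in self.kernel.shape), indexing="ij")
        c = np.array([float((g * self.kernel).sum()) for g in grids])
        return c - (np.array(self.kernel.shape) - 1) / 2.0

    def write(self, path: str | Path) -> None:
        import tifffile

        tifffile.imwrite(str(path), self.kernel.astype(np.float32),
                         metadata={"axes": "ZYX", "voxel_size_um": self.voxel_size,
                                   "view": self.view})


@dataclass
class DriftSeries:
    """Per-timepoint global XYZ offset relative to the first frame."""

    offsets: np.ndarray  # (n_frames, 3) µm

    def __post_init__(self) -> None:
        self.offsets = np.asarray(self.offsets, dtype=float).reshape(-1, 3)
        if len(self.offsets) and np.abs(self.offsets[0]).max() > 1e-9:
            raise ValueError("first-frame offset must be zero")

    def __len__(self) -> int:
        return len(self.offsets)


# --------------------------------------------------------------------------


def detect_beads(
    stack: VolumeStack,
    min_separation: float = 4.0,
    snr_threshold: float = 8.0,
    window_um: float = 1.5,
) -> BeadDetections:
    """Localize isolated point sources in a stack.

    Local maxima above ``background + snr_threshold * noise`` (background
    and noise estimated robustly from the median and MAD of the whole
    stack) are refined to sub-voxel positions by an intensity-weighted
    centroid over a ``window_um`` half-width box; of any pair closer than
    ``min_separation`` only the brighter is kept.  An empty result is
    valid.
    """
    img = np.asarray(stack.data, dtype=float)
    if img.size == 0:
        raise ValueError("empty stack")
    bg = float(np.median(img))
    mad = float(np.median(np.abs(img - bg)))
    noise = 1.4826 * mad if mad > 0 else max(img.std(), 1e-12)
    thresh = bg + snr_threshold * noise

    footprint = np.ones((3, 3, 3), bool)
    maxed = ndimage.maximum_filter(img, footprint=footprint, mode="constant")
    peaks = np.argwhere((img >= maxed) & (img > thresh))
    if len(peaks) == 0:
        return BeadDetections(np.zeros((0, 3)), np.zeros(0), np.zeros(0),
                              view=stack.view, timepoint=stack.timepoint)

    vx, vy, vz = stack.voxel_size
    hw = np.maximum(np.round(window_um / np.array([vz, vy, vx])).astype(int), 1)
    cents, inten, qual = [], [], []
    for pz, py, px in peaks:
        lo = np.maximum([pz - hw[0], py - hw[1], px - hw[2]], 0)
        hi = np.minimum([pz + hw[0] + 1, py + hw[1] + 1, px + hw[2] + 1], img.shape)
        win = img[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] - bg
        win = np.clip(win, 0, None)
        tot = win.sum()
        if tot <= 0:
            continue
        zz, yy, xx = np.meshgrid(*(np.arange(l, h) for l, h in zip(lo, hi)), indexing="ij")
        cz = (zz * win).sum() / tot
        cy = (yy * win).sum() / tot
        cx = (xx * win).sum() / tot
        cents.append([cx * vx, cy * vy, cz * vz])
        inten.append(img[pz, py, px] - bg)
        qual.append((img[pz, py, px] - bg) / noise)
    cents = np.asarray(cents).reshape(-1, 3)
    inten = np.asarray(inten)
    qual = np.asarray(qual)

    # suppress near-duplicates: keep brighter of any pair within min_separation
    order = np.argsort(-inten)
    keep: list[int] = []
    for i in order:
        if all(np.linalg.norm(cents[i] - cents[j]) >= min_separation for j in keep):
            keep.append(i)
    keep = sorted(keep)
    return BeadDetections(cents[keep], inten[keep], qual[keep],
                          view=stack.view, timepoint=stack.timepoint)


def _fit_affine(src: np.ndarray, dst: np.ndarray) -> AffineTransform3D:
    """Least-squares affine mapping src -> dst (n >= 4, non-coplanar)."""
    n = len(src)
    A = np.hstack([src, np.ones((n, 1))])
    if np.linalg.matrix_rank(A) < 4:
        raise ValueError("degenerate calibration: correspondences are coplanar")
    sol, *_ = np.linalg.lstsq(A, dst, rcond=None)
    M = sol[:3].T
    t = sol[3]
    return AffineTransform3D(M, t)


def estimate_registration(
    beads_a: BeadDetections,
    beads_b: BeadDetections,
    init: AffineTransform3D | None = None,
    max_match_dist: float = 5.0,
    max_iter: int = 30,
) -> AffineTransform3D:
    """Estimate the affine B→A registration from bead point sets.

    Correspondences are found by nearest neighbour after applying ``init``
    (default: the nominal 90° view rotation about the joint FOV centre),
    matches farther than ``max_match_dist`` µm are rejected, an affine is
    fit by least squares, and match→fit is iterated until the assignment
    is stable.  The residual RMS over the final correspondences is stored
    on the returned transform.
    """
    if len(beads_a) < 4 or len(beads_b) < 4:
        raise ValueError("degenerate calibration: need at least 4 beads per view")
    A = beads_a.centroids
    B = beads_b.centroids
    if init is None:
        # nominal 90° rotation with the translation that aligns the two
        # point-cloud centroids (works for any unknown rotation pivot)
        R = nominal_view_rotation().matrix
        init = AffineTransform3D(R, A.mean(axis=0) - R @ B.mean(axis=0))

    tree = cKDTree(A)
    current = init
    prev_assign = None
    for _ in range(max_iter):
        Bt = current.apply(B)
        dist, idx = tree.query(Bt)
        ok = dist <= max_match_dist
        # one-to-one: for each A point keep the closest B claimant
        best: dict[int, int] = {}
        for bi in np.nonzero(ok)[0]:
            ai = idx[bi]
            if ai not in best or dist[bi] < dist[best[ai]]:
                best[ai] = bi
        pairs = sorted(best.items())
        if len(pairs) < 4:
            raise ValueError("degenerate calibration: fewer than 4 correspondences")
        ai = np.array([p[0] for p in pairs])
        bi = np.array([p[1] for p in pairs])
        fit = _fit_affine(B[bi], A[ai])
        assign = tuple(zip(ai.tolist(), bi.tolist()))
        if assign == prev_assign:
            current = fit
            break
        prev_assign = assign
        current = fit

    res = current.apply(B[bi]) - A[ai]
    current.residual_rms = float(np.sqrt((res**2).sum(axis=1).mean()))
    current.n_correspondences = len(ai)
    return current


def extract_psf(
    stack: VolumeStack,
    beads: BeadDetections,
    radius: float = 3.0,
) -> PSFModel:
    """Average an empirical PSF from isolated beads.

    Only beads with no neighbour within ``2 * radius`` are used.  Windows
    of half-width ``radius`` µm are sampled centred at each sub-voxel
    centroid (trilinear), background-subtracted, clipped at zero, averaged
    over beads and normalized to unit sum.
    """
    if len(beads) == 0:
        raise ValueError("no beads supplied")
    pts = beads.centroids
    iso = []
    for i in range(len(pts)):
        d = np.linalg.norm(pts - pts[i], axis=1)
        d[i] = np.inf
        if d.min() >= 2 * radius:
            iso.append(i)
    if not iso:
        raise ValueError("no isolated bead (all have neighbours within 2*radius)")

    img = np.asarray(stack.data, dtype=float)
    bg = float(np.median(img))
    vx, vy, vz = stack.voxel_size
    if not stack.is_isotropic:
        raise ValueError("PSF extraction expects an isotropic stack")
    v = vx
    h = max(int(np.ceil(radius / v)), 2)
    offs = np.arange(-h, h + 1)
    oz, oy, ox = np.meshgrid(offs, offs, offs, indexing="ij")

    acc = np.zeros((2 * h + 1,) * 3)
    used = 0
    for i in iso:
        cx, cy, cz = pts[i]
        coords = np.stack([oz + cz / v, oy + cy / v, ox + cx / v]).reshape(3, -1)
        if (coords.min() < -0.5 or coords[0].max() > img.shape[0] - 0.5
                or coords[1].max() > img.shape[1] - 0.5
                or coords[2].max() > img.shape[2] - 0.5):
            continue
        # cubic spline: trilinear sampling would blur a ~1-voxel-wide PSF
        win = ndimage.map_coordinates(img, coords, order=3, mode="nearest")
        acc += np.clip(win.reshape(acc.shape) - bg, 0, None)
        used += 1
    if used == 0:
        raise ValueError("no isolated bead window fits inside the stack")
    return PSFModel(acc / used, voxel_size=v, view=stack.view)


def track_drift(
    detections_by_time: list[BeadDetections],
    max_gate: float = 5.0,
) -> DriftSeries:
    """Global stage drift from bead positions over time.

    Beads are matched frame-to-frame by nearest neighbour within
    ``max_gate`` µm of the previous (drift-propagated) position; the
    per-frame offset is the per-axis median of matched displacements
    relative to frame 0.  Frames without matches inherit the previous
    offset.
    """
    if not detections_by_time:
        raise ValueError("no detections supplied")
    ref = detections_by_time[0].centroids
    if len(ref) == 0:
        raise ValueError("no beads in the first frame")
    offsets = [np.zeros(3)]
    prev = offsets[0]
    for det in detections_by_time[1:]:
        pts = det.centroids
        if len(pts) == 0:
            offsets.append(prev.copy())
            continue
        tree = cKDTree(pts)
        dist, idx = tree.query(ref + prev)
        ok = dist <= max_gate
        if not ok.any():
            offsets.append(prev.copy())
            continue
        disp = pts[idx[ok]] - ref[ok]
        prev = np.median(disp, axis=0)
        offsets.append(prev.copy())
    return DriftSeries(np.array(offsets))


# --------------------------------------------------------------------------


def write_calibration(path: str | Path, transform: AffineTransform3D,
                      psf_a: PSFModel | None = None, psf_b: PSFModel | None = None) -> None:
    """Serialize a calibration (transform + optional PSF metadata) as JSON."""
    d = {"transform": transform.to_dict()}
    for tag, psf in (("psf_a", psf_a), ("psf_b", psf_b)):
        if psf is not None:
            d[tag] = {"shape": list(psf.kernel.shape), "voxel_size_um": psf.voxel_size,
                      "view": psf.view, "kernel": psf.kernel.ravel().tolist()}
    Path(path).write_text(json.dumps(d))


def read_calibration(path: str | Path):
    d = json.loads(Path(path).read_text())
    transform = AffineTransform3D.from_dict(d["transform"])
    psfs = {}
    for tag in ("psf_a", "psf_b"):
        if tag in d:
            p = d[tag]
            psfs[tag] = PSFModel(np.array(p["kernel"]).reshape(p["shape"]),
                                 p["voxel_size_um"], p["view"])
    return transform, psfs.get("psf_a"), psfs.get("psf_b")
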