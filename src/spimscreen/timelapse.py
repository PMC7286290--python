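"""Spheroid-level time-series assembly.

Turns per-frame nucleus records into spheroid analytics: distance-based
clustering of segments into spheroids with frame-stable ids, greedy
mutual-nearest-neighbour tracking with one-generation division links,
median migration speed, radial positions, phase-occupancy fractions,
cell-cycle transition bookkeeping (with an improper-transition flag),
lowess-smoothed instantaneous growth rates and 3D shape descriptors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial import ConvexHull, cKDTree
from scipy import ndimage
from skimage.measure import marching_cubes, mesh_surface_area

from .classify import PHASE_CLASSES_4

#: transitions a healthy cell cycle allows along one track
VALID_TRANSITIONS = {
    ("interphase", "prophase"),
    ("prophase", "metaphase"),
    ("metaphase", "anaphase"),
    ("anaphase", "interphase"),
    ("anaphase", "division"),
}


@dataclass
class Track:
    track_id: int
    steps: list  # ordered (timepoint, nucleus_id)
    parent_track_id: int | None = None
    displacements: list = field(default_factory=list)  # µm per step
    spheroid_id: int | None = None

    @property
    def timepoints(self):
        return [t for t, _ in self.steps]


@dataclass
class GrowthRateParams:
    """Lowess smoothing parameters for instantaneous growth rates.

    ``delta`` is derived as ``delta_fraction`` × the range of the series
    being smoothed, matching the screen's R lowess call.
    """

    f: float = 1.0 / 3.0
    iterations: int = 3
    delta_fraction: float = 0.01

    def __post_init__(self) -> None:
        if not 0 < self.f <= 1:
            raise ValueError("lowess span fraction must be in (0, 1]")


# --------------------------------------------------------------------------


def cluster_into_spheroids(centroids_by_time, cutoff: float = 25.0):
    """Cluster nuclei into spheroids per frame; ids stable across frames.

    Single-linkage agglomeration cut at ``cutoff`` µm within each frame;
    cluster ids are propagated frame-to-frame by matching cluster centres
    to the nearest centre of the previous frame (new centres get new ids).
    """
    out = []
    prev_centers: dict[int, np.ndarray] = {}
    next_id = 0
    for pts in centroids_by_time:
        pts = np.asarray(pts, dtype=float).reshape(-1, 3)
        if len(pts) == 0:
            out.append(np.zeros(0, dtype=int))
            continue
        if len(pts) == 1:
            local = np.array([1])
        else:
            Z = linkage(pts, method="single")
            local = fcluster(Z, t=cutoff, criterion="distance")
        ids = np.zeros(len(pts), dtype=int)
        centers = {}
        used = set()
        for c in np.unique(local):
            center = pts[local == c].mean(axis=0)
            best, best_d = None, np.inf
            for sid, pc in prev_centers.items():
                if sid in used:
                    continue
                d = np.linalg.norm(center - pc)
                if d < best_d:
                    best, best_d = sid, d
            if best is not None and best_d <= cutoff:
                sid = best
                used.add(sid)
            else:
                sid = next_id
                next_id += 1
            ids[local == c] = sid
            centers[sid] = center
        prev_centers = centers
        out.append(ids)
    return out


def track_nuclei(frames, max_gate: float = 10.0):
    """Greedy mutual-nearest-neighbour tracking over consecutive frames.

    ``frames`` is a list (per timepoint) of NucleusRecord lists.  Unmatched
    nuclei start new tracks; when several new nuclei appear near a track
    that just ended (a division), the children record that parent track.
    """
    tracks: list[Track] = []
    active: dict[int, Track] = {}  # nucleus row index in prev frame -> track
    prev_records = None

    for t, recs in enumerate(frames):
        pts = np.array([r.centroid for r in recs]).reshape(-1, 3)
        if prev_records is None:
            for i, r in enumerate(recs):
                tr = Track(track_id=len(tracks), steps=[(t, r.nucleus_id)])
                tracks.append(tr)
                active[i] = tr
            prev_records = recs
            continue

        prev_pts = np.array([r.centroid for r in prev_records]).reshape(-1, 3)
        matched_prev, matched_cur = set(), set()
        pairs = []
        if len(pts) and len(prev_pts):
            d = np.linalg.norm(prev_pts[:, None, :] - pts[None, :, :], axis=-1)
            fwd = d.argmin(axis=1)
            bwd = d.argmin(axis=0)
            for i in range(len(prev_pts)):
                j = fwd[i]
                if bwd[j] == i and d[i, j] <= max_gate:
                    pairs.append((i, j, d[i, j]))
        new_active: dict[int, Track] = {}
        linked_to: dict[int, int] = {}  # prev index -> current index
        for i, j, dist in pairs:
            tr = active[i]
            tr.steps.append((t, recs[j].nucleus_id))
            tr.displacements.append(float(dist))
            new_active[j] = tr
            matched_prev.add(i)
            matched_cur.add(j)
            linked_to[i] = j
        # division resolution: an unmatched new nucleus near a previous
        # nucleus signals a division.  If that mother vanished, the child
        # adopts her track as parent; if she was linked onward to another
        # nucleus, that link is reinterpreted as the sibling — the mother
        # track ends and both children record it as parent.
        divided: set[int] = set()
        for j, r in enumerate(recs):
            if j in matched_cur:
                continue
            parent = None
            if len(prev_pts):
                dists = np.linalg.norm(prev_pts - pts[j], axis=1)
                i_best = int(np.argmin(dists))
                if dists[i_best] <= max_gate:
                    mother = active[i_best]
                    if i_best in divided or i_best not in matched_prev:
                        parent = mother.track_id
                    else:
                        j2 = linked_to[i_best]
                        mother.steps.pop()
                        mother.displacements.pop()
                        sibling = Track(track_id=len(tracks),
                                        steps=[(t, recs[j2].nucleus_id)],
                                        parent_track_id=mother.track_id)
                        tracks.append(sibling)
                        new_active[j2] = sibling
                        divided.add(i_best)
                        parent = mother.track_id
            tr = Track(track_id=len(tracks), steps=[(t, r.nucleus_id)],
                       parent_track_id=parent)
            tracks.append(tr)
            new_active[j] = tr
        active = new_active
        prev_records = recs

    # annotate spheroid membership (majority vote over member records)
    by_key = {}
    for t, recs in enumerate(frames):
        for r in recs:
            by_key[(t, r.nucleus_id)] = r
    for tr in tracks:
        sids = [by_key[s].spheroid_id for s in tr.steps
                if by_key[s].spheroid_id is not None]
        if sids:
            vals, counts = np.unique(sids, return_counts=True)
            tr.spheroid_id = int(vals[counts.argmax()])
    return tracks


def migration_speed(tracks, frame_interval: float):
    """Median migration speed (µm/min) per spheroid over all track steps."""
    steps_by_sph: dict = {}
    for tr in tracks:
        for d in tr.displacements:
            steps_by_sph.setdefault(tr.spheroid_id, []).append(d / frame_interval)
    return {sid: float(np.median(v)) for sid, v in steps_by_sph.items() if v}


def radial_distances(frames):
    """Distance of each nucleus to its spheroid's centre at that frame.

    The centre is the mean of member nucleus centroids.  Fills each
    record's ``radial_distance_um`` and returns the per-frame arrays.
    """
    out = []
    for recs in frames:
        if not recs:
            out.append(np.zeros(0))
            continue
        sids = np.array([r.spheroid_id for r in recs])
        pts = np.array([r.centroid for r in recs])
        dist = np.zeros(len(recs))
        for s in np.unique(sids):
            m = sids == s
            center = pts[m].mean(axis=0)
            dist[m] = np.linalg.norm(pts[m] - center, axis=1)
        for r, d in zip(recs, dist):
            r.radial_distance_um = float(d)
        out.append(dist)
    return out


def phase_fractions(phases, class_order=PHASE_CLASSES_4):
    """Fraction of nucleus-frames per phase; fractions sum to 1."""
    phases = list(phases)
    if not phases:
        raise ValueError("no classified nucleus-frames")
    n = len(phases)
    return {c: sum(p == c for p in phases) / n for c in class_order}


def detect_transitions(tracks, phase_by_key):
    """Cell-cycle transition events along tracks, flagged for validity.

    ``phase_by_key`` maps ``(timepoint, nucleus_id)`` to a phase call.
    Consecutive differing calls emit an event; a track that ends in a
    division emits an ``(last phase, "division")`` event.  Events outside
    :data:`VALID_TRANSITIONS` are flagged improper.  Returns
    ``(events DataFrame, summary dict)`` where the summary counts both
    events and affected nuclei.
    """
    children_of: dict[int, int] = {}
    for tr in tracks:
        if tr.parent_track_id is not None:
            children_of[tr.parent_track_id] = children_of.get(tr.parent_track_id, 0) + 1

    rows = []
    for tr in tracks:
        calls = [(t, phase_by_key.get((t, nid))) for t, nid in tr.steps]
        calls = [(t, p) for t, p in calls if p is not None]
        for (t0, p0), (t1, p1) in zip(calls, calls[1:]):
            if p0 != p1:
                rows.append(dict(track_id=tr.track_id, timepoint=t1,
                                 from_phase=p0, to_phase=p1,
                                 valid=(p0, p1) in VALID_TRANSITIONS))
        if children_of.get(tr.track_id, 0) >= 1 and calls:
            p_last = calls[-1][1]
            rows.append(dict(track_id=tr.track_id, timepoint=calls[-1][0],
                             from_phase=p_last, to_phase="division",
                             valid=(p_last, "division") in VALID_TRANSITIONS))
    events = pd.DataFrame(rows, columns=["track_id", "timepoint", "from_phase",
                                         "to_phase", "valid"])
    summary = {
        "n_transitions": int(len(events)),
        "n_improper": int((~events["valid"]).sum()) if len(events) else 0,
        "n_nuclei_with_transition": int(events["track_id"].nunique()) if len(events) else 0,
        "n_nuclei_with_improper": int(events.loc[~events["valid"], "track_id"].nunique())
        if len(events) else 0,
    }
    return events, summary


def growth_rate(series, params: GrowthRateParams | None = None):
    """Instantaneous growth rate: lowess-smoothed series, first-differenced.

    Locally weighted regression (tricube weights, ``iterations``
    robustifying passes, delta-based point skipping) smooths the count or
    volume series; the returned rates are the first differences of the
    smoothed series (length n−1, units of the series per frame).
    """
    import statsmodels.api as sm

    params = params or GrowthRateParams()
    y = np.asarray(series, dtype=float)
    if len(y) < 4:
        raise ValueError("need at least 4 timepoints")
    x = np.arange(len(y), dtype=float)
    delta = params.delta_fraction * (y.max() - y.min())
    smoothed = sm.nonparametric.lowess(
        y, x, frac=params.f, it=params.iterations, delta=delta, return_sorted=False
    )
    return np.diff(smoothed)


def shape_descriptors(mask: np.ndarray, voxel_size: float):
    """Compactness, convexity and sphericity of a binary spheroid mask.

    * sphericity = π^(1/3) · (6V)^(2/3) / A, surface area A from a
      marching-cubes mesh;
    * convexity = V / V_convex_hull (hull of the voxel corner points, so
      the hull always contains the voxel union);
    * compactness = V / volume of the bounding sphere (centred at the
      centroid, radius = farthest voxel corner — a tight approximation of
      the minimal enclosing sphere for blob-like shapes).
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("empty mask")
    v = float(voxel_size)
    V = mask.sum() * v**3

    padded = np.pad(mask.astype(float), 1)
    verts, faces, *_ = marching_cubes(padded, level=0.5)
    A = mesh_surface_area(verts, faces) * v**2
    sphericity = np.pi ** (1 / 3) * (6 * V) ** (2 / 3) / A

    pts = np.argwhere(mask).astype(float)
    # voxelized hull keeps the discretization of numerator and denominator
    # consistent, so a digital ball scores convexity ~1
    from skimage.morphology import convex_hull_image

    try:
        hull_vox = convex_hull_image(mask, offset_coordinates=False).sum()
        convexity = min(1.0, mask.sum() / hull_vox)
    except Exception:
        convexity = 1.0

    centroid = pts.mean(axis=0)
    r = np.linalg.norm(pts - centroid, axis=1).max() * v
    compactness = V / (4 / 3 * np.pi * r**3)
    return {"compactness": float(compactness), "convexity": float(convexity),
            "sphericity": float(sphericity)}


def spheroid_series(
    frames,
    labels_by_time=None,
    frame_interval: float = 5.0,
    growth_params: GrowthRateParams | None = None,
) -> pd.DataFrame:
    """Per-spheroid per-timepoint feature table.

    Counts, hull volume, shape descriptors (when label volumes are given),
    mean cell volume (spheroid volume / nuclei count) and, appended per
    spheroid, the lowess growth rate of the nuclei count.
    """
    rows = []
    for t, recs in enumerate(frames):
        sids = sorted({r.spheroid_id for r in recs if r.spheroid_id is not None})
        for s in sids:
            members = [r for r in recs if r.spheroid_id == s]
            pts = np.array([r.centroid for r in members])
            row = dict(spheroid_id=s, timepoint=t,
                       center_x_um=pts[:, 0].mean(), center_y_um=pts[:, 1].mean(),
                       center_z_um=pts[:, 2].mean(), n_nuclei=len(members))
            vol = np.nan
            if len(pts) >= 5:
                try:
                    vol = ConvexHull(pts).volume
                except Exception:
                    vol = np.nan
            if labels_by_time is not None:
                lab = labels_by_time[t]
                ids = [r.nucleus_id for r in members]
                m = np.isin(lab.labels, ids)
                if m.any():
                    shp = shape_descriptors(m, lab.voxel_size)
                    row.update(shp)
                    hull_pts = np.argwhere(m) * lab.voxel_size
                    if len(hull_pts) >= 5:
                        vol = ConvexHull(hull_pts).volume
            row["spheroid_volume_um3"] = vol
            row["mean_cell_volume_um3"] = vol / len(members) if np.isfinite(vol) else np.nan
            rows.append(row)
    df = pd.DataFrame(rows).sort_values(["spheroid_id", "timepoint"]).reset_index(drop=True)
    df["growth_rate"] = np.nan
    for s, grp in df.groupby("spheroid_id"):
        counts = grp["n_nuclei"].to_numpy(dtype=float)
        if len(counts) >= 4:
            rates = growth_rate(counts, growth_params)
            df.loc[grp.index[1:], "growth_rate"] = rates
    return df
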