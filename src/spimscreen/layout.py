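"""Plate layout, acquisition accounting and pre-screen spheroid selection.

The screen spots transfection mixtures onto a one-well plate at the
positions of a standard 1536-well grid: each sample occupies a contiguous
2-column × 4-row subarray of 8 spots, 40 columns × 8 rows = 320 spots in
total.  A fast low-resolution stage-scan pre-screen locates candidate
spheroids; small, flat or elongated clusters are excluded and, per
condition, the remaining spheroids with the largest Z coordinate (least
obstructed light path) are selected for high-resolution imaging.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class SpotGrid:
    centers_mm: np.ndarray  # (n, 2) plate coordinates
    n_columns: int
    n_rows: int
    spots_per_sample: int
    pitch_mm: float
    sample_of_spot: np.ndarray  # (n,) sample index per spot

    @property
    def n_spots(self) -> int:
        return self.n_columns * self.n_rows

    @property
    def n_samples(self) -> int:
        return self.n_spots // self.spots_per_sample

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "n_columns": self.n_columns, "n_rows": self.n_rows,
            "spots_per_sample": self.spots_per_sample, "pitch_mm": self.pitch_mm,
            "centers_mm": self.centers_mm.tolist(),
            "sample_of_spot": self.sample_of_spot.tolist(),
        }, indent=2))


@dataclass
class AcquisitionPlan:
    n_positions: int
    n_slices: int
    n_views: int
    width_px: int
    height_px: int
    bytes_per_pixel: int
    n_timepoints: int = 1

    def __post_init__(self) -> None:
        for f in ("n_positions", "n_slices", "n_views", "width_px",
                  "height_px", "bytes_per_pixel", "n_timepoints"):
            if getattr(self, f) < 1:
                raise ValueError(f"{f} must be >= 1")

    @property
    def images_per_pass(self) -> int:
        return self.n_positions * self.n_slices * self.n_views

    @property
    def bytes_per_position_timepoint(self) -> int:
        return (self.n_views * self.width_px * self.height_px
                * self.n_slices * self.bytes_per_pixel)

    @property
    def total_bytes(self) -> int:
        return self.bytes_per_position_timepoint * self.n_positions * self.n_timepoints

    def to_dict(self) -> dict:
        return {
            "n_positions": self.n_positions, "n_slices": self.n_slices,
            "n_views": self.n_views, "width_px": self.width_px,
            "height_px": self.height_px, "bytes_per_pixel": self.bytes_per_pixel,
            "n_timepoints": self.n_timepoints,
            "images_per_pass": self.images_per_pass,
            "bytes_per_position_timepoint": self.bytes_per_position_timepoint,
            "total_bytes": self.total_bytes,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionPlan":
        return cls(**{k: d[k] for k in ("n_positions", "n_slices", "n_views",
                                        "width_px", "height_px",
                                        "bytes_per_pixel", "n_timepoints")})


@dataclass
class PrescreenCandidate:
    centroid_um: tuple
    size_um3: float
    axis_lengths_um: tuple  # principal axes, descending
    spot_id: int = 0
    rank: int | None = None

    @property
    def aspect_ratio(self) -> float:
        a = self.axis_lengths_um
        return a[0] / a[2] if a[2] > 0 else np.inf

    @property
    def flatness(self) -> float:
        """Ratio of the middle to the smallest principal axis."""
        a = self.axis_lengths_um
        return a[1] / a[2] if a[2] > 0 else np.inf


def generate_spot_grid(n_columns: int = 40, n_rows: int = 8,
                       spots_per_sample: int = 8, pitch_mm: float = 2.25) -> SpotGrid:
    """Spot grid with contiguous 2-column × 4-row sample subarrays."""
    if n_columns < 1 or n_rows < 1 or spots_per_sample < 1:
        raise ValueError("counts must be >= 1")
    total = n_columns * n_rows
    if total % spots_per_sample:
        raise ValueError("spots_per_sample must divide the total spot count")
    cols, rows = np.meshgrid(np.arange(n_columns), np.arange(n_rows), indexing="ij")
    centers = np.column_stack([cols.ravel() * pitch_mm, rows.ravel() * pitch_mm])
    sample = np.zeros(total, dtype=int)
    if spots_per_sample == 8 and n_rows % 4 == 0 and n_columns % 2 == 0:
        # 2 cols × 4 rows blocks
        block_c = cols.ravel() // 2
        block_r = rows.ravel() // 4
        sample = (block_c * (n_rows // 4) + block_r).astype(int)
    else:
        sample = np.arange(total) // spots_per_sample
    return SpotGrid(centers, n_columns, n_rows, spots_per_sample, pitch_mm, sample)


def plan_acquisition(**kwargs) -> AcquisitionPlan:
    """Exact-integer acquisition accounting (images and raw bytes)."""
    return AcquisitionPlan(**kwargs)


def select_spheroids(
    candidates_by_condition: dict,
    n_select: int = 1,
    min_size: float = 2e4,
    max_aspect: float = 2.5,
    max_flatness: float = 3.0,
):
    """Pre-screen selection: exclude small/flat/elongated, take largest Z.

    Returns ``(selected, unselectable)``: a mapping condition → chosen
    candidates (ranked by descending Z) and the list of conditions with no
    surviving candidate.
    """
    selected, unselectable = {}, []
    for cond, cands in candidates_by_condition.items():
        ok = [c for c in cands
              if c.size_um3 >= min_size
              and c.aspect_ratio <= max_aspect
              and c.flatness <= max_flatness]
        if not ok:
            unselectable.append(cond)
            continue
        ok.sort(key=lambda c: -c.centroid_um[2])
        for r, c in enumerate(ok):
            c.rank = r + 1
        selected[cond] = ok[:n_select]
    return selected, unselectable


def candidates_to_frame(candidates) -> pd.DataFrame:
    rows = []
    for c in candidates:
        rows.append(dict(
            x_um=c.centroid_um[0], y_um=c.centroid_um[1], z_um=c.centroid_um[2],
            size_um3=c.size_um3, axis_major_um=c.axis_lengths_um[0],
            axis_middle_um=c.axis_lengths_um[1], axis_minor_um=c.axis_lengths_um[2],
            aspect_ratio=c.aspect_ratio, flatness=c.flatness,
            spot_id=c.spot_id, rank=c.rank,
        ))
    return pd.DataFrame(rows)
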