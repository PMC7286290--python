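"""3D affine transforms between the two light-sheet views.

A transform maps view-B world coordinates (x, y, z, µm) into the view-A
frame: ``p_A = matrix @ p_B + translation``.  The dual-view geometry puts
the second objective at 90° to the first, so the nominal calibration is a
quarter-turn about the Y axis; bead registration refines it to a full
affine (absorbing stage translation and small calibration scale errors).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


@dataclass
class AffineTransform3D:
    matrix: np.ndarray
    translation: np.ndarray
    residual_rms: float = 0.0
    n_correspondences: int = 0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if abs(np.linalg.det(self.matrix)) < 1e-9:
            raise ValueError("linear part is singular")

    @classmethod
    def identity(cls) -> "AffineTransform3D":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points_xyz: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points_xyz, dtype=float))
        out = p @ self.matrix.T + self.translation
        return out if np.asarray(points_xyz).ndim == 2 else out[0]

    def inverse(self) -> "AffineTransform3D":
        inv = np.linalg.inv(self.matrix)
        return AffineTransform3D(inv, -inv @ self.translation)

    def compose(self, other: "AffineTransform3D") -> "AffineTransform3D":
        """Return the transform ``self ∘ other`` (apply ``other`` first)."""
        return AffineTransform3D(
            self.matrix @ other.matrix,
            self.matrix @ other.translation + self.translation,
        )

    # --- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "matrix_row_major": self.matrix.ravel().tolist(),
            "translation_um": self.translation.tolist(),
            "residual_rms_um": float(self.residual_rms),
            "n_correspondences": int(self.n_correspondences),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AffineTransform3D":
        t = cls(
            np.array(d["matrix_row_major"], dtype=float).reshape(3, 3),
            np.array(d["translation_um"], dtype=float),
        )
        t.residual_rms = float(d.get("residual_rms_um", 0.0))
        t.n_correspondences = int(d.get("n_correspondences", 0))
        return t

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def read_json(cls, path: str | Path) -> "AffineTransform3D":
        return cls.from_dict(json.loads(Path(path).read_text()))


def rotation_about_axis(axis: str, degrees: float) -> np.ndarray:
    """Right-handed rotation matrix about a world axis ('x', 'y' or 'z')."""
    th = np.deg2rad(degrees)
    c, s = np.cos(th), np.sin(th)
    if axis == "x":
        return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])
    if axis == "y":
        return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])
    if axis == "z":
        return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])
    raise ValueError(f"unknown axis {axis!r}")


def nominal_view_rotation(center_xyz=None) -> AffineTransform3D:
    """Nominal B→A transform: 90° about Y, optionally about a pivot point.

    With a pivot at the volume centre a cubic field of view maps onto
    itself, which is how the synthetic scenes are laid out.
    """
    R = rotation_about_axis("y", 90.0)
    if center_xyz is None:
        t = np.zeros(3)
    else:
        c = np.asarray(center_xyz, dtype=float)
        t = c - R @ c
    return AffineTransform3D(R, t)
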