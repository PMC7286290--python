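"""Volume containers and TIFF input/output.

Conventions used throughout the package:

* arrays are indexed ``(Z, Y, X)`` (the axis order tifffile reads/writes);
* world coordinates are right-handed ``(x, y, z)`` vectors in micrometres;
* voxel ``(iz, iy, ix)`` has its centre at ``(ix*vx, iy*vy, iz*vz)`` µm,
  0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile


@dataclass
class VolumeStack:
    """One 3D intensity stack plus its acquisition metadata.

    Parameters
    ----------
    data:
        3D array, ``(Z, Y, X)`` axis order.
    voxel_size:
        ``(vx, vy, vz)`` voxel edge lengths in µm.
    view:
        View tag, typically ``"A"`` or ``"B"``.
    timepoint:
        Frame index within a time lapse.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    view: str = "A"
    timepoint: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("VolumeStack requires a 3D array")
        vx, vy, vz = self.voxel_size
        if min(vx, vy, vz) <= 0:
            raise ValueError("voxel sizes must be positive")
        self.voxel_size = (float(vx), float(vy), float(vz))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def is_isotropic(self) -> bool:
        vx, vy, vz = self.voxel_size
        return abs(vx - vy) < 1e-9 and abs(vy - vz) < 1e-9

    def world_extent(self) -> np.ndarray:
        """Upper corner (x, y, z) of the sampled region in µm."""
        nz, ny, nx = self.data.shape
        vx, vy, vz = self.voxel_size
        return np.array([(nx - 1) * vx, (ny - 1) * vy, (nz - 1) * vz])

    def world_to_index(self, points_xyz: np.ndarray) -> np.ndarray:
        """Map world (x, y, z) µm points to fractional (z, y, x) indices."""
        p = np.atleast_2d(np.asarray(points_xyz, dtype=float))
        vx, vy, vz = self.voxel_size
        idx = np.column_stack([p[:, 2] / vz, p[:, 1] / vy, p[:, 0] / vx])
        return idx if np.asarray(points_xyz).ndim == 2 else idx[0]

    def index_to_world(self, idx_zyx: np.ndarray) -> np.ndarray:
        """Map fractional (z, y, x) indices to world (x, y, z) µm points."""
        i = np.atleast_2d(np.asarray(idx_zyx, dtype=float))
        vx, vy, vz = self.voxel_size
        pts = np.column_stack([i[:, 2] * vx, i[:, 1] * vy, i[:, 0] * vz])
        return pts if np.asarray(idx_zyx).ndim == 2 else pts[0]

    def copy_with(self, data: np.ndarray) -> "VolumeStack":
        return replace(self, data=data)

    # --- IO -------------------------------------------------------------

    def write_tiff(self, path: str | Path) -> None:
        vx, vy, vz = self.voxel_size
        tifffile.imwrite(
            str(path),
            self.data,
            metadata={
                "axes": "ZYX",
                "voxel_size_um": [vx, vy, vz],
                "view": self.view,
                "timepoint": int(self.timepoint),
            },
        )


def read_tiff(path: str | Path, voxel_size=None, view="A", timepoint=0) -> VolumeStack:
    """Read a stack written by :meth:`VolumeStack.write_tiff`.

    ``voxel_size`` overrides metadata when given (plain TIFFs carry none).
    """
    with tifffile.TiffFile(str(path)) as tif:
        data = tif.asarray()
        meta = tif.shaped_metadata[0] if tif.shaped_metadata else {}
    if voxel_size is None:
        voxel_size = tuple(meta.get("voxel_size_um", (1.0, 1.0, 1.0)))
    view = meta.get("view", view)
    timepoint = int(meta.get("timepoint", timepoint))
    if data.ndim == 2:
        data = data[None]
    return VolumeStack(data=data, voxel_size=tuple(voxel_size), view=view, timepoint=timepoint)


@dataclass
class FusedVolume:
    """Fused (optionally deconvolved) volume on an isotropic grid."""

    data: np.ndarray
    voxel_size: float
    iterations: int = 0
    fit_log: list = field(default_factory=list)
    validity: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("FusedVolume requires a 3D array")
        if self.voxel_size <= 0:
            raise ValueError("voxel size must be positive")

    def as_stack(self) -> VolumeStack:
        v = float(self.voxel_size)
        return VolumeStack(self.data, (v, v, v), view="fused")
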