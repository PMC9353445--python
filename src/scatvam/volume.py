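"""Voxel volumes and vial geometry.

The third array axis is the vial rotation axis (vertical).  All physical
lengths are in millimetres; voxel grids are isotropic.  Voxel centers sit at
``origin + (index + 0.5) * pitch``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["VoxelVolume", "VialGeometry"]


@dataclass
class VoxelVolume:
    """3D scalar grid with physical voxel pitch.

    Parameters
    ----------
    values
        3D array of nonnegative reals; binary occupancy volumes contain only
        {0, 1}.  Axis 2 is the vial rotation axis.
    pitch
        Voxel edge length in mm (isotropic, > 0).
    origin
        Physical coordinate of the grid corner in mm.
    """

    values: np.ndarray
    pitch: float
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"values must be 3D, got ndim={self.values.ndim}")
        if not self.pitch > 0:
            raise ValueError(f"pitch must be > 0, got {self.pitch}")
        if self.values.size and float(self.values.min()) < 0:
            raise ValueError("voxel values must be nonnegative")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def is_binary(self) -> bool:
        v = self.values
        return bool(np.isin(np.unique(v), (0, 1)).all())

    def center_xy(self) -> tuple[float, float]:
        """Physical (x, y) of the in-plane grid center, mm."""
        nx, ny = self.shape[0], self.shape[1]
        return (
            self.origin[0] + 0.5 * nx * self.pitch,
            self.origin[1] + 0.5 * ny * self.pitch,
        )

    def xy_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical coordinates of voxel centers along axes 0 and 1."""
        nx, ny = self.shape[0], self.shape[1]
        x = self.origin[0] + (np.arange(nx) + 0.5) * self.pitch
        y = self.origin[1] + (np.arange(ny) + 0.5) * self.pitch
        return x, y

    def copy(self, values: np.ndarray | None = None) -> "VoxelVolume":
        return VoxelVolume(
            self.values.copy() if values is None else values,
            self.pitch,
            self.origin,
        )

    # -- serialization: multi-page TIFF (one page per slice along axis 2)
    #    plus a JSON sidecar --------------------------------------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        pages = np.moveaxis(self.values, 2, 0)
        tifffile.imwrite(path, pages, photometric="minisblack")
        sidecar = {
            "pitch_mm": self.pitch,
            "origin_mm": list(self.origin),
            "axis_order": "xyz",
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "VoxelVolume":
        path = Path(path)
        pages = tifffile.imread(path)
        if pages.ndim == 2:
            pages = pages[None]
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(
            np.moveaxis(pages, 0, 2),
            float(meta["pitch_mm"]),
            tuple(meta["origin_mm"]),
        )


@dataclass
class VialGeometry:
    """Cylindrical print container rotating about the vertical axis.

    ``axis_xy`` is the (x, y) position of the rotation axis in the grid's
    physical coordinates; ``None`` means the in-plane center of the volume.
    """

    inner_diameter: float
    axis_xy: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not self.inner_diameter > 0:
            raise ValueError("inner_diameter must be > 0")

    @property
    def radius(self) -> float:
        return 0.5 * self.inner_diameter

    def axis_for(self, volume: VoxelVolume) -> tuple[float, float]:
        if self.axis_xy is not None:
            return self.axis_xy
        return volume.center_xy()

    def radial_distance(self, volume: VoxelVolume) -> np.ndarray:
        """In-plane distance (mm) of each (x, y) voxel center from the axis."""
        ax, ay = self.axis_for(volume)
        x, y = volume.xy_centers()
        return np.hypot(x[:, None] - ax, y[None, :] - ay)
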