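"""Voxelized scalar volumes with physical spacing.

Axis convention: ``values[ix, iy, iz]`` with X the anteroposterior axis
and Y the left-right axis in the transverse plane; the third axis is
cranio-caudal.  The centre of rotation of the camera orbit sits at the
physical origin, which by default is the centre of the grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VoxelVolume"]


@dataclass
class VoxelVolume:
    """A 3D scalar field (activity, attenuation in cm^-1, or image intensity).

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
    spacing : per-axis voxel size in mm
    origin : physical coordinate (mm) of the centre of voxel (0, 0, 0)
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3D array")
        self.spacing = tuple(float(s) for s in np.broadcast_to(self.spacing, (3,)))
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite values")
        if self.origin is None:
            # grid centre at the physical origin (centre of rotation)
            self.origin = tuple(
                -(n - 1) / 2.0 * s for n, s in zip(self.values.shape, self.spacing)
            )
        else:
            self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def axis_coordinates(self, axis: int) -> np.ndarray:
        """Physical coordinates (mm) of voxel centres along one axis."""
        n = self.values.shape[axis]
        return self.origin[axis] + np.arange(n) * self.spacing[axis]

    def index_of(self, point_mm) -> tuple[int, int, int]:
        """Nearest voxel index of a physical point."""
        p = np.asarray(point_mm, dtype=float)
        idx = np.round((p - np.asarray(self.origin)) / np.asarray(self.spacing))
        return tuple(int(i) for i in idx)

    def copy_with(self, values: np.ndarray, **meta) -> "VoxelVolume":
        return VoxelVolume(values, self.spacing, self.origin, {**self.meta, **meta})

    def same_grid(self, other: "VoxelVolume") -> bool:
        return (
            self.values.shape == other.values.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    def total(self) -> float:
        """Sum of voxel values times voxel volume (mm^3)."""
        return float(self.values.sum() * self.voxel_volume_mm3)
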