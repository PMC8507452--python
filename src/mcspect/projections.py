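"""Projection data container shared by the analytic and Monte Carlo projectors."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ProjectionSet", "add_raw"]


@dataclass
class ProjectionSet:
    """A stack of 2D detector frames, one per projection angle.

    ``frames`` has shape (n_views, n_u, n_z) where u is the transverse
    detector coordinate and z the axial one.  Values are counts (analog
    acquisitions) or expected counts (noise-free forward projections).
    """

    frames: np.ndarray
    angles_deg: np.ndarray
    orbit_radius_mm: float
    pixel_size_mm: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must have shape (n_views, n_u, n_z)")
        if len(self.frames) != len(self.angles_deg):
            raise ValueError("frame count must match angle count")
        if np.any(self.frames < 0):
            raise ValueError("projection data must be non-negative")

    @property
    def n_views(self) -> int:
        return len(self.frames)

    def total_counts(self) -> float:
        return float(self.frames.sum())

    def geometry_matches(self, other: "ProjectionSet") -> bool:
        return (
            self.frames.shape == other.frames.shape
            and np.allclose(self.angles_deg, other.angles_deg)
            and np.isclose(self.orbit_radius_mm, other.orbit_radius_mm)
            and np.isclose(self.pixel_size_mm, other.pixel_size_mm)
        )


def add_raw(background: ProjectionSet, lesion: ProjectionSet) -> ProjectionSet:
    """Frame-wise sum of two raw data sets (projection-space lesion insertion)."""
    if not background.geometry_matches(lesion):
        raise ValueError("projection geometries do not match")
    return ProjectionSet(
        background.frames + lesion.frames,
        background.angles_deg.copy(),
        background.orbit_radius_mm,
        background.pixel_size_mm,
        meta={
            "background": background.meta,
            "lesion": lesion.meta,
            "combined": True,
        },
    )
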