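"""Synthetic phantoms: triple-line resolution insert and liver background.

Everything downstream (projection simulation, reconstruction and the
measurement layer) runs on these generated volumes, so no external data
are needed.  The triple-line phantom holds three ~1 mm capillary line
sources inside a water-filled Jaszczak-style cylinder (or in air); the
liver phantom is a water-equivalent elliptical-cylinder torso with an
ellipsoidal liver compartment into which a small spherical lesion can be
inserted at a prescribed tumour-to-normal concentration (TNC) ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .materials import attenuation_coefficient
from .volume import VoxelVolume

__all__ = [
    "LineSourceSpec",
    "LesionSpec",
    "DEFAULT_LINE_SPECS",
    "make_grid",
    "make_cylinder_attenuation",
    "make_triple_line_activity",
    "make_liver_phantom",
    "place_lesion",
    "lesion_activity",
    "lesion_sphere_offsets",
]


@dataclass(frozen=True)
class LineSourceSpec:
    """A thin axial line source in the transverse plane.

    ``center_xy`` is the (X, Y) position in mm relative to the centre of
    rotation; X is anteroposterior, Y left-right.
    """

    label: str
    center_xy: tuple[float, float]
    diameter_mm: float = 1.0
    axis_extent_mm: float = 100.0

    def __post_init__(self):
        if self.diameter_mm <= 0:
            raise ValueError("line diameter must be positive")

    @property
    def radial_distance_mm(self) -> float:
        return float(np.hypot(*self.center_xy))


# The camera's centre of rotation sits ~2 cm from line A; B and C are
# placed to give three distinct radial distances in a triangular layout.
DEFAULT_LINE_SPECS = (
    LineSourceSpec("A", (0.0, 20.0)),
    LineSourceSpec("B", (-40.0, 45.0)),
    LineSourceSpec("C", (45.0, 50.0)),
)


@dataclass(frozen=True)
class LesionSpec:
    """A small spherical lesion inside the liver mask."""

    center_voxel: tuple[int, int, int]
    radius_voxels: int = 1
    tnc_true: float = 8.0

    def __post_init__(self):
        if self.radius_voxels < 1:
            raise ValueError("lesion radius must be at least one voxel")
        if self.tnc_true <= 0:
            raise ValueError("TNC ratio must be positive")


def make_grid(n: int = 64, nz: int = 32, spacing_mm: float = 4.42) -> VoxelVolume:
    """An empty square-transverse grid centred on the centre of rotation."""
    return VoxelVolume(np.zeros((n, n, nz)), (spacing_mm, spacing_mm, spacing_mm))


def make_cylinder_attenuation(
    radius_mm: float,
    length_mm: float,
    grid: VoxelVolume,
    medium: str = "water",
    energy_keV: float = 171.0,
) -> VoxelVolume:
    """Attenuation map of a water- or air-filled cylinder centred on the CoR.

    Voxels whose centre lies inside the cylinder (boundary inclusive)
    receive the linear attenuation coefficient of the medium at the given
    emission energy; everything else gets the (negligible) value of air.
    """
    if radius_mm <= 0 or length_mm <= 0:
        raise ValueError("cylinder radius and length must be positive")
    if medium not in ("water", "air"):
        raise ValueError(f"unknown medium {medium!r}")
    mu_medium = float(attenuation_coefficient(medium, energy_keV))
    mu_air = float(attenuation_coefficient("air", energy_keV))
    x = grid.axis_coordinates(0)[:, None, None]
    y = grid.axis_coordinates(1)[None, :, None]
    z = grid.axis_coordinates(2)[None, None, :]
    inside = (x**2 + y**2 <= radius_mm**2) & (np.abs(z) <= length_mm / 2.0)
    values = np.where(inside, mu_medium, mu_air)
    return grid.copy_with(values, kind="attenuation", energy_keV=float(energy_keV))


def _disc_fractions(grid: VoxelVolume, center_xy, diameter_mm, supersample=16):
    """Per-voxel area fractions of a transverse disc, normalised to unit sum."""
    dx, dy = grid.spacing[0], grid.spacing[1]
    cx, cy = center_xy
    r = diameter_mm / 2.0
    xs = grid.axis_coordinates(0)
    ys = grid.axis_coordinates(1)
    ix = np.where(np.abs(xs - cx) <= r + dx)[0]
    iy = np.where(np.abs(ys - cy) <= r + dy)[0]
    if ix.size == 0 or iy.size == 0:
        raise ValueError(f"line centre {center_xy} outside the grid")
    # supersample candidate voxels to anti-alias the sub-voxel disc
    off = (np.arange(supersample) + 0.5) / supersample - 0.5
    w = np.zeros((ix.size, iy.size))
    for a, i in enumerate(ix):
        sx = xs[i] + off * dx
        for b, j in enumerate(iy):
            sy = ys[j] + off * dy
            inside = (sx[:, None] - cx) ** 2 + (sy[None, :] - cy) ** 2 <= r**2
            w[a, b] = inside.mean()
    total = w.sum()
    if total <= 0:
        raise ValueError(f"line at {center_xy} does not overlap any voxel")
    return ix, iy, w / total


def make_triple_line_activity(
    specs,
    activity_per_mm: float,
    grid: VoxelVolume,
    supersample: int = 16,
) -> VoxelVolume:
    """Rasterize line sources with sub-voxel area weighting.

    Each line contributes ``activity_per_mm * axis_extent`` in total
    (relative units), distributed over the transverse voxels it overlaps
    and constant over the axial slices it spans; normalisation makes the
    rasterized total exact.
    """
    specs = list(specs)
    if not specs:
        raise ValueError("need at least one line source")
    if len({s.label for s in specs}) != len(specs):
        raise ValueError("line labels must be unique")
    values = np.zeros(grid.shape)
    z = grid.axis_coordinates(2)
    dz = grid.spacing[2]
    for spec in specs:
        ix, iy, w = _disc_fractions(grid, spec.center_xy, spec.diameter_mm, supersample)
        half = spec.axis_extent_mm / 2.0
        # axial overlap length of each slice with the line extent
        overlap = np.clip(
            np.minimum(z + dz / 2.0, half) - np.maximum(z - dz / 2.0, -half), 0.0, dz
        )
        per_slice = activity_per_mm * overlap  # activity per slice
        values[np.ix_(ix, iy)] += w[:, :, None] * per_slice[None, None, :]
    return grid.copy_with(values, kind="activity")


def make_liver_phantom(
    grid: VoxelVolume,
    background_conc: float = 1.0,
    liver_conc: float = 3.0,
    torso_semiaxes_mm: tuple[float, float] = (90.0, 130.0),
    liver_center_mm: tuple[float, float, float] = (20.0, -45.0, 0.0),
    liver_semiaxes_mm: tuple[float, float, float] = (45.0, 55.0, 50.0),
    energy_keV: float = 171.0,
):
    """Torso background with an ellipsoidal liver compartment.

    Returns ``(activity, mu, liver_mask)``.  The torso is an elliptical
    cylinder of water-equivalent attenuation holding ``background_conc``;
    the liver region holds ``liver_conc`` (octreotide accumulates in the
    liver, so normally ``liver_conc >= background_conc``).
    """
    if not liver_conc >= background_conc >= 0:
        raise ValueError("need liver_conc >= background_conc >= 0")
    x = grid.axis_coordinates(0)[:, None, None]
    y = grid.axis_coordinates(1)[None, :, None]
    z = grid.axis_coordinates(2)[None, None, :]
    ax, ay = torso_semiaxes_mm
    torso = (x / ax) ** 2 + (y / ay) ** 2 <= 1.0
    torso = np.broadcast_to(torso, grid.shape).copy()
    lx, ly, lz = liver_center_mm
    sx, sy, sz = liver_semiaxes_mm
    liver = ((x - lx) / sx) ** 2 + ((y - ly) / sy) ** 2 + ((z - lz) / sz) ** 2 <= 1.0
    liver &= torso
    activity = np.where(liver, liver_conc, np.where(torso, background_conc, 0.0))
    mu_water = float(attenuation_coefficient("water", energy_keV))
    mu_air = float(attenuation_coefficient("air", energy_keV))
    mu = np.where(torso, mu_water, mu_air)
    return (
        grid.copy_with(activity, kind="activity"),
        grid.copy_with(mu, kind="attenuation", energy_keV=float(energy_keV)),
        liver,
    )


def lesion_sphere_offsets(radius_voxels: int = 1) -> np.ndarray:
    """Voxel offsets whose centres lie within ``radius_voxels`` pitches.

    For radius 1 this is the 7-voxel 3D cross (centre plus the six face
    neighbours).
    """
    r = int(radius_voxels)
    rng = np.arange(-r, r + 1)
    dx, dy, dz = np.meshgrid(rng, rng, rng, indexing="ij")
    inside = dx**2 + dy**2 + dz**2 <= r**2
    return np.stack([dx[inside], dy[inside], dz[inside]], axis=1)


def place_lesion(
    liver_mask: np.ndarray,
    rng_seed: int,
    radius_voxels: int = 1,
    tnc_true: float = 8.0,
    margin_voxels: int = 2,
) -> LesionSpec:
    """Sample a lesion centre uniformly over the admissible liver voxels.

    Admissible centres are liver voxels whose ``radius + margin``
    neighbourhood lies inside the mask, so that both the lesion and the
    surrounding normal-tissue measurement shell sit in liver tissue.
    """
    if not np.any(liver_mask):
        raise ValueError("empty liver mask")
    size = 2 * (radius_voxels + margin_voxels) + 1
    admissible = ndimage.binary_erosion(
        liver_mask, structure=np.ones((size, size, size), dtype=bool)
    )
    centers = np.argwhere(admissible)
    if centers.size == 0:
        raise ValueError("no admissible lesion centre inside the liver mask")
    rng = np.random.default_rng(rng_seed)
    center = centers[rng.integers(len(centers))]
    return LesionSpec(tuple(int(c) for c in center), radius_voxels, tnc_true)


def lesion_activity(
    spec: LesionSpec, background_conc: float, grid: VoxelVolume
) -> VoxelVolume:
    """Excess activity realising the TNC ratio when added to the background.

    The lesion volume holds ``(tnc_true - 1) * background_conc`` over the
    sphere's voxels so that background + excess has concentration
    ``tnc_true * background_conc`` there.
    """
    values = np.zeros(grid.shape)
    excess = (spec.tnc_true - 1.0) * background_conc
    for off in lesion_sphere_offsets(spec.radius_voxels):
        idx = tuple(np.asarray(spec.center_voxel) + off)
        if not all(0 <= i < n for i, n in zip(idx, grid.shape)):
            raise ValueError("lesion sphere extends outside the grid")
        values[idx] = excess
    return grid.copy_with(values, kind="activity", lesion=spec.center_voxel)
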