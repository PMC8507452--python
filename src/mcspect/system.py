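"""Camera, collimator and acquisition protocol description.

Defaults emulate a dual-window In-111 acquisition on a NaI(Tl) camera
with a medium-energy parallel-hole collimator: 20% energy windows at
171 and 245 keV, 15.9 mm crystal, 2.21 mm detector pixels.  Collimator
hole dimensions are not part of the acquisition record and use typical
medium-energy general-purpose values; all of them are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .materials import attenuation_coefficient

__all__ = [
    "SystemModel",
    "AcquisitionProtocol",
    "PsfModel",
    "energy_window_bounds",
    "projection_angles",
    "default_system",
    "default_protocol",
    "IN111_EMISSION_LINES",
]

_FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))

# In-111 gamma emissions: (energy keV, photons per decay)
IN111_EMISSION_LINES = ((171.28, 0.907), (245.35, 0.941))


def energy_window_bounds(center_keV: float, width_fraction: float) -> tuple[float, float]:
    """Bounds of a symmetric fractional energy window, e.g. 20% at 171 keV."""
    if not 0.0 < width_fraction < 1.0:
        raise ValueError("window width fraction must be in (0, 1)")
    half = 0.5 * width_fraction * center_keV
    return (center_keV - half, center_keV + half)


def projection_angles(n_projections: int, start_deg: float = 0.0) -> np.ndarray:
    """Evenly spaced projection angles over 360 degrees."""
    if n_projections < 1:
        raise ValueError("need at least one projection")
    return start_deg + np.arange(n_projections) * (360.0 / n_projections)


@dataclass(frozen=True)
class SystemModel:
    """Gamma camera geometry and response parameters."""

    intrinsic_fwhm_mm: float = 3.9
    hole_diameter_mm: float = 3.0
    hole_length_mm: float = 58.0
    septal_thickness_mm: float = 1.05
    crystal_thickness_mm: float = 15.9
    pixel_size_mm: float = 2.21
    matrix: tuple[int, int] = (256, 256)
    energy_resolution_140keV: float = 0.098  # FWHM/E, scales as 1/sqrt(E)
    sensitivity: float = 1.0  # overall counts scale factor

    def __post_init__(self):
        for name in (
            "intrinsic_fwhm_mm",
            "hole_diameter_mm",
            "hole_length_mm",
            "septal_thickness_mm",
            "crystal_thickness_mm",
            "pixel_size_mm",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.energy_resolution_140keV < 0.3:
            raise ValueError("energy resolution fraction must be in (0, 0.3)")

    @property
    def septal_mu_cm(self) -> float:
        """Linear attenuation of the lead septa at 171 keV."""
        return float(attenuation_coefficient("lead", 171.0))

    @property
    def effective_hole_length_mm(self) -> float:
        """Hole length corrected for septal penetration, L - 2/mu."""
        return self.hole_length_mm - 2.0 / self.septal_mu_cm * 10.0

    @property
    def acceptance_half_angle_rad(self) -> float:
        """Half-angle of the collimator acceptance cone.

        tan(theta) = D / (sqrt(3) L_eff): a uniform cone of this half-angle
        projected to a plane at distance d is a disc whose 1D profile has
        FWHM sqrt(3) d tan(theta) = d D / L_eff, matching the
        distance-dependent part of the standard parallel-hole response
        FWHM D (L_eff + d) / L_eff that the PSF model uses.
        """
        return float(
            np.arctan(
                self.hole_diameter_mm / (np.sqrt(3.0) * self.effective_hole_length_mm)
            )
        )

    def geometric_acceptance(self) -> float:
        """Fraction of isotropic photons inside the acceptance cone."""
        return 0.5 * (1.0 - np.cos(self.acceptance_half_angle_rad))

    def collimator_fwhm_mm(self, distance_mm):
        d = np.asarray(distance_mm, dtype=float)
        if np.any(d < 0):
            raise ValueError("distance must be non-negative")
        l_eff = self.effective_hole_length_mm
        return self.hole_diameter_mm * (l_eff + d) / l_eff

    def system_fwhm_mm(self, distance_mm):
        """Combined intrinsic (+) geometric collimator FWHM at distance d."""
        return np.sqrt(
            self.intrinsic_fwhm_mm**2 + self.collimator_fwhm_mm(distance_mm) ** 2
        )

    def energy_sigma_keV(self, energy_keV):
        """Gaussian sigma of the measured energy at a given photon energy."""
        e = np.asarray(energy_keV, dtype=float)
        frac = self.energy_resolution_140keV * np.sqrt(140.0 / e)
        return frac * e / _FWHM_PER_SIGMA


@dataclass(frozen=True)
class PsfModel:
    """Distance-dependent Gaussian response sigma(d) of a system."""

    system: SystemModel

    def sigma_at(self, distance_mm):
        return self.system.system_fwhm_mm(distance_mm) / _FWHM_PER_SIGMA


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Orbit and energy-window settings of one SPECT acquisition."""

    n_projections: int = 120
    orbit_radius_mm: float = 250.0
    frame_duration_s: float = 30.0
    energy_windows: tuple = ((171.28, 0.20), (245.35, 0.20))
    emission_lines: tuple = IN111_EMISSION_LINES
    start_angle_deg: float = 0.0

    def __post_init__(self):
        if self.n_projections < 1:
            raise ValueError("need at least one projection")
        for _, width in self.energy_windows:
            if not 0.0 < width < 1.0:
                raise ValueError("degenerate energy window")
        for _, intensity in self.emission_lines:
            if not 0.0 < intensity <= 1.0:
                raise ValueError("emission intensity must be in (0, 1]")

    @property
    def angles_deg(self) -> np.ndarray:
        return projection_angles(self.n_projections, self.start_angle_deg)

    @property
    def window_bounds(self) -> list[tuple[float, float]]:
        return [energy_window_bounds(c, w) for c, w in self.energy_windows]

    @property
    def photons_per_decay(self) -> float:
        return float(sum(i for _, i in self.emission_lines))


def default_system(pixel_size_mm: float = 2.21, matrix: int = 256) -> SystemModel:
    return SystemModel(pixel_size_mm=pixel_size_mm, matrix=(matrix, matrix))


def default_protocol(n_projections: int = 120) -> AcquisitionProtocol:
    return AcquisitionProtocol(n_projections=n_projections)
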