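"""Photon interaction data for the materials used in the phantoms.

The phantoms are binary (air / water-equivalent soft tissue); lead only
enters through the collimator septa.  Total attenuation is modelled as
incoherent (Compton) scattering on free electrons via the Klein-Nishina
cross section plus a photoelectric component with an E^-3 energy
dependence anchored at 100 keV.  Coherent (Rayleigh) scattering is
omitted; at 150-300 keV it contributes on the order of 2% to the total
attenuation of water and does not change the photon direction enough to
leave the photopeak windows.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "ELECTRON_REST_KEV",
    "attenuation_coefficient",
    "compton_scattered_energy",
    "klein_nishina_differential",
    "klein_nishina_total",
    "photoelectric_fraction",
]

ELECTRON_REST_KEV = 510.998_95
_R_E_CM = 2.817_940_3262e-13  # classical electron radius

# electrons per gram and bulk density (g/cm^3)
_ELECTRONS_PER_GRAM = {"water": 3.3428e23, "air": 3.0064e23}
_DENSITY = {"water": 1.0, "air": 1.205e-3}

# photoelectric mass attenuation (cm^2/g) at 100 keV, scaled as (100/E)^3
_PE_ANCHOR_100KEV = {"water": 2.8e-3, "air": 3.0e-3}

# lead handled by a small log-log table of total mass attenuation
# (cm^2/g); only used for collimator septa, above the K edge.
_LEAD_E_KEV = np.array([100.0, 150.0, 200.0, 300.0, 500.0])
_LEAD_MU_RHO = np.array([5.549, 2.014, 0.999, 0.403, 0.161])
_LEAD_DENSITY = 11.35


def klein_nishina_total(energy_keV):
    """Total Klein-Nishina cross section per electron in cm^2."""
    eps = np.asarray(energy_keV, dtype=float) / ELECTRON_REST_KEV
    if np.any(eps <= 0):
        raise ValueError("photon energy must be positive")
    t = 1.0 + 2.0 * eps
    log_t = np.log(t)
    term1 = (1.0 + eps) / eps**2 * (2.0 * (1.0 + eps) / t - log_t / eps)
    term2 = log_t / (2.0 * eps)
    term3 = (1.0 + 3.0 * eps) / t**2
    return 2.0 * np.pi * _R_E_CM**2 * (term1 + term2 - term3)


def klein_nishina_differential(energy_keV, cos_theta):
    """d(sigma)/d(Omega) per electron in cm^2/sr at scattering angle theta."""
    e = np.asarray(energy_keV, dtype=float)
    c = np.asarray(cos_theta, dtype=float)
    ratio = compton_scattered_energy(e, c) / e
    return 0.5 * _R_E_CM**2 * ratio**2 * (ratio + 1.0 / ratio - (1.0 - c**2))


def compton_scattered_energy(energy_keV, cos_theta):
    """Photon energy after Compton scattering through angle theta (keV)."""
    e = np.asarray(energy_keV, dtype=float)
    return e / (1.0 + (e / ELECTRON_REST_KEV) * (1.0 - np.asarray(cos_theta, dtype=float)))


def _mass_attenuation(material: str, energy_keV):
    e = np.asarray(energy_keV, dtype=float)
    if np.any(e < 30.0) or np.any(e > 600.0):
        raise ValueError(f"energy {energy_keV} keV outside the tabulated 30-600 keV range")
    if material == "lead":
        return np.exp(
            np.interp(np.log(e), np.log(_LEAD_E_KEV), np.log(_LEAD_MU_RHO))
        )
    try:
        incoh = klein_nishina_total(e) * _ELECTRONS_PER_GRAM[material]
        pe = _PE_ANCHOR_100KEV[material] * (100.0 / e) ** 3
    except KeyError:
        raise ValueError(f"unknown material {material!r}") from None
    return incoh + pe


def attenuation_coefficient(material: str, energy_keV):
    """Linear attenuation coefficient in cm^-1 (coherent scattering excluded)."""
    rho = _LEAD_DENSITY if material == "lead" else _DENSITY.get(material)
    if rho is None:
        raise ValueError(f"unknown material {material!r}")
    return _mass_attenuation(material, energy_keV) * rho


def photoelectric_fraction(material: str, energy_keV):
    """Fraction of interactions that are photoelectric (absorbing)."""
    e = np.asarray(energy_keV, dtype=float)
    if material == "lead":
        # collimator septa: treat every lead interaction as absorbing
        return np.ones_like(e)
    pe = _PE_ANCHOR_100KEV[material] * (100.0 / e) ** 3
    incoh = klein_nishina_total(e) * _ELECTRONS_PER_GRAM[material]
    return pe / (pe + incoh)
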