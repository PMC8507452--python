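"""Photon-history Monte Carlo projector.

Photons are emitted proportionally to the activity map, tracked through
the attenuation map with Woodcock (delta) tracking, scattered with
Klein-Nishina kinematics and detected through a parallel-hole collimator
modelled as an acceptance cone plus the camera's intrinsic spatial and
energy response.

Two detection modes are provided:

``poisson`` (analog)
    Every history is followed to absorption or escape; escaped photons
    are tested against the acceptance cone of every projection angle and
    binned as integer counts.  Count statistics arise directly from the
    history-level sampling, which for the small per-pixel detection
    probabilities involved is Poisson to excellent approximation.

``expected`` (forced detection)
    Noise-reduced expected-count frames for use as the forward step of
    Monte Carlo OSEM.  Primary photons deposit, for every requested
    angle, their analytic escape probability along the detector normal
    (attenuation path from a per-angle transmission map, the same
    midpoint discretisation the analytic projector uses) blurred with
    the distance-dependent system PSF; every Compton vertex of the
    analog random walk additionally deposits its probability of
    scattering into the acceptance cone, escaping, and falling inside an
    energy window.  Given the same seed the result is bit-reproducible.

The attenuation map is treated as water-equivalent: voxel values scale
the attenuation of water at the map's reference energy, which is exact
for the air/water phantoms used here and standard practice for
CT-derived maps at these energies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import erf

from . import materials
from .projections import ProjectionSet
from .projector import AnalyticProjector
from .system import AcquisitionProtocol, SystemModel
from .volume import VoxelVolume

__all__ = [
    "PhotonBatch",
    "sample_emission",
    "sample_klein_nishina_cos",
    "compton_scatter",
    "transport",
    "detect_frame",
    "simulate_projections",
    "simulate_lesion_raw",
    "matched_primary_scale",
    "window_acceptance",
]

_MIN_ENERGY_KEV = 50.0
_MAX_SCATTER = 10


@dataclass
class PhotonBatch:
    """State arrays of a batch of photon histories (positions in mm)."""

    position: np.ndarray
    direction: np.ndarray
    energy: np.ndarray
    weight: np.ndarray
    alive: np.ndarray
    n_scatter: np.ndarray

    def __post_init__(self):
        norms = np.linalg.norm(self.direction, axis=1)
        if self.direction.size and not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("directions must be unit vectors")
        if np.any(self.energy <= 0):
            raise ValueError("photon energies must be positive")

    @property
    def n(self) -> int:
        return len(self.energy)


def _isotropic_directions(
    rng: np.random.Generator, n: int, polar_band_deg: float | None = None
) -> np.ndarray:
    if polar_band_deg is None:
        cos_t = rng.uniform(-1.0, 1.0, n)
    else:
        s = np.sin(np.deg2rad(polar_band_deg))
        cos_t = rng.uniform(-s, s, n)
    sin_t = np.sqrt(1.0 - cos_t**2)
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    return np.stack([sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t], axis=1)


def sample_emission(
    activity: VoxelVolume,
    emission_lines,
    rng: np.random.Generator,
    n: int,
    polar_band_deg: float | None = None,
) -> PhotonBatch:
    """Emit ``n`` photons: position ~ activity, direction isotropic,
    energy from the emission lines with probabilities ~ intensities.

    ``polar_band_deg`` restricts emission directions to a band around
    the transverse plane (uniform in solid angle within the band): a
    variance-reduction device for analog acquisitions, since photons
    emitted far out of plane can only be detected after a large-angle
    scatter into the narrow collimator cone.  The n histories then stand
    for ``n / sin(band)`` isotropic decays.
    """
    flat = activity.values.ravel()
    total = flat.sum()
    if total <= 0 or np.any(flat < 0):
        raise ValueError("activity must be non-negative with positive total")
    cdf = np.cumsum(flat) / total
    vox = np.searchsorted(cdf, rng.random(n), side="right")
    idx = np.stack(np.unravel_index(vox, activity.shape), axis=1)
    jitter = rng.uniform(-0.5, 0.5, (n, 3))
    pos = np.asarray(activity.origin) + (idx + jitter) * np.asarray(activity.spacing)
    energies = np.array([e for e, _ in emission_lines])
    intens = np.array([i for _, i in emission_lines])
    line = rng.choice(len(energies), size=n, p=intens / intens.sum())
    return PhotonBatch(
        position=pos,
        direction=_isotropic_directions(rng, n, polar_band_deg),
        energy=energies[line],
        weight=np.ones(n),
        alive=np.ones(n, dtype=bool),
        n_scatter=np.zeros(n, dtype=int),
    )


def sample_klein_nishina_cos(
    energy_keV: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Sample cos(theta) from the Klein-Nishina distribution by rejection.

    The envelope is the forward-direction maximum of the differential
    cross section, which bounds it for all photon energies.
    """
    e = np.asarray(energy_keV, dtype=float)
    out = np.empty(e.shape)
    pending = np.ones(e.shape, dtype=bool)
    f_max = materials.klein_nishina_differential(e, 1.0)
    for _ in range(1000):
        if not pending.any():
            break
        m = pending
        c = rng.uniform(-1.0, 1.0, m.sum())
        f = materials.klein_nishina_differential(e[m], c)
        accept = rng.random(m.sum()) * f_max[m] <= f
        sel = np.where(m)[0][accept]
        out[sel] = c[accept]
        pending[sel] = False
    if pending.any():  # pragma: no cover - rejection efficiency ~50%
        out[pending] = 1.0
    return out


def _rotate_directions(direction, cos_theta, phi):
    """Rotate unit vectors by polar angle theta about themselves."""
    d = np.asarray(direction, dtype=float)
    # build an orthonormal basis (e1, e2) perpendicular to d
    helper = np.zeros_like(d)
    smallest = np.argmin(np.abs(d), axis=1)
    helper[np.arange(len(d)), smallest] = 1.0
    e1 = np.cross(d, helper)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(d, e1)
    sin_theta = np.sqrt(np.clip(1.0 - cos_theta**2, 0.0, 1.0))
    new = (
        d * cos_theta[:, None]
        + e1 * (sin_theta * np.cos(phi))[:, None]
        + e2 * (sin_theta * np.sin(phi))[:, None]
    )
    return new / np.linalg.norm(new, axis=1, keepdims=True)


def compton_scatter(
    direction: np.ndarray, energy_keV: np.ndarray, rng: np.random.Generator
):
    """Sample a Compton interaction: returns (new_direction, new_energy)."""
    cos_t = sample_klein_nishina_cos(energy_keV, rng)
    phi = rng.uniform(0.0, 2.0 * np.pi, len(cos_t))
    new_dir = _rotate_directions(direction, cos_t, phi)
    new_e = materials.compton_scattered_energy(energy_keV, cos_t)
    return new_dir, np.asarray(new_e)


class _WaterEquivalentMap:
    """Attenuation lookup mu(x, E) from a water-equivalent density map."""

    def __init__(self, mu: VoxelVolume):
        self.volume = mu
        self.ref_energy = float(mu.meta.get("energy_keV", 171.0))
        mu_ref = float(materials.attenuation_coefficient("water", self.ref_energy))
        self.rel_density = np.maximum(mu.values, 0.0) / mu_ref
        self.rel_max = float(self.rel_density.max())
        if self.rel_max <= 0:
            raise ValueError("attenuation map is identically zero or negative")

    def energy_ratio(self, energy_keV):
        """mu_water(E) / mu_water(E_ref): rescales stored path integrals."""
        return materials.attenuation_coefficient(
            "water", energy_keV
        ) / materials.attenuation_coefficient("water", self.ref_energy)

    def voxel_index(self, pos):
        v = self.volume
        idx = np.round(
            (pos - np.asarray(v.origin)) / np.asarray(v.spacing)
        ).astype(int)
        inside = np.all((idx >= 0) & (idx < np.asarray(v.shape)), axis=1)
        return idx, inside

    def relative_density_at(self, pos):
        idx, inside = self.voxel_index(pos)
        rel = np.zeros(len(pos))
        ii = idx[inside]
        rel[inside] = self.rel_density[ii[:, 0], ii[:, 1], ii[:, 2]]
        return rel, inside


def transport(
    batch: PhotonBatch,
    mu: VoxelVolume | None,
    rng: np.random.Generator,
    collect_vertices: bool = False,
    max_scatter: int = _MAX_SCATTER,
    min_energy_keV: float = _MIN_ENERGY_KEV,
):
    """Woodcock-track a photon batch until absorption or escape.

    Returns ``(escaped, vertices)`` where ``escaped`` is a PhotonBatch of
    the photons leaving the grid (``alive`` False, positions at the exit
    point) and ``vertices`` is a dict of arrays describing every Compton
    interaction site (used for forced detection), or None.
    """
    pos = batch.position.copy()
    dirn = batch.direction.copy()
    energy = batch.energy.copy()
    n_scat = batch.n_scatter.copy()
    active = batch.alive.copy()
    escaped = np.zeros(batch.n, dtype=bool)

    vertices = (
        {"position": [], "direction": [], "energy": [], "order": []}
        if collect_vertices
        else None
    )

    if mu is None or np.all(mu.values <= 0):
        # vacuum: every photon escapes unscathed
        escaped[:] = active
        active[:] = False
    else:
        wmap = _WaterEquivalentMap(mu)
        # bounding sphere of the grid, used to retire far-flung photons
        extent = np.asarray(mu.shape) * np.asarray(mu.spacing)
        diag = float(np.linalg.norm(extent))
        for _ in range(10_000):
            idx = np.where(active)[0]
            if idx.size == 0:
                break
            e = energy[idx]
            mu_now = (
                np.asarray(materials.attenuation_coefficient("water", e))
                * wmap.rel_max
            )
            step_mm = rng.exponential(size=idx.size) / mu_now * 10.0
            pos[idx] += dirn[idx] * step_mm[:, None]
            rel, inside = wmap.relative_density_at(pos[idx])
            out = ~inside | (np.linalg.norm(pos[idx], axis=1) > diag)
            esc = idx[out]
            escaped[esc] = True
            active[esc] = False
            live = idx[~out]
            if live.size == 0:
                continue
            rel_live = rel[~out]
            real = rng.random(live.size) < rel_live / wmap.rel_max
            hit = live[real]
            if hit.size == 0:
                continue
            f_pe = np.asarray(materials.photoelectric_fraction("water", energy[hit]))
            absorbed = rng.random(hit.size) < f_pe
            active[hit[absorbed]] = False
            sc = hit[~absorbed]
            if sc.size == 0:
                continue
            if collect_vertices:
                vertices["position"].append(pos[sc].copy())
                vertices["direction"].append(dirn[sc].copy())
                vertices["energy"].append(energy[sc].copy())
                vertices["order"].append(n_scat[sc] + 1)
            new_dir, new_e = compton_scatter(dirn[sc], energy[sc], rng)
            dirn[sc] = new_dir
            energy[sc] = new_e
            n_scat[sc] += 1
            dead = (energy[sc] < min_energy_keV) | (n_scat[sc] > max_scatter)
            active[sc[dead]] = False

    esc_batch = PhotonBatch(
        position=pos[escaped],
        direction=dirn[escaped],
        energy=energy[escaped],
        weight=batch.weight[escaped],
        alive=np.zeros(escaped.sum(), dtype=bool),
        n_scatter=n_scat[escaped],
    )
    if collect_vertices:
        for key, stack in vertices.items():
            vertices[key] = (
                np.concatenate(stack)
                if stack
                else np.zeros((0, 3) if key in ("position", "direction") else 0)
            )
    return esc_batch, vertices


def window_acceptance(energy_keV, system: SystemModel, protocol: AcquisitionProtocol):
    """Probability that a photon's blurred energy falls in any window."""
    e = np.asarray(energy_keV, dtype=float)
    sigma = np.asarray(system.energy_sigma_keV(e))
    p = np.zeros(e.shape)
    for lo, hi in protocol.window_bounds:
        p += 0.5 * (
            erf((hi - e) / (np.sqrt(2.0) * sigma))
            - erf((lo - e) / (np.sqrt(2.0) * sigma))
        )
    return p


def _rotated_coords(pos: np.ndarray, angle_deg: float):
    """(depth, u) coordinates of world points in the frame of one view."""
    phi = np.deg2rad(angle_deg)
    c, s = np.cos(phi), np.sin(phi)
    qx = c * pos[:, 0] + s * pos[:, 1]
    qu = -s * pos[:, 0] + c * pos[:, 1]
    return qx, qu


def detect_frame(
    escaped: PhotonBatch,
    system: SystemModel,
    protocol: AcquisitionProtocol,
    angle_deg: float,
    rng: np.random.Generator,
    frame_shape: tuple[int, int],
    pixel_size_mm: float,
) -> np.ndarray:
    """Analog detection of escaped photons in one view.

    Geometric parallel-hole acceptance (direction inside the collimator
    cone), projection along the actual flight direction to the detector
    plane, intrinsic Gaussian displacement, Gaussian energy blur and
    window rejection, nearest-pixel binning.
    """
    frame = np.zeros(frame_shape)
    if escaped.n == 0:
        return frame
    phi = np.deg2rad(angle_deg)
    normal = np.array([np.cos(phi), np.sin(phi), 0.0])
    cos_acc = np.cos(system.acceptance_half_angle_rad)
    d_dot_n = escaped.direction @ normal
    cand = d_dot_n >= cos_acc
    if not cand.any():
        return frame
    pos = escaped.position[cand]
    dirn = escaped.direction[cand]
    e = escaped.energy[cand]
    p_dot_n = pos @ normal
    # signed distance to the detector plane: the escape position may
    # already lie beyond it (the last free-flight step overshoots), in
    # which case the ray-plane intersection is simply behind the photon
    t = (protocol.orbit_radius_mm - p_dot_n) / d_dot_n[cand]
    hit = pos + dirn * t[:, None]
    u = -np.sin(phi) * hit[:, 0] + np.cos(phi) * hit[:, 1]
    v = hit[:, 2]
    sigma_int = system.intrinsic_fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    u = u + rng.normal(0.0, sigma_int, len(u))
    v = v + rng.normal(0.0, sigma_int, len(v))
    e_meas = e + rng.normal(0.0, 1.0, len(e)) * np.asarray(system.energy_sigma_keV(e))
    in_window = np.zeros(len(e), dtype=bool)
    for lo, hi in protocol.window_bounds:
        in_window |= (e_meas >= lo) & (e_meas <= hi)
    n_u, n_z = frame_shape
    iu = np.round(u / pixel_size_mm + (n_u - 1) / 2.0).astype(int)
    iz = np.round(v / pixel_size_mm + (n_z - 1) / 2.0).astype(int)
    keep = in_window & (iu >= 0) & (iu < n_u) & (iz >= 0) & (iz < n_z)
    np.add.at(frame, (iu[keep], iz[keep]), 1.0)
    return frame


def _expected_frames(
    activity: VoxelVolume,
    mu: VoxelVolume | None,
    system: SystemModel,
    protocol: AcquisitionProtocol,
    angles_deg: np.ndarray,
    n_histories: int,
    rng: np.random.Generator,
    projector: AnalyticProjector,
    scatter: bool,
) -> np.ndarray:
    """Forced-detection expected-count frames.

    Histories are binned (with their escape-probability weights) into the
    detector-aligned rotated grid of each view; the distance-dependent
    PSF and the depth summation are then applied analytically, exactly as
    in the analytic projector, so the only Monte Carlo noise left is that
    of the sampled activity distribution itself.
    """
    n_u = activity.shape[1]
    n_z = activity.shape[2]
    frames = np.zeros((len(angles_deg), n_u, n_z))
    total_activity = float(activity.values.sum())
    if total_activity <= 0:
        return frames
    w0 = (
        system.sensitivity
        * protocol.frame_duration_s
        * protocol.photons_per_decay
        * total_activity
        / n_histories
    )
    p_geom = system.geometric_acceptance()
    omega_cone = 4.0 * np.pi * p_geom

    batch = sample_emission(activity, protocol.emission_lines, rng, n_histories)
    wmap = _WaterEquivalentMap(mu) if mu is not None else None
    path_maps = {
        float(a): (projector.path_integral_map(mu, float(a)) if mu is not None else None)
        for a in angles_deg
    }
    if scatter and mu is not None:
        _, vertices = transport(batch, mu, rng, collect_vertices=True)
    else:
        vertices = None

    sigmas_px = projector.depth_sigmas_px()
    dl_scale = 1.0  # weights are per-history probabilities, not ray sums

    def rotated_bins(pos, angle):
        qx, qu = _rotated_coords(pos, angle)
        ix = np.round((qx - activity.origin[0]) / activity.spacing[0]).astype(int)
        iu = np.round((qu - activity.origin[1]) / activity.spacing[1]).astype(int)
        iz = np.round((pos[:, 2] - activity.origin[2]) / activity.spacing[2]).astype(int)
        ok = (
            (ix >= 0)
            & (ix < activity.shape[0])
            & (iu >= 0)
            & (iu < n_u)
            & (iz >= 0)
            & (iz < n_z)
        )
        return ix, iu, iz, ok

    p_win_primary = np.asarray(window_acceptance(batch.energy, system, protocol))
    if vertices is not None and len(vertices["position"]):
        vpos = vertices["position"]
        vdir = vertices["direction"]
        venergy = vertices["energy"]
        f_compton = 1.0 - np.asarray(materials.photoelectric_fraction("water", venergy))
        kn_total = np.asarray(materials.klein_nishina_total(venergy))
    else:
        vpos = None

    for k, a in enumerate(angles_deg):
        acc = np.zeros(activity.shape)
        pmap = path_maps[float(a)]

        # primaries: escape probability along the detector normal
        ix, iu, iz, ok = rotated_bins(batch.position, float(a))
        if wmap is not None:
            path = pmap[ix[ok], iu[ok], iz[ok]]
            ratio = np.asarray(wmap.energy_ratio(batch.energy[ok]))
            trans = np.exp(-path * ratio)
        else:
            trans = 1.0
        w = w0 * p_geom * p_win_primary[ok] * trans
        np.add.at(acc, (ix[ok], iu[ok], iz[ok]), w)

        # Compton vertices: probability of scattering into the cone,
        # escaping at the scattered energy and passing a window
        if vpos is not None:
            phi = np.deg2rad(float(a))
            normal = np.array([np.cos(phi), np.sin(phi), 0.0])
            cos_t = vdir @ normal
            e_out = np.asarray(materials.compton_scattered_energy(venergy, cos_t))
            kn_diff = np.asarray(materials.klein_nishina_differential(venergy, cos_t))
            vix, viu, viz, vok = rotated_bins(vpos, float(a))
            usable = vok & (e_out >= _MIN_ENERGY_KEV)
            path = pmap[vix[usable], viu[usable], viz[usable]]
            ratio = np.asarray(wmap.energy_ratio(e_out[usable]))
            trans = np.exp(-path * ratio)
            p_win = np.asarray(
                window_acceptance(e_out[usable], system, protocol)
            )
            wv = (
                w0
                * f_compton[usable]
                * (kn_diff[usable] / kn_total[usable])
                * omega_cone
                * trans
                * p_win
            )
            np.add.at(acc, (vix[usable], viu[usable], viz[usable]), wv)

        # analytic distance-dependent PSF per depth plane, then ray sum
        out = np.zeros((n_u, n_z))
        for i, s in enumerate(sigmas_px):
            if acc[i].any():
                out += _gaussian_blur_2d(acc[i], s)
        frames[k] = out * dl_scale
    return frames


def _gaussian_blur_2d(plane: np.ndarray, sigma_px) -> np.ndarray:
    from scipy.ndimage import gaussian_filter

    return gaussian_filter(plane, sigma=sigma_px, mode="constant")


def simulate_projections(
    activity: VoxelVolume,
    mu: VoxelVolume | None,
    system: SystemModel,
    protocol: AcquisitionProtocol,
    n_histories: int,
    seed,
    noise: str = "poisson",
    angles_deg=None,
    projector: AnalyticProjector | None = None,
    scatter: bool = True,
    emission_band_deg: float | None = None,
) -> ProjectionSet:
    """Simulate detector frames for all (or a subset of) projection angles.

    ``noise='poisson'`` runs analog histories and returns integer counts;
    ``noise='expected'`` returns forced-detection expected counts.
    ``emission_band_deg`` (analog mode only) restricts emissions to a
    polar band around the transverse plane; see :func:`sample_emission`.
    ``scatter=False`` in analog mode transports through vacuum, isolating
    the unattenuated primary component.
    """
    if n_histories < 1:
        raise ValueError("need at least one photon history")
    if noise not in ("poisson", "expected"):
        raise ValueError(f"unknown noise mode {noise!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    angles = np.asarray(
        protocol.angles_deg if angles_deg is None else angles_deg, dtype=float
    )
    n_u, n_z = activity.shape[1], activity.shape[2]
    pixel = activity.spacing[1]

    if noise == "expected":
        if projector is None:
            projector = AnalyticProjector(system, protocol, activity)
        frames = _expected_frames(
            activity, mu, system, protocol, angles, n_histories, rng, projector, scatter
        )
    else:
        batch = sample_emission(
            activity, protocol.emission_lines, rng, n_histories, emission_band_deg
        )
        if scatter:
            escaped, _ = transport(batch, mu, rng)
        else:
            escaped, _ = transport(batch, None, rng)
        frames = np.stack(
            [
                detect_frame(escaped, system, protocol, a, rng, (n_u, n_z), pixel)
                for a in angles
            ]
        )
    return ProjectionSet(
        frames,
        angles,
        protocol.orbit_radius_mm,
        pixel,
        meta={
            "generator": "monte-carlo",
            "mode": noise,
            "n_histories": int(n_histories),
            "emission_band_deg": emission_band_deg,
        },
    )


def simulate_lesion_raw(
    lesion_excess_activity: VoxelVolume,
    mu: VoxelVolume,
    system: SystemModel,
    protocol: AcquisitionProtocol,
    n_histories: int,
    seed,
) -> ProjectionSet:
    """Raw data of the lesion's excess activity alone (for projection-space
    addition to a background acquisition)."""
    out = simulate_projections(
        lesion_excess_activity, mu, system, protocol, n_histories, seed, "poisson"
    )
    out.meta["lesion"] = True
    return out


def matched_histories(
    n_background: int, background: VoxelVolume, lesion: VoxelVolume
) -> int:
    """History count for a lesion acquisition consistent with a background
    acquisition of ``n_background`` histories (counts scale with total
    activity)."""
    ratio = lesion.values.sum() / background.values.sum()
    return max(1, int(round(n_background * ratio)))


def matched_primary_scale(
    system: SystemModel,
    protocol: AcquisitionProtocol,
    energy_keV: float,
    spacing_mm: float,
) -> float:
    """Scale making the analytic projector equal (in expectation) to the
    Monte Carlo expected-mode primary component for a single emission line."""
    p_win = float(window_acceptance(np.array([energy_keV]), system, protocol)[0])
    return (
        system.sensitivity
        * protocol.frame_duration_s
        * protocol.photons_per_decay
        * system.geometric_acceptance()
        * p_win
        / (spacing_mm / 10.0)
    )
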