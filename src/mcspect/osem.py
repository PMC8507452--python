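"""Ordered-subset expectation maximization with pluggable forward models.

Variants
--------
``AC``    attenuation-corrected OSEM: analytic forward/back projection
          with attenuation weighting, no resolution modelling.
``ACRR``  AC plus resolution recovery: the distance-dependent system PSF
          is modelled in both the forward and the back projection.
``MC``    Monte Carlo forward projection (attenuation, distance-dependent
          PSF and Compton scatter via forced detection) with an analytic
          attenuation + PSF back projection.

Setting ``attenuation=False`` yields the non-corrected NC / NCRR / MC-NC
counterparts used for acquisitions in air.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import montecarlo
from .projections import ProjectionSet
from .projector import AnalyticProjector
from .system import AcquisitionProtocol, SystemModel
from .volume import VoxelVolume

__all__ = ["ReconConfig", "make_subsets", "osem_reconstruct", "butterworth_filter"]

_EPS = 1e-10

_VARIANT_DEFAULTS = {
    # variant: (psf_forward, psf_backward)
    "AC": (False, False),
    "ACRR": (True, True),
    "MC": (None, True),  # forward model is Monte Carlo
}


@dataclass
class ReconConfig:
    variant: str = "AC"
    n_iterations: int = 2
    n_subsets: int = 10
    attenuation: bool = True
    psf_forward: bool | None = None
    psf_backward: bool | None = None
    mc_histories_per_subset: int = 200_000
    mc_scatter: bool = True
    seed: int = 0
    postfilter: dict | None = None  # {"name": "butterworth", "order", "cutoff_cycles_per_cm"}

    def __post_init__(self):
        if self.variant not in _VARIANT_DEFAULTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.n_iterations < 1:
            raise ValueError("need at least one iteration")
        fwd, bwd = _VARIANT_DEFAULTS[self.variant]
        if self.psf_forward is None:
            self.psf_forward = fwd
        if self.psf_backward is None:
            self.psf_backward = bwd


def make_subsets(n_angles: int, n_subsets: int) -> list[np.ndarray]:
    """Interleaved angle subsets in maximal-angular-separation order.

    Subset k contains angle indices k, k + n_subsets, ...; subsets are
    processed in a greedy order that keeps successive subset offsets as
    far apart as possible (bit-reversal-like).
    """
    if n_subsets < 1 or n_angles % n_subsets != 0:
        raise ValueError(
            f"{n_subsets} subsets do not evenly divide {n_angles} projections"
        )
    subsets = [np.arange(k, n_angles, n_subsets) for k in range(n_subsets)]
    order = [0]
    remaining = list(range(1, n_subsets))
    while remaining:
        # circular distance between subset offsets, in subset units
        def min_dist(k):
            return min(
                min(abs(k - u), n_subsets - abs(k - u)) for u in order
            )

        best = max(remaining, key=lambda k: (min_dist(k), -k))
        order.append(best)
        remaining.remove(best)
    return [subsets[k] for k in order]


def butterworth_filter(
    volume: VoxelVolume,
    order: int = 10,
    cutoff_cycles_per_cm: float = 0.48,
) -> VoxelVolume:
    """3D Butterworth low-pass, gain [1 + (f/fc)^(2n)]^(-1/2), unit DC gain."""
    if order < 1:
        raise ValueError("filter order must be >= 1")
    if cutoff_cycles_per_cm <= 0:
        raise ValueError("critical frequency must be positive")
    freqs = [
        np.fft.fftfreq(n, d=s / 10.0)  # spacing mm -> cm, f in cycles/cm
        for n, s in zip(volume.shape, volume.spacing)
    ]
    fx, fy, fz = np.meshgrid(*freqs, indexing="ij")
    f = np.sqrt(fx**2 + fy**2 + fz**2)
    gain = 1.0 / np.sqrt(1.0 + (f / cutoff_cycles_per_cm) ** (2 * order))
    filtered = np.fft.ifftn(np.fft.fftn(volume.values) * gain).real
    return volume.copy_with(filtered, postfilter=f"butterworth({order}, {cutoff_cycles_per_cm})")


def osem_reconstruct(
    projections: ProjectionSet,
    mu: VoxelVolume | None,
    system: SystemModel,
    config: ReconConfig,
    protocol: AcquisitionProtocol | None = None,
    grid: VoxelVolume | None = None,
    track_volumes: bool = False,
):
    """OSEM reconstruction of a projection set.

    ``grid`` defaults to the attenuation map's grid.  With
    ``track_volumes=True`` returns ``(volume, [volume after each full
    iteration])`` for convergence diagnostics.
    """
    if grid is None:
        if mu is None:
            raise ValueError("need an attenuation map or an explicit grid")
        grid = mu
    if protocol is None:
        protocol = AcquisitionProtocol(
            n_projections=projections.n_views,
            orbit_radius_mm=projections.orbit_radius_mm,
        )
    projector = AnalyticProjector(system, protocol, grid, scale=1.0)
    angles = projections.angles_deg
    subsets = make_subsets(len(angles), config.n_subsets)

    att = config.attenuation and mu is not None

    if projections.total_counts() <= 0:
        warnings.warn("all-zero projection data: returning a uniform volume")
        return grid.copy_with(np.ones(grid.shape))

    # initial estimate: uniform inside the attenuated object, else uniform
    if att and np.any(mu.values > 1e-4):
        support = mu.values > 0.5 * mu.values.max()
        x = np.where(support, 1.0, 0.0)
        if not support.any():
            x = np.ones(grid.shape)
    else:
        x = np.ones(grid.shape)

    # per-subset sensitivity images (back projection of unit frames)
    frame_shape = projections.frames.shape[1:]
    sens = []
    for sub in subsets:
        ones = [np.ones(frame_shape)] * len(sub)
        sens.append(
            projector.back_set(
                ones, mu if att else None, angles[sub], att, config.psf_backward
            )
        )

    mc_rng = np.random.SeedSequence(config.seed)
    history = []
    for _ in range(config.n_iterations):
        for sub, s_img in zip(subsets, sens):
            xvol = grid.copy_with(x)
            if config.variant == "MC":
                sub_seed = np.random.default_rng(mc_rng.spawn(1)[0])
                est = montecarlo.simulate_projections(
                    xvol,
                    mu if att else None,
                    system,
                    protocol,
                    config.mc_histories_per_subset,
                    sub_seed,
                    noise="expected",
                    angles_deg=angles[sub],
                    projector=projector,
                    scatter=config.mc_scatter,
                ).frames
            else:
                est = np.stack(
                    [
                        projector.forward_project(
                            xvol, mu if att else None, a, att, config.psf_forward
                        )
                        for a in angles[sub]
                    ]
                )
            ratio = projections.frames[sub] / (est + _EPS)
            # pixels with neither measured nor expected counts contribute 1
            ratio[(projections.frames[sub] == 0) & (est <= _EPS)] = 1.0
            back = projector.back_set(
                ratio, mu if att else None, angles[sub], att, config.psf_backward
            )
            x = x * back / (s_img + _EPS)
            np.clip(x, 0.0, None, out=x)
        if track_volumes:
            history.append(grid.copy_with(x.copy()))

    out = grid.copy_with(
        x, variant=config.variant, iterations=config.n_iterations, subsets=config.n_subsets
    )
    if config.postfilter:
        pf = dict(config.postfilter)
        if pf.pop("name", "butterworth") != "butterworth":
            raise ValueError("unknown postfilter")
        out = butterworth_filter(out, **pf)
    if track_volumes:
        return out, history
    return out
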