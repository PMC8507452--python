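"""Rotation-based analytic forward/back projector.

The forward operator rotates the volume so the detector is axis-aligned,
optionally weights each voxel by its attenuation path to the detector
(midpoint rule along the depth axis), optionally convolves each depth
plane with the distance-dependent Gaussian response, and sums along the
rays.  The back projector is the literal transpose of the same discrete
operator: the in-plane rotation is a sparse matrix applied per axial
slice, the Gaussian convolution uses a symmetric kernel with zero-filled
boundaries (hence self-adjoint), and the attenuation weights are
diagonal — so <Ax, y> = <x, A'y> holds to machine precision by
construction.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage, sparse

from .projections import ProjectionSet
from .system import AcquisitionProtocol, PsfModel, SystemModel
from .volume import VoxelVolume

__all__ = ["RotationOperator", "AnalyticProjector"]


class RotationOperator:
    """Bilinear in-plane rotation about the grid centre as a sparse matrix."""

    def __init__(self, n: int, angle_deg: float):
        self.n = n
        self.angle_deg = float(angle_deg)
        self.matrix = self._build(n, float(angle_deg))

    @staticmethod
    def _build(n: int, angle_deg: float) -> sparse.csr_matrix:
        c = (n - 1) / 2.0
        phi = np.deg2rad(angle_deg)
        cos, sin = np.cos(phi), np.sin(phi)
        ox, oy = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        ax, ay = ox - c, oy - c
        # sample the input at the forward-rotated coordinates
        sx = cos * ax - sin * ay + c
        sy = sin * ax + cos * ay + c
        fx, fy = np.floor(sx), np.floor(sy)
        tx, ty = sx - fx, sy - fy
        rows, cols, vals = [], [], []
        out_idx = (ox * n + oy).ravel()
        for dx, wx in ((0, 1 - tx), (1, tx)):
            for dy, wy in ((0, 1 - ty), (1, ty)):
                ix = (fx + dx).astype(int)
                iy = (fy + dy).astype(int)
                w = (wx * wy).ravel()
                ok = (
                    (ix.ravel() >= 0)
                    & (ix.ravel() < n)
                    & (iy.ravel() >= 0)
                    & (iy.ravel() < n)
                    & (w > 0)
                )
                rows.append(out_idx[ok])
                cols.append((ix.ravel() * n + iy.ravel())[ok])
                vals.append(w[ok])
        mat = sparse.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n * n, n * n),
        )
        return mat.tocsr()

    def apply(self, stack: np.ndarray) -> np.ndarray:
        """Rotate a (n, n, nz) stack slice-wise."""
        n, nz = self.n, stack.shape[2]
        return (self.matrix @ stack.reshape(n * n, nz)).reshape(n, n, nz)

    def apply_adjoint(self, stack: np.ndarray) -> np.ndarray:
        n, nz = self.n, stack.shape[2]
        return (self.matrix.T @ stack.reshape(n * n, nz)).reshape(n, n, nz)


class AnalyticProjector:
    """Deterministic projector tied to a square-transverse voxel grid.

    Detector pixels coincide with the rotated (u, z) voxel grid; the
    frame value is scaled by the voxel depth in cm, the camera
    sensitivity and the frame duration.
    """

    def __init__(
        self,
        system: SystemModel,
        protocol: AcquisitionProtocol,
        grid: VoxelVolume,
        scale: float | None = None,
    ):
        nx, ny, _ = grid.shape
        if nx != ny:
            raise ValueError("the transverse grid must be square")
        if not np.isclose(grid.spacing[0], grid.spacing[1]):
            raise ValueError("transverse voxels must be isotropic")
        self.system = system
        self.protocol = protocol
        self.grid = grid
        self.n = nx
        self.psf = PsfModel(system)
        self.scale = (
            scale
            if scale is not None
            else system.sensitivity * protocol.frame_duration_s
        )
        self._rotations: dict[float, RotationOperator] = {}

    # -- geometry helpers -------------------------------------------------
    def rotation(self, angle_deg: float) -> RotationOperator:
        key = round(float(angle_deg) % 360.0, 9)
        if key not in self._rotations:
            self._rotations[key] = RotationOperator(self.n, key)
        return self._rotations[key]

    def plane_distances_mm(self) -> np.ndarray:
        """Distance of each rotated depth plane to the collimator face."""
        x = self.grid.axis_coordinates(0)
        return self.protocol.orbit_radius_mm - x

    def depth_sigmas_px(self) -> np.ndarray:
        return np.asarray(self.psf.sigma_at(self.plane_distances_mm())) / self.grid.spacing[0]

    def path_integral_map(self, mu: VoxelVolume, angle_deg: float) -> np.ndarray:
        """Midpoint cumulative attenuation path (dimensionless) to the detector.

        Depth index 0 is farthest from the detector; the detector sits
        past the last depth plane.
        """
        mu_rot = self.rotation(angle_deg).apply(mu.values)
        dl_cm = self.grid.spacing[0] / 10.0
        rev = np.flip(np.cumsum(np.flip(mu_rot, axis=0), axis=0), axis=0)
        return (rev - 0.5 * mu_rot) * dl_cm

    # -- core operators ---------------------------------------------------
    def _check(self, volume: VoxelVolume, mu: VoxelVolume | None):
        if mu is not None and not volume.same_grid(mu):
            raise ValueError("activity and attenuation grids do not match")
        if volume.values.shape != self.grid.shape:
            raise ValueError("volume does not match the projector grid")

    def _blur_planes(self, stack: np.ndarray) -> np.ndarray:
        sigmas = self.depth_sigmas_px()
        out = np.empty_like(stack)
        for i, s in enumerate(sigmas):
            out[i] = ndimage.gaussian_filter(stack[i], sigma=s, mode="constant")
        return out

    def forward_project(
        self,
        volume: VoxelVolume,
        mu: VoxelVolume | None,
        angle_deg: float,
        attenuation_on: bool = True,
        psf_on: bool = False,
    ) -> np.ndarray:
        """Expected-count detector frame (n_u, n_z) at one angle."""
        self._check(volume, mu)
        stack = self.rotation(angle_deg).apply(volume.values)
        if attenuation_on and mu is not None:
            stack = stack * np.exp(-self.path_integral_map(mu, angle_deg))
        if psf_on:
            stack = self._blur_planes(stack)
        return stack.sum(axis=0) * (self.grid.spacing[0] / 10.0) * self.scale

    def back_project(
        self,
        frame: np.ndarray,
        mu: VoxelVolume | None,
        angle_deg: float,
        attenuation_on: bool = True,
        psf_on: bool = False,
    ) -> np.ndarray:
        """Exact adjoint of :meth:`forward_project` for one frame."""
        stack = np.broadcast_to(frame, (self.n,) + frame.shape).copy()
        stack *= (self.grid.spacing[0] / 10.0) * self.scale
        if psf_on:
            stack = self._blur_planes(stack)
        if attenuation_on and mu is not None:
            stack = stack * np.exp(-self.path_integral_map(mu, angle_deg))
        return self.rotation(angle_deg).apply_adjoint(stack)

    # -- convenience ------------------------------------------------------
    def forward_set(
        self,
        volume: VoxelVolume,
        mu: VoxelVolume | None,
        angles_deg=None,
        attenuation_on: bool = True,
        psf_on: bool = False,
    ) -> ProjectionSet:
        angles = np.asarray(
            self.protocol.angles_deg if angles_deg is None else angles_deg, dtype=float
        )
        frames = np.stack(
            [
                self.forward_project(volume, mu, a, attenuation_on, psf_on)
                for a in angles
            ]
        )
        return ProjectionSet(
            frames,
            angles,
            self.protocol.orbit_radius_mm,
            self.grid.spacing[1],
            meta={"generator": "analytic", "attenuation": attenuation_on, "psf": psf_on},
        )

    def back_set(
        self,
        frames: np.ndarray,
        mu: VoxelVolume | None,
        angles_deg,
        attenuation_on: bool = True,
        psf_on: bool = False,
    ) -> np.ndarray:
        out = np.zeros(self.grid.shape)
        for frame, a in zip(frames, angles_deg):
            out += self.back_project(frame, mu, a, attenuation_on, psf_on)
        return out
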