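"""Monte Carlo transport and detection: sampling laws, closed-form checks,
equivalence with the analytic projector."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import chisquare

from mcspect import materials as M
from mcspect import montecarlo as mc
from mcspect.phantoms import make_cylinder_attenuation, make_grid
from mcspect.projections import add_raw
from mcspect.projector import AnalyticProjector
from mcspect.system import AcquisitionProtocol, SystemModel
from mcspect.volume import VoxelVolume

MU_WATER_171 = float(M.attenuation_coefficient("water", 171.0))


def _point_activity(grid, index):
    vals = np.zeros(grid.shape)
    vals[index] = 1.0
    return VoxelVolume(vals, grid.spacing)


class TestEmission:
    def test_positions_confined_to_hot_voxel(self, small_grid, rng):
        act = _point_activity(small_grid, (5, 9, 3))
        batch = mc.sample_emission(act, ((171.0, 1.0),), rng, 5000)
        lo = np.asarray(act.origin) + (np.array([5, 9, 3]) - 0.5) * 4.42
        hi = lo + 4.42
        assert np.all(batch.position >= lo - 1e-9)
        assert np.all(batch.position <= hi + 1e-9)

    def test_direction_isotropy(self, small_grid, rng):
        act = _point_activity(small_grid, (5, 9, 3))
        n = 100_000
        batch = mc.sample_emission(act, ((171.0, 1.0),), rng, n)
        assert np.linalg.norm(batch.direction.mean(axis=0)) < 3.0 / np.sqrt(n)

    def test_equal_intensity_lines_split_evenly(self, small_grid, rng):
        act = _point_activity(small_grid, (5, 9, 3))
        n = 50_000
        batch = mc.sample_emission(act, ((171.0, 0.5), (245.0, 0.5)), rng, n)
        frac = np.mean(batch.energy == 171.0)
        assert abs(frac - 0.5) < 3.0 * 0.5 / np.sqrt(n)

    def test_zero_activity_rejected(self, small_grid, rng):
        zero = VoxelVolume(np.zeros(small_grid.shape), small_grid.spacing)
        with pytest.raises(ValueError):
            mc.sample_emission(zero, ((171.0, 1.0),), rng, 10)


class TestTransport:
    def test_vacuum_escapes_without_interaction(self, small_grid, rng):
        act = _point_activity(small_grid, (8, 8, 4))
        batch = mc.sample_emission(act, ((171.0, 1.0),), rng, 1000)
        escaped, _ = mc.transport(batch, None, rng)
        assert escaped.n == 1000
        assert np.all(escaped.n_scatter == 0)

    def test_free_path_is_exponential(self, rng):
        """Distance to the first interaction in uniform water has mean
        1/mu; checked within 3 standard errors at n = 1e5."""
        grid = make_grid(64, 64, 20.0)  # big enough that few photons escape
        mu = VoxelVolume(
            np.full(grid.shape, MU_WATER_171), grid.spacing, meta={"energy_keV": 171.0}
        )
        n = 100_000
        start = np.zeros((n, 3))
        batch = mc.PhotonBatch(
            position=start.copy(),
            direction=np.tile([[1.0, 0.0, 0.0]], (n, 1)),
            energy=np.full(n, 171.0),
            weight=np.ones(n),
            alive=np.ones(n, dtype=bool),
            n_scatter=np.zeros(n, dtype=int),
        )
        _, vertices = mc.transport(batch, mu, rng, collect_vertices=True)
        first = vertices["position"][vertices["order"] == 1]
        # first Compton vertices: their distance from the origin samples the
        # free-path law (interaction type is independent of position)
        d_cm = np.linalg.norm(first, axis=1) / 10.0
        expected = 1.0 / MU_WATER_171
        se = d_cm.std(ddof=1) / np.sqrt(len(d_cm))
        assert abs(d_cm.mean() - expected) < 3.0 * se

    def test_seed_reproducibility(self, small_grid, water_cylinder, rng):
        act = _point_activity(small_grid, (8, 8, 4))
        sys_ = SystemModel(pixel_size_mm=4.42, matrix=(16, 16))
        prot = AcquisitionProtocol(n_projections=4, orbit_radius_mm=150.0)
        a = mc.simulate_projections(act, water_cylinder, sys_, prot, 20_000, 77, "expected")
        b = mc.simulate_projections(act, water_cylinder, sys_, prot, 20_000, 77, "expected")
        assert np.array_equal(a.frames, b.frames)


class TestComptonScattering:
    def test_forward_scatter_preserves_energy(self, rng):
        e = np.full(10, 171.0)
        assert np.allclose(M.compton_scattered_energy(e, np.ones(10)), 171.0)

    def test_backscatter_energy_171keV(self):
        """171 keV photons backscatter to 171/(1 + 2*171/511) = 102.4 keV."""
        assert np.isclose(
            float(M.compton_scattered_energy(171.0, -1.0)), 102.4, atol=0.05
        )

    def test_sampled_angles_follow_klein_nishina(self, rng):
        """Chi-squared comparison of sampled cos(theta) against the
        numerically integrated Klein-Nishina density at 171 keV."""
        n = 200_000
        samples = mc.sample_klein_nishina_cos(np.full(n, 171.0), rng)
        edges = np.linspace(-1.0, 1.0, 21)
        observed, _ = np.histogram(samples, bins=edges)
        total = float(M.klein_nishina_total(171.0))
        expected = np.array(
            [
                quad(
                    lambda c: 2.0 * np.pi * float(M.klein_nishina_differential(171.0, c)),
                    lo,
                    hi,
                )[0]
                / total
                for lo, hi in zip(edges[:-1], edges[1:])
            ]
        )
        result = chisquare(observed, expected * n)
        assert result.pvalue > 1e-3

    def test_scattered_directions_rotated_by_sampled_angle(self, rng):
        d = np.tile([[0.0, 0.0, 1.0]], (1000, 1))
        new_dir, new_e = mc.compton_scatter(d, np.full(1000, 171.0), rng)
        assert np.allclose(np.linalg.norm(new_dir, axis=1), 1.0)
        cos_t = new_dir[:, 2]
        assert np.allclose(
            new_e, np.asarray(M.compton_scattered_energy(171.0, cos_t)), rtol=1e-9
        )


class TestDetection:
    def _escaped(self, positions, directions, energies):
        n = len(energies)
        return mc.PhotonBatch(
            position=np.asarray(positions, dtype=float),
            direction=np.asarray(directions, dtype=float),
            energy=np.asarray(energies, dtype=float),
            weight=np.ones(n),
            alive=np.zeros(n, dtype=bool),
            n_scatter=np.zeros(n, dtype=int),
        )

    def test_photon_parallel_to_detector_not_detected(self, rng):
        sys_ = SystemModel(pixel_size_mm=4.42, matrix=(16, 16))
        prot = AcquisitionProtocol(n_projections=1, orbit_radius_mm=150.0)
        batch = self._escaped([[0, 0, 0]], [[0, 1, 0]], [171.0])
        frame = mc.detect_frame(batch, sys_, prot, 0.0, rng, (16, 16), 4.42)
        assert frame.sum() == 0

    def test_normal_incidence_photopeak_accepted(self, rng):
        sys_ = SystemModel(
            pixel_size_mm=4.42, matrix=(16, 16), energy_resolution_140keV=1e-6,
            intrinsic_fwhm_mm=1e-6,
        )
        prot = AcquisitionProtocol(n_projections=1, orbit_radius_mm=150.0)
        batch = self._escaped([[0, 0, 0]], [[1, 0, 0]], [171.0])
        frame = mc.detect_frame(batch, sys_, prot, 0.0, rng, (16, 16), 4.42)
        assert frame.sum() == 1
        # lands in the central pixel row/column
        assert frame[7, 7] + frame[8, 8] + frame[7, 8] + frame[8, 7] == 1

    def test_acceptance_fraction_matches_solid_angle(self, rng):
        """Within a +/-5 degree emission band the detected fraction of a
        single view equals the cone-to-band solid-angle ratio."""
        sys_ = SystemModel(pixel_size_mm=4.42, matrix=(64, 64), intrinsic_fwhm_mm=1e-6)
        prot = AcquisitionProtocol(
            n_projections=1,
            orbit_radius_mm=150.0,
            energy_windows=((171.28, 0.5),),  # wide window: geometry only
            emission_lines=((171.28, 1.0),),
        )
        grid = make_grid(64, 64, 4.42)
        act = _point_activity(grid, (32, 32, 32))
        n = 1_000_000
        batch = mc.sample_emission(act, prot.emission_lines, rng, n, polar_band_deg=5.0)
        frame = mc.detect_frame(batch, sys_, prot, 0.0, rng, (64, 64), 4.42)
        expected = sys_.geometric_acceptance() / np.sin(np.deg2rad(5.0))
        observed = frame.sum() / n
        assert abs(observed - expected) < 0.1 * expected


class TestBeerLambertPrimaries:
    def test_primary_attenuation_ratio(self, rng):
        """Photopeak primaries from a point source behind d cm of water are
        attenuated by exp(-mu d) (within 3 Monte Carlo SEs, N = 1e6)."""
        grid = make_grid(48, 16, 4.42)
        mu = VoxelVolume(
            np.full(grid.shape, MU_WATER_171), grid.spacing, meta={"energy_keV": 171.0}
        )
        act = _point_activity(grid, (10, 24, 8))
        sys_ = SystemModel(pixel_size_mm=4.42, matrix=(48, 48))
        prot = AcquisitionProtocol(
            n_projections=1,
            orbit_radius_mm=200.0,
            energy_windows=((171.28, 0.20),),
            emission_lines=((171.28, 1.0),),
        )
        n = 1_000_000
        counts = {}
        for label, medium in (("on", mu), ("off", None)):
            r = np.random.default_rng(5)
            batch = mc.sample_emission(act, prot.emission_lines, r, n, polar_band_deg=3.0)
            escaped, _ = mc.transport(batch, medium, r)
            primaries = mc.PhotonBatch(
                position=escaped.position[escaped.n_scatter == 0],
                direction=escaped.direction[escaped.n_scatter == 0],
                energy=escaped.energy[escaped.n_scatter == 0],
                weight=escaped.weight[escaped.n_scatter == 0],
                alive=np.zeros((escaped.n_scatter == 0).sum(), dtype=bool),
                n_scatter=escaped.n_scatter[escaped.n_scatter == 0],
            )
            frame = mc.detect_frame(primaries, sys_, prot, 0.0, r, (48, 48), 4.42)
            counts[label] = frame.sum()
        ratio = counts["on"] / counts["off"]
        d_cm = ((48 - 1 - 10) + 0.5) * 4.42 / 10.0
        expected = np.exp(-MU_WATER_171 * d_cm)
        se = ratio * np.sqrt(1.0 / counts["on"] + 1.0 / counts["off"])
        assert abs(ratio - expected) < 3.0 * se


class TestSimulateProjections:
    def test_zero_activity_rejected(self, small_grid, water_cylinder, small_system, small_protocol):
        zero = VoxelVolume(np.zeros(small_grid.shape), small_grid.spacing)
        with pytest.raises(ValueError):
            mc.simulate_projections(
                zero, water_cylinder, small_system, small_protocol, 100, 1
            )

    def test_total_detected_not_more_than_emitted(self, small_grid, water_cylinder,
                                                  small_system, small_protocol):
        act = _point_activity(small_grid, (8, 8, 4))
        ps = mc.simulate_projections(
            act, water_cylinder, small_system, small_protocol, 50_000, 3, "poisson"
        )
        assert ps.total_counts() <= 50_000 * small_protocol.n_projections

    def test_point_source_at_cor_centred_in_all_views(self, rng):
        grid = make_grid(32, 16, 4.42)
        act = _point_activity(grid, (16, 16, 8))  # one voxel off-centre of (15.5,15.5)
        sys_ = SystemModel(pixel_size_mm=4.42, matrix=(32, 32))
        prot = AcquisitionProtocol(n_projections=8, orbit_radius_mm=150.0)
        ps = mc.simulate_projections(
            act, None, sys_, prot, 400_000, 9, "poisson", emission_band_deg=5.0
        )
        u = np.arange(32)
        for frame in ps.frames:
            profile = frame.sum(axis=1)
            centroid = np.sum(u * profile) / profile.sum()
            assert abs(centroid - 15.5) <= 1.0 + 0.5  # within one pixel of centre

    def test_relative_se_scales_as_inverse_sqrt_histories(self):
        """Total counts are sums of independent detections, so the relative
        SE follows the 1/sqrt(n) Monte Carlo error law."""
        grid = make_grid(16, 8, 8.0)
        act = _point_activity(grid, (8, 8, 4))
        sys_ = SystemModel(pixel_size_mm=8.0, matrix=(16, 16))
        prot = AcquisitionProtocol(n_projections=4, orbit_radius_mm=120.0)
        levels = [20_000, 80_000, 320_000]
        rel_se = []
        for n in levels:
            totals = [
                mc.simulate_projections(
                    act, None, sys_, prot, n, 100 + r, "poisson", emission_band_deg=5.0
                ).total_counts()
                for r in range(8)
            ]
            totals = np.array(totals)
            rel_se.append(totals.std(ddof=1) / totals.mean())
        slope = np.polyfit(np.log(levels), np.log(rel_se), 1)[0]
        assert -0.75 < slope < -0.25

    def test_scatter_tail_and_scatter_fraction_grow_with_radius(self, rng):
        """Water produces a down-scattered energy tail; the scattered share
        of photopeak counts grows with the cylinder radius."""
        fractions = []
        for radius in (30.0, 90.0):
            grid = make_grid(48, 16, 4.42)
            mu = make_cylinder_attenuation(radius, 200.0, grid, "water", 171.0)
            act = _point_activity(grid, (24, 24, 8))
            r = np.random.default_rng(11)
            batch = mc.sample_emission(act, ((171.28, 1.0),), r, 150_000, polar_band_deg=10.0)
            escaped, _ = mc.transport(batch, mu, r)
            assert np.any(escaped.energy < 153.9)  # scatter tail below the window
            lo, hi = 153.9, 188.1
            sys_ = SystemModel(pixel_size_mm=4.42, matrix=(48, 48))
            e_blur = escaped.energy + r.normal(
                0.0, 1.0, escaped.n
            ) * np.asarray(sys_.energy_sigma_keV(escaped.energy))
            in_window = (e_blur >= lo) & (e_blur <= hi)
            frac = np.mean(escaped.n_scatter[in_window] > 0)
            fractions.append(frac)
        assert fractions[1] > fractions[0]


class TestExpectedModeEquivalence:
    def test_matches_analytic_forward_without_scatter(self):
        """With scatter disabled, forced-detection expected projections are
        an unbiased estimate of the analytic attenuated, PSF-blurred
        forward projection (<= 5% relative RMS on a 32^3-scale phantom)."""
        grid = make_grid(32, 16, 4.42)
        mu = make_cylinder_attenuation(60.0, 200.0, grid, "water", 171.0)
        x = grid.axis_coordinates(0)[:, None, None]
        y = grid.axis_coordinates(1)[None, :, None]
        z = grid.axis_coordinates(2)[None, None, :]
        act = np.exp(-((x - 10) ** 2 + (y + 15) ** 2) / 800.0 - z**2 / 1800.0)
        act[np.broadcast_to(x**2 + y**2 > 55**2, grid.shape)] = 0.0
        vol = VoxelVolume(act, grid.spacing)
        sys_ = SystemModel(pixel_size_mm=4.42, matrix=(32, 32))
        prot = AcquisitionProtocol(
            n_projections=8,
            orbit_radius_mm=200.0,
            energy_windows=((171.28, 0.20),),
            emission_lines=((171.28, 1.0),),
        )
        scale = mc.matched_primary_scale(sys_, prot, 171.28, 4.42)
        proj = AnalyticProjector(sys_, prot, grid, scale=scale)
        ps = mc.simulate_projections(
            vol, mu, sys_, prot, 400_000, 13, "expected",
            angles_deg=[0.0, 70.0], scatter=False,
        )
        for k, angle in enumerate([0.0, 70.0]):
            ana = proj.forward_project(vol, mu, angle, True, True)
            rel_rms = np.sqrt(np.mean((ps.frames[k] - ana) ** 2)) / np.sqrt(
                np.mean(ana**2)
            )
            assert rel_rms < 0.05


class TestLesionRaw:
    def _setup(self):
        grid = make_grid(32, 16, 4.42)
        mu = make_cylinder_attenuation(60.0, 200.0, grid, "water", 171.0)
        sys_ = SystemModel(pixel_size_mm=4.42, matrix=(32, 32))
        prot = AcquisitionProtocol(n_projections=8, orbit_radius_mm=200.0)
        return grid, mu, sys_, prot

    def test_adding_zero_lesion_is_identity(self):
        grid, mu, sys_, prot = self._setup()
        act = _point_activity(grid, (16, 16, 8))
        bg = mc.simulate_projections(act, mu, sys_, prot, 50_000, 3, "poisson")
        zero = bg.__class__(
            np.zeros_like(bg.frames), bg.angles_deg, bg.orbit_radius_mm, bg.pixel_size_mm
        )
        combined = add_raw(bg, zero)
        assert np.array_equal(combined.frames, bg.frames)

    def test_counts_add_exactly(self):
        grid, mu, sys_, prot = self._setup()
        a = mc.simulate_projections(_point_activity(grid, (16, 16, 8)), mu, sys_, prot,
                                    50_000, 3, "poisson")
        b = mc.simulate_lesion_raw(_point_activity(grid, (20, 12, 8)), mu, sys_, prot,
                                   20_000, 4)
        combined = add_raw(a, b)
        assert combined.total_counts() == a.total_counts() + b.total_counts()

    def test_geometry_mismatch_rejected(self):
        grid, mu, sys_, prot = self._setup()
        a = mc.simulate_projections(_point_activity(grid, (16, 16, 8)), mu, sys_, prot,
                                    10_000, 3, "poisson")
        other = a.__class__(a.frames[:4], a.angles_deg[:4], a.orbit_radius_mm,
                            a.pixel_size_mm)
        with pytest.raises(ValueError):
            add_raw(a, other)

    def test_lesion_counts_follow_projection_geometry(self, rng):
        """An off-centre lesion's view centroids track the rotating
        projection of its position."""
        grid, mu, sys_, prot = self._setup()
        lesion_idx = (22, 16, 8)
        act = _point_activity(grid, lesion_idx)
        ps = mc.simulate_projections(act, None, sys_, prot, 400_000, 5, "poisson",
                                     emission_band_deg=5.0)
        pos = np.asarray(grid.origin) + np.asarray(lesion_idx) * 4.42
        u_grid = np.arange(32)
        for frame, angle in zip(ps.frames, ps.angles_deg):
            if frame.sum() < 50:
                continue
            phi = np.deg2rad(angle)
            expected_u = -np.sin(phi) * pos[0] + np.cos(phi) * pos[1]
            profile = frame.sum(axis=1)
            centroid_mm = (np.sum(u_grid * profile) / profile.sum() - 15.5) * 4.42
            assert abs(centroid_mm - expected_u) < 2.0 * 4.42
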