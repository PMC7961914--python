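"""Monte Carlo transport: source replication, physics benchmarks,
conservation, and determinism."""

import math

import numpy as np
import pytest

from qpatsim.mc_fluence import (
    ConeSource,
    IlluminationGeometry,
    FluenceMap,
    default_illumination,
    replicate_sources,
    scale_to_pulse_energy,
    simulate_fluence,
)
from qpatsim.phantom_model import OpticalPropertyVolume, PhantomSpec


def homogeneous_volume(shape, mua, musp, g=0.0, n=1.0, pitch=1.0):
    full = np.full
    return OpticalPropertyVolume(
        mu_a=full(shape, mua, np.float32),
        mu_s=full(shape, musp / (1 - g) if g else musp, np.float32),
        g=full(shape, g, np.float32),
        n=full(shape, n, np.float32),
        pitch_mm=pitch,
        origin_mm=np.full(3, pitch / 2),
        wavelength=755,
    )


def side_fibers(n=9):
    return [
        ConeSource(
            position_mm=(50.0 * math.cos(2 * math.pi * k / n),
                         50.0 * math.sin(2 * math.pi * k / n), 20.0),
            direction=(-math.cos(2 * math.pi * k / n), -math.sin(2 * math.pi * k / n), 0.0),
            aperture_radius_mm=2.0,
            divergence_half_angle_deg=10.0,
        )
        for k in range(n)
    ]


def bottom_source():
    return ConeSource(position_mm=(0.0, 0.0, -5.0), direction=(0.0, 0.0, 1.0),
                      aperture_radius_mm=20.0, divergence_half_angle_deg=5.0)


class TestReplicateSources:
    def test_full_scan_has_406_sources(self):
        geom = replicate_sources(side_fibers(9), bottom_source(), n_steps=45, arc_deg=60.0)
        assert len(geom.sources) == 406

    def test_single_fiber_single_step_is_identity(self):
        fiber = side_fibers(1)[0]
        geom = replicate_sources([fiber], bottom_source(), n_steps=1, arc_deg=60.0)
        assert len(geom.sources) == 2
        np.testing.assert_allclose(geom.sources[0].position_mm, fiber.position_mm)
        np.testing.assert_allclose(geom.sources[0].direction, fiber.direction)

    @pytest.mark.parametrize("n_fibers, n_steps", [(9, 45), (3, 7), (1, 1)])
    def test_total_weight_normalized(self, n_fibers, n_steps):
        geom = replicate_sources(side_fibers(n_fibers), bottom_source(),
                                 n_steps=n_steps, arc_deg=60.0)
        assert sum(s.weight for s in geom.sources) == pytest.approx(1.0, abs=1e-12)

    def test_default_illumination_replicates_the_tomographic_scan(self):
        geom = default_illumination(PhantomSpec(), 755)
        assert len(geom.sources) == 406
        assert geom.pulse_energy_J == pytest.approx(0.320)
        assert default_illumination(PhantomSpec(), 1064).pulse_energy_J == pytest.approx(0.400)


class TestTransportPhysics:
    def test_beer_lambert_in_pure_absorber(self):
        """mu_s = 0, collimated pencil: on-axis fluence decays as exp(-mu_a d)."""
        mua = 1.0  # cm^-1
        vol = homogeneous_volume((21, 21, 60), mua, 0.0, pitch=1.0)
        src = ConeSource(position_mm=(10.5, 10.5, 0.5), direction=(0, 0, 1),
                         aperture_radius_mm=0.0, divergence_half_angle_deg=0.0)
        geom = IlluminationGeometry([src], wavelength=755, pulse_energy_J=1.0)
        fl = simulate_fluence(vol, geom, 400_000, seed=11)
        z = np.arange(5, 45, 5)
        phi = fl.values[10, 10, z]
        expected = np.exp(-mua * z / 10.0)
        expected *= phi[0] / expected[0]
        # 8% tolerance: ~700 deposition events per deep voxel -> ~2 sigma
        np.testing.assert_allclose(phi, expected, rtol=0.08)

    def test_diffusion_green_function_within_10_percent(self):
        """Isotropic point source in scattering medium vs diffusion theory."""
        mua, musp = 0.1, 10.0  # cm^-1
        n = 80
        vol = homogeneous_volume((n, n, n), mua, musp, pitch=1.0)
        src = ConeSource.isotropic((40.0, 40.0, 40.0))
        geom = IlluminationGeometry([src], wavelength=755, pulse_energy_J=1.0)
        fl = simulate_fluence(vol, geom, 200_000, seed=3)
        x = np.arange(n) + 0.5
        X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
        r_mm = np.sqrt((X - 40) ** 2 + (Y - 40) ** 2 + (Z - 40) ** 2)
        D = 1.0 / (3.0 * (mua + musp))
        mueff = math.sqrt(mua / D)
        for r0 in (5.0, 10.0, 15.0):
            shell = (r_mm > r0 - 0.5) & (r_mm < r0 + 0.5)
            r_cm = r_mm[shell].mean() / 10.0
            theory = math.exp(-mueff * r_cm) / (4.0 * math.pi * D * r_cm)
            assert fl.values[shell].mean() == pytest.approx(theory, rel=0.10)

    def test_energy_conservation_in_closed_absorbing_volume(self):
        """Matched boundaries: deposited + escaped accounts for all launched
        energy within 0.5%."""
        vol = homogeneous_volume((40, 40, 40), 0.5, 5.0, pitch=1.0)
        src = ConeSource.isotropic((20.0, 20.0, 20.0))
        geom = IlluminationGeometry([src], wavelength=755, pulse_energy_J=1.0)
        fl = simulate_fluence(vol, geom, 100_000, seed=5)
        assert fl.absorbed_fraction + fl.escaped_fraction == pytest.approx(1.0, abs=0.005)

    def test_fluence_nonnegative_and_finite(self):
        vol = homogeneous_volume((30, 30, 30), 0.2, 8.0, g=0.9, n=1.4, pitch=1.0)
        src = ConeSource(position_mm=(15.0, 15.0, 0.5), direction=(0, 0, 1),
                         aperture_radius_mm=5.0, divergence_half_angle_deg=20.0)
        geom = IlluminationGeometry([src], wavelength=755, pulse_energy_J=1.0)
        fl = simulate_fluence(vol, geom, 50_000, seed=9)
        assert np.all(np.isfinite(fl.values))
        assert np.all(fl.values >= 0)

    def test_variance_decreases_with_photon_count(self):
        """Voxelwise relative seed-to-seed difference shrinks as N grows."""
        vol = homogeneous_volume((40, 40, 40), 0.1, 10.0, pitch=1.0)
        src = ConeSource.isotropic((20.0, 20.0, 20.0))
        geom = IlluminationGeometry([src], wavelength=755, pulse_energy_J=1.0)

        def rel_diff(n_photons):
            a = simulate_fluence(vol, geom, n_photons, seed=21).values
            b = simulate_fluence(vol, geom, n_photons, seed=22).values
            bright = a > np.percentile(a, 90)
            return np.mean(np.abs(a[bright] - b[bright])) / np.mean(a[bright])

        assert rel_diff(80_000) < rel_diff(10_000)

    def test_same_seed_reproduces_map(self):
        vol = homogeneous_volume((20, 20, 20), 0.3, 5.0, pitch=1.0)
        src = ConeSource.isotropic((10.0, 10.0, 10.0))
        geom = IlluminationGeometry([src], wavelength=755, pulse_energy_J=1.0)
        a = simulate_fluence(vol, geom, 20_000, seed=13)
        b = simulate_fluence(vol, geom, 20_000, seed=13)
        assert np.array_equal(a.values, b.values)


class TestScaling:
    def make_map(self):
        return FluenceMap(values=np.ones((3, 3, 3)), wavelength=755, pitch_mm=1.0,
                          origin_mm=np.zeros(3), photon_count=1, rng_seed=0)

    def test_zero_energy_gives_zero_map(self):
        assert np.all(scale_to_pulse_energy(self.make_map(), 0.0).values == 0)

    def test_known_pulse_energy(self):
        scaled = scale_to_pulse_energy(self.make_map(), 0.320)
        assert scaled.values[0, 0, 0] == pytest.approx(0.320)

    def test_composition(self):
        m = self.make_map()
        ab = scale_to_pulse_energy(scale_to_pulse_energy(m, 2.0), 3.0)
        once = scale_to_pulse_energy(m, 6.0)
        np.testing.assert_allclose(ab.values, once.values)

    def test_negative_energy_rejected(self):
        with pytest.raises(ValueError):
            scale_to_pulse_energy(self.make_map(), -1.0)
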