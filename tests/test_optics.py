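"""Beam irradiance, fiber acceptance, and the weighted-emission forward model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nanosolder.errors import ExtrapolationError, GeometryError, UndefinedRatioError
from nanosolder.fields import DEFAULT_GRID, GridSpec, TemperatureField
from nanosolder.optics import (
    BeamModel,
    FiberModel,
    NoiseConfig,
    add_spectrum_noise,
    beam_power_map,
    fiber_acceptance_map,
    fiber_grid_positions,
    sample_fiber_grid,
    simulate_fiber_spectrum,
)
from nanosolder.spectra import (
    celsius_to_kelvin,
    compute_fir,
    fir_from_temperature,
    interpolate_spectrum,
)
from nanosolder.dataset import SimConfig


def uniform_field(t_c, grid=DEFAULT_GRID):
    return TemperatureField(np.full(grid.shape, float(t_c)), grid)


#: odd-sized grid with a pixel exactly on the optical axis
ODD_GRID = GridSpec(shape=(101, 101), extent_mm=(4.0, 4.0))


class TestBeamPowerMap:
    def test_center_pixel_is_one(self):
        p = beam_power_map(BeamModel(), ODD_GRID)
        assert p[50, 50] == pytest.approx(1.0)
        assert p.max() == pytest.approx(1.0)

    def test_gaussian_value_at_beam_radius(self):
        beam = BeamModel(waist_w0_mm=1.0, quality_m=1.0, source_distance_z_mm=0.001)
        p = beam_power_map(beam, ODD_GRID)
        xs, ys = ODD_GRID.coordinates_mm()
        iy = np.argmin(np.abs(ys))
        ix = np.argmin(np.abs(xs - 1.0))
        r = np.hypot(xs[ix], ys[iy])
        w = beam.radius_at_z_mm()
        assert p[iy, ix] == pytest.approx(np.exp(-2.0 * r**2 / w**2), rel=1e-9)
        assert p[iy, ix] == pytest.approx(np.exp(-2.0), rel=0.05)

    def test_tophat_hard_edge(self):
        beam = BeamModel(profile="tophat", waist_w0_mm=1.0)
        p = beam_power_map(beam, ODD_GRID)
        xs, ys = ODD_GRID.coordinates_mm()
        iy = np.argmin(np.abs(ys))
        inside = np.argmin(np.abs(xs - 0.9))
        outside = np.argmin(np.abs(xs - 1.05))
        assert p[iy, inside] == 1.0
        assert p[iy, outside] == 0.0

    def test_beam_quality_widens_rayleigh_range(self):
        b1 = BeamModel(quality_m=1.0)
        b8 = BeamModel(quality_m=8.0)
        assert b8.rayleigh_range_mm == pytest.approx(b1.rayleigh_range_mm / 8.0)


class TestFiberAcceptance:
    def test_pixel_under_tip_is_maximum(self):
        f = fiber_acceptance_map(FiberModel(), DEFAULT_GRID)
        iy, ix = np.unravel_index(np.argmax(f), f.shape)
        xs, ys = DEFAULT_GRID.coordinates_mm()
        assert abs(xs[ix]) <= DEFAULT_GRID.pixel_pitch_mm
        assert abs(ys[iy]) <= DEFAULT_GRID.pixel_pitch_mm
        assert f.max() == pytest.approx(1.0)

    def test_outside_acceptance_cone_is_zero(self):
        fiber = FiberModel(numerical_aperture=0.22, standoff_mm=1.0)
        f = fiber_acceptance_map(fiber, DEFAULT_GRID)
        xs, ys = DEFAULT_GRID.coordinates_mm()
        xx, yy = np.meshgrid(xs, ys)
        theta = np.arctan(np.hypot(xx, yy) / 1.0)
        assert np.all(f[theta > np.arcsin(0.22)] == 0.0)
        # the acceptance half-angle of NA 0.22 in air is about 12.7 deg
        assert np.degrees(fiber.acceptance_half_angle_rad) == pytest.approx(12.71, abs=0.01)

    def test_inverse_square_law_on_axis(self):
        f1 = fiber_acceptance_map(FiberModel(standoff_mm=1.0), ODD_GRID, normalize=False)
        f2 = fiber_acceptance_map(FiberModel(standoff_mm=2.0), ODD_GRID, normalize=False)
        assert f1[50, 50] == pytest.approx(4.0 * f2[50, 50], rel=1e-12)

    def test_nonpositive_standoff_rejected(self):
        with pytest.raises(GeometryError):
            FiberModel(standoff_mm=0.0)


class TestForwardModel:
    def test_uniform_field_reproduces_database_fir(self, wide_db):
        field = uniform_field(60.0)
        spec = simulate_fiber_spectrum(field, BeamModel(), FiberModel(), wide_db)
        expected = compute_fir(interpolate_spectrum(wide_db, celsius_to_kelvin(60.0)))
        assert compute_fir(spec) == pytest.approx(expected, rel=1e-12)

    def test_two_pixel_mixture_fir_is_strictly_between(self, wide_db):
        # both pixels sit inside the fiber's acceptance disc under the tip
        field = uniform_field(40.0)
        field.values_c[48, 62] = 80.0
        conc = np.zeros(field.values_c.shape)
        conc[48, 62] = 1.0
        conc[46, 66] = 1.0
        spec = simulate_fiber_spectrum(field, BeamModel(), FiberModel(), wide_db, conc)
        fir = compute_fir(spec)
        f40 = compute_fir(interpolate_spectrum(wide_db, celsius_to_kelvin(40.0)))
        f80 = compute_fir(interpolate_spectrum(wide_db, celsius_to_kelvin(80.0)))
        assert f40 < fir < f80

    def test_brute_force_oracle_parity_few_pixels(self, wide_db):
        # independent oracle: explicit per-pixel sum of interpolated spectra
        rng = np.random.default_rng(3)
        field = uniform_field(50.0)
        idx = [(5, 7), (20, 40), (60, 100), (90, 12)]
        temps = [35.0, 52.5, 71.0, 88.0]
        conc = np.zeros(field.values_c.shape)
        for (iy, ix), t in zip(idx, temps):
            field.values_c[iy, ix] = t
            conc[iy, ix] = rng.uniform(0.2, 1.0)
        beam, fiber = BeamModel(), FiberModel(tip_xy_mm=(0.3, -0.2))
        spec = simulate_fiber_spectrum(field, beam, fiber, wide_db, conc)
        from nanosolder.optics import beam_power_map as bpm, fiber_acceptance_map as fam

        p = bpm(beam, field.grid)
        f = fam(fiber, field.grid)
        expected = np.zeros_like(wide_db.wavelengths_nm)
        for (iy, ix) in idx:
            w = p[iy, ix] * f[iy, ix] * conc[iy, ix]
            node = interpolate_spectrum(wide_db, celsius_to_kelvin(field.values_c[iy, ix]))
            expected = expected + w * node.intensities
        np.testing.assert_allclose(spec.intensities, expected, rtol=1e-12, atol=1e-300)

    def test_zero_concentration_annihilates(self, wide_db):
        field = uniform_field(60.0)
        conc = np.zeros(field.values_c.shape)
        spec = simulate_fiber_spectrum(field, BeamModel(), FiberModel(), wide_db, conc)
        assert spec.intensities.max() == 0.0
        with pytest.raises(UndefinedRatioError):
            compute_fir(spec)

    def test_out_of_range_temperature_names_offender(self, default_db):
        field = uniform_field(95.0)  # six-node db tops out at 80 degC
        with pytest.raises(ExtrapolationError, match="95"):
            simulate_fiber_spectrum(field, BeamModel(), FiberModel(), default_db)

    def test_warming_every_pixel_increases_fir(self, wide_db):
        rng = np.random.default_rng(8)
        base = 40.0 + 30.0 * rng.random(DEFAULT_GRID.shape)
        f1 = TemperatureField(base, DEFAULT_GRID)
        f2 = TemperatureField(base + 5.0, DEFAULT_GRID)
        s1 = simulate_fiber_spectrum(f1, BeamModel(), FiberModel(), wide_db)
        s2 = simulate_fiber_spectrum(f2, BeamModel(), FiberModel(), wide_db)
        assert compute_fir(s2) > compute_fir(s1)


@settings(deadline=None, max_examples=10, derandomize=True)
@given(seed=st.integers(min_value=0, max_value=10_000))
def test_fir_bounded_by_weighted_pixel_extremes(seed):
    """FIR of any mixture lies within the FIR range of its contributing pixels."""
    db = _bound_db()
    rng = np.random.default_rng(seed)
    grid = GridSpec(shape=(16, 16), extent_mm=(1.0, 1.0))
    temps = rng.uniform(25.0, 95.0, grid.shape)
    field = TemperatureField(temps, grid)
    conc = (rng.random(grid.shape) > 0.3).astype(float)
    if conc.sum() == 0:
        conc[8, 8] = 1.0
    spec = simulate_fiber_spectrum(field, BeamModel(), FiberModel(), db, conc)
    w = beam_power_map(BeamModel(), grid) * fiber_acceptance_map(FiberModel(), grid) * conc
    active = w > 0
    firs = fir_from_temperature(celsius_to_kelvin(temps[active]))
    fir = compute_fir(spec)
    # database interpolation is piecewise linear between 5-degC nodes, so
    # allow the small node-discretization tolerance on the bound
    assert firs.min() * (1 - 5e-3) <= fir <= firs.max() * (1 + 5e-3)


_BOUND_DB_CACHE = []


def _bound_db():
    from nanosolder.spectra import synthesize_emission_database

    if not _BOUND_DB_CACHE:
        _BOUND_DB_CACHE.append(
            synthesize_emission_database(
                temperatures_K=celsius_to_kelvin(np.arange(15.0, 120.0 + 1e-9, 5.0))
            )
        )
    return _BOUND_DB_CACHE[0]


class TestSpectrumNoise:
    def test_disabled_noise_is_identity(self, wide_db, rng):
        spec = interpolate_spectrum(wide_db, celsius_to_kelvin(60.0))
        out = add_spectrum_noise(spec, NoiseConfig(enabled=False), rng)
        assert out is spec

    def test_high_count_fir_within_half_percent(self, wide_db):
        rng = np.random.default_rng(17)
        spec = interpolate_spectrum(wide_db, celsius_to_kelvin(60.0))
        clean = compute_fir(spec)
        noisy = add_spectrum_noise(spec, NoiseConfig(peak_counts=1e6, read_noise_counts=5.0), rng)
        assert compute_fir(noisy) == pytest.approx(clean, rel=5e-3)

    def test_seed_determinism(self, wide_db):
        spec = interpolate_spectrum(wide_db, celsius_to_kelvin(60.0))
        cfg = NoiseConfig(peak_counts=2000.0)
        a = add_spectrum_noise(spec, cfg, np.random.default_rng(4))
        b = add_spectrum_noise(spec, cfg, np.random.default_rng(4))
        np.testing.assert_array_equal(a.intensities, b.intensities)


class TestFiberGridSampling:
    def test_uniform_field_recovered_exactly_without_noise(self, wide_db, sim_config):
        field = uniform_field(60.0)
        img, pos = sample_fiber_grid(
            field, sim_config.beam, sim_config.fiber, wide_db, sim_config.calibration
        )
        np.testing.assert_allclose(img, 60.0, atol=1e-6)

    def test_grid_geometry(self):
        pos = fiber_grid_positions()
        assert pos.shape == (5, 5, 2)
        assert pos[0, 1, 0] - pos[0, 0, 0] == pytest.approx(0.5)  # 500 um spacing
        assert pos[2, 2, 0] == pytest.approx(0.0) and pos[2, 2, 1] == pytest.approx(0.0)

    def test_centered_peak_maximizes_center_entry(self, wide_db, sim_config):
        from nanosolder.fields import SkewedGaussianParams, make_skewed_gaussian_field

        p = SkewedGaussianParams(sigma_x_mm=0.7, sigma_y_mm=0.7, t_max_c=80.0, t_min_c=30.0)
        field = make_skewed_gaussian_field(p)
        img, _ = sample_fiber_grid(
            field, sim_config.beam, sim_config.fiber, wide_db, sim_config.calibration
        )
        assert img[2, 2] == img.max()
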