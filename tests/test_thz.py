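"""Time-trace processing, slab transfer functions and water extraction."""

import numpy as np
import pytest

from stomadry.dielectrics import (
    DielectricSpectrum,
    FrequencyGrid,
    air_permittivity,
    dry_material_permittivity,
    water_permittivity,
)
from stomadry.synthetic import PulseModel, synthesize_thz_traces
from stomadry.thz import (
    LeafGeometry,
    TimeTrace,
    experimental_transfer_function,
    extract_water_content,
    leaf_transfer_function,
    theoretical_transfer_function,
    to_frequency_domain,
    volumetric_to_weight_percent,
    weight_percent_to_volumetric,
)


def _trace(field, dt=0.05):
    return TimeTrace(np.arange(len(field)) * dt, np.asarray(field, float))


class TestFourier:
    def test_rejects_nonuniform_axis(self):
        with pytest.raises(ValueError):
            TimeTrace(np.array([0.0, 1.0, 3.0, 4.0]), np.zeros(4))

    def test_impulse_gives_flat_magnitude(self):
        e = np.zeros(512)
        e[0] = 1.0
        spec = to_frequency_domain(_trace(e), window=None)
        np.testing.assert_allclose(np.abs(spec.amp), 1.0, rtol=1e-12)

    def test_shift_theorem_phase_slope(self):
        rng = np.random.default_rng(0)
        e = rng.normal(size=512)
        base = to_frequency_domain(_trace(e), window=None)
        k = 17
        shifted = to_frequency_domain(_trace(np.roll(e, k)), window=None)
        dt_shift = k * 0.05
        expected = np.exp(1j * 2 * np.pi * base.grid.freqs * dt_shift)
        mask = np.abs(base.amp) > 1e-9
        np.testing.assert_allclose((shifted.amp / base.amp)[mask],
                                   expected[mask], rtol=1e-8, atol=1e-8)

    def test_gaussian_pulse_matches_analytic_transform(self):
        dt, w, tc = 0.05, 1.0, 25.0
        t = np.arange(1000) * dt
        e = np.exp(-0.5 * ((t - tc) / w) ** 2)
        spec = to_frequency_domain(_trace(e), window=None)
        f = spec.grid.freqs
        analytic = np.exp(-0.5 * (2 * np.pi * f * w) ** 2)
        mag = np.abs(spec.amp) / np.abs(spec.amp[0])
        keep = analytic > 1e-3
        np.testing.assert_allclose(mag[keep], analytic[keep], rtol=1e-2)


class TestExperimentalTransferFunction:
    def test_identity_and_scaling(self):
        e = np.sin(np.linspace(0, 20, 256)) * np.hanning(256)
        ref = to_frequency_domain(_trace(e))
        same = experimental_transfer_function(ref, ref, noise_floor=1e-9)
        np.testing.assert_allclose(same.h[same.valid], 1.0, rtol=1e-12)
        half = to_frequency_domain(_trace(0.5 * e))
        h = experimental_transfer_function(half, ref, noise_floor=1e-9)
        np.testing.assert_allclose(h.h[h.valid], 0.5, rtol=1e-12)

    def test_fully_masked_reference_raises(self):
        e = np.zeros(64)
        e[3] = 1.0
        ref = to_frequency_domain(_trace(e), window=None)
        with pytest.raises(ValueError):
            experimental_transfer_function(ref, ref, noise_floor=10.0)

    def test_round_trip_against_theoretical_slab(self):
        """A sample synthesized through a known slab reproduces its H."""
        geom = LeafGeometry(thickness_um=185.0)
        ref, sample = synthesize_thz_traces(60.0, geom, PulseModel())
        h_exp = experimental_transfer_function(
            to_frequency_domain(sample, window=None),
            to_frequency_domain(ref, window=None), noise_floor=1e-8)
        x = weight_percent_to_volumetric(60.0, geom.dry_air_ratio,
                                         geom.density_dry_g_cm3)
        band = h_exp.grid.band_mask(0.1, 0.3) & h_exp.valid
        h_th = leaf_transfer_function(
            x, FrequencyGrid(h_exp.grid.freqs[band]), geom).h
        np.testing.assert_allclose(h_exp.h[band], h_th, rtol=1e-6)


class TestTheoreticalTransferFunction:
    def test_index_matched_and_zero_thickness(self, band_grid):
        ones = air_permittivity(band_grid)
        np.testing.assert_allclose(
            theoretical_transfer_function(ones, 500.0).h, 1.0, rtol=1e-12)
        water = water_permittivity(band_grid)
        np.testing.assert_allclose(
            theoretical_transfer_function(water, 0.0).h, 1.0, rtol=1e-12)

    def test_lossless_n2_fresnel_product(self, band_grid):
        eps = DielectricSpectrum(band_grid,
                                 np.full(len(band_grid), 4.0 + 0j))
        h = theoretical_transfer_function(eps, 120.0).h
        np.testing.assert_allclose(np.abs(h), 8.0 / 9.0, rtol=1e-12)

    @pytest.mark.parametrize("x_water", [0.1, 0.4, 0.8])
    def test_passive_slab_never_amplifies(self, band_grid, x_water):
        h = leaf_transfer_function(x_water, band_grid, LeafGeometry()).h
        assert np.all(np.abs(h) <= 1.0)


class TestConversions:
    @pytest.mark.parametrize("x, ratio, rho, expected", [
        (0.0, 1.0, 1.5, 0.0),
        (0.6, 2.0, 1.5, 100 * 0.6 / (0.6 + 1.5 * 0.4 * 2 / 3)),
    ])
    def test_volumetric_to_weight(self, x, ratio, rho, expected):
        assert volumetric_to_weight_percent(x, ratio, rho) == pytest.approx(
            expected)

    def test_equal_masses_give_50_percent(self):
        # with ratio 1, x_dry = (1 - x_w)/2; the water and dry masses are
        # equal when x_w = rho_d (1 - x_w)/2, i.e. x_w = rho_d/(2 + rho_d)
        rho = 1.5
        x_w = rho / (2.0 + rho)
        assert volumetric_to_weight_percent(x_w, 1.0, rho) == \
            pytest.approx(50.0)

    @pytest.mark.parametrize("wt", [0.0, 10.0, 50.0, 66.7, 95.0])
    def test_inverse_round_trip(self, wt):
        x = weight_percent_to_volumetric(wt, 1.3, 1.4)
        assert volumetric_to_weight_percent(x, 1.3, 1.4) == pytest.approx(wt)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            volumetric_to_weight_percent(0.0, 1.0, 0.0)
        with pytest.raises(ValueError):
            volumetric_to_weight_percent(0.5, -1.0, 1.5)
        with pytest.raises(ValueError):
            weight_percent_to_volumetric(120.0, 1.0, 1.5)


class TestExtraction:
    def _h_exp(self, wt, geom, pulse=PulseModel(), seed=None):
        ref, sample = synthesize_thz_traces(wt, geom, pulse, seed=seed)
        return experimental_transfer_function(
            to_frequency_domain(sample), to_frequency_domain(ref),
            noise_floor=1e-8)

    def test_dry_leaf_identity(self):
        geom = LeafGeometry()
        res = extract_water_content(self._h_exp(0.0, geom), geom)
        assert res.water_wt_pct == pytest.approx(0.0, abs=1e-6)
        assert res.at_boundary

    def test_noise_free_recovery(self):
        geom = LeafGeometry()
        wt_in = volumetric_to_weight_percent(0.6, geom.dry_air_ratio,
                                             geom.density_dry_g_cm3)
        res = extract_water_content(self._h_exp(wt_in, geom), geom)
        assert abs(res.x_water - 0.6) < 1e-3

    def test_recovery_with_thickness_law(self):
        geom = LeafGeometry(thickness_um=180.0,
                            thickness_slope_um_per_wtpct=0.8,
                            thickness_intercept_um=120.0)
        for wt in (15.0, 55.0, 82.0):
            res = extract_water_content(self._h_exp(wt, geom), geom)
            assert res.water_wt_pct == pytest.approx(wt, abs=0.1)

    def test_noisy_monte_carlo_recovery(self):
        """Spectral noise of the configured amplitude leaves the estimate
        within half a weight percent on average over 100 seeded repeats."""
        geom = LeafGeometry()
        pulse = PulseModel(noise_sd=1e-3)
        wt_in = 60.0
        errs = []
        for seed in range(100):
            res = extract_water_content(
                self._h_exp(wt_in, geom, pulse, seed=seed), geom)
            errs.append(res.water_wt_pct - wt_in)
        errs = np.asarray(errs)
        assert np.abs(errs).mean() < 0.5
        assert np.abs(errs).max() < 2.0

    @pytest.mark.parametrize("wt_true", [20.0, 50.0, 80.0])
    def test_objective_unimodal_against_grid_scan(self, wt_true):
        """The 1-D objective has a single interior minimum on a 50-point
        grid, so the bounded scalar minimizer cannot be trapped."""
        geom = LeafGeometry()
        h_exp = self._h_exp(wt_true, geom)
        mask = h_exp.grid.band_mask(0.1, 0.3) & h_exp.valid
        sub = FrequencyGrid(h_exp.grid.freqs[mask])
        obs = h_exp.h[mask]
        xs = np.linspace(0.0, 1.0, 50)
        obj = np.array([np.sum(np.abs(
            obs - leaf_transfer_function(x, sub, geom).h) ** 2)
            for x in xs])
        interior_minima = sum(
            1 for i in range(1, len(xs) - 1)
            if obj[i] < obj[i - 1] and obj[i] < obj[i + 1])
        assert interior_minima <= 1
        res = extract_water_content(h_exp, geom)
        assert abs(res.x_water - xs[np.argmin(obj)]) < 0.03
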