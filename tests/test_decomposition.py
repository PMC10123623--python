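import lmfit
import numpy as np
import pytest

import laurdanspec as ls
from laurdanspec.bandshape import LogNormalBand
from laurdanspec.decomposition import FitBounds, FitError

from conftest import make_two_band


class TestRSquared:
    def _pair(self, grid):
        rng = np.random.default_rng(2)
        obs = ls.Spectrum(grid, rng.uniform(1.0, 5.0, grid.size))
        return obs

    def test_perfect_model_gives_one(self, grid):
        obs = self._pair(grid)
        assert ls.r_squared(obs, obs) == 1.0

    def test_constant_mean_model_gives_zero(self, grid):
        obs = self._pair(grid)
        mean = obs.with_intensities(np.full(grid.size, obs.intensities.mean()))
        assert np.isclose(ls.r_squared(obs, mean), 0.0, atol=1e-12)

    def test_worse_than_mean_is_negative(self, grid):
        obs = self._pair(grid)
        anti = obs.with_intensities(
            2 * obs.intensities.mean() - obs.intensities + 3.0
        )
        assert ls.r_squared(obs, anti) < 0

    def test_constant_observed_is_error(self, grid):
        flat = ls.Spectrum(grid, np.ones(grid.size))
        with pytest.raises(FitError, match="SS_tot"):
            ls.r_squared(flat, flat)

    def test_grid_mismatch_is_error(self, grid):
        obs = self._pair(grid)
        other = ls.Spectrum(grid + 1.0, obs.intensities)
        with pytest.raises(ValueError, match="grid"):
            ls.r_squared(obs, other)


class TestBounds:
    def test_default_asymmetry_cap(self):
        assert FitBounds().rho[1] == 1.5

    def test_cap_above_limit_rejected(self):
        with pytest.raises(ValueError, match="asymmetry cap"):
            FitBounds(rho=(0.5, 2.0))

    def test_inverted_bounds_rejected(self):
        with pytest.raises(ValueError, match="lower < upper"):
            FitBounds(fwhm=(4000.0, 800.0))


class TestInitialGuess:
    def test_single_long_band_still_two_valid_bands(self, grid):
        band = LogNormalBand.from_shape(100.0, 1e7 / 480.0, 3400.0, 1.3)
        s = ls.Spectrum(grid, band.evaluate(1e7 / grid))
        guess = ls.initial_guess(s)
        bounds = FitBounds()
        assert bounds.contains(guess)

    def test_guess_satisfies_asymmetry_cap(self, grid):
        model = make_two_band(i_long=50.0, i_short=80.0)
        s = ls.model_spectrum(model, grid)
        guess = ls.initial_guess(s)
        for band in (guess.band_long, guess.band_short):
            assert band.rho <= 1.5

    def test_guess_peaks_near_truth_for_two_band_spectrum(self, grid):
        model = make_two_band(i_long=60.0, i_short=40.0)
        s = ls.model_spectrum(model, grid)
        guess = ls.initial_guess(s)
        assert abs(guess.band_long.nu_m - model.band_long.nu_m) < 1000.0
        assert abs(guess.band_short.nu_m - model.band_short.nu_m) < 1000.0

    def test_uncovered_peak_window_is_error(self):
        s = ls.Spectrum(np.arange(450.0, 600.0, 0.4),
                        np.ones(375))
        with pytest.raises(FitError, match="cover"):
            ls.initial_guess(s)


class TestFitIndividual:
    def test_noiseless_round_trip_recovers_parameters(self, grid):
        truth = make_two_band(i_long=700.0, i_short=400.0)
        s = ls.model_spectrum(truth, grid)
        fit = ls.fit_individual(s)
        assert fit.converged
        assert fit.r2 >= 0.999
        for got, want in ((fit.model.band_long, truth.band_long),
                          (fit.model.band_short, truth.band_short)):
            for attr in ("i_max", "nu_m", "nu_max", "nu_min"):
                assert abs(getattr(got, attr) - getattr(want, attr)) <= (
                    1e-3 * abs(getattr(want, attr))
                )

    def test_noiseless_in_family_meets_quality_floor(self, dehydration_set):
        sset, _ = dehydration_set
        for cond in (80.0, 20.0):
            assert ls.fit_individual(sset.select(cond)[0]).r2 >= 0.993

    def test_fraction_conservation_is_exact(self, grid):
        fit = ls.fit_individual(ls.model_spectrum(make_two_band(), grid))
        assert abs(fit.fraction_long + fit.fraction_short - 100.0) <= 1e-9

    def test_label_stability(self, grid):
        fit = ls.fit_individual(ls.model_spectrum(make_two_band(), grid))
        assert fit.model.band_short.nu_m > fit.model.band_long.nu_m

    def test_asymmetry_cap_enforced_under_noise(self, grid):
        rng = np.random.default_rng(8)
        truth = make_two_band(i_long=700.0, i_short=400.0, rho_long=1.45)
        base = ls.model_spectrum(truth, grid).intensities
        for _ in range(3):
            noisy = np.clip(base + rng.normal(0, 7.0, base.size), 0, None)
            fit = ls.fit_individual(ls.Spectrum(grid, noisy))
            assert fit.model.band_long.rho <= 1.5 + 1e-12
            assert fit.model.band_short.rho <= 1.5 + 1e-12

    def test_constant_spectrum_is_error(self, grid):
        with pytest.raises(FitError, match="constant"):
            ls.fit_individual(ls.Spectrum(grid, np.ones(grid.size)))

    def test_one_parameter_fit_matches_grid_search_oracle(self):
        # 3-point toy problem, single free parameter (peak position):
        # the bounded optimizer must land on the brute-force minimum
        nu = np.array([20500.0, 21000.0, 21500.0])
        truth = LogNormalBand.from_shape(1.0, 21100.0, 2000.0, 1.2)
        obs = truth.evaluate(nu)

        def sse(num):
            return float(np.sum(
                (LogNormalBand.from_shape(1.0, num, 2000.0, 1.2).evaluate(nu)
                 - obs) ** 2))

        grid_num = np.linspace(20000.0, 22000.0, 4001)  # 0.5 cm^-1 oracle
        oracle = grid_num[int(np.argmin([sse(x) for x in grid_num]))]

        params = lmfit.Parameters()
        params.add("num", value=20500.0, min=20000.0, max=22000.0)
        res = lmfit.minimize(
            lambda p: LogNormalBand.from_shape(1.0, p["num"].value, 2000.0,
                                               1.2).evaluate(nu) - obs,
            params, method="least_squares",
        )
        assert abs(res.params["num"].value - oracle) <= 0.5


class TestFitGlobal:
    def test_single_condition_reduces_to_individual(self, grid):
        truth = make_two_band(i_long=700.0, i_short=400.0)
        s = ls.model_spectrum(truth, grid, condition_value=1.0)
        sset = ls.SpectrumSet([s], axis_kind="custom")
        gfit = ls.fit_global(sset)
        ifit = ls.fit_individual(s)
        assert abs(gfit.nu_m_long - ifit.model.band_long.nu_m) <= 1.0
        assert abs(gfit.nu_m_short - ifit.model.band_short.nu_m) <= 1.0

    def test_shared_peaks_recovered(self, dehydration_global, dehydration_set):
        _, truth = dehydration_set
        gfit = dehydration_global
        assert abs(gfit.nu_m_long - 1e7 / truth["band_long"]["peak_nm"]) <= 20.0
        assert abs(gfit.nu_m_short - 1e7 / truth["band_short"]["peak_nm"]) <= 20.0
        assert abs(gfit.peak_long_nm - 475.0) <= 1.0

    def test_global_r2_close_to_individual(self, dehydration_global):
        gfit = dehydration_global
        for cond in gfit.conditions:
            assert gfit.r2[cond] >= gfit.individual_r2[cond] - 0.005

    def test_every_condition_uses_shared_positions(self, dehydration_global):
        gfit = dehydration_global
        for model in gfit.models.values():
            assert model.band_long.nu_m == pytest.approx(gfit.nu_m_long)
            assert model.band_short.nu_m == pytest.approx(gfit.nu_m_short)

    def test_multiple_spots_per_condition_rejected(self, grid):
        truth = make_two_band()
        a = ls.model_spectrum(truth, grid, condition_value=1.0, spot_id="a")
        b = ls.model_spectrum(truth, grid, condition_value=1.0, spot_id="b")
        sset = ls.SpectrumSet([a, b])
        with pytest.raises(FitError, match="average"):
            ls.fit_global(sset)


class TestPopulationFractions:
    def test_equal_area_bands_split_evenly(self):
        band = LogNormalBand.from_shape(1.0, 21000.0, 2000.0, 1.2)
        other = LogNormalBand.from_shape(1.0, 23000.0, 2000.0, 1.2)
        model = ls.TwoBandModel(band_long=band, band_short=other)
        al, ash = model.band_long.area(), model.band_short.area()
        assert np.isclose(al, ash)

    def test_global_fractions_sum_to_100(self, dehydration_global):
        table = ls.population_fractions(dehydration_global)
        np.testing.assert_allclose(
            table["fraction_long"] + table["fraction_short"], 100.0, atol=1e-9
        )

    def test_unexpected_type_rejected(self):
        with pytest.raises(TypeError):
            ls.population_fractions(42)
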