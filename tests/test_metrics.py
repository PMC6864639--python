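"""RMSE, colour difference, oxygenation estimation and summaries."""

import numpy as np
import pytest

from sfaeval import (
    Illuminant,
    SIX_WAVELENGTHS,
    Spectrum,
    SpectrumSet,
    THREE_WAVELENGTHS,
    delta_e00,
    delta_oxy,
    estimate_oxygenation,
    evenly_spread_gsb,
    reconstruct,
    reflectance_to_absorbance,
    rmse,
    simulate_responses,
    summarize,
    train_wiener,
)
from sfaeval.skin import (
    beer_lambert_from_contributions,
    generate_parameter_grid,
    generate_training_set,
)


class TestRMSE:
    def test_identical_spectra_zero(self, grid, rng):
        s = Spectrum(grid, rng.uniform(0, 1, grid.n_points))
        assert rmse(s, s) == 0.0

    def test_constant_offset(self, grid):
        a = Spectrum(grid, np.full(grid.n_points, 0.2))
        b = Spectrum(grid, np.full(grid.n_points, 0.5))
        assert rmse(a, b) == pytest.approx(0.3, abs=1e-14)

    def test_matches_loop_oracle(self, grid, rng):
        a = Spectrum(grid, rng.uniform(0, 1, grid.n_points))
        b = Spectrum(grid, rng.uniform(0, 1, grid.n_points))
        acc = 0.0
        for x, y in zip(a.values, b.values):
            acc += (x - y) ** 2
        assert rmse(a, b) == pytest.approx(np.sqrt(acc / grid.n_points), abs=1e-14)

    def test_grid_mismatch_rejected(self, grid):
        from sfaeval import WavelengthGrid

        other = WavelengthGrid(400, 600, 2)
        with pytest.raises(ValueError):
            rmse(Spectrum(grid, np.ones(grid.n_points)),
                 Spectrum(other, np.ones(other.n_points)))


class TestDeltaE00Spectra:
    def test_identical_spectra_zero(self, grid, rng):
        s = Spectrum(grid, rng.uniform(0.2, 0.8, grid.n_points))
        assert delta_e00(s, s) == pytest.approx(0.0, abs=1e-12)

    def test_symmetric(self, grid, rng):
        a = Spectrum(grid, rng.uniform(0.2, 0.8, grid.n_points))
        b = Spectrum(grid, rng.uniform(0.2, 0.8, grid.n_points))
        assert delta_e00(a, b) == pytest.approx(delta_e00(b, a), abs=1e-12)

    def test_distinct_spectra_positive(self, grid):
        a = Spectrum(grid, np.full(grid.n_points, 0.2))
        b = Spectrum(grid, np.full(grid.n_points, 0.6))
        assert delta_e00(a, b) > 1.0


class TestAbsorbance:
    def test_unit_reflectance_zero_absorbance(self, grid):
        a = reflectance_to_absorbance(Spectrum(grid, np.ones(grid.n_points)))
        np.testing.assert_array_equal(a.values, 0.0)

    def test_tenth_reflectance_unit_absorbance(self, grid):
        a = reflectance_to_absorbance(Spectrum(grid, np.full(grid.n_points, 0.1)))
        np.testing.assert_allclose(a.values, 1.0, atol=1e-12)

    def test_round_trip(self, grid, rng):
        r = Spectrum(grid, rng.uniform(0.01, 1.0, grid.n_points))
        back = 10.0 ** (-reflectance_to_absorbance(r).values)
        np.testing.assert_allclose(back, r.values, atol=1e-12)

    def test_floor_keeps_absorbance_finite(self, grid):
        a = reflectance_to_absorbance(Spectrum(grid, np.zeros(grid.n_points)))
        assert np.all(np.isfinite(a.values))


class TestOxygenationEstimation:
    def test_pure_blood_mixture_recovered_exactly(self, lib):
        # absorbance built as 0.3 eps_ob + 0.7 eps_db; scaled to typical size
        c = np.array([0.0, 0.0, 0.3e-5, 0.7e-5])
        r = beer_lambert_from_contributions(c, lib)
        est = estimate_oxygenation(r, SIX_WAVELENGTHS, lib)
        assert est.s_oxy == pytest.approx(0.3, abs=1e-10)

    def test_fully_oxygenated_gives_saturation_one(self, lib):
        r = beer_lambert_from_contributions((0, 0, 1e-5, 0), lib)
        est = estimate_oxygenation(r, SIX_WAVELENGTHS, lib)
        assert est.s_oxy == pytest.approx(1.0, abs=1e-10)

    def test_all_four_coefficients_recovered(self, synthetic_lib):
        c_true = np.array([2e-5, 1e-5, 3e-5, 4e-5])
        r = beer_lambert_from_contributions(c_true, synthetic_lib)
        est = estimate_oxygenation(r, SIX_WAVELENGTHS, synthetic_lib)
        np.testing.assert_allclose(est.coefficients, c_true, atol=1e-10)

    def test_exact_on_span_for_any_full_rank_wavelength_set(self, lib, rng):
        wls = (500.0, 530.0, 552.0, 576.0, 598.0, 620.0, 650.0)
        eps = lib.extinction_matrix(wls)
        assert np.linalg.matrix_rank(eps) == 4
        c_true = rng.uniform(0, 1e-5, 4)
        r = beer_lambert_from_contributions(c_true, lib)
        est = estimate_oxygenation(r, wls, lib)
        np.testing.assert_allclose(est.coefficients, c_true, atol=1e-10)

    def test_three_wavelength_set_uses_minimum_norm_solution(self, lib):
        c_true = np.array([1e-5, 0.5e-5, 2e-5, 1e-5])
        r = beer_lambert_from_contributions(c_true, lib)
        est = estimate_oxygenation(r, THREE_WAVELENGTHS, lib)
        # underdetermined: the estimate reproduces the absorbances...
        eps = lib.extinction_matrix(THREE_WAVELENGTHS)
        np.testing.assert_allclose(eps @ est.coefficients, eps @ c_true, atol=1e-10)
        # ...with the smallest coefficient norm
        assert np.linalg.norm(est.coefficients) <= np.linalg.norm(c_true) + 1e-12

    def test_undefined_saturation_is_signalled_not_nan(self):
        from sfaeval import OxygenationEstimate

        est = OxygenationEstimate(1e-5, 2e-5, 0.0, 0.0)
        assert not est.defined
        assert est.s_oxy is None  # a signal, not a NaN
        assert est.s_oxy is not float("nan")


class TestDeltaOxy:
    def test_basic_values(self):
        assert delta_oxy(0.5, 0.5) == 0.0
        assert delta_oxy(1.0, 0.0) == 1.0

    def test_symmetric_and_matches_abs(self, rng):
        for _ in range(100):
            a, b = rng.uniform(0, 1, 2)
            assert delta_oxy(a, b) == delta_oxy(b, a) == abs(a - b)

    def test_undefined_propagates(self):
        assert delta_oxy(None, 0.5) is None
        assert delta_oxy(0.5, None) is None


class TestSummarize:
    def test_single_value(self):
        s = summarize([4.2])
        assert (s.min, s.max, s.mean, s.std) == (4.2, 4.2, 4.2, 0.0)
        assert s.p98 == 4.2

    def test_arithmetic_series(self):
        s = summarize(np.arange(1, 101, dtype=float))
        assert (s.min, s.max, s.mean) == (1.0, 100.0, 50.5)
        assert s.std == pytest.approx(np.std(np.arange(1, 101), ddof=1))

    def test_p98_matches_sorted_interpolation_oracle(self):
        vals = np.arange(1, 101, dtype=float)
        # linear-interpolation quantile at q=0.98 over sorted data
        pos = 0.98 * (len(vals) - 1)
        lo, frac = int(pos), pos - int(pos)
        oracle = vals[lo] * (1 - frac) + vals[lo + 1] * frac
        assert summarize(vals).p98 == pytest.approx(oracle, abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize([])


class TestEndToEndOxygenationRecovery:
    def test_mean_delta_oxy_decreases_with_channel_count(self, lib):
        """Simulated-skin saturation sweep: reconstructing with more
        Gaussian bands over 480-600 nm lowers the oxygenation error."""
        levels = {
            "s_oxy": tuple(np.linspace(0.1, 1.0, 4)),
            "f_blood": tuple(np.linspace(0.001, 0.01, 4)),
            "c_bilirubin": tuple(np.linspace(0.0, 0.225, 4)),
            "f_melanin": tuple(np.linspace(0.0, 0.1, 4)),
        }
        full = generate_training_set(generate_parameter_grid(levels), lib)
        train_half = SpectrumSet(lib.grid, full.values[0::2], kind="training")
        test_half = SpectrumSet(lib.grid, full.values[1::2], kind="test")
        illum = Illuminant.equi_energy(lib.grid)
        means = []
        for k in (3, 9):
            sensor = evenly_spread_gsb(k, lib.grid, lo=480.0, hi=600.0)
            est = train_wiener(train_half, illum, sensor)
            recon = reconstruct(est, simulate_responses(test_half, illum, sensor))
            errs = []
            for j in range(len(test_half)):
                s_ref = estimate_oxygenation(test_half[j], SIX_WAVELENGTHS, lib).s_oxy
                s_rec = estimate_oxygenation(recon[j], SIX_WAVELENGTHS, lib).s_oxy
                d = delta_oxy(s_ref, s_rec)
                if d is not None:
                    errs.append(d)
            means.append(np.mean(errs))
        assert means[1] < means[0]
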