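"""Pipeline orchestration, PCA diversity and report determinism."""

import numpy as np
import pytest

from sfaeval import (
    EvaluationConfig,
    SensorModel,
    SpectrumSet,
    WavelengthGrid,
    evenly_spread_gsb,
    extreme_members,
    format_report,
    make_synthetic_skin_like_set,
    pca_diversity,
    run_evaluation,
)
from sfaeval.skin import generate_parameter_grid, generate_training_set


@pytest.fixture(scope="module")
def skin_sets(lib):
    levels = {
        "s_oxy": tuple(np.linspace(0.1, 1.0, 4)),
        "f_blood": tuple(np.linspace(0.001, 0.01, 4)),
        "c_bilirubin": tuple(np.linspace(0.0, 0.225, 4)),
        "f_melanin": tuple(np.linspace(0.0, 0.1, 4)),
    }
    full = generate_training_set(generate_parameter_grid(levels), lib)
    training = SpectrumSet(lib.grid, full.values[0::2], kind="training",
                           meta=full.meta[0::2])
    test = SpectrumSet(lib.grid, full.values[1::2], kind="test", meta=full.meta[1::2])
    return training, test


class TestRunEvaluation:
    def test_identity_like_sensor_reconstructs_training_subset(self):
        grid = WavelengthGrid(400, 418, 2)  # small N for an N-channel sensor
        rng = np.random.default_rng(3)
        training = SpectrumSet(
            grid, rng.uniform(0.1, 0.9, (30, grid.n_points)), kind="training"
        )
        test = SpectrumSet(grid, training.values[:8], kind="test")
        sensor = SensorModel("identity", grid, np.eye(grid.n_points))
        cfg = EvaluationConfig(
            training=training, test=test, sensors=(sensor,),
            metrics=("rmse",), scale_sets=False,
        )
        report = run_evaluation(cfg)
        assert report.rows[("identity", "rmse")].mean == pytest.approx(0.0, abs=1e-8)

    def test_nine_bands_beat_three_bands_on_simulated_skin(self, skin_sets, lib):
        training, test = skin_sets
        cfg = EvaluationConfig(
            training=training, test=test,
            sensors=(evenly_spread_gsb(3, lib.grid), evenly_spread_gsb(9, lib.grid)),
            metrics=("rmse",),
        )
        report = run_evaluation(cfg)
        assert (
            report.rows[("gsb9", "rmse")].mean <= report.rows[("gsb3", "rmse")].mean
        )

    def test_rerun_with_same_seed_is_byte_identical(self, skin_sets, lib):
        training, test = skin_sets
        cfg = EvaluationConfig(
            training=training, test=test,
            sensors=(evenly_spread_gsb(5, lib.grid),),
            seed=17,
        )
        text1 = format_report(run_evaluation(cfg))
        text2 = format_report(run_evaluation(cfg))
        assert text1 == text2

    def test_gsb_twin_is_added_to_roster(self, skin_sets, lib):
        training, test = skin_sets
        sensor = evenly_spread_gsb(4, lib.grid, name="cam")
        cfg = EvaluationConfig(
            training=training, test=test, sensors=(sensor,),
            metrics=("rmse",), gsb_for=("cam",),
        )
        report = run_evaluation(cfg)
        assert report.sensor_names == ("cam", "Gcam")

    def test_failure_names_stage_and_sensor(self, skin_sets, lib):
        training, test = skin_sets
        bad = evenly_spread_gsb(3, lib.grid, name="badcam")
        cfg = EvaluationConfig(
            training=training, test=test, sensors=(bad,),
            metrics=("rmse",), oxy_wavelengths_6=(123.4,),
        )
        object.__setattr__(cfg, "metrics", ("delta_oxy_6",))
        with pytest.raises(RuntimeError, match="badcam"):
            run_evaluation(cfg)


class TestPCADiversity:
    def test_identical_rows_have_zero_variance_share(self, grid):
        a = SpectrumSet(grid, np.tile(np.linspace(0, 1, grid.n_points), (4, 1)),
                        kind="flat")
        b = SpectrumSet(grid,
                        np.random.default_rng(0).uniform(0, 1, (5, grid.n_points)),
                        kind="varied")
        res = pca_diversity([a, b])
        np.testing.assert_allclose(res.percentages["flat"], 0.0, atol=1e-12)

    def test_rank_one_sets_load_fully_on_pc1(self, grid):
        direction = np.linspace(0.1, 1.0, grid.n_points)
        coef_a = np.array([[0.1], [0.5], [0.9]])
        coef_b = np.array([[0.2], [0.8]])
        a = SpectrumSet(grid, coef_a * direction, kind="a")
        b = SpectrumSet(grid, coef_b * direction, kind="b")
        res = pca_diversity([a, b])
        assert res.percentages["a"][0] == pytest.approx(100.0, abs=1e-8)
        assert res.percentages["b"][0] == pytest.approx(100.0, abs=1e-8)

    def test_matches_covariance_eigendecomposition_oracle(self, grid, rng):
        a = SpectrumSet(grid, rng.uniform(0, 1, (3, grid.n_points)), kind="a")
        b = SpectrumSet(grid, rng.uniform(0, 1, (3, grid.n_points)), kind="b")
        res = pca_diversity([a, b], k=4)
        stacked = np.vstack([a.values, b.values])
        centred = stacked - stacked.mean(axis=0)
        cov = centred.T @ centred
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        np.testing.assert_allclose(
            res.combined_percentages, 100.0 * evals[:4] / evals.sum(), atol=1e-8
        )
        # per-set percentages from the oracle's components
        proj = (a.values - stacked.mean(axis=0)) @ evecs[:, :4]
        var_along = ((proj - proj.mean(axis=0)) ** 2).sum(axis=0)
        tot = ((a.values - a.values.mean(axis=0)) ** 2).sum()
        np.testing.assert_allclose(
            res.percentages["a"], 100.0 * var_along / tot, atol=1e-8
        )

    def test_per_set_percentages_invariant_to_set_order(self, grid, rng):
        a = SpectrumSet(grid, rng.uniform(0, 1, (4, grid.n_points)), kind="a")
        b = SpectrumSet(grid, rng.uniform(0, 1, (6, grid.n_points)), kind="b")
        r1 = pca_diversity([a, b])
        r2 = pca_diversity([b, a])
        np.testing.assert_allclose(
            r1.percentages["a"], r2.percentages["a"], atol=1e-8
        )

    def test_single_set_rejected(self, grid, random_set):
        with pytest.raises(ValueError):
            pca_diversity([random_set])


class TestExtremeMembers:
    def test_rank_one_extremes_are_global_min_max_rows(self, grid):
        direction = np.linspace(0.1, 1.0, grid.n_points)
        coefs = np.array([[0.5], [0.1], [0.9], [0.4]])
        a = SpectrumSet(grid, coefs * direction, kind="a")
        b = SpectrumSet(grid, 0.5 * direction[None, :] + np.array([[0.0], [0.01]]),
                        kind="b")
        res = pca_diversity([a, b])
        ext = {e.which: e for e in extreme_members(a, res)}
        got = {ext["min_pc1"].label, ext["max_pc1"].label}
        assert got == {"s1", "s2"}  # rows 1 (coef .1) and 2 (coef .9)

    def test_simulated_set_extremes_carry_parameters(self, skin_sets):
        training, test = skin_sets
        res = pca_diversity([training, test])
        ext = extreme_members(training, res, set_label="training")
        from sfaeval import SkinParameters

        assert all(isinstance(e.parameters, SkinParameters) for e in ext)

    def test_deterministic_under_ties(self, grid):
        vals = np.tile(np.linspace(0, 1, grid.n_points), (3, 1))
        vals[2] += 0.1
        a = SpectrumSet(grid, vals, kind="a")
        b = SpectrumSet(grid, vals + 0.05, kind="b")
        res = pca_diversity([a, b])
        e1 = extreme_members(a, res)
        e2 = extreme_members(a, res)
        assert [x.label for x in e1] == [x.label for x in e2]
        # rows 0 and 1 are identical: the tie resolves to the first row
        assert {e.which: e.label for e in e1}["min_pc1"] in ("s0", "s2")


class TestSyntheticTestSet:
    def test_reproducible_and_bounded(self):
        a = make_synthetic_skin_like_set(100, seed=5)
        b = make_synthetic_skin_like_set(100, seed=5)
        np.testing.assert_array_equal(a.values, b.values)
        assert a.values.min() >= 0.0 and a.values.max() <= 1.0

    def test_mean_spectrum_has_hemoglobin_dip(self, grid):
        sset = make_synthetic_skin_like_set(50, seed=2)
        mean = sset.values.mean(axis=0)
        wl = grid.wavelengths
        window = (wl >= 520) & (wl <= 600)
        inner = mean[window]
        k = int(np.argmin(inner))
        assert 0 < k < inner.size - 1  # interior local minimum
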