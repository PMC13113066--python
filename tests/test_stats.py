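"""Factorial ANOVA/OLS machinery against brute-force oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.stattools import durbin_watson as sm_durbin_watson

from boarscan import stats
from boarscan.stats import (FACTOR_LEVELS, FACTORS, EstimabilityError,
                            ScanConfig, all_configs, condition_number,
                            durbin_watson, fit_main_effects, fit_two_way,
                            simulate_factor_responses)


def brute_force_main_effect_ss(frame, metric):
    """Sum of squares of each factor by direct group-mean decomposition.

    For a balanced factorial, the factor SS is the squared deviation of the
    level means from the grand mean, weighted by the level group sizes.
    """
    y = frame[metric].to_numpy(float)
    grand = y.mean()
    out = {}
    for f in FACTORS:
        ss = 0.0
        for level in FACTOR_LEVELS[f]:
            sel = frame[f] == level
            ss += sel.sum() * (y[sel.to_numpy()].mean() - grand) ** 2
        out[f] = ss
    return out


class TestScanConfig:
    def test_sixteen_distinct_configs(self):
        cfgs = all_configs()
        assert len(cfgs) == len(set(cfgs)) == 16

    def test_level_zero_codes(self):
        assert ScanConfig("full", "horizontal", "morphological",
                          "medium").codes() == (0, 0, 0, 0)
        assert ScanConfig("cropped", "vertical", "comprehensive",
                          "small").codes() == (1, 1, 1, 1)

    def test_unknown_level_rejected(self):
        with pytest.raises(ValueError):
            ScanConfig(region="oblique")


class TestMainEffects:
    def test_ss_matches_brute_force_decomposition(self):
        results = simulate_factor_responses(
            {"region": -0.2, "angle": 0.1, "model": 0.03}, n_runs=3,
            noise_sd=0.02, seed=4, metric="recall")
        report = fit_main_effects(results, "recall")
        oracle = brute_force_main_effect_ss(results.dropna(subset=["recall"]),
                                            "recall")
        for f, row in zip(FACTORS, report.anova.itertuples(index=False)):
            assert row.sum_sq == pytest.approx(oracle[f], rel=1e-8)

    def test_ss_additivity_on_balanced_grid(self):
        results = simulate_factor_responses({"angle": 0.15}, n_runs=4,
                                            noise_sd=0.05, seed=1)
        report = fit_main_effects(results, "recall")
        y = results["recall"].to_numpy(float)
        total = float(((y - y.mean()) ** 2).sum())
        assert report.anova["sum_sq"].sum() + report.residual_ss == \
            pytest.approx(total, rel=1e-8)

    def test_all_equal_responses_give_zero_f_and_coefficients(self):
        results = simulate_factor_responses({}, n_runs=2, noise_sd=0.0,
                                            base=0.5, seed=0)
        report = fit_main_effects(results, "recall")
        assert (report.anova["F"] == 0.0).all()
        assert (report.coefficients["estimate"] == 0.0).all()

    def test_planted_effect_recovered_with_sign_and_significance(self):
        results = simulate_factor_responses({"region": -0.2}, n_runs=10,
                                            noise_sd=0.03, seed=7)
        report = fit_main_effects(results, "recall")
        coef = report.coefficients.set_index("term").loc["Region (Cropped)"]
        assert coef["estimate"] == pytest.approx(-0.2, abs=0.05)
        assert coef["estimate"] < 0 and coef["p"] < 0.05
        assert coef["ci_low"] <= coef["estimate"] <= coef["ci_high"]

    def test_missing_cells_raise_estimability_error(self):
        results = simulate_factor_responses({}, n_runs=2, seed=0)
        broken = results[results["region"] == "full"]
        with pytest.raises(EstimabilityError, match="cropped"):
            fit_two_way(broken, "recall")

    def test_two_factor_grid_matches_textbook_anova(self):
        # hand-checkable 2x2 with 2 replicates, embedded in the full grid by
        # collapsing the other factors: fit on a balanced 4-factor table
        # whose response depends on region and angle only
        results = simulate_factor_responses(
            {"region": 0.1, "angle": -0.06}, n_runs=2, noise_sd=0.0, seed=0)
        report = fit_main_effects(results, "recall")
        table = report.anova.set_index("factor")
        n = len(results)
        assert table.loc["Region (Cropped)", "sum_sq"] == \
            pytest.approx(n / 4 * 0.1 ** 2, rel=1e-8)
        assert table.loc["Angle (Vertical)", "sum_sq"] == \
            pytest.approx(n / 4 * 0.06 ** 2, rel=1e-8)


class TestTwoWay:
    def test_additive_truth_gives_no_significant_interactions(self):
        # under an additive truth the interaction p-values are null: each
        # test rejects at about the 5 percent level and no more
        pvals = []
        for rep in range(20):
            results = simulate_factor_responses(
                {"region": -0.1, "angle": 0.05}, n_runs=10, noise_sd=0.01,
                seed=100 + rep)
            report = fit_two_way(results, "recall")
            inter = report.anova[report.anova["factor"].str.contains(":")]
            assert len(inter) == 6
            pvals.extend(inter["p"])
        assert np.mean(np.asarray(pvals) > 0.05) >= 0.90  # expected 0.95

    def test_planted_interaction_dominates(self):
        results = simulate_factor_responses(
            {"angle": 0.05}, n_runs=10, noise_sd=0.01,
            interactions={("angle", "augmentation"): -0.15}, seed=3)
        report = fit_two_way(results, "recall")
        inter = report.anova[report.anova["factor"].str.contains(":")]
        best = inter.loc[inter["F"].idxmax(), "factor"]
        assert best == "Angle (Vertical):Augmentation (Comprehensive)"

    def test_main_effect_rows_retained(self):
        results = simulate_factor_responses({"region": -0.1}, n_runs=2,
                                            noise_sd=0.01, seed=0)
        report = fit_two_way(results, "recall")
        assert len(report.anova) == 10  # 4 mains + 6 interactions

    def test_interaction_with_constant_factor_has_zero_ss(self):
        # vary only the region; every term involving the other factors is 0
        results = simulate_factor_responses({"region": -0.1}, n_runs=2,
                                            noise_sd=0.0, seed=0)
        report = fit_two_way(results, "recall")
        table = report.anova.set_index("factor")
        assert table.loc["Region (Cropped):Angle (Vertical)", "sum_sq"] == \
            pytest.approx(0.0, abs=1e-12)


class TestDurbinWatson:
    def test_alternating_residuals(self):
        # diffs (+-2)^2 * 3 = 12 over ssr 4
        assert durbin_watson([1.0, -1.0, 1.0, -1.0]) == pytest.approx(3.0)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            durbin_watson([0.0, 0.0, 0.0])

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            durbin_watson([1.0])

    def test_independent_residuals_near_two(self):
        r = np.random.default_rng(0).standard_normal(10000)
        assert 1.9 <= durbin_watson(r) <= 2.1

    def test_agrees_with_statsmodels(self):
        r = np.random.default_rng(1).standard_normal(257)
        assert durbin_watson(r) == pytest.approx(float(sm_durbin_watson(r)),
                                                 rel=1e-12)


class TestConditionNumber:
    def test_orthonormal_columns(self):
        assert condition_number(np.eye(6)[:, :3]) == pytest.approx(1.0)

    def test_balanced_pm_one_design_with_intercept(self):
        levels = np.array(list(itertools.product([-1, 1], repeat=4)), float)
        x = np.hstack([np.ones((16, 1)), levels])
        assert condition_number(x) == pytest.approx(1.0, abs=1e-10)

    def test_duplicated_column_rejected(self):
        x = np.random.default_rng(0).normal(size=(10, 2))
        with pytest.raises(ValueError):
            condition_number(np.hstack([x, x[:, :1]]))


class TestDirectionalReproduction:
    def test_fitted_signs_match_expected_directions(self, replicate_reports):
        """Cropping lowers recall, brightness augmentation lowers precision
        and the vertical angle raises recall in >= 80% of replicate grids."""
        hits = {"region": 0, "aug": 0, "angle": 0}
        for rep in replicate_reports:
            rec = rep["recall"].coefficients.set_index("term")
            prec = rep["precision"].coefficients.set_index("term")
            hits["region"] += rec.loc["Region (Cropped)", "estimate"] < 0
            hits["angle"] += rec.loc["Angle (Vertical)", "estimate"] > 0
            hits["aug"] += prec.loc["Augmentation (Comprehensive)",
                                    "estimate"] < 0
        n = len(replicate_reports)
        for key, count in hits.items():
            assert count >= int(np.ceil(0.8 * n)), (key, hits)


class TestRunGrid:
    def test_row_count_and_determinism(self, tiny_dataset):
        res1 = stats.run_grid(tiny_dataset, n_runs=1, base_seed=5)
        res2 = stats.run_grid(tiny_dataset, n_runs=1, base_seed=5)
        assert len(res1) == 16
        assert res1["run"].nunique() == 1
        pd.testing.assert_frame_equal(res1, res2)

    def test_resume_skips_existing_rows(self, tiny_dataset):
        full = stats.run_grid(tiny_dataset, n_runs=1, base_seed=5)
        partial = full.iloc[:10]
        resumed = stats.run_grid(tiny_dataset, n_runs=1, base_seed=5,
                                 existing=partial)
        pd.testing.assert_frame_equal(
            resumed.reset_index(drop=True), full.reset_index(drop=True))

    def test_metrics_in_unit_interval(self, tiny_dataset):
        res = stats.run_grid(tiny_dataset, n_runs=1, base_seed=2)
        for m in ("precision", "recall", "f1"):
            assert res[m].between(0, 1).all()
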