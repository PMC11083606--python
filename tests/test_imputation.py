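"""Ridge imputation: coverage filter, harmonization, fitting, prediction."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from drugsense.imputation import (fit_models, fit_ridge, filter_drugs,
                                  gene_response_correlation, harmonize,
                                  impute, impute_panel)
from drugsense.simulate import apply_platform_effect


def _screen(n_lines, coverage_by_drug, seed=0):
    rng = np.random.default_rng(seed)
    cols = {}
    for drug, n_obs in coverage_by_drug.items():
        col = rng.normal(15, 2, n_lines)
        missing = rng.permutation(n_lines)[n_obs:]
        col[missing] = np.nan
        cols[drug] = col
    return pd.DataFrame(cols, index=[f"CL{i}" for i in range(n_lines)])


class TestFilterDrugs:
    def test_strict_removal_below_threshold(self):
        # 350 of 887 lines = 39.5% coverage -> removed
        screen = _screen(887, {"low": 350, "high": 500})
        out = filter_drugs(screen)
        assert list(out.columns) == ["high"]
        assert out.shape[0] == 887

    def test_exact_boundary_retained(self):
        screen = _screen(100, {"edge": 40})
        assert list(filter_drugs(screen).columns) == ["edge"]
        screen = _screen(100, {"below": 39})
        with pytest.warns(UserWarning):
            assert filter_drugs(screen).shape[1] == 0

    def test_complete_screen_unchanged(self):
        screen = _screen(50, {"a": 50, "b": 50})
        pd.testing.assert_frame_equal(filter_drugs(screen), screen)

    def test_empty_screen_errors(self):
        with pytest.raises(ValueError, match="empty"):
            filter_drugs(pd.DataFrame())

    def test_all_removed_warns(self):
        screen = _screen(100, {"a": 10})
        with pytest.warns(UserWarning, match="every drug"):
            out = filter_drugs(screen)
        assert out.shape[1] == 0


class TestHarmonize:
    def test_identity_round_trip(self, small_panel):
        expr, _, _ = small_panel
        train, test = harmonize(expr, expr)
        pd.testing.assert_frame_equal(train, expr)
        np.testing.assert_allclose(test.to_numpy(), expr.to_numpy(), atol=1e-9)

    def test_monotone_distortion_recovered(self, small_panel):
        expr, _, _ = small_panel
        distorted = apply_platform_effect(expr, "monotone", seed=3)
        _, recovered = harmonize(expr, distorted)
        np.testing.assert_allclose(recovered.to_numpy(), expr.to_numpy(),
                                   atol=1e-8)

    def test_disjoint_gene_ids_error(self, toy_expression):
        other = toy_expression.copy()
        other.index = ["X1", "X2", "X3"]
        with pytest.raises(ValueError, match="no shared gene"):
            harmonize(toy_expression, other)

    def test_idempotence(self, small_panel, rng):
        expr, _, _ = small_panel
        test = pd.DataFrame(rng.normal(0, 2, (expr.shape[0], 30)),
                            index=expr.index,
                            columns=[f"T{i}" for i in range(30)])
        _, once = harmonize(expr, test)
        _, twice = harmonize(expr, once)
        np.testing.assert_allclose(twice.to_numpy(), once.to_numpy(), atol=1e-9)

    def test_restricts_to_shared_genes_in_train_order(self, toy_expression):
        test = toy_expression.iloc[[2, 0]].copy()  # GC, GA
        train_out, test_out = harmonize(toy_expression, test)
        assert list(train_out.index) == ["GA", "GC"]
        assert list(test_out.index) == ["GA", "GC"]


class TestFitRidge:
    def test_constant_response_gives_zero_weights(self, rng):
        expr = pd.DataFrame(rng.normal(size=(5, 30)),
                            index=[f"G{i}" for i in range(5)],
                            columns=[f"C{i}" for i in range(30)])
        auc = pd.Series(12.5, index=expr.columns)
        m = fit_ridge(expr, auc, lam_mode="fixed", lam=1.0)
        assert np.abs(m.coef).max() < 1e-8
        assert m.intercept == pytest.approx(12.5)

    def test_matches_hand_solved_normal_equations(self):
        # 3 lines, 2 genes, lambda = 1, small integers
        expr = pd.DataFrame([[1.0, 2.0, 3.0], [2.0, 1.0, 2.0]],
                            index=["g1", "g2"], columns=["a", "b", "c"])
        auc = pd.Series([1.0, 2.0, 4.0], index=["a", "b", "c"])
        m = fit_ridge(expr, auc, lam_mode="fixed", lam=1.0, standardize=False)
        X = expr.to_numpy().T
        yc = auc.to_numpy() - auc.mean()
        beta = np.linalg.solve(X.T @ X + np.eye(2), X.T @ yc)
        np.testing.assert_allclose(m.coef, beta, atol=1e-10)
        assert m.intercept == pytest.approx(auc.mean())

    def test_noiseless_weight_recovery(self, rng):
        g = rng.normal(size=(2, 200))
        expr = pd.DataFrame(g, index=["g1", "g2"],
                            columns=[f"C{i}" for i in range(200)])
        auc = pd.Series(2.0 * g[0] - 1.0 * g[1], index=expr.columns)
        m = fit_ridge(expr, auc, lam_mode="fixed", lam=1e-6)
        recovered = m.coef / m.gene_scale   # back to raw-expression scale
        np.testing.assert_allclose(recovered, [2.0, -1.0], atol=1e-3)

    def test_shrinkage_monotone_in_lambda(self, rng):
        expr = pd.DataFrame(rng.normal(size=(10, 40)),
                            index=[f"G{i}" for i in range(10)],
                            columns=[f"C{i}" for i in range(40)])
        auc = pd.Series(rng.normal(15, 2, 40), index=expr.columns)
        norms = [np.linalg.norm(
            fit_ridge(expr, auc, lam_mode="fixed", lam=lam).coef)
            for lam in [0.01, 0.1, 1, 10, 100]]
        assert all(a >= b - 1e-12 for a, b in zip(norms, norms[1:]))

    def test_lines_with_missing_auc_do_not_affect_fit(self, rng):
        expr = pd.DataFrame(rng.normal(size=(6, 50)),
                            index=[f"G{i}" for i in range(6)],
                            columns=[f"C{i}" for i in range(50)])
        auc = pd.Series(rng.normal(15, 2, 50), index=expr.columns)
        m_full = fit_ridge(expr, auc, lam_mode="fixed", lam=1.0)
        extra = pd.DataFrame(rng.normal(size=(6, 10)), index=expr.index,
                             columns=[f"X{i}" for i in range(10)])
        expr2 = pd.concat([expr, extra], axis=1)
        auc2 = pd.concat([auc, pd.Series(np.nan, index=extra.columns)])
        m_aug = fit_ridge(expr2, auc2, lam_mode="fixed", lam=1.0)
        np.testing.assert_allclose(m_aug.coef, m_full.coef, atol=1e-12)
        assert m_aug.n_train == m_full.n_train == 50

    def test_too_few_training_points_error(self, toy_expression):
        auc = pd.Series([np.nan] * 5 + [15.0], index=toy_expression.columns)
        with pytest.raises(ValueError, match=">= 2"):
            fit_ridge(toy_expression, auc)

    def test_zero_variance_gene_dropped(self, rng, caplog):
        expr = pd.DataFrame(rng.normal(size=(3, 20)),
                            index=["g1", "g2", "g3"],
                            columns=[f"C{i}" for i in range(20)])
        expr.loc["g2"] = 7.0
        auc = pd.Series(rng.normal(15, 1, 20), index=expr.columns)
        with caplog.at_level("WARNING"):
            m = fit_ridge(expr, auc, lam_mode="fixed", lam=1.0)
        assert m.genes == ["g1", "g3"]
        assert "zero-variance" in caplog.text


class TestImpute:
    def test_training_point_interpolated_in_noiseless_limit(self, rng):
        # more lines than genes, noiseless linear response, tiny penalty
        g = rng.normal(size=(4, 60))
        expr = pd.DataFrame(g, index=[f"G{i}" for i in range(4)],
                            columns=[f"C{i}" for i in range(60)])
        w = np.array([1.0, -2.0, 0.5, 3.0])
        auc = pd.Series(15.0 + w @ g, index=expr.columns)
        m = fit_ridge(expr, auc, lam_mode="fixed", lam=1e-8)
        predicted = impute(m, expr[["C3"]])
        assert predicted["C3"] == pytest.approx(auc["C3"], abs=1e-6)

    def test_mean_profile_scores_at_intercept(self, rng):
        expr = pd.DataFrame(rng.normal(size=(5, 40)),
                            index=[f"G{i}" for i in range(5)],
                            columns=[f"C{i}" for i in range(40)])
        auc = pd.Series(rng.normal(15, 2, 40), index=expr.columns)
        m = fit_ridge(expr, auc, lam_mode="fixed", lam=1.0)
        mean_profile = pd.DataFrame(
            {"S0": pd.Series(m.gene_mean, index=m.genes)})
        assert impute(m, mean_profile)["S0"] == pytest.approx(m.intercept)

    def test_gene_mismatch_error(self, rng):
        expr = pd.DataFrame(rng.normal(size=(4, 30)),
                            index=[f"G{i}" for i in range(4)],
                            columns=[f"C{i}" for i in range(30)])
        auc = pd.Series(rng.normal(15, 2, 30), index=expr.columns)
        m = fit_ridge(expr, auc, lam_mode="fixed", lam=1.0)
        bad = expr.iloc[:2]
        with pytest.raises(ValueError, match="lacks"):
            impute(m, bad)

    def test_shifted_gbm_cohort_scores_more_sensitive(self, small_config,
                                                      small_panel,
                                                      small_cohort):
        expr, screen, _ = small_panel
        models = fit_models(expr, filter_drugs(screen))
        _, harmonized = harmonize(expr, small_cohort.expression)
        imputed = impute_panel(models, harmonized)
        for drug in imputed.columns:
            gbm = imputed.loc[small_cohort.labels == "GBM", drug]
            ctrl = imputed.loc[small_cohort.labels == "control", drug]
            assert gbm.mean() < ctrl.mean()


class TestGeneResponseCorrelation:
    def test_self_and_antimonotone_correlation(self, rng):
        resp = rng.normal(size=20)
        expr = pd.DataFrame(
            [resp, -np.exp(resp), rng.normal(size=20)],
            index=["same", "anti", "noise"],
            columns=[f"S{i}" for i in range(20)])
        imputed = pd.DataFrame({"d": resp}, index=expr.columns)
        tab = gene_response_correlation(expr, imputed, "d").set_index("gene")
        assert tab.loc["same", "r"] == pytest.approx(1.0)
        assert tab.loc["anti", "r"] == pytest.approx(-1.0)
        assert abs(tab.loc["noise", "r"]) < 0.7

    def test_matches_rank_then_pearson_with_ties(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 4.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 5.0])
        expr = pd.DataFrame([x], index=["g"],
                            columns=[f"S{i}" for i in range(5)])
        imputed = pd.DataFrame({"d": y}, index=expr.columns)
        tab = gene_response_correlation(expr, imputed, "d")
        oracle = stats.pearsonr(stats.rankdata(x), stats.rankdata(y)).statistic
        assert tab["r"].iloc[0] == pytest.approx(oracle, abs=1e-12)

    def test_constant_gene_reported_missing(self, rng):
        expr = pd.DataFrame([np.full(10, 3.0), rng.normal(size=10)],
                            index=["flat", "ok"],
                            columns=[f"S{i}" for i in range(10)])
        imputed = pd.DataFrame({"d": rng.normal(size=10)}, index=expr.columns)
        with pytest.warns(UserWarning, match="constant"):
            tab = gene_response_correlation(expr, imputed, "d")
        assert np.isnan(tab.set_index("gene").loc["flat", "r"])
        assert np.isfinite(tab.set_index("gene").loc["ok", "q"])
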