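"""Constraint-based discovery: CI tests, MMPC, orientation, reporting."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from drugsense.causal import (LABEL_RESISTANCE, LABEL_SENSITIVITY,
                              RESPONSE, biomarker_report, fisher_z_test,
                              mmpc, orient_parents, partial_correlation,
                              scc_filter)


def _df(rows: dict, prefix="S") -> pd.DataFrame:
    n = len(next(iter(rows.values())))
    return pd.DataFrame(rows, index=[f"{prefix}{i}" for i in range(n)]).T


class TestSccFilter:
    def test_retained_iff_thresholds_met(self, rng):
        expr = pd.DataFrame(rng.normal(size=(50, 100)),
                            index=[f"G{i}" for i in range(50)],
                            columns=[f"S{i}" for i in range(100)])
        resp = pd.Series(rng.normal(size=100), index=expr.columns)
        expr.iloc[0] = resp.to_numpy() + rng.normal(0, 0.3, 100)  # strong
        tab = scc_filter(expr, resp, r_min=0.6, q_max=0.05)
        expected = (tab["q"] < 0.05) & (tab["r"].abs() >= 0.6)
        assert (tab["retained"] == expected).all()
        assert tab.set_index("gene").loc["G0", "retained"]

    def test_threshold_is_on_absolute_r(self, rng):
        expr = pd.DataFrame(rng.normal(size=(5, 200)),
                            index=[f"G{i}" for i in range(5)],
                            columns=[f"S{i}" for i in range(200)])
        resp = pd.Series(rng.normal(size=200), index=expr.columns)
        expr.iloc[0] = -resp.to_numpy() + rng.normal(0, 0.2, 200)
        tab = scc_filter(expr, resp).set_index("gene")
        assert tab.loc["G0", "r"] < -0.6
        assert tab.loc["G0", "retained"]

    def test_noise_gene_excluded_at_large_n(self, rng):
        expr = pd.DataFrame(rng.normal(size=(1, 500)), index=["noise"],
                            columns=[f"S{i}" for i in range(500)])
        resp = pd.Series(rng.normal(size=500), index=expr.columns)
        assert not scc_filter(expr, resp)["retained"].iloc[0]

    def test_constant_response_errors(self, toy_expression):
        resp = pd.Series(1.0, index=toy_expression.columns)
        with pytest.raises(ValueError, match="constant"):
            scc_filter(toy_expression, resp)


class TestPartialCorrelation:
    def test_empty_conditioning_equals_pearson(self, rng):
        x, y = rng.normal(size=(2, 60))
        assert partial_correlation(x, y) == pytest.approx(
            stats.pearsonr(x, y).statistic, abs=1e-12)

    def test_matches_correlation_matrix_formula(self, rng):
        z = rng.normal(size=200)
        x = 0.9 * z + 0.45 * rng.normal(size=200)
        y = 0.9 * z + 0.45 * rng.normal(size=200)
        r_xy = stats.pearsonr(x, y).statistic
        r_xz = stats.pearsonr(x, z).statistic
        r_yz = stats.pearsonr(y, z).statistic
        oracle = (r_xy - r_xz * r_yz) / math.sqrt(
            (1 - r_xz**2) * (1 - r_yz**2))
        assert partial_correlation(x, y, z) == pytest.approx(oracle, abs=1e-10)

    def test_residual_vs_matrix_inverse_on_random_samples(self, rng):
        # dual-route agreement over many random 3- and 4-variable draws
        for _ in range(300):
            k = rng.integers(1, 3)
            data = rng.normal(size=(30, 2 + k))
            mixed = data @ rng.normal(size=(2 + k, 2 + k)) * 0.5 + data
            x, y, Z = mixed[:, 0], mixed[:, 1], mixed[:, 2:]
            res = partial_correlation(x, y, Z)
            corr = np.corrcoef(mixed, rowvar=False)
            prec = np.linalg.inv(corr)
            oracle = -prec[0, 1] / math.sqrt(prec[0, 0] * prec[1, 1])
            assert res == pytest.approx(oracle, abs=1e-8)

    def test_identical_vectors_give_one(self, rng):
        x = rng.normal(size=50)
        z = rng.normal(size=50)
        assert partial_correlation(x, x.copy(), z) == pytest.approx(1.0)

    def test_rank_deficient_conditioning_errors(self, rng):
        x, y, z = rng.normal(size=(3, 40))
        Z = np.column_stack([z, 2 * z])
        with pytest.raises(ValueError, match="linearly dependent"):
            partial_correlation(x, y, Z)

    def test_sample_size_guard(self, rng):
        x, y = rng.normal(size=(2, 5))
        Z = rng.normal(size=(5, 3))
        with pytest.raises(ValueError, match="n >"):
            partial_correlation(x, y, Z)


class TestFisherZ:
    def test_zero_correlation(self):
        t, p = fisher_z_test(0.0, 100, 0)
        assert t == 0.0
        assert p == 1.0

    def test_formula_evaluation(self):
        t, p = fisher_z_test(0.5, 50, 1)
        assert t == pytest.approx(math.sqrt(46) * math.atanh(0.5), abs=1e-9)
        assert t == pytest.approx(3.726, abs=0.001)
        assert p == pytest.approx(1.95e-4, rel=0.01)

    def test_perfect_correlation_sentinel(self):
        t, p = fisher_z_test(1.0, 50, 0)
        assert t == math.inf and p == 0.0
        t, p = fisher_z_test(-1.0, 50, 0)
        assert t == -math.inf and p == 0.0

    def test_p_monotone_in_abs_rho(self):
        ps = [fisher_z_test(r, 40, 2)[1] for r in np.linspace(0, 0.95, 12)]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_sign_carried_through(self):
        t_pos, _ = fisher_z_test(0.4, 50, 0)
        t_neg, _ = fisher_z_test(-0.4, 50, 0)
        assert t_pos > 0 > t_neg
        assert t_pos == pytest.approx(-t_neg)


class TestMMPC:
    def test_redundant_proxy_excluded(self, rng):
        n = 2000
        x1, x2 = rng.normal(size=(2, n))
        x3 = x1 + 0.1 * rng.normal(size=n)          # proxy of x1, no effect
        resp = pd.Series(x1 + x2 + 0.5 * rng.normal(size=n),
                         index=[f"S{i}" for i in range(n)])
        cand = _df({"X1": x1, "X2": x2, "X3": x3})
        cand.columns = resp.index
        # sanity: X3 really is independent of response given X1
        assert abs(partial_correlation(x3, resp.to_numpy(), x1)) < 0.05
        pc = mmpc(resp, cand)
        assert set(pc.pc_genes) == {"X1", "X2"}

    def test_independent_candidates_give_empty_pc(self, rng):
        n = 400
        resp = pd.Series(rng.normal(size=n),
                         index=[f"S{i}" for i in range(n)])
        cand = pd.DataFrame(rng.normal(size=(10, n)),
                            index=[f"G{i}" for i in range(10)],
                            columns=resp.index)
        pc = mmpc(resp, cand, alpha=0.01)
        assert len(pc.pc_genes) <= 1      # at most a chance survivor

    def test_empty_candidate_matrix(self, rng):
        resp = pd.Series(rng.normal(size=50),
                         index=[f"S{i}" for i in range(50)])
        pc = mmpc(resp, pd.DataFrame(columns=resp.index))
        assert pc.pc_genes == []

    def test_every_pc_gene_has_signed_statistic(self, rng):
        n = 1000
        x1, x2 = rng.normal(size=(2, n))
        resp = pd.Series(2 * x1 - x2 + rng.normal(size=n),
                         index=[f"S{i}" for i in range(n)])
        cand = _df({"up": x1, "down": x2})
        cand.columns = resp.index
        pc = mmpc(resp, cand)
        assert set(pc.pc_genes) == {"up", "down"}
        assert pc.stats["up"].stat > 0 > pc.stats["down"].stat
        for rec in pc.stats.values():
            assert rec.p <= pc.alpha
            assert np.sign(rec.stat) == np.sign(rec.rho)

    def test_alpha_monotonicity_on_fixed_data(self, rng):
        n = 600
        x = rng.normal(size=(6, n))
        resp = pd.Series(x[0] - 0.8 * x[1] + 0.4 * x[2]
                         + rng.normal(size=n) * 1.0,
                         index=[f"S{i}" for i in range(n)])
        cand = pd.DataFrame(x, index=[f"G{i}" for i in range(6)],
                            columns=resp.index)
        strict = set(mmpc(resp, cand, alpha=0.01).pc_genes)
        loose = set(mmpc(resp, cand, alpha=0.05).pc_genes)
        assert strict <= loose


class TestOrientation:
    def test_collider_parents_oriented(self, rng):
        n = 2000
        x1, x2 = rng.normal(size=(2, n))
        resp = pd.Series(x1 + x2 + 0.7 * rng.normal(size=n),
                         index=[f"S{i}" for i in range(n)])
        child = 0.8 * (resp.to_numpy() / resp.std()) + 0.6 * rng.normal(size=n)
        cand = _df({"P1": x1, "P2": x2, "C1": child})
        cand.columns = resp.index
        pc = mmpc(resp, cand)
        assert set(pc.pc_genes) == {"P1", "P2", "C1"}
        oriented = orient_parents(resp, pc, cand)
        assert set(oriented.parental_genes) == {"P1", "P2"}
        edges = oriented.edges.set_index(["source", "target"])
        assert edges.loc[(RESPONSE, "C1"), "orientation"] == "->"

    def test_single_pc_gene_left_undirected(self, rng):
        n = 800
        x = rng.normal(size=n)
        resp = pd.Series(x + rng.normal(size=n),
                         index=[f"S{i}" for i in range(n)])
        cand = _df({"G1": x})
        cand.columns = resp.index
        pc = mmpc(resp, cand)
        assert pc.pc_genes == ["G1"]
        oriented = orient_parents(resp, pc, cand)
        assert oriented.parental_genes == []
        assert (oriented.edges["orientation"] == "--").all()

    def test_empty_pc_gives_empty_result(self, rng):
        resp = pd.Series(rng.normal(size=100),
                         index=[f"S{i}" for i in range(100)])
        cand = pd.DataFrame(rng.normal(size=(3, 100)),
                            index=["a", "b", "c"], columns=resp.index)
        pc = mmpc(resp, cand, alpha=1e-6)
        if not pc.pc_genes:     # overwhelmingly likely
            oriented = orient_parents(resp, pc, cand)
            assert oriented.parental_genes == []
            assert oriented.edges.empty


@pytest.fixture(scope="module")
def pipeline_outputs():
    rng = np.random.default_rng(11)
    n = 1500
    pos_parent = rng.normal(size=n)       # positive weight on AUC
    neg_parent = rng.normal(size=n)
    resp_raw = 1.2 * pos_parent - 1.0 * neg_parent + rng.normal(size=n)
    resp = pd.Series(resp_raw, index=[f"S{i}" for i in range(n)])
    child = 0.9 * resp_raw / resp_raw.std() + 0.5 * rng.normal(size=n)
    noise = rng.normal(size=n)
    expr = _df({"POSP": pos_parent, "NEGP": neg_parent,
                "CHILD": child, "NOISE": noise})
    expr.columns = resp.index
    filt = scc_filter(expr, resp, r_min=0.30)
    cand = expr.loc[filt.loc[filt["retained"], "gene"]]
    pc = mmpc(resp, cand)
    oriented = orient_parents(resp, pc, cand)
    report = biomarker_report(filt, pc, oriented, drug="toy")
    return filt, pc, oriented, report


class TestBiomarkerReport:
    def test_positive_weight_parent_labeled_resistance(self, pipeline_outputs):
        _, _, oriented, report = pipeline_outputs
        row = report.set_index("gene").loc["POSP"]
        assert row["is_pc"] and row["is_parent"]
        assert row["direction"] == LABEL_RESISTANCE
        neg = report.set_index("gene").loc["NEGP"]
        assert neg["direction"] == LABEL_SENSITIVITY

    def test_child_is_pc_but_not_parental(self, pipeline_outputs):
        _, _, _, report = pipeline_outputs
        row = report.set_index("gene").loc["CHILD"]
        assert row["is_pc"] and not row["is_parent"]

    def test_filtered_out_gene_absent(self, pipeline_outputs):
        filt, _, _, report = pipeline_outputs
        assert not filt.set_index("gene").loc["NOISE", "retained"]
        assert "NOISE" not in set(report["gene"])
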