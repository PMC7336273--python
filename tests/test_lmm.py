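"""Mixed-model machinery: kinship, spectral likelihood, LRT and per-drug FDR."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from moascan import lmm

# frozen n=6 instance for the dense-likelihood oracle check
TOY_Y = np.array([0.82, -1.31, 0.44, 2.05, -0.17, 0.96])
TOY_M = np.array([[1.0, 0.3], [1.0, -1.2], [1.0, 0.7],
                  [1.0, 1.9], [1.0, -0.4], [1.0, 0.1]])
TOY_K = np.array([
    [1.30, 0.40, 0.10, 0.05, 0.20, 0.15],
    [0.40, 1.10, 0.30, 0.10, 0.05, 0.10],
    [0.10, 0.30, 0.90, 0.25, 0.15, 0.05],
    [0.05, 0.10, 0.25, 1.20, 0.35, 0.10],
    [0.20, 0.05, 0.15, 0.35, 0.80, 0.30],
    [0.15, 0.10, 0.05, 0.10, 0.30, 0.70],
])


def _random_kinship(rng, n):
    A = rng.standard_normal((n, 2 * n))
    K = A @ A.T / (2 * n)
    return K / np.diag(K).mean()


class TestBuildKinship:
    def test_identical_profiles_saturate_similarity(self):
        rng = np.random.default_rng(0)
        base = rng.standard_normal((30, 4))
        base[:, 1] = base[:, 0]  # two cell lines share a fitness profile
        K = lmm.build_kinship(pd.DataFrame(base, columns=list("abcd"))).matrix
        assert K.loc["a", "b"] == pytest.approx(K.loc["a", "a"])
        assert K.loc["a", "b"] == pytest.approx(K.loc["b", "b"])

    def test_independent_profiles_near_zero(self):
        rng = np.random.default_rng(1)
        values = pd.DataFrame(rng.standard_normal((10000, 100)))
        K = lmm.build_kinship(values).matrix.to_numpy()
        off = K[~np.eye(100, dtype=bool)]
        assert np.abs(off).max() < 0.05

    def test_matches_hand_computed_cross_product(self):
        values = pd.DataFrame(
            [[1.0, 2.0, 3.0, 4.0],
             [0.0, 1.0, 0.0, 1.0],
             [-1.0, 2.0, -2.0, 1.0]],
            index=["g1", "g2", "g3"], columns=list("abcd"),
        )
        K = lmm.build_kinship(values).matrix.to_numpy()
        # oracle: standardize each gene across lines, cross-product / p
        Z = []
        for g in range(3):
            row = values.iloc[g].to_numpy()
            Z.append((row - row.mean()) / row.std())
        Z = np.array(Z)
        expected = Z.T @ Z / 3
        expected /= np.diag(expected).mean()
        assert np.allclose(K, expected)

    def test_zero_variance_genes_dropped(self):
        values = pd.DataFrame(
            [[1.0, 1.0, 1.0], [0.0, 1.0, 2.0]], index=["flat", "ok"]
        )
        K = lmm.build_kinship(values)
        assert np.isfinite(K.matrix.to_numpy()).all()

    def test_mean_diagonal_is_one(self, default_scan):
        K = default_scan["kinship"].matrix.to_numpy()
        assert np.diag(K).mean() == pytest.approx(1.0)


class TestFitLMM:
    def test_identity_kinship_matches_ols_likelihood(self):
        rng = np.random.default_rng(5)
        n = 40
        M = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = M @ [1.0, 2.0] + rng.standard_normal(n)
        fit = lmm.fit_lmm(y, M, np.eye(n))
        beta_ols, *_ = np.linalg.lstsq(M, y, rcond=None)
        rss = ((y - M @ beta_ols) ** 2).sum()
        ll_ols = -0.5 * n * (np.log(2 * np.pi * rss / n) + 1)
        assert fit.log_likelihood == pytest.approx(ll_ols, abs=1e-6)
        assert np.allclose(fit.betas, beta_ols, atol=1e-6)

    def test_frozen_toy_matches_dense_likelihood_oracle(self):
        fit = lmm.fit_lmm(TOY_Y, TOY_M, TOY_K)
        V = fit.sigma_g2 * TOY_K + fit.sigma_e2 * np.eye(6)
        ll_dense = stats.multivariate_normal.logpdf(TOY_Y, TOY_M @ fit.betas, V)
        assert abs(ll_dense - fit.log_likelihood) < 1e-8

    def test_shift_equivariance_with_intercept(self):
        rng = np.random.default_rng(6)
        n = 25
        K = _random_kinship(rng, n)
        M = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = rng.standard_normal(n)
        a, b = lmm.fit_lmm(y, M, K), lmm.fit_lmm(y + 10.0, M, K)
        assert b.sigma_g2 == pytest.approx(a.sigma_g2, rel=1e-6)
        assert b.sigma_e2 == pytest.approx(a.sigma_e2, rel=1e-6)
        assert b.log_likelihood == pytest.approx(a.log_likelihood, abs=1e-6)
        assert b.betas[0] == pytest.approx(a.betas[0] + 10.0, abs=1e-6)

    def test_non_psd_kinship_fatal(self):
        with pytest.raises(ValueError, match="semi-definite"):
            lmm.fit_lmm(np.zeros(3), np.ones((3, 1)), np.diag([1.0, 1.0, -1.0]))


class TestLRTSingle:
    def test_predictor_equal_to_covariate_gives_null_result(self):
        rng = np.random.default_rng(7)
        n = 30
        K = _random_kinship(rng, n)
        x = rng.standard_normal(n)
        M = np.column_stack([np.ones(n), x])
        y = rng.standard_normal(n)
        res = lmm.lrt_single(y, M, K, x)
        assert res["lrt_stat"] == pytest.approx(0.0, abs=1e-6)
        assert res["pval"] == pytest.approx(1.0, abs=1e-6)

    def test_matches_ols_lrt_oracle_under_identity_kinship(self):
        rng = np.random.default_rng(8)
        n = 200
        e = rng.standard_normal(n)
        y = 2.0 * e + rng.standard_normal(n)
        M = np.ones((n, 1))
        res = lmm.lrt_single(y, M, np.eye(n), e)

        # ordinary-regression likelihood-ratio oracle
        rss0 = ((y - y.mean()) ** 2).sum()
        X = np.column_stack([M, e])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss1 = ((y - X @ beta) ** 2).sum()
        stat = n * np.log(rss0 / rss1)
        assert res["lrt_stat"] == pytest.approx(stat, rel=1e-6)
        assert res["pval"] == pytest.approx(stats.chi2.sf(stat, 1), rel=1e-5)
        assert res["beta"] == pytest.approx(beta[1], rel=1e-6)

    def test_rescaling_predictor_scales_beta_inversely(self):
        rng = np.random.default_rng(9)
        n = 40
        K = _random_kinship(rng, n)
        M = np.ones((n, 1))
        e = rng.standard_normal(n)
        y = e + rng.standard_normal(n)
        a = lmm.lrt_single(y, M, K, e)
        b = lmm.lrt_single(y, M, K, 4.0 * e)
        assert b["lrt_stat"] == pytest.approx(a["lrt_stat"], rel=1e-6)
        assert b["beta"] == pytest.approx(a["beta"] / 4.0, rel=1e-6)

    def test_degenerate_predictor_flagged(self):
        res = lmm.lrt_single(
            np.arange(20.0), np.ones((20, 1)), np.eye(20), np.full(20, 3.0)
        )
        assert res == pytest.approx(
            {"beta": 0.0, "lrt_stat": 0.0, "pval": 1.0, "n_obs": 20,
             "predictor_class": "fitness", "flagged": True}, abs=0
        ) or (res["pval"] == 1.0 and res["flagged"])

    def test_null_predictor_pvalues_uniform(self):
        """Independent predictors under a structured null give uniform p."""
        rng = np.random.default_rng(10)
        n, reps = 120, 2000
        K = _random_kinship(rng, n)
        L = np.linalg.cholesky(K + 1e-9 * np.eye(n))
        y = L @ rng.standard_normal(n) + 0.5 * rng.standard_normal(n)
        drm = pd.DataFrame([y], index=["drug"])
        preds = pd.DataFrame(rng.standard_normal((reps, n)))
        drm.columns = preds.columns = [f"c{i}" for i in range(n)]
        cov = pd.DataFrame({"intercept": 1.0}, index=drm.columns)
        kin = lmm.Kinship(pd.DataFrame(K, index=drm.columns, columns=drm.columns))
        res = lmm.scan(drm, preds, cov, kin)
        assert stats.kstest(res["pval"], "uniform").pvalue > 0.01


class TestScan:
    def test_planned_enumeration(self):
        assert lmm.planned_test_count(2, 3) == 6

    def test_row_count_and_columns(self, small_panel):
        from conftest import build_scan_inputs

        sfm, kin, cov = build_scan_inputs(small_panel)
        preds = sfm.values.iloc[:3]
        res = lmm.scan(small_panel.drug_response, preds, cov, kin, min_obs=10)
        assert len(res) == len(small_panel.drug_response.drugs) * 3
        assert {"drug_id", "predictor_id", "beta", "lrt_stat", "pval",
                "qval", "n_obs", "predictor_class"} <= set(res.columns)

    def test_underobserved_drug_skipped(self, small_panel):
        from conftest import build_scan_inputs

        sfm, kin, cov = build_scan_inputs(small_panel)
        values = small_panel.drug_response.values.copy()
        values.iloc[0, 5:] = np.nan  # leave 5 observations at most
        drm = pd.DataFrame(values)
        res = lmm.scan(drm, sfm.values.iloc[:2], cov, kin, min_obs=10)
        assert small_panel.drug_response.drugs[0] not in set(res["drug_id"])

    def test_fast_mode_agrees_with_exact_on_top_hits(self, default_scan):
        """Reused-delta screening plus refinement matches per-test refits."""
        res = default_scan["results"]
        panel = default_scan["panel"]
        sfm, kin, cov = (default_scan["sfm"], default_scan["kinship"],
                         default_scan["covariates"])
        for drug in list(panel.drug_response.drugs)[:5]:
            block = res[res["drug_id"] == drug].nsmallest(1, "pval")
            top = block.iloc[0]
            y_all = panel.drug_response.values.loc[drug]
            obs = y_all.dropna().index
            S, U = kin.eigen(tuple(obs))
            exact = lmm.lrt_single(
                y_all.loc[obs].to_numpy(), cov.loc[obs],
                lmm._Precomputed(S, U),
                sfm.values.loc[top["predictor_id"], obs].to_numpy(),
            )
            if exact["pval"] > 0:
                assert abs(top["pval"] / exact["pval"] - 1) < 0.10
            else:
                assert abs(top["lrt_stat"] / exact["lrt_stat"] - 1) < 0.10


class TestFDR:
    def _frame(self, pvals, drug="d1"):
        return pd.DataFrame({"drug_id": drug, "pval": pvals})

    def test_stepup_example(self):
        out = lmm.adjust_fdr_per_drug(self._frame([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(out["qval"], 0.04)

    def test_single_test_q_equals_p(self):
        out = lmm.adjust_fdr_per_drug(self._frame([0.37]))
        assert out["qval"].iloc[0] == pytest.approx(0.37)

    def test_blocks_are_independent(self):
        p = [0.001, 0.5, 0.02, 0.9]
        both = pd.concat([self._frame(p, "d1"), self._frame(p, "d2")],
                         ignore_index=True)
        out = lmm.adjust_fdr_per_drug(both)
        q1 = out[out["drug_id"] == "d1"]["qval"].to_numpy()
        q2 = out[out["drug_id"] == "d2"]["qval"].to_numpy()
        assert np.allclose(q1, q2)

    def test_invalid_pvalues_fatal(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            lmm.adjust_fdr_per_drug(self._frame([0.5, 1.5]))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40))
    def test_qvalues_match_stepup_definition_oracle(self, pvals):
        out = lmm.adjust_fdr_per_drug(self._frame(pvals))
        # oracle: literal Benjamini-Hochberg step-up definition
        p = np.asarray(pvals, dtype=float)
        m = len(p)
        order = np.argsort(p, kind="mergesort")
        q = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            idx = order[rank - 1]
            running = min(running, p[idx] * m / rank)
            q[idx] = running
        assert np.allclose(out["qval"].to_numpy(), q, atol=1e-12)
        # q is a monotone transform of p within the block
        sorted_q = q[order]
        assert (np.diff(sorted_q) >= -1e-12).all()
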