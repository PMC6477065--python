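"""Cohort statistics: summaries, transform, correlation, regressions, MGM."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from proalkit import stats as S


class TestSummarize:
    def test_simple_values(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
        row = S.summarize(df).loc["x"]
        assert row["mean"] == 2.0 and row["sd"] == 1.0
        assert row["median"] == 2.0 and row["skewness"] == 0.0

    def test_constant_variable_marked_undefined(self):
        df = pd.DataFrame({"x": [5.0, 5.0, 5.0]})
        row = S.summarize(df).loc["x"]
        assert np.isnan(row["skewness"]) and np.isnan(row["kurtosis"])

    def test_normal_sample_excess_kurtosis(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"x": rng.standard_normal(100_000)})
        row = S.summarize(df).loc["x"]
        se = math.sqrt(24 / 100_000)
        assert abs(row["kurtosis"]) < 3 * se


class TestTukeyLadder:
    def test_symmetric_data_keeps_identity(self):
        rng = np.random.default_rng(1)
        x = rng.normal(10, 1, 500)
        _, lam, off = S.tukey_ladder(x)
        assert lam == 1.0 and off == 0.0

    def test_lognormal_selects_log(self):
        rng = np.random.default_rng(2)
        x = np.exp(rng.standard_normal(1000))
        _, lam, _ = S.tukey_ladder(x)
        assert lam == 0.0

    def test_zeros_get_offset_and_stay_finite(self):
        rng = np.random.default_rng(3)
        x = np.concatenate([np.zeros(50), rng.exponential(5, 200)])
        t, lam, off = S.tukey_ladder(x)
        assert off == 1.0 and np.all(np.isfinite(t))

    def test_monotone_increasing_for_negative_powers(self):
        x = np.array([0.0, 1.0, 3.0, 8.0, 20.0])
        t = S._ladder_transform(x + 1, -0.5)
        assert np.all(np.diff(t) > 0)


class TestPearsonMatrix:
    def test_perfect_linear_relation(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0]})
        df["y"] = 2 * df.x + 1
        r, p = S.pearson_matrix(df)
        assert r.loc["x", "y"] == pytest.approx(1.0)

    def test_hand_computed_case(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0],
                           "y": [2.0, 1.0, 4.0, 3.0]})
        r, p = S.pearson_matrix(df)
        assert r.loc["x", "y"] == pytest.approx(0.6, abs=1e-12)
        # two-sided p from the t reference with n-2 df
        t = 0.6 * math.sqrt(2 / (1 - 0.36))
        want = 2 * sps.t.sf(t, 2)
        assert p.loc["x", "y"] == pytest.approx(want, rel=1e-9)

    def test_symmetry_and_unit_diagonal(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.standard_normal((30, 3)), columns=list("abc"))
        r, _ = S.pearson_matrix(df)
        assert np.allclose(r.values, r.values.T)
        assert np.allclose(np.diag(r.values), 1.0)

    def test_type_one_error_calibration(self):
        """Under independence, p-values reject at the nominal 5% rate."""
        rng = np.random.default_rng(5)
        n, reps = 36, 10_000
        x = rng.standard_normal((reps, n))
        y = rng.standard_normal((reps, n))
        xc = x - x.mean(1, keepdims=True)
        yc = y - y.mean(1, keepdims=True)
        r = (xc * yc).sum(1) / np.sqrt((xc ** 2).sum(1) * (yc ** 2).sum(1))
        t = r * np.sqrt((n - 2) / (1 - r ** 2))
        pvals = 2 * sps.t.sf(np.abs(t), n - 2)
        rate = (pvals < 0.05).mean()
        se = math.sqrt(0.05 * 0.95 / reps)
        assert abs(rate - 0.05) < 3 * se

    def test_zero_variance_marked(self):
        df = pd.DataFrame({"x": [1.0, 1.0, 1.0, 1.0],
                           "y": [1.0, 2.0, 3.0, 4.0]})
        r, _ = S.pearson_matrix(df)
        assert np.isnan(r.loc["x", "y"])


class TestVIF:
    def test_orthogonal_predictors(self):
        df = pd.DataFrame({"a": [1, 1, -1, -1], "b": [1, -1, 1, -1]},
                          dtype=float)
        v = S.vif(df, ["a", "b"])
        assert np.allclose(v, 1.0)

    def test_closed_form_two_predictors(self):
        rng = np.random.default_rng(6)
        a = rng.standard_normal(200)
        b = 0.8 * a + 0.6 * rng.standard_normal(200)
        df = pd.DataFrame({"a": a, "b": b})
        r = np.corrcoef(a, b)[0, 1]
        v = S.vif(df, ["a", "b"])
        assert v["a"] == pytest.approx(1 / (1 - r ** 2), rel=1e-9)
        assert v["b"] == pytest.approx(1 / (1 - r ** 2), rel=1e-9)

    def test_duplicated_predictor_flagged_infinite(self):
        rng = np.random.default_rng(7)
        a = rng.standard_normal(50)
        df = pd.DataFrame({"a": a, "b": a.copy(), "c": rng.standard_normal(50)})
        v = S.vif(df, ["a", "b", "c"])
        assert math.isinf(v["a"]) and math.isinf(v["b"])


def _toy_table(n=40, seed=8, noise=0.0):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({"vaq_preschool_t": rng.normal(1.3, 1.0, n),
                       "omega2": rng.normal(-5.5, 2.8, n)})
    df["ras_emotion"] = (15.0 - 0.9 * df.vaq_preschool_t - 0.3 * df.omega2
                         + noise * rng.standard_normal(n))
    return df


class TestRegressionSuite:
    def test_noise_free_exact_recovery(self):
        df = _toy_table(noise=0.0)
        rep = S.fit_ols(df, "ras_emotion", ["vaq_preschool_t", "omega2"])
        assert rep.terms.loc["const", "estimate"] == pytest.approx(15.0, abs=1e-8)
        assert rep.terms.loc["vaq_preschool_t", "estimate"] == \
            pytest.approx(-0.9, abs=1e-8)
        assert rep.adj_r2 == pytest.approx(1.0, abs=1e-9)

    def test_f_statistic_matches_anova_decomposition(self):
        """Overall F cross-checked against an explicit sum-of-squares
        decomposition."""
        df = _toy_table(n=25, noise=2.0)
        terms = ["vaq_preschool_t", "omega2"]
        rep = S.fit_ols(df, "ras_emotion", terms)
        X = np.column_stack([np.ones(len(df)), df.vaq_preschool_t, df.omega2])
        y = df.ras_emotion.to_numpy()
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        yhat = X @ beta
        ssr = ((yhat - y.mean()) ** 2).sum()
        sse = ((y - yhat) ** 2).sum()
        f = (ssr / 2) / (sse / (len(df) - 3))
        assert rep.f_stat == pytest.approx(f, rel=1e-9)
        assert rep.f_pvalue == pytest.approx(sps.f.sf(f, 2, len(df) - 3),
                                             rel=1e-9)
        assert rep.resid_se == pytest.approx(math.sqrt(sse / (len(df) - 3)),
                                             rel=1e-9)
        assert rep.df_resid == len(df) - 3

    def test_all_four_models_fit(self):
        df = _toy_table(noise=2.0)
        reports = S.fit_linear_models(df, "ras_emotion", with_q2=True)
        assert set(reports) == {"simple", "full", "partial_omega2",
                                "partial_vaq"}
        for rep in reports.values():
            assert rep.q2 is not None
            assert rep.terms.shape[1] == 3

    def test_scaling_equivariance(self):
        """Scaling a predictor by c scales its coefficient by 1/c and leaves
        fit statistics unchanged."""
        df = _toy_table(noise=2.0)
        rep1 = S.fit_ols(df, "ras_emotion", ["vaq_preschool_t", "omega2"],
                         with_q2=True)
        df2 = df.copy()
        df2["omega2"] = df2["omega2"] * 10.0
        rep2 = S.fit_ols(df2, "ras_emotion", ["vaq_preschool_t", "omega2"],
                         with_q2=True)
        assert rep2.terms.loc["omega2", "estimate"] == \
            pytest.approx(rep1.terms.loc["omega2", "estimate"] / 10, rel=1e-9)
        assert rep2.adj_r2 == pytest.approx(rep1.adj_r2, rel=1e-9)
        assert rep2.f_stat == pytest.approx(rep1.f_stat, rel=1e-9)
        assert rep2.q2 == pytest.approx(rep1.q2, rel=1e-9)

    def test_rank_deficiency_names_term(self):
        df = _toy_table(noise=1.0)
        df["dup"] = df["omega2"]
        with pytest.raises(ValueError, match="dup|aliased"):
            S.fit_ols(df, "ras_emotion", ["vaq_preschool_t", "omega2", "dup"])


class TestLOOCV:
    def test_noise_free_is_one(self):
        df = _toy_table(noise=0.0)
        q2 = S.loocv_q2(df, "ras_emotion", ["vaq_preschool_t", "omega2"])
        assert q2 == pytest.approx(1.0, abs=1e-9)

    def test_five_point_fold_by_fold_oracle(self):
        df = pd.DataFrame({"x": [0.0, 1.0, 2.0, 3.0, 4.0],
                           "y": [0.1, 0.9, 2.2, 2.8, 4.1]})
        press = 0.0
        for i in range(5):
            tr = df.drop(index=i)
            b, a = np.polyfit(tr.x, tr.y, 1)
            press += (df.y[i] - (b * df.x[i] + a)) ** 2
        want = 1 - press / ((df.y - df.y.mean()) ** 2).sum()
        got = S.loocv_q2(df, "y", ["x"])
        assert got == pytest.approx(want, rel=1e-9)

    def test_unrelated_outcome_gives_negative_q2_on_average(self):
        rng = np.random.default_rng(9)
        vals = []
        for _ in range(100):
            df = pd.DataFrame({"x": rng.standard_normal(20),
                               "z": rng.standard_normal(20),
                               "y": rng.standard_normal(20)})
            vals.append(S.loocv_q2(df, "y", ["x", "z"]))
        assert np.mean(vals) < 0


class TestSimpleModelRecoveryStudy:
    def test_unbiased_at_small_replication(self):
        out = S.simple_model_recovery_study(n_cohorts=60, n=36, seed=0)
        assert out["vaq_preschool_t"] == pytest.approx(-0.891, abs=0.15)
        assert out["omega2"] == pytest.approx(-0.282, abs=0.06)
        assert out["intercept"] == pytest.approx(15.072, abs=0.5)


class TestMixedGraphicalModel:
    def test_null_graph_is_empty(self):
        counts = []
        for s in range(20):
            rng = np.random.default_rng(s)
            df = pd.DataFrame(rng.standard_normal((500, 6)),
                              columns=list("abcdef"))
            g = S.fit_mixed_graphical_model(
                df, {c: "continuous" for c in df.columns})
            counts.append(len(g.edges()))
        assert np.mean(counts) < 0.5

    def test_chain_recovered_without_spurious_edge(self):
        hits = 0
        for s in range(20):
            rng = np.random.default_rng(100 + s)
            x = rng.standard_normal(1000)
            y = 0.7 * x + rng.standard_normal(1000)
            z = 0.7 * y + rng.standard_normal(1000)
            df = pd.DataFrame({"x": x, "y": y, "z": z})
            g = S.fit_mixed_graphical_model(
                df, {c: "continuous" for c in "xyz"})
            e = {frozenset(p[:2]) for p in g.edges()}
            hits += (frozenset("xy") in e and frozenset("yz") in e
                     and frozenset("xz") not in e)
        assert hits >= 18

    def test_binary_continuous_edge_recovered(self):
        rng = np.random.default_rng(10)
        x = rng.standard_normal(1000)
        b = (rng.random(1000) < 1 / (1 + np.exp(-2 * x))).astype(float)
        c = rng.standard_normal(1000)
        df = pd.DataFrame({"x": x, "b": b, "c": c})
        g = S.fit_mixed_graphical_model(
            df, {"x": "continuous", "b": "binary", "c": "continuous"})
        e = {frozenset(p[:2]) for p in g.edges()}
        assert frozenset(("x", "b")) in e
        assert frozenset(("x", "c")) not in e

    def test_graph_structure_invariants(self):
        rng = np.random.default_rng(11)
        x = rng.standard_normal(400)
        df = pd.DataFrame({"x": x, "y": 0.9 * x + rng.standard_normal(400),
                           "z": rng.standard_normal(400)})
        g = S.fit_mixed_graphical_model(df, {c: "continuous" for c in "xyz"})
        A = g.adjacency.to_numpy()
        assert np.allclose(A, A.T)
        assert np.allclose(np.diag(A), 0.0)

    def test_zero_variance_node_named(self):
        df = pd.DataFrame({"x": np.ones(50),
                           "y": np.random.default_rng(0).standard_normal(50),
                           "z": np.random.default_rng(1).standard_normal(50)})
        with pytest.raises(ValueError, match="x"):
            S.fit_mixed_graphical_model(
                df, {c: "continuous" for c in "xyz"})
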