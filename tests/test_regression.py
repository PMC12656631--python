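"""Segment regressions and the diagnostic battery, each checked
against independent brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

import trailpace as tp
from trailpace.regression import segment_columns

TRUTH = {"constant": 1.0, "WT": 0.9, "WTV": 5.0, "CPR": 1.5}


def toy_features(rng, n=40, noise=0.0, coefs=TRUTH):
    wt = rng.lognormal(2.0, 0.3, n)
    wtv = rng.normal(0.3, 0.1, n)
    cpr = rng.uniform(0.01, 1.0, n)
    tt = (coefs["constant"] + coefs["WT"] * wt + coefs["WTV"] * wtv
          + coefs["CPR"] * cpr + rng.normal(0, noise, n))
    return pd.DataFrame({
        "runner_id": [f"r{i}" for i in range(n)],
        "WT_1": wt, "WTV_13": wtv, "CPR_1": cpr, "TT": tt,
    })


def normal_equation_solution(X, y):
    """Brute-force OLS oracle via the normal equations."""
    Xc = np.column_stack([np.ones(len(X)), X])
    return np.linalg.solve(Xc.T @ Xc, Xc.T @ y)


class TestFitSegmentModel:
    def test_exact_interpolation(self):
        feats = toy_features(np.random.default_rng(0), noise=0.0)
        m = tp.fit_segment_model(feats, "ascent1", exclude_influential=False)
        assert m.coef("constant").b == pytest.approx(1.0, abs=1e-8)
        assert m.coef("WT_1").b == pytest.approx(0.9, abs=1e-8)
        assert m.coef("WTV_13").b == pytest.approx(5.0, abs=1e-8)
        assert m.coef("CPR_1").b == pytest.approx(1.5, abs=1e-8)
        assert m.r2 == pytest.approx(1.0, abs=1e-10)

    def test_matches_normal_equation_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            feats = toy_features(rng, n=25, noise=0.5)
            m = tp.fit_segment_model(feats, "ascent1", exclude_influential=False)
            beta = normal_equation_solution(
                feats[["WT_1", "WTV_13", "CPR_1"]].to_numpy(), feats["TT"].to_numpy())
            got = [m.coef(c).b for c in ("constant", "WT_1", "WTV_13", "CPR_1")]
            assert got == pytest.approx(list(beta), abs=1e-9)

    def test_noisy_recovery_within_standard_errors(self):
        feats = toy_features(np.random.default_rng(42), n=400, noise=0.3)
        m = tp.fit_segment_model(feats, "ascent1")
        names = ("constant", "WT_1", "WTV_13", "CPR_1")
        for name, truth in zip(names, (1.0, 0.9, 5.0, 1.5)):
            c = m.coef(name)
            assert abs(c.b - truth) < 4 * c.se
        assert m.adj_r2 > 0.95

    def test_fit_statistics_identities(self):
        """adjR2 and SEE follow their defining formulas exactly."""
        feats = toy_features(np.random.default_rng(3), n=60, noise=1.0)
        m = tp.fit_segment_model(feats, "ascent1", exclude_influential=False)
        n, k = m.n_used, 3
        assert m.adj_r2 == pytest.approx(1 - (1 - m.r2) * (n - 1) / (n - k - 1), abs=1e-12)
        rss = float(np.sum(m.residuals ** 2))
        assert m.see ** 2 == pytest.approx(rss / (n - k - 1), abs=1e-10)
        assert m.r == pytest.approx(np.sqrt(m.r2), abs=1e-12)

    def test_standardized_beta_invariant_to_rescaling(self):
        feats = toy_features(np.random.default_rng(4), n=80, noise=0.5)
        m1 = tp.fit_segment_model(feats, "ascent1", exclude_influential=False)
        rescaled = feats.copy()
        rescaled["WT_1"] = rescaled["WT_1"] * 37.0 + 5.0
        m2 = tp.fit_segment_model(rescaled, "ascent1", exclude_influential=False)
        assert m2.coef("WT_1").beta == pytest.approx(m1.coef("WT_1").beta, rel=1e-9)

    def test_influential_case_excluded_once(self):
        feats = toy_features(np.random.default_rng(5), n=30, noise=0.2)
        feats.loc[len(feats)] = {"runner_id": "outlier", "WT_1": 200.0,
                                 "WTV_13": 0.3, "CPR_1": 0.5, "TT": 5000.0}
        m = tp.fit_segment_model(feats, "ascent1")
        assert "outlier" in m.excluded_cases
        assert m.n_used == 30

    def test_rank_deficient_design_named(self):
        feats = toy_features(np.random.default_rng(6), n=30, noise=0.2)
        feats["CPR_1"] = feats["WT_1"] * 2.0
        with pytest.raises(ValueError, match="collinear"):
            tp.fit_segment_model(feats, "ascent1")

    def test_too_few_rows_rejected(self):
        feats = toy_features(np.random.default_rng(1), n=5)
        with pytest.raises(ValueError, match=">= 10"):
            tp.fit_segment_model(feats, "ascent1")

    @pytest.mark.parametrize("segment", ["ascent1", "descent", "ascent2"])
    def test_all_segments_fit_on_default_field(self, default_features, segment):
        m = tp.fit_segment_model(default_features, segment)
        assert m.adj_r2 > 0.9
        assert 1 < m.dw < 3
        assert all(1 <= v < 10 for v in m.vif.values())
        assert set(c.name for c in m.coefficients) == {"constant", *segment_columns(segment)}


class TestDurbinWatson:
    def test_alternating_residuals(self):
        assert tp.durbin_watson([1.0, -1.0, 1.0, -1.0]) == pytest.approx(3.0)

    def test_constant_residuals(self):
        assert tp.durbin_watson([2.0, 2.0, 2.0]) == pytest.approx(0.0)

    def test_independent_noise_near_two(self):
        rng = np.random.default_rng(10)
        assert tp.durbin_watson(rng.normal(size=20000)) == pytest.approx(2.0, abs=0.05)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(11)
        e = rng.normal(size=50)
        expected = np.sum(np.diff(e) ** 2) / np.sum(e ** 2)
        assert tp.durbin_watson(e) == pytest.approx(expected, abs=1e-12)

    def test_all_zero_undefined(self):
        with pytest.raises(ValueError):
            tp.durbin_watson(np.zeros(5))


class TestVif:
    def test_orthogonal_predictors(self):
        n = 64
        t = np.arange(n)
        X = pd.DataFrame({"a": np.cos(2 * np.pi * t / n),
                          "b": np.sin(2 * np.pi * t / n),
                          "c": np.cos(4 * np.pi * t / n)})
        assert all(v == pytest.approx(1.0, abs=1e-9) for v in tp.vif(X).values())

    def test_near_collinear_inflates(self):
        rng = np.random.default_rng(13)
        x1 = rng.normal(size=100)
        X = pd.DataFrame({"x1": x1, "x2": x1 + rng.normal(0, 1e-3, 100),
                          "x3": rng.normal(size=100)})
        assert tp.vif(X)["x2"] > 10

    def test_matches_auxiliary_regression_oracle(self):
        rng = np.random.default_rng(14)
        X = pd.DataFrame(rng.normal(size=(40, 3)) @ np.array(
            [[1, 0.5, 0.2], [0, 1, 0.4], [0, 0, 1]]), columns=list("abc"))
        got = tp.vif(X)
        for j, name in enumerate(X.columns):
            others = X.drop(columns=[name]).to_numpy()
            target = X[name].to_numpy()
            beta = normal_equation_solution(others, target)
            fitted = np.column_stack([np.ones(len(X)), others]) @ beta
            r2 = 1 - np.sum((target - fitted) ** 2) / np.sum((target - target.mean()) ** 2)
            assert got[name] == pytest.approx(1 / (1 - r2), abs=1e-9)

    def test_perfect_collinearity_reported_infinite(self):
        x = np.arange(20, dtype=float)
        assert tp.vif(pd.DataFrame({"a": x, "b": 2 * x}))["b"] == np.inf


class TestCooksDistance:
    @staticmethod
    def _fit(X, y):
        import statsmodels.api as sm
        return sm.OLS(y, sm.add_constant(X)).fit()

    def test_matches_leave_one_out_oracle(self):
        rng = np.random.default_rng(15)
        X = rng.normal(size=(15, 2))
        y = X @ [1.0, -2.0] + rng.normal(0, 0.5, 15)
        fit = self._fit(X, y)
        d = tp.cooks_distance(fit)
        p = 3  # parameters incl. intercept
        s2 = np.sum(fit.resid ** 2) / (15 - p)
        Xc = np.column_stack([np.ones(15), X])
        for i in range(15):
            keep = np.arange(15) != i
            beta_i = np.linalg.solve(Xc[keep].T @ Xc[keep], Xc[keep].T @ y[keep])
            d_loo = np.sum((Xc @ fit.params - Xc @ beta_i) ** 2) / (p * s2)
            assert d[i] == pytest.approx(d_loo, abs=1e-10)

    def test_gross_outlier_flagged(self):
        rng = np.random.default_rng(16)
        X = np.vstack([rng.normal(size=(30, 1)), [[15.0]]])
        y = np.concatenate([X[:30, 0] * 2 + rng.normal(0, 0.1, 30), [-60.0]])
        d = tp.cooks_distance(self._fit(X, y))
        assert d[-1] > 1
        assert np.all(d[:-1] < 1)

    def test_balanced_duplicates_small_and_equal(self):
        X = np.array([[-1.0], [1.0]] * 10)
        y = np.array([-1.0, 1.0] * 10) + np.array([0.01, -0.01] * 10)
        d = tp.cooks_distance(self._fit(X, y))
        assert np.all(d < 0.2)
        assert np.ptp(d) == pytest.approx(0.0, abs=1e-12)


class TestBlandAltman:
    def test_identity(self):
        x = np.linspace(5, 20, 30)
        ba = tp.bland_altman(x, x)
        assert ba.bias == 0 and ba.loa_low == 0 and ba.loa_high == 0
        assert ba.pct_outside == 0 and ba.degenerate

    def test_constant_offset_degenerate(self):
        x = np.linspace(5, 20, 30)
        ba = tp.bland_altman(x + 0.5, x)
        assert ba.bias == pytest.approx(0.5)
        assert ba.degenerate

    def test_gaussian_coverage_near_95(self):
        rng = np.random.default_rng(18)
        actual = rng.uniform(8, 20, 1000)
        predicted = actual + rng.normal(0, 0.5, 1000)
        ba = tp.bland_altman(predicted, actual)
        assert ba.pct_outside == pytest.approx(0.05, abs=0.02)
        assert ba.loa_low <= ba.bias <= ba.loa_high
        assert ba.residual_normality is not None

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(19)
        a = rng.normal(10, 2, 50)
        p = a + rng.normal(0.3, 0.4, 50)
        ba = tp.bland_altman(p, a)
        diff = p - a
        assert ba.bias == pytest.approx(diff.mean(), abs=1e-12)
        assert ba.loa_high == pytest.approx(diff.mean() + 1.96 * diff.std(ddof=1), abs=1e-12)

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            tp.bland_altman([1.0, 2.0], [1.0, 2.0])
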