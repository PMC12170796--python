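"""Standardization, change scores, OLS/mixed models, t-tests, HR change."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import dyadsync as ds


def _long_ratings(pre, post, measure="warmth", condition="Gazing", dyads=None):
    n = len(pre)
    return pd.DataFrame(
        {
            "rater": [f"r{i}" for i in range(n)],
            "partner": [f"q{i}" for i in range(n)],
            "dyad_id": dyads or [f"d{i}" for i in range(n)],
            "session": 0,
            "round": 1,
            "condition": condition,
            "familiarity": 0,
            "measure": measure,
            "pre": pre,
            "post": post,
        }
    )


class TestStandardize:
    def test_pre_values_become_zero_mean_unit_sd(self):
        table = _long_ratings([40.0, 50.0, 60.0, 50.0, 55.0], [45.0, 55.0, 65.0, 50.0, 60.0])
        out = ds.standardize(table, "warmth")
        assert out["pre"].mean() == pytest.approx(0.0, abs=1e-12)
        assert out["pre"].std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_post_equals_pre_gives_zero_change(self):
        table = _long_ratings([3.0, 4.0, 5.0], [3.0, 4.0, 5.0])
        out = ds.standardize(table, "warmth")
        assert np.allclose(out["post"] - out["pre"], 0.0)

    def test_matches_hand_arithmetic(self):
        """5-row fixture against explicit spreadsheet-style arithmetic."""
        pre = [40.0, 50.0, 60.0, 50.0, 55.0]
        post = [45.0, 55.0, 65.0, 50.0, 60.0]
        out = ds.standardize(_long_ratings(pre, post), "warmth")
        mu = sum(pre) / 5.0
        sd = (sum((x - mu) ** 2 for x in pre) / 4.0) ** 0.5
        for i in range(5):
            assert out["pre"].iloc[i] == pytest.approx((pre[i] - mu) / sd, abs=1e-12)
            assert out["post"].iloc[i] == pytest.approx((post[i] - mu) / sd, abs=1e-12)

    def test_post_only_measure_zscored(self):
        table = _long_ratings([np.nan] * 4, [10.0, 20.0, 30.0, 40.0], measure="dictator_give")
        out = ds.standardize(table, "dictator_give")
        assert out["post"].mean() == pytest.approx(0.0, abs=1e-12)
        assert out["post"].std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_zero_sd_raises(self):
        table = _long_ratings([5.0, 5.0, 5.0], [6.0, 7.0, 8.0])
        with pytest.raises(ValueError, match="SD"):
            ds.standardize(table, "warmth")


class TestChangeScores:
    def _two_member_ratings(self, changes_by_dyad):
        rows = []
        for dyad, (ca, cb) in changes_by_dyad.items():
            for rater, change in ((f"{dyad}a", ca), (f"{dyad}b", cb)):
                rows.append(
                    {
                        "rater": rater,
                        "partner": "x",
                        "dyad_id": dyad,
                        "session": 0,
                        "round": 1,
                        "condition": "Gazing",
                        "familiarity": 0,
                        "measure": "warmth",
                        "pre": 50.0,
                        "post": 50.0 + change,
                    }
                )
        return pd.DataFrame(rows)

    def test_symmetric_change(self):
        changes, excluded = ds.dyad_change_scores(self._two_member_ratings({"d1": (1.0, 1.0)}))
        assert changes["change_warmth"].iloc[0] == pytest.approx(1.0)
        assert excluded.empty

    def test_asymmetric_change_averages(self):
        changes, _ = ds.dyad_change_scores(self._two_member_ratings({"d1": (2.0, 0.0)}))
        assert changes["change_warmth"].iloc[0] == pytest.approx(1.0)

    def test_missing_member_excluded_and_logged(self):
        table = self._two_member_ratings({"d1": (1.0, 1.0), "d2": (2.0, 2.0)})
        table = table[~((table["dyad_id"] == "d2") & (table["rater"] == "d2b"))]
        changes, excluded = ds.dyad_change_scores(table)
        assert list(changes["dyad_id"]) == ["d1"]
        assert list(excluded["dyad_id"]) == ["d2"]


class TestOLS:
    def test_exact_fit_flagged(self):
        x = np.arange(1.0, 7.0)
        X = pd.DataFrame({"x": x})
        fit = ds.fit_ols(2.0 * x, X)
        assert fit["x"]["estimate"] == pytest.approx(2.0, abs=1e-12)
        assert fit.extra["perfect_fit"]

    def test_matches_normal_equations_oracle(self):
        """6-point regression vs (X'X)^-1 X'y with classical SEs."""
        X = pd.DataFrame({"const": np.ones(6), "x": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]})
        y = np.array([2.1, 3.9, 6.2, 8.1, 9.8, 12.2])
        fit = ds.fit_ols(y, X)
        Xm = X.to_numpy()
        beta = np.linalg.inv(Xm.T @ Xm) @ Xm.T @ y
        resid = y - Xm @ beta
        s2 = resid @ resid / (6 - 2)
        se = np.sqrt(np.diag(s2 * np.linalg.inv(Xm.T @ Xm)))
        tstat = beta / se
        pvals = 2 * stats.t.sf(np.abs(tstat), 4)
        assert np.allclose(fit.estimates, beta, atol=1e-10)
        assert np.allclose(fit.se, se, atol=1e-10)
        assert np.allclose(fit.pvalues, pvals, atol=1e-10)
        assert fit.df == 4

    @given(st.integers(0, 10_000))
    @settings(max_examples=50)
    def test_random_designs_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n, k = 12, 3
        X = pd.DataFrame(rng.normal(size=(n, k)), columns=["a", "b", "c"])
        X["const"] = 1.0
        y = rng.normal(size=n)
        fit = ds.fit_ols(y, X)
        Xm = X.to_numpy()
        beta = np.linalg.solve(Xm.T @ Xm, Xm.T @ y)
        assert np.allclose(fit.estimates, beta, atol=1e-8)

    def test_rank_deficiency_names_collinear_term(self):
        X = pd.DataFrame({"const": np.ones(5), "x": np.arange(5.0), "x2": 2 * np.arange(5.0)})
        with pytest.raises(ValueError, match="x2"):
            ds.fit_ols(np.arange(5.0), X)


class TestDyadicMixed:
    def test_degenerate_limit_matches_ols(self):
        """No between-cluster variance: fixed effects agree with OLS."""
        rng = np.random.default_rng(0)
        n = 120
        data = pd.DataFrame(
            {
                "x": rng.normal(size=n),
                "participant": np.repeat([f"p{i}" for i in range(30)], 4),
                "dyad": np.tile([f"d{i}" for i in range(40)], 3),
            }
        )
        data["y"] = 1.5 + 0.5 * data["x"] + rng.normal(0, 1, n)
        mixed = ds.fit_dyadic_mixed(data, "y ~ x", random_factors=("participant", "dyad"))
        ols = ds.fit_ols_formula(data, "y ~ x")
        assert mixed["x"]["estimate"] == pytest.approx(ols["x"]["estimate"], abs=0.05)

    def test_variance_component_recovery(self):
        """50 clusters x 4 observations, intercept SD 1, residual SD 1."""
        rng = np.random.default_rng(1)
        clusters = np.repeat([f"p{i}" for i in range(50)], 4)
        u = dict(zip([f"p{i}" for i in range(50)], rng.normal(0, 1, 50)))
        y = np.array([u[c] for c in clusters]) + rng.normal(0, 1, 200)
        data = pd.DataFrame({"y": y, "participant": clusters})
        fit = ds.fit_dyadic_mixed(data, "y ~ 1", random_factors=("participant",))
        var = fit.extra["variance_components"].get("participant")
        assert var is not None
        assert 0.7 < var < 1.3
        assert 0.7 < fit.extra["residual_variance"] < 1.3

    def test_condition_effect_recovery(self):
        """Balanced two-condition design with a 0.5 SD effect."""
        rng = np.random.default_rng(2)
        n_part = 40
        parts = np.repeat([f"p{i}" for i in range(n_part)], 4)
        cond = np.tile(["A", "A", "B", "B"], n_part)
        u = dict(zip([f"p{i}" for i in range(n_part)], rng.normal(0, 0.5, n_part)))
        y = np.array([u[p] for p in parts]) + 0.5 * (cond == "B") + rng.normal(0, 1, parts.size)
        data = pd.DataFrame({"y": y, "participant": parts, "condition": cond})
        fit = ds.fit_dyadic_mixed(data, "y ~ C(condition)", random_factors=("participant",))
        term = fit["C(condition)[T.B]"]
        assert abs(term["estimate"] - 0.5) < 2 * term["se"]

    def test_unknown_factor_rejected(self):
        data = pd.DataFrame({"y": [1.0, 2.0], "x": [0.0, 1.0]})
        with pytest.raises(ValueError, match="random factor"):
            ds.fit_dyadic_mixed(data, "y ~ x", random_factors=("participant",))


class TestPairVsPseudoTests:
    def _table(self, arms):
        rows = []
        for (cond, ptype), values in arms.items():
            for v in values:
                rows.append({"condition": cond, "pair_type": ptype, "r": v})
        return pd.DataFrame(rows)

    def test_identical_arms_give_t_zero_p_one(self):
        vals = [0.1, 0.2, 0.3, 0.4]
        table = self._table({("JLM", "real"): vals, ("JLM", "pseudo"): vals})
        out = ds.pair_vs_pseudo_tests(
            table,
            comparisons=[
                {
                    "label": "JLM real vs pseudo",
                    "a": {"condition": "JLM", "pair_type": "real"},
                    "b": {"condition": "JLM", "pair_type": "pseudo"},
                }
            ],
        )
        assert out["t"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert out["p"].iloc[0] == pytest.approx(1.0)
        assert out["df"].iloc[0] == 6

    def test_six_contrasts_bonferroni_threshold(self):
        rng = np.random.default_rng(3)
        arms = {
            (c, t): rng.normal(0, 0.1, 10)
            for c in ("JLM", "Gazing", "Eyes Closed")
            for t in ("real", "pseudo")
        }
        out = ds.pair_vs_pseudo_tests(self._table(arms), alpha=0.05)
        assert len(out) == 6
        assert out["threshold"].iloc[0] == pytest.approx(0.05 / 6)
        assert round(out["threshold"].iloc[0], 3) == 0.008

    def test_pooled_df_convention_and_welch_flag(self):
        rng = np.random.default_rng(4)
        table = self._table(
            {("JLM", "real"): rng.normal(0.3, 0.1, 12), ("JLM", "pseudo"): rng.normal(0.0, 0.3, 30)}
        )
        comp = [
            {
                "label": "c",
                "a": {"condition": "JLM", "pair_type": "real"},
                "b": {"condition": "JLM", "pair_type": "pseudo"},
            }
        ]
        student = ds.pair_vs_pseudo_tests(table, comparisons=comp)
        welch = ds.pair_vs_pseudo_tests(table, comparisons=comp, welch=True)
        assert student["df"].iloc[0] == 40
        assert student["t"].iloc[0] != pytest.approx(welch["t"].iloc[0])

    def test_empty_arm_raises(self):
        table = self._table({("JLM", "real"): [0.1, 0.2]})
        with pytest.raises(ValueError, match="fewer than 2"):
            ds.pair_vs_pseudo_tests(
                table,
                comparisons=[
                    {
                        "label": "x",
                        "a": {"condition": "JLM", "pair_type": "real"},
                        "b": {"condition": "JLM", "pair_type": "pseudo"},
                    }
                ],
            )


class TestHRChange:
    def test_constant_change_flagged_degenerate(self):
        changes = pd.DataFrame(
            {"participant": [f"p{i}" for i in range(10)], "condition": "JLM", "change": -10.0}
        )
        fits = ds.hr_change_model(changes)
        fit = fits["JLM"]
        assert fit["Intercept"]["estimate"] == pytest.approx(-10.0)
        assert fit.extra["degenerate"]

    def test_single_participation_equals_one_sample_t(self):
        rng = np.random.default_rng(5)
        y = rng.normal(-9.0, 2.0, 25)
        changes = pd.DataFrame(
            {"participant": [f"p{i}" for i in range(25)], "condition": "Gazing", "change": y}
        )
        fit = ds.hr_change_model(changes)["Gazing"]
        t, p = stats.ttest_1samp(y, 0.0)
        assert fit["Intercept"]["estimate"] == pytest.approx(y.mean(), abs=1e-10)
        assert fit["Intercept"]["stat"] == pytest.approx(t, abs=1e-10)
        assert fit["Intercept"]["p"] == pytest.approx(p, abs=1e-10)

    def test_repeated_participation_uses_random_intercept(self):
        rng = np.random.default_rng(6)
        parts = np.repeat([f"p{i}" for i in range(20)], 3)
        u = dict(zip([f"p{i}" for i in range(20)], rng.normal(0, 2, 20)))
        y = -10 + np.array([u[p] for p in parts]) + rng.normal(0, 1, 60)
        changes = pd.DataFrame({"participant": parts, "condition": "JLM", "change": y})
        fit = ds.hr_change_model(changes)["JLM"]
        est = fit["Intercept"]
        assert abs(est["estimate"] + 10) < 3 * est["se"] + 0.5
        assert "participant" in fit.extra.get("variance_components", {}) or fit.extra["dropped"]

    def test_changes_extracted_from_signals(self, hr_bundle):
        changes = ds.hr_changes_from_signals(hr_bundle.signals)
        assert len(changes) == len(hr_bundle.signals)
        assert set(changes["condition"]) <= set(hr_bundle.config.conditions)
        # arousal decay: changes are mostly negative
        assert (changes["change"] < 0).mean() > 0.8
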