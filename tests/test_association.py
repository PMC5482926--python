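import numpy as np
import pandas as pd
import pytest
from scipy import stats

from earlychange.association import (
    contingency_analysis,
    hierarchical_regression,
    multinomial_class_prediction,
    oneway_anova_bonferroni,
    screen_predictors,
)
from earlychange.simulate import default_study_config, generate

CLASS_BY_OUTCOME = pd.DataFrame(
    [[99, 5, 54], [104, 12, 69], [18, 26, 22]],
    index=["C1", "C2", "C3"],
    columns=["improved", "deteriorated", "unchanged"],
)


class TestContingency:
    def test_published_class_by_outcome_table(self):
        res = contingency_analysis(CLASS_BY_OUTCOME)
        assert res.chi2 == pytest.approx(74.8, abs=0.06)
        assert res.df == 4
        r = res.standardized_residuals
        assert r.loc["C1", "improved"] == pytest.approx(1.5, abs=0.05)
        assert r.loc["C3", "improved"] == pytest.approx(-3.00, abs=0.05)
        assert r.loc["C3", "deteriorated"] == pytest.approx(7.2, abs=0.05)

    def test_independent_table_gives_zero(self):
        res = contingency_analysis(np.array([[10, 10], [10, 10]]))
        assert res.chi2 == 0.0
        assert (res.standardized_residuals.to_numpy() == 0).all()

    def test_permutation_invariance(self):
        res = contingency_analysis(CLASS_BY_OUTCOME)
        perm = contingency_analysis(CLASS_BY_OUTCOME.iloc[[2, 0, 1], [1, 0, 2]])
        assert perm.chi2 == pytest.approx(res.chi2, rel=1e-12)
        assert perm.standardized_residuals.loc["C3", "deteriorated"] == pytest.approx(
            res.standardized_residuals.loc["C3", "deteriorated"], rel=1e-12
        )

    def test_degenerate_tables_rejected(self):
        with pytest.raises(ValueError):
            contingency_analysis(np.array([[1, 2, 3]]))
        with pytest.raises(ValueError):
            contingency_analysis(np.array([[0, 0], [1, 2]]))


class TestAnova:
    def test_identical_groups_give_zero_f(self):
        vals = np.r_[np.arange(5.0), np.arange(5.0)]
        labs = np.r_[np.zeros(5), np.ones(5)]
        res = oneway_anova_bonferroni(vals, labs)
        assert res.f_statistic == pytest.approx(0.0, abs=1e-12)
        assert (res.pairwise["p_bonferroni"] == 1.0).all()

    def test_two_groups_f_equals_squared_t(self, rng):
        vals = rng.normal(0, 1, 40)
        labs = np.repeat([0, 1], 20)
        vals[labs == 1] += 0.8
        res = oneway_anova_bonferroni(vals, labs)
        t = res.pairwise["t"].iloc[0]
        assert res.f_statistic == pytest.approx(t**2, rel=1e-10)
        assert res.p_value == pytest.approx(res.pairwise["p_raw"].iloc[0], rel=1e-10)

    def test_three_groups_against_sums_of_squares_oracle(self):
        vals = np.array([3.0, 5, 4, 8, 9, 7, 2, 1, 3])
        labs = np.repeat(["a", "b", "c"], 3)
        res = oneway_anova_bonferroni(vals, labs)
        grand = vals.mean()
        ssb = sum(3 * (vals[labs == g].mean() - grand) ** 2 for g in "abc")
        ssw = sum(((vals[labs == g] - vals[labs == g].mean()) ** 2).sum() for g in "abc")
        f_oracle = (ssb / 2) / (ssw / 6)
        assert res.f_statistic == pytest.approx(f_oracle, rel=1e-12)
        assert res.df_between == 2 and res.df_within == 6

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            oneway_anova_bonferroni(np.arange(4.0), np.array([0, 0, 0, 1]))


class TestScreenPredictors:
    def test_identity_and_orthogonal(self):
        y = np.array([1.0, 2, 3, 4, 5])
        x_orth = np.array([-1.0, 2, 0, -2, 1])  # orthogonal to centred y
        frame = screen_predictors(pd.DataFrame({"same": y, "orth": x_orth}), y)
        assert frame.loc["same", "r"] == pytest.approx(1.0)
        assert frame.loc["orth", "r"] == pytest.approx(0.0, abs=1e-12)

    def test_toy_values_match_covariance_formula(self, rng):
        x = rng.normal(0, 1, 5)
        y = rng.normal(0, 1, 5)
        frame = screen_predictors(pd.DataFrame({"x": x}), y)
        r_oracle = np.cov(x, y, ddof=1)[0, 1] / (np.std(x, ddof=1) * np.std(y, ddof=1))
        assert frame.loc["x", "r"] == pytest.approx(r_oracle, rel=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            screen_predictors(pd.DataFrame({"c": np.ones(5)}), np.arange(5.0))


class TestHierarchicalRegression:
    def test_orthonormal_blocks_decompose_r2(self, rng):
        # with orthonormal predictors each block's delta R^2 equals the sum
        # of its squared correlations with the outcome
        n = 50
        raw = rng.normal(0, 1, (n, 4))
        q, _ = np.linalg.qr(raw - raw.mean(0))
        X = pd.DataFrame(q * np.sqrt(n - 1), columns=list("abcd"))  # unit variance
        y = rng.normal(0, 1, n)
        res = hierarchical_regression(
            y, [("b1", X[["a", "b"]]), ("b2", X[["c", "d"]])], exclusion_alpha=1.0
        )
        corrs = {c: np.corrcoef(X[c], y)[0, 1] ** 2 for c in "abcd"}
        assert res.steps[0]["delta_r2"] == pytest.approx(corrs["a"] + corrs["b"], abs=1e-10)
        assert res.steps[1]["delta_r2"] == pytest.approx(corrs["c"] + corrs["d"], abs=1e-10)
        # nested R^2 non-decreasing
        assert res.steps[1]["r2"] >= res.steps[0]["r2"]

    def test_perfect_first_block(self, rng):
        n = 30
        x = rng.normal(0, 1, n)
        z = rng.normal(0, 1, n)
        res = hierarchical_regression(
            x, [("b1", pd.DataFrame({"x": x})), ("b2", pd.DataFrame({"z": z}))],
            exclusion_alpha=1.0,
        )
        assert res.steps[0]["r2"] == pytest.approx(1.0)
        assert res.steps[1]["delta_r2"] == pytest.approx(0.0, abs=1e-10)

    def test_nonsignificant_entrant_excluded_with_t_and_p(self, rng):
        n = 200
        x = rng.normal(0, 1, n)
        noise = rng.normal(0, 1, n)
        y = x + rng.normal(0, 0.5, n)
        res = hierarchical_regression(
            y,
            [
                ("signal", pd.DataFrame({"x": x})),
                ("noise", pd.DataFrame({"u": noise})),
                ("tail", pd.DataFrame({"v": rng.normal(0, 1, n)})),
            ],
        )
        dropped = [e["predictor"] for e in res.excluded]
        assert "u" in dropped
        assert all({"predictor", "t", "p", "step"} <= set(e) for e in res.excluded)
        assert "u" not in res.final_betas.index

    def test_class_dummies_add_explained_variance_at_defaults(self):
        # class-linked outcome shift: entering true-class dummies last must
        # add explained variance
        ds, truth = generate(default_study_config(), seed=31)
        post = ds.column("post")
        pre = ds.column("screening")
        ok = ~np.isnan(post)
        dummies = pd.get_dummies(pd.Series(truth.classes[ok] + 1), prefix="class").iloc[:, 1:]
        res = hierarchical_regression(
            post[ok],
            [
                ("baseline", pd.DataFrame({"phq9": pre[ok]})),
                ("class", dummies.astype(float).reset_index(drop=True)),
            ],
        )
        assert res.steps[1]["delta_r2"] > 0
        assert res.steps[1]["p_change"] < 0.05


class TestMultinomial:
    def test_intercept_only_closed_form(self):
        labels = np.r_[np.zeros(75), np.ones(25)]
        design = pd.DataFrame(index=range(100))
        fit = multinomial_class_prediction(design, labels, reference_class=0.0)
        b0 = fit.coefficients.loc[fit.coefficients["predictor"] == "const", "B"].iloc[0]
        assert b0 == pytest.approx(np.log(0.25 / 0.75), abs=1e-6)

    def test_binary_predictor_or_equals_cross_product_ratio(self, rng):
        x = rng.integers(0, 2, 300).astype(float)
        p = np.where(x == 1, 0.7, 0.3)
        y = (rng.random(300) < p).astype(int)
        tab = pd.crosstab(y, x).to_numpy().astype(float)
        cpr = (tab[1, 1] * tab[0, 0]) / (tab[1, 0] * tab[0, 1])
        fit = multinomial_class_prediction(pd.DataFrame({"x": x}), y, reference_class=0)
        row = fit.coefficients[fit.coefficients["predictor"] == "x"].iloc[0]
        assert row["odds_ratio"] == pytest.approx(cpr, rel=1e-4)
        assert row["ci_lower"] < row["odds_ratio"] < row["ci_upper"]

    def test_severity_sign_pattern_at_defaults(self):
        # higher screening severity must lower the odds of the mild
        # early-response-after-screening class relative to the severe
        # early-response-after-registration class
        ds, truth = generate(default_study_config(), seed=13)
        design = pd.DataFrame({"phq9_screening": ds.column("screening")})
        fit = multinomial_class_prediction(design, truth.classes + 1, reference_class=1)
        row = fit.coefficients[
            (fit.coefficients["contrast"] == "1 vs 2")
            & (fit.coefficients["predictor"] == "phq9_screening")
        ].iloc[0]
        assert row["B"] < 0 and row["p"] < 0.05
        assert fit.log_likelihood >= fit.null_log_likelihood
        assert 0 <= fit.cox_snell_r2 <= fit.nagelkerke_r2 <= 1

    def test_empty_or_single_class_rejected(self):
        with pytest.raises(ValueError):
            multinomial_class_prediction(pd.DataFrame({"x": [1.0, 2.0]}), [1, 1])
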