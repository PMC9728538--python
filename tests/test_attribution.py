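"""Difference-model attribution: betas, partial R², VIF, and their oracles."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from cbp_enhance import (
    CohortTable,
    GeneratorConfig,
    design_matrix,
    fit_difference_model,
    generate_cohort,
    vif,
)


def _with_columns(n=64, seed=0, **overrides) -> CohortTable:
    """Generated cohort with selected columns overwritten (no re-validation)."""
    df = generate_cohort(GeneratorConfig(n=n, seed=seed)).df.copy()
    for col, values in overrides.items():
        df[col] = values
    return CohortTable(df=df, provenance="synthetic", seed=seed)


def _partial_r2_by_refit(cohort, target, predictors):
    """Oracle: explicit SSE ratio from refitting without each predictor."""
    X = design_matrix(cohort, predictors)
    y = (cohort.df[f"{target}sbp"] - cohort.df["aosbp_invasive"]).to_numpy()
    sse_full = sm.OLS(y, sm.add_constant(X.to_numpy())).fit().ssr
    out = {}
    for name in predictors:
        reduced = sm.add_constant(X.drop(columns=[name]).to_numpy())
        sse_red = sm.OLS(y, reduced).fit().ssr
        out[name] = 100.0 * (sse_red - sse_full) / sse_red
    return out


class TestFitDifferenceModel:
    def test_noise_free_linear_target_recovered_exactly(self):
        rng = np.random.default_rng(3)
        n = 80
        age = rng.normal(65, 10, n)
        height = rng.normal(170, 10, n)
        base = generate_cohort(GeneratorConfig(n=n, seed=3)).df.copy()
        base["age"], base["height"] = age, height
        # make the C1 difference an exact linear function of age and height
        base["c1sbp"] = base["aosbp_invasive"] + 2.0 - 0.5 * age + 0.1 * height
        base["brachial_sbp"] = base["c1sbp"] + base["amplification"]
        cohort = CohortTable(df=base, provenance="synthetic", seed=3)
        fit = fit_difference_model(cohort, "c1", ["age", "height"])
        assert fit.effect("age").beta == pytest.approx(-0.5, abs=1e-8)
        assert fit.effect("height").beta == pytest.approx(0.1, abs=1e-8)
        assert fit.intercept == pytest.approx(2.0, abs=1e-6)
        assert fit.global_r2 == pytest.approx(100.0, abs=1e-8)

    def test_orthogonalized_predictor_has_zero_partial_r2(self):
        n = 40
        rng = np.random.default_rng(5)
        x1 = rng.normal(size=n)
        y = 3.0 * x1 + rng.normal(size=n)
        # residualize a second predictor on x1 and make it orthogonal to y's
        # residual on x1 as well -> its partial R² is 0 by definition
        resid_y = y - np.polyval(np.polyfit(x1, y, 1), x1)
        x2 = rng.normal(size=n)
        x2 = x2 - np.polyval(np.polyfit(x1, x2, 1), x1)
        x2 = x2 - resid_y * (x2 @ resid_y) / (resid_y @ resid_y)
        cohort = _with_columns(n=n, seed=5, age=x1, height=x2)
        df = cohort.df
        df["c1sbp"] = df["aosbp_invasive"] + y
        df["brachial_sbp"] = df["c1sbp"] + df["amplification"]
        fit = fit_difference_model(cohort, "c1", ["age", "height"])
        assert fit.effect("height").partial_r2 == pytest.approx(0.0, abs=1e-8)

    @pytest.mark.parametrize("target", ["c1", "c2"])
    def test_partial_r2_matches_refit_oracle(self, target, default_cohort):
        predictors = ["age", "sex", "heart_rate", "amplification", "height"]
        fit = fit_difference_model(default_cohort, target, predictors)
        oracle = _partial_r2_by_refit(default_cohort, target, predictors)
        for name in predictors:
            assert fit.effect(name).partial_r2 == pytest.approx(
                oracle[name], abs=1e-8
            )

    def test_partial_r2_oracle_on_random_small_designs(self):
        """t²-based partial R² equals explicit refitting on random designs."""
        for seed in range(25):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(20, 51))
            preds = list(
                rng.choice(
                    ["age", "height", "weight", "egfr", "heart_rate", "epwv"],
                    size=int(rng.integers(2, 6)),
                    replace=False,
                )
            )
            cohort = generate_cohort(GeneratorConfig(n=n, seed=seed + 1000))
            fit = fit_difference_model(cohort, "c1", preds)
            oracle = _partial_r2_by_refit(cohort, "c1", preds)
            for name in preds:
                assert fit.effect(name).partial_r2 == pytest.approx(
                    oracle[name], abs=1e-8
                )

    def test_r2_invariant_under_predictor_rescaling(self, default_cohort):
        preds = ["age", "height", "heart_rate"]
        fit = fit_difference_model(default_cohort, "c2", preds)
        df = default_cohort.df.copy()
        df["height"] = df["height"] * 10.0 + 3.0
        scaled = CohortTable(df=df, provenance="synthetic", seed=1)
        fit2 = fit_difference_model(scaled, "c2", preds)
        assert fit2.global_r2 == pytest.approx(fit.global_r2, abs=1e-8)
        assert fit2.effect("height").beta == pytest.approx(
            fit.effect("height").beta / 10.0, abs=1e-10
        )

    def test_partial_r2_sum_not_constrained_to_global(self, default_cohort):
        fit = fit_difference_model(default_cohort, "c1")
        total = sum(e.partial_r2 for e in fit.effects)
        assert total != pytest.approx(fit.global_r2, abs=1e-6)

    def test_rank_deficient_design_raises(self, default_cohort):
        df = default_cohort.df.copy()
        df["weight"] = 2.0 * df["height"]
        cohort = CohortTable(df=df, provenance="synthetic", seed=1)
        with pytest.raises(ValueError, match="rank"):
            fit_difference_model(cohort, "c1", ["age", "height", "weight"])

    def test_too_small_n_raises(self):
        cohort = generate_cohort(GeneratorConfig(n=3, seed=0))
        with pytest.raises(ValueError):
            fit_difference_model(cohort, "c1", ["age", "height", "weight"])


class TestVif:
    def test_exactly_orthogonal_predictors_have_unit_vif(self):
        # centred, mutually orthogonal ±1 patterns
        h = np.array([1.0, -1.0, 1.0, -1.0] * 10)
        w = np.array([1.0, 1.0, -1.0, -1.0] * 10)
        g = np.array([1.0, -1.0, -1.0, 1.0] * 10)
        cohort = _with_columns(n=40, seed=7, height=h, weight=w, egfr=g)
        out = vif(cohort, ["height", "weight", "egfr"])
        for v in out.values():
            assert v == pytest.approx(1.0, abs=1e-10)

    def test_correlation_0p8_gives_closed_form_vif(self):
        # x2 = 0.8*x1 + 0.6*x1perp with orthonormal halves -> corr exactly 0.8
        x1 = np.array([1.0, -1.0] * 20)
        x1p = np.array([1.0, 1.0, -1.0, -1.0] * 10)
        x2 = 0.8 * x1 + 0.6 * x1p
        cohort = _with_columns(n=40, seed=7, height=x1, weight=x2)
        out = vif(cohort, ["height", "weight"])
        expected = 1.0 / (1.0 - 0.64)
        assert out["height"] == pytest.approx(expected, abs=1e-10)
        assert out["weight"] == pytest.approx(expected, abs=1e-10)

    def test_duplicated_column_flagged_infinite(self):
        df = generate_cohort(GeneratorConfig(n=30, seed=2)).df.copy()
        df["weight"] = df["height"]
        cohort = CohortTable(df=df, provenance="synthetic", seed=2)
        out = vif(cohort, ["height", "weight", "age"])
        assert np.isinf(out["height"]) and np.isinf(out["weight"])
        assert np.isfinite(out["age"])

    def test_matches_statsmodels_oracle(self, default_cohort):
        from statsmodels.stats.outliers_influence import variance_inflation_factor

        preds = ["age", "height", "weight", "heart_rate", "epwv"]
        X = sm.add_constant(design_matrix(default_cohort, preds).to_numpy())
        ours = vif(default_cohort, preds)
        for j, name in enumerate(preds, start=1):
            assert ours[name] == pytest.approx(
                variance_inflation_factor(X, j), rel=1e-8
            )
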