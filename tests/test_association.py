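"""Robust regression, variance explained, bootstrap and deviance tests."""

import numpy as np
import pandas as pd
import pytest

from tampgx.association import (
    ModelSpec,
    NonConvergenceError,
    RankDeficientDesignError,
    bootstrap_r2_ci,
    build_design,
    compare_models_deviance,
    covariate_effect_screen,
    fit_robust_linear,
    robust_adjusted_r2,
)
from tampgx.simulate import CohortConfig, generate_cohort, sample_diplotypes


def _toy_cohort(n=300, noise=0.3, seed=0, beta=0.8):
    """Cohort whose log endoxifen is linear in the standard activity score."""
    cfg = CohortConfig(n_patients=n)
    rng = np.random.default_rng(seed)
    dips = sample_diplotypes(cfg, n, seed=seed)
    a = np.array([d.activity_score("standard") for d in dips])
    y = 1.0 + beta * a + rng.normal(0, noise, n)
    return pd.DataFrame(
        {
            "id": [f"T{i}" for i in range(n)],
            "label": [d.label for d in dips],
            "as_standard": a,
            "roc_activity": [d.roc_activity for d in dips],
            "e_ngml": np.exp(y),
            "dmt_ngml": 100.0,
            "cyp2c9_class": "*1/*1",
            "cyp3a5": "*1/*1",
        }
    )


NOCOV = dict(covariates=False)


class TestRobustFit:
    def test_reduces_to_ols_in_low_noise_limit(self):
        coh = _toy_cohort(n=500, noise=1e-6, seed=1)
        spec = ModelSpec(endpoint="E", predictors=("activity_score",), **NOCOV)
        robust = fit_robust_linear(spec, coh)
        ols = fit_robust_linear(
            ModelSpec(endpoint="E", predictors=("activity_score",),
                      estimator="ordinary", **NOCOV),
            coh,
        )
        assert np.allclose(robust.params, ols.params, atol=1e-6)
        assert robust_adjusted_r2(robust) == pytest.approx(
            robust_adjusted_r2(ols), abs=1e-6
        )

    def test_gross_outliers_downweighted(self):
        coh = _toy_cohort(n=500, noise=0.2, seed=2)
        spec = ModelSpec(endpoint="E", predictors=("activity_score",), **NOCOV)
        clean = fit_robust_linear(spec, coh)
        contaminated = coh.copy()
        out_idx = np.arange(0, 500, 20)  # 5% gross outliers
        contaminated.loc[out_idx, "e_ngml"] *= np.e**8
        robust = fit_robust_linear(spec, contaminated)
        ols = fit_robust_linear(
            ModelSpec(endpoint="E", predictors=("activity_score",),
                      estimator="ordinary", **NOCOV),
            contaminated,
        )
        # robust coefficients barely move; OLS absorbs the shifted mean
        shift_robust = np.max(np.abs(robust.params - clean.params) / np.abs(clean.params))
        shift_ols = np.max(np.abs(ols.params - clean.params) / np.abs(clean.params))
        assert shift_robust < 0.10
        assert shift_ols > 0.10
        assert np.all(robust.weights[out_idx] < 0.01)

    def test_exact_linear_response_r2_one(self):
        coh = _toy_cohort(n=200, noise=0.0, seed=3)
        spec = ModelSpec(endpoint="E", predictors=("activity_score",), **NOCOV)
        fit = fit_robust_linear(spec, coh)
        assert robust_adjusted_r2(fit) == pytest.approx(1.0, abs=1e-10)
        assert np.all(fit.weights == 1.0)

    def test_too_few_observations_rejected(self):
        coh = _toy_cohort(n=2, noise=0.1)
        with pytest.raises(ValueError, match="must exceed"):
            fit_robust_linear(
                ModelSpec(endpoint="E", predictors=("activity_score",)), coh
            )

    def test_rank_deficient_design_names_aliased_columns(self):
        coh = _toy_cohort(n=100, noise=0.1, seed=4)
        # diplotype factor + activity score + scheme factor is heavily aliased
        spec = ModelSpec(
            endpoint="E",
            predictors=("diplotype", "activity_score", ("scheme", "TAM1")),
            **NOCOV,
        )
        with pytest.raises(RankDeficientDesignError, match="aliased"):
            fit_robust_linear(spec, coh)


class TestRobustAdjustedR2:
    def test_unit_weights_reduce_to_classical_formula(self):
        coh = _toy_cohort(n=150, noise=0.4, seed=5)
        spec = ModelSpec(endpoint="E", predictors=("activity_score",),
                         estimator="ordinary", **NOCOV)
        fit = fit_robust_linear(spec, coh)
        assert np.all(fit.weights == 1.0)
        import statsmodels.api as sm

        classical = sm.OLS(fit.y, fit.X).fit().rsquared_adj
        assert robust_adjusted_r2(fit) == pytest.approx(classical, abs=1e-10)


class TestBootstrap:
    def test_single_replicate_ci_collapses(self):
        coh = _toy_cohort(n=120, noise=0.3, seed=6)
        spec = ModelSpec(endpoint="E", predictors=("activity_score",), **NOCOV)
        res = bootstrap_r2_ci(spec, coh, replicates=1, seed=0)
        assert res.ci_low == res.ci_high == res.r2_boot_median

    def test_seed_stability_of_bootstrap_median(self, cohort900):
        spec = ModelSpec(endpoint="E_over_DMT", predictors=("diplotype",))
        medians = [
            bootstrap_r2_ci(spec, cohort900, replicates=300, seed=s).r2_boot_median
            for s in (1, 2)
        ]
        assert abs(medians[0] - medians[1]) < 0.01

    def test_result_invariants(self, cohort900):
        spec = ModelSpec(endpoint="E_over_DMT", predictors=("diplotype",))
        res = bootstrap_r2_ci(spec, cohort900, replicates=200, seed=3)
        assert res.ci_low <= res.r2_boot_median <= res.ci_high
        assert 0.0 <= res.r2_point <= 1.0


class TestDeviance:
    def test_identical_specs_rejected(self, cohort900):
        spec = ModelSpec(endpoint="E", predictors=(("scheme", "TAM2"),))
        with pytest.raises(ValueError, match="degenerate"):
            compare_models_deviance(spec, spec, cohort900)

    def test_non_nested_specs_rejected(self, cohort900):
        one = ModelSpec(endpoint="E", predictors=(("scheme", "TAM1"),))
        two = ModelSpec(endpoint="E", predictors=(("scheme", "TAM2"),))
        with pytest.raises(ValueError, match="not nested"):
            compare_models_deviance(one, two, cohort900)

    def test_added_true_factor_detected(self):
        # response depends on the diplotype factor beyond the linear AS trend
        rng = np.random.default_rng(7)
        coh = _toy_cohort(n=900, noise=0.25, seed=7)
        bump = {"EM/UM": 0.8, "PM/PM": -0.8}
        coh["e_ngml"] *= np.exp(
            [bump.get(l, 0.0) for l in coh["label"]]
        )
        one = ModelSpec(endpoint="E", predictors=("activity_score",), **NOCOV)
        two = ModelSpec(endpoint="E", predictors=("activity_score", "diplotype"), **NOCOV)
        res = compare_models_deviance(one, two, coh)
        assert res["p"] < 1e-3

    def test_type_one_error_calibrated_under_null(self):
        """Adding a pure-noise predictor rejects at ~the nominal 5% rate."""
        rejections = 0
        reps = 200
        for s in range(reps):
            rng = np.random.default_rng(1000 + s)
            n = 120
            coh = pd.DataFrame(
                {
                    "label": rng.choice(["EM/EM", "EM/PM", "PM/PM"], n),
                    "as_standard": rng.normal(size=n),
                    "e_ngml": np.exp(rng.normal(size=n)),
                    "dmt_ngml": 100.0,
                    "cyp2c9_class": "*1/*1",
                    "cyp3a5": "*1/*1",
                }
            )
            one = ModelSpec(endpoint="E", predictors=("activity_score",), **NOCOV)
            two = ModelSpec(endpoint="E", predictors=("activity_score", "diplotype"), **NOCOV)
            if compare_models_deviance(one, two, coh)["p"] < 0.05:
                rejections += 1
        rate = rejections / reps
        assert 0.01 <= rate <= 0.10  # binomial error band around 0.05


class TestCovariateScreen:
    def test_default_effects_recovered(self):
        coh = generate_cohort(CohortConfig(n_patients=3000), seed=9)
        screen = covariate_effect_screen(coh).set_index("gene")
        assert screen.loc["CYP3A5", "median_reduction_pct"] == pytest.approx(12, abs=4)
        assert screen.loc["CYP2C9", "median_reduction_pct"] == pytest.approx(26, abs=4)
        assert (screen["p"] < 0.05).all()

    def test_null_multiplier_gives_null_effect(self):
        cfg = CohortConfig(
            n_patients=2000, cyp3a5_hom_dmt_tam_mult=1.0, cyp2c9_hom_4oh_tam_mult=1.0
        )
        coh = generate_cohort(cfg, seed=10)
        screen = covariate_effect_screen(coh).set_index("gene")
        assert abs(screen.loc["CYP3A5", "median_reduction_pct"]) < 4
        assert screen.loc["CYP3A5", "p"] > 0.05

    def test_identical_groups_p_near_one(self):
        # both genotype groups drawn from the same tied distribution
        coh = pd.DataFrame(
            {
                "dmt_ngml": [100.0] * 12,
                "tam_ngml": [50.0] * 12,
                "foh_tam_ngml": [1.0] * 12,
                "cyp3a5": ["*1/*1"] * 6 + ["*3/*3"] * 6,
                "cyp2c9_class": ["*1/*1"] * 6 + ["variant_hom"] * 6,
            }
        )
        screen = covariate_effect_screen(coh).set_index("gene")
        assert screen.loc["CYP3A5", "p"] > 0.9
        assert screen.loc["CYP3A5", "median_reduction_pct"] == pytest.approx(0.0)

    def test_empty_group_skipped_with_warning(self):
        coh = pd.DataFrame(
            {
                "dmt_ngml": [100.0] * 6,
                "tam_ngml": [50.0] * 6,
                "foh_tam_ngml": [1.0] * 6,
                "cyp3a5": ["*3/*3"] * 6,
                "cyp2c9_class": ["variant_hom"] * 6,
            }
        )
        with pytest.warns(UserWarning, match="skipped"):
            screen = covariate_effect_screen(coh)
        assert screen["median_reduction_pct"].isna().all()


class TestCoarseningProperty:
    def test_scheme_r2_never_above_diplotype_r2(self, cohort900):
        """Phenotypes are coarsenings of the diplotype factor."""
        dip = robust_adjusted_r2(
            fit_robust_linear(
                ModelSpec(endpoint="E_over_DMT", predictors=("diplotype",)), cohort900
            )
        )
        for scheme in ("Codeine", "TAM1", "TAM2", "TAM3", "TAM4"):
            sch = robust_adjusted_r2(
                fit_robust_linear(
                    ModelSpec(endpoint="E_over_DMT", predictors=(("scheme", scheme),)),
                    cohort900,
                )
            )
            assert sch <= dip + 0.02
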