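"""Threshold dichotomization, ROC over diplotype ranks, Youden, metrics."""

import numpy as np
import pandas as pd
import pytest

from tampgx.classify import (
    CUTOFF_CANDIDATES,
    ThresholdOutcomes,
    binarize_outcome,
    bootstrap_metric_ci,
    diagnostic_metrics,
    fdr_from_rates,
    roc_over_diplotype_ranks,
    youden_optimal_cutoff,
)


def _outcomes(above, activity):
    return ThresholdOutcomes(
        above=np.asarray(above, bool),
        activity=np.asarray(activity, float),
        threshold_ngml=5.9,
    )


class TestBinarize:
    def test_boundary_counts_as_above(self):
        coh = pd.DataFrame(
            {"e_ngml": [5.9, 5.8999, 6.0, 0.0], "roc_activity": [1.0] * 4}
        )
        out = binarize_outcome(coh)
        assert out.above.tolist() == [True, False, True, False]

    def test_all_zero_none_above(self):
        coh = pd.DataFrame({"e_ngml": [0.0, 0.0], "roc_activity": [1.0, 2.0]})
        assert binarize_outcome(coh).n_positive == 0

    def test_generated_positive_fraction_near_design_target(self, cohort900):
        out = binarize_outcome(cohort900)
        assert out.n_positive / out.n == pytest.approx(0.823, abs=0.04)


class TestRoc:
    def test_published_cutoff_set_at_half(self):
        """activity > 0.5 keeps IM/IM, EM/PM, EM/IM, EM/EM, EM/UM test-positive."""
        acts = {"EM/UM": 3.0, "EM/EM": 2.0, "EM/IM": 1.5, "EM/PM": 1.0,
                "IM/IM": 0.75, "IM/PM": 0.5, "PM/PM": 0.0}
        positive_set = {c for c, a in acts.items() if a > 0.5}
        assert positive_set == {"IM/IM", "EM/PM", "EM/IM", "EM/EM", "EM/UM"}

    def test_trivial_endpoints(self):
        out = _outcomes([True, False, True], [2.0, 0.0, 1.0])
        roc = roc_over_diplotype_ranks(out).set_index("cutoff")
        assert roc.loc[-np.inf, "sensitivity"] == 1.0
        assert roc.loc[-np.inf, "specificity"] == 0.0
        assert roc.loc[3.0, "sensitivity"] == 0.0
        assert roc.loc[3.0, "specificity"] == 1.0

    def test_sensitivity_nonincreasing_with_cutoff(self, cohort900):
        roc = roc_over_diplotype_ranks(binarize_outcome(cohort900))
        assert (roc["sensitivity"].diff().dropna() <= 1e-12).all()

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="each class"):
            roc_over_diplotype_ranks(_outcomes([True, True], [1.0, 2.0]))

    def test_perfect_separation_reaches_corner(self):
        above = [True] * 5 + [False] * 5
        act = [2.0] * 5 + [0.0] * 5
        roc = roc_over_diplotype_ranks(_outcomes(above, act))
        assert ((roc["sensitivity"] == 1.0) & (roc["specificity"] == 1.0)).any()


class TestYouden:
    def test_tie_broken_toward_specificity(self):
        roc = pd.DataFrame(
            {"cutoff": [0.5, 1.0], "sensitivity": [0.9, 0.8],
             "specificity": [0.5, 0.6], "youden_j": [0.4, 0.4]}
        )
        assert youden_optimal_cutoff(roc) == 1.0

    def test_monotone_separated_data_picks_boundary(self):
        above = [True] * 6 + [False] * 4
        act = [2.0, 2.0, 1.5, 1.5, 1.0, 1.0, 0.5, 0.5, 0.0, 0.0]
        roc = roc_over_diplotype_ranks(_outcomes(above, act))
        assert youden_optimal_cutoff(roc) == 0.5


class TestMetrics:
    def test_pm_pm_low_endoxifen_proportion(self):
        """45 of 50 poor-metabolizer homozygotes below threshold -> 90%."""
        e = np.r_[np.full(45, 3.0), np.full(5, 7.0)]
        coh = pd.DataFrame({"e_ngml": e, "roc_activity": 0.0})
        out = binarize_outcome(coh, 5.9)
        frac_below = 1.0 - out.n_positive / out.n
        assert frac_below == pytest.approx(0.90)

    def test_fdr_identity_counts_vs_closed_form(self, cohort900):
        out = binarize_outcome(cohort900)
        m = diagnostic_metrics(out, 0.5)
        prev = out.n_positive / out.n
        assert m["fdr"] == pytest.approx(
            fdr_from_rates(m["sensitivity"], m["specificity"], prev), abs=1e-12
        )

    def test_youden_identity(self, cohort900):
        roc = roc_over_diplotype_ranks(binarize_outcome(cohort900))
        assert np.allclose(
            roc["youden_j"], roc["sensitivity"] + roc["specificity"] - 1.0
        )

    def test_perfect_classifier(self):
        out = _outcomes([True] * 3 + [False] * 3, [2.0] * 3 + [0.0] * 3)
        m = diagnostic_metrics(out, 1.0)
        assert (m["sensitivity"], m["specificity"], m["fdr"]) == (1.0, 1.0, 0.0)

    def test_undefined_metrics_flagged(self):
        out = _outcomes([False, False, True], [0.0, 0.0, 0.0])
        m = diagnostic_metrics(out, 2.0)  # nothing test-positive
        assert np.isnan(m["fdr"])
        assert any("FDR" in f for f in m["flags"])


class TestBootstrapCI:
    def test_single_replicate_ci_collapses_to_point(self):
        out = _outcomes([True] * 30 + [False] * 10, [2.0] * 25 + [0.0] * 15)
        res = bootstrap_metric_ci(out, 0.5, replicates=1, seed=0)
        assert res.sensitivity_ci[0] == res.sensitivity_ci[1]

    def test_deterministic_given_seed(self, cohort900):
        out = binarize_outcome(cohort900)
        a = bootstrap_metric_ci(out, 0.5, replicates=500, seed=7)
        b = bootstrap_metric_ci(out, 0.5, replicates=500, seed=7)
        assert a.sensitivity_ci == b.sensitivity_ci
        assert a.fdr_ci == b.fdr_ci

    def test_point_estimate_inside_ci(self, cohort900):
        out = binarize_outcome(cohort900)
        res = bootstrap_metric_ci(out, 0.5, replicates=2000, seed=1)
        assert res.sensitivity_ci[0] <= res.sensitivity <= res.sensitivity_ci[1]
        assert res.specificity_ci[0] <= res.specificity <= res.specificity_ci[1]

    def test_default_conditions_exclude_low_activity_classes(self, default_config):
        """Under study-like conditions the genotype test separates patients
        in the middle of the activity range: the published cutoff
        (activity > 0.5) keeps sensitivity >= 0.90, and the Youden optimum
        never drops below it or climbs above the EM/PM level."""
        from tampgx.simulate import generate_cohort

        hits = 0
        for seed in range(5):
            coh = generate_cohort(default_config, seed=100 + seed)
            out = binarize_outcome(coh)
            roc = roc_over_diplotype_ranks(out)
            cutoff = youden_optimal_cutoff(roc)
            assert cutoff in (0.5, 0.75, 1.0)
            if diagnostic_metrics(out, 0.5)["sensitivity"] >= 0.90:
                hits += 1
        assert hits >= 3

    def test_invalid_cutoff_rejected(self, cohort900):
        out = binarize_outcome(cohort900)
        with pytest.raises(ValueError, match="not among candidates"):
            bootstrap_metric_ci(out, 0.6, replicates=10)

    def test_cutoff_candidates_cover_seven_levels(self):
        assert len(CUTOFF_CANDIDATES) == 8  # 7 levels + all-positive endpoint
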