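"""Genotype-based classification of patients against the endoxifen threshold.

Patients with plasma (Z)-endoxifen at or above the clinical threshold of
5.9 ng/mL (15.8 nM) are the positive class ("clinical benefit"); the
genotype test calls a patient positive when their CYP2D6 diplotype's
numeric ROC activity exceeds a cutoff.  The seven generic diplotype
categories define the candidate cutoffs (EM/UM 3 > EM/EM 2 > EM/IM 1.5 >
EM/PM 1 > IM/IM 0.75 > IM/PM 0.5 > PM/PM 0; *10-refined labels inherit
their generic class's activity).  The operating cutoff is chosen by
maximizing Youden's J = sensitivity + specificity - 1, and sensitivity,
specificity and the false discovery rate FDR = FP/(FP+TP) are reported
with stratified-bootstrap percentile confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .star_alleles import ROC_ACTIVITY

__all__ = [
    "DEFAULT_THRESHOLD_NGML",
    "CUTOFF_CANDIDATES",
    "ThresholdOutcomes",
    "ClassifierResult",
    "binarize_outcome",
    "roc_over_diplotype_ranks",
    "youden_optimal_cutoff",
    "diagnostic_metrics",
    "fdr_from_rates",
    "bootstrap_metric_ci",
]

DEFAULT_THRESHOLD_NGML = 5.9

#: The seven ordered activity levels; a cutoff c defines the test
#: "activity > c".  -inf is the trivial all-positive endpoint.
CUTOFF_CANDIDATES = (-np.inf, 0.0, 0.5, 0.75, 1.0, 1.5, 2.0, 3.0)


@dataclass
class ThresholdOutcomes:
    """Binary outcome (E >= threshold) and diplotype activity per patient."""

    above: np.ndarray          # bool
    activity: np.ndarray       # float, ROC activity
    threshold_ngml: float
    ids: Optional[Sequence[str]] = None

    @property
    def n(self) -> int:
        return self.above.size

    @property
    def n_positive(self) -> int:
        return int(self.above.sum())


def binarize_outcome(
    cohort: pd.DataFrame, threshold_ngml: float = DEFAULT_THRESHOLD_NGML
) -> ThresholdOutcomes:
    """Dichotomize patients at the endoxifen threshold (ng/mL scale).

    Boundary convention: E exactly at the threshold counts as above.
    """
    e = cohort["e_ngml"].to_numpy(float)
    above = e >= threshold_ngml
    activity = cohort["roc_activity"].to_numpy(float)
    return ThresholdOutcomes(
        above=above,
        activity=activity,
        threshold_ngml=threshold_ngml,
        ids=list(cohort["id"]) if "id" in cohort else None,
    )


def _confusion(outcomes: ThresholdOutcomes, cutoff: float) -> Dict[str, int]:
    test_pos = outcomes.activity > cutoff
    tp = int(np.sum(test_pos & outcomes.above))
    fp = int(np.sum(test_pos & ~outcomes.above))
    fn = int(np.sum(~test_pos & outcomes.above))
    tn = int(np.sum(~test_pos & ~outcomes.above))
    return {"tp": tp, "fp": fp, "fn": fn, "tn": tn}


def roc_over_diplotype_ranks(outcomes: ThresholdOutcomes) -> pd.DataFrame:
    """One (sensitivity, specificity) point per candidate activity cutoff.

    Requires at least one positive and one negative outcome; sensitivity
    is non-increasing as the cutoff rises.
    """
    n_pos = outcomes.n_positive
    n_neg = outcomes.n - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError(
            "ROC undefined: need at least one outcome in each class "
            f"(positives={n_pos}, negatives={n_neg})"
        )
    rows = []
    for c in CUTOFF_CANDIDATES:
        cm = _confusion(outcomes, c)
        rows.append(
            {
                "cutoff": c,
                "sensitivity": cm["tp"] / n_pos,
                "specificity": cm["tn"] / n_neg,
                **cm,
            }
        )
    roc = pd.DataFrame(rows)
    roc["youden_j"] = roc["sensitivity"] + roc["specificity"] - 1.0
    return roc


def youden_optimal_cutoff(roc: pd.DataFrame) -> float:
    """Cutoff maximizing Youden's J; ties go to the more specific cutoff."""
    best = roc.sort_values(
        ["youden_j", "specificity"], ascending=[False, False], kind="stable"
    ).iloc[0]
    return float(best["cutoff"])


def diagnostic_metrics(outcomes: ThresholdOutcomes, cutoff: float) -> Dict[str, float]:
    """Sensitivity, specificity, FDR and test-positive fraction at a cutoff.

    Metrics with an empty denominator are returned as NaN and flagged.
    """
    cm = _confusion(outcomes, cutoff)
    tp, fp, fn, tn = cm["tp"], cm["fp"], cm["fn"], cm["tn"]
    flags = []
    if tp + fn == 0:
        sens = float("nan"); flags.append("no positives: sensitivity undefined")
    else:
        sens = tp / (tp + fn)
    if tn + fp == 0:
        spec = float("nan"); flags.append("no negatives: specificity undefined")
    else:
        spec = tn / (tn + fp)
    if tp + fp == 0:
        fdr = float("nan"); flags.append("no test-positives: FDR undefined")
    else:
        fdr = fp / (fp + tp)
    return {
        "cutoff": cutoff,
        "sensitivity": sens,
        "specificity": spec,
        "fdr": fdr,
        "positive_fraction": (tp + fp) / outcomes.n,
        "youden_j": sens + spec - 1.0,
        **cm,
        "flags": flags,
    }


def fdr_from_rates(sensitivity: float, specificity: float, prevalence: float) -> float:
    """Closed-form FDR from (sensitivity, specificity, prevalence).

    ``FDR = (1-spec)(1-prev) / [(1-spec)(1-prev) + sens*prev]``.
    """
    fp = (1.0 - specificity) * (1.0 - prevalence)
    tp = sensitivity * prevalence
    return fp / (fp + tp)


@dataclass
class ClassifierResult:
    """Full ROC/Youden classification output with bootstrap CIs."""

    roc: pd.DataFrame = field(repr=False)
    cutoff: float
    sensitivity: float
    specificity: float
    fdr: float
    positive_fraction: float
    sensitivity_ci: tuple
    specificity_ci: tuple
    fdr_ci: tuple
    sensitivity_boot_median: float
    specificity_boot_median: float
    fdr_boot_median: float
    n: int
    replicates: int
    dropped_replicates: int
    seed: Optional[int]

    def to_dict(self) -> dict:
        return {
            "cutoff": self.cutoff,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "fdr": self.fdr,
            "positive_fraction": self.positive_fraction,
            "sensitivity_ci_95": list(self.sensitivity_ci),
            "specificity_ci_95": list(self.specificity_ci),
            "fdr_ci_95": list(self.fdr_ci),
            "sensitivity_boot_median": self.sensitivity_boot_median,
            "specificity_boot_median": self.specificity_boot_median,
            "fdr_boot_median": self.fdr_boot_median,
            "n": self.n,
            "replicates": self.replicates,
            "dropped_replicates": self.dropped_replicates,
            "seed": self.seed,
            "roc": self.roc.replace({-np.inf: None}).to_dict(orient="records"),
        }


def bootstrap_metric_ci(
    outcomes: ThresholdOutcomes,
    cutoff: float,
    replicates: int = 10_000,
    seed: Optional[int] = None,
) -> ClassifierResult:
    """Stratified case-resampling bootstrap CIs for the metrics at a cutoff.

    Patients are resampled with replacement within the positive and
    negative strata.  Because sensitivity, specificity and FDR depend on
    the resample only through the per-stratum test-positive counts, the
    stratified resample is drawn exactly through those sufficient counts
    (binomial draws per stratum) — distributionally identical to index
    resampling and fully vectorized.  Replicates where a metric's
    denominator is empty are dropped for that metric and counted; more
    than 10% drops is an error.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if cutoff not in CUTOFF_CANDIDATES:
        raise ValueError(f"cutoff {cutoff!r} not among candidates {CUTOFF_CANDIDATES}")
    point = diagnostic_metrics(outcomes, cutoff)
    n_pos = outcomes.n_positive
    n_neg = outcomes.n - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("bootstrap undefined for a single-class outcome vector")
    rng = np.random.default_rng(seed)
    p_tp = point["tp"] / n_pos          # P(test+ | above threshold)
    p_fp = point["fp"] / n_neg          # P(test+ | below threshold)
    tp_b = rng.binomial(n_pos, p_tp, size=replicates)
    fp_b = rng.binomial(n_neg, p_fp, size=replicates)
    sens_b = tp_b / n_pos
    spec_b = (n_neg - fp_b) / n_neg
    denom = tp_b + fp_b
    ok = denom > 0
    dropped = int((~ok).sum())
    if dropped > 0.1 * replicates:
        raise RuntimeError(
            f"{dropped}/{replicates} bootstrap replicates had no test-positive "
            f"patients; FDR bootstrap unstable"
        )
    fdr_b = fp_b[ok] / denom[ok]

    def ci(v: np.ndarray) -> tuple:
        return (float(np.percentile(v, 2.5)), float(np.percentile(v, 97.5)))

    roc = roc_over_diplotype_ranks(outcomes)
    return ClassifierResult(
        roc=roc,
        cutoff=cutoff,
        sensitivity=point["sensitivity"],
        specificity=point["specificity"],
        fdr=point["fdr"],
        positive_fraction=point["positive_fraction"],
        sensitivity_ci=ci(sens_b),
        specificity_ci=ci(spec_b),
        fdr_ci=ci(fdr_b),
        sensitivity_boot_median=float(np.median(sens_b)),
        specificity_boot_median=float(np.median(spec_b)),
        fdr_boot_median=float(np.median(fdr_b)),
        n=outcomes.n,
        replicates=replicates,
        dropped_replicates=dropped,
        seed=seed,
    )
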