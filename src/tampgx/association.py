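"""Robust association of transformed endpoints with CYP2D6 genotype.

Quantifies the fraction of inter-patient variability in log endoxifen (E)
or log metabolic ratio (E/DMT) explained by the CYP2D6 diplotype, by a
phenotype scheme, or by the numeric activity score, adjusting for CYP2C9
and CYP3A5 covariate genotypes.

The estimator is an M-type robust linear fit (iteratively reweighted least
squares with the redescending Tukey bisquare weight function at ~95%
Gaussian efficiency), so single gross outliers — a well-documented feature
of plasma metabolite panels — cannot dominate the variance decomposition.
The robust adjusted R² is the weighted coefficient of determination under
the fit's final robustness weights with the standard small-sample
adjustment; when every weight is 1 it reduces exactly to the classical
adjusted R².  Uncertainty is quantified by case-resampling bootstrap with
percentile intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dataclasses_replace
from typing import Dict, List, Optional, Tuple, Union

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .endpoints import metabolic_ratio, transform_endpoint
from .schemes import SchemeTable, get_scheme

__all__ = [
    "ModelSpec",
    "RobustFit",
    "AssociationResult",
    "build_design",
    "fit_robust_linear",
    "robust_adjusted_r2",
    "bootstrap_r2_ci",
    "compare_models_deviance",
    "covariate_effect_screen",
    "NonConvergenceError",
    "RankDeficientDesignError",
]


class NonConvergenceError(RuntimeError):
    """Robust IRLS failed to converge."""


class RankDeficientDesignError(ValueError):
    """Design matrix is rank deficient (aliased factor levels)."""


@dataclass(frozen=True)
class ModelSpec:
    """What to regress on what.

    ``predictor`` is one of ``"diplotype"`` (the 10-level diplotype label
    as a factor), ``("scheme", name)`` (phenotype under a named scheme as
    an ordered factor), or ``"activity_score"`` (numeric standard AS).
    Several predictors may be combined by passing a tuple of the above to
    ``predictors``.
    """

    endpoint: str  # "E" | "E_over_DMT"
    predictors: Tuple = ("diplotype",)
    covariates: bool = True
    estimator: str = "robust_mm"  # "robust_mm" | "ordinary"
    transform: str = "log"

    def describe(self) -> str:
        parts = []
        for p in self.predictors:
            parts.append(f"scheme:{p[1]}" if isinstance(p, tuple) else str(p))
        return f"{self.endpoint} ~ {' + '.join(parts)}" + (
            " + covariates" if self.covariates else ""
        )


def _endpoint_values(spec: ModelSpec, cohort: pd.DataFrame) -> np.ndarray:
    if spec.endpoint == "E":
        raw = cohort["e_ngml"].to_numpy(float)
    elif spec.endpoint == "E_over_DMT":
        raw = metabolic_ratio(cohort["e_ngml"].to_numpy(float), cohort["dmt_ngml"].to_numpy(float))
    else:
        raise ValueError(f"unknown endpoint {spec.endpoint!r}")
    return transform_endpoint(raw, spec.transform, name=spec.endpoint).transformed


def _dummies(series: pd.Series, prefix: str) -> pd.DataFrame:
    d = pd.get_dummies(series.astype(str), prefix=prefix, dtype=float)
    d = d.reindex(sorted(d.columns), axis=1)
    return d.iloc[:, 1:]  # drop reference level


def build_design(
    spec: ModelSpec, cohort: pd.DataFrame, drop_aliased: bool = False
) -> Tuple[np.ndarray, np.ndarray, List[str]]:
    """(y, X, column names) for a model spec; X includes an intercept.

    A rank-deficient design raises by default, naming the aliased levels.
    ``drop_aliased=True`` instead keeps a maximal independent subset of
    columns in construction order (intercept and covariates first), the
    convention linear-model software uses when two phenotype assignments
    of the same diplotypes — necessarily partly collinear — enter one
    model.
    """
    y = _endpoint_values(spec, cohort)
    blocks = [pd.DataFrame({"const": np.ones(len(cohort))})]
    if spec.covariates:
        blocks.append(_dummies(cohort["cyp2c9_class"], "c9"))
        blocks.append(_dummies(cohort["cyp3a5"], "a5"))
    for pred in spec.predictors:
        if pred == "diplotype":
            blocks.append(_dummies(cohort["label"], "dip"))
        elif pred == "activity_score":
            blocks.append(pd.DataFrame({"as_standard": cohort["as_standard"].to_numpy(float)}))
        elif isinstance(pred, tuple) and pred[0] == "scheme":
            scheme = get_scheme(pred[1]) if isinstance(pred[1], str) else pred[1]
            pheno = cohort["label"].map(scheme.assign)
            blocks.append(_dummies(pheno, f"ph_{scheme.name}"))
        else:
            raise ValueError(f"unknown predictor {pred!r}")
    X = pd.concat(blocks, axis=1)
    names = list(X.columns)
    Xv = X.to_numpy(float)
    rank = np.linalg.matrix_rank(Xv)
    if rank < Xv.shape[1]:
        if not drop_aliased:
            aliased = [
                names[j]
                for j in range(Xv.shape[1])
                if np.linalg.matrix_rank(np.delete(Xv, j, axis=1)) == rank
            ]
            raise RankDeficientDesignError(
                f"rank-deficient design (rank {rank} < {Xv.shape[1]}); aliased "
                f"columns include {aliased[:8]}"
            )
        keep: List[int] = []
        current = np.empty((Xv.shape[0], 0))
        for j in range(Xv.shape[1]):
            cand = np.hstack([current, Xv[:, [j]]])
            if np.linalg.matrix_rank(cand) > current.shape[1]:
                keep.append(j)
                current = cand
        Xv = Xv[:, keep]
        names = [names[j] for j in keep]
    return y, Xv, names


@dataclass
class RobustFit:
    """A converged robust (or ordinary) linear fit."""

    spec: ModelSpec
    params: np.ndarray
    names: List[str]
    fitted: np.ndarray
    resid: np.ndarray
    weights: np.ndarray
    y: np.ndarray
    X: np.ndarray
    scale: float
    n: int

    @property
    def coefficients(self) -> pd.Series:
        return pd.Series(self.params, index=self.names)


#: residual scale below which a fit is treated as exact (weights := 1)
_DEGENERATE_SCALE = 1e-12


def fit_robust_linear(
    spec: ModelSpec,
    cohort: pd.DataFrame,
    maxiter: int = 100,
    drop_aliased: bool = False,
) -> RobustFit:
    """Robust M-type IRLS fit (Tukey bisquare, c=4.685, ~95% efficiency).

    Degenerate responses (residual scale ~0 relative to the response, e.g.
    an exactly linear response) fall back to the least-squares solution
    with unit weights.  ``estimator="ordinary"`` requests plain OLS.
    """
    y, X, names = build_design(spec, cohort, drop_aliased=drop_aliased)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"n={n} must exceed number of parameters p={p}")
    ols = sm.OLS(y, X).fit()
    yscale = float(np.std(y)) or 1.0
    mad_scale = float(sm.robust.scale.mad(ols.resid, center=0))
    if spec.estimator == "ordinary" or mad_scale < _DEGENERATE_SCALE * yscale:
        return RobustFit(
            spec=spec, params=np.asarray(ols.params), names=names,
            fitted=np.asarray(ols.fittedvalues), resid=np.asarray(ols.resid),
            weights=np.ones(n), y=y, X=X, scale=mad_scale, n=n,
        )
    model = sm.RLM(y, X, M=sm.robust.norms.TukeyBiweight())
    res = model.fit(maxiter=maxiter, start_params=ols.params)
    niter = len(res.fit_history.get("params", [])) or maxiter
    if niter >= maxiter:
        raise NonConvergenceError(
            f"robust IRLS did not converge within {maxiter} iterations "
            f"for {spec.describe()} (deviance trace tail: "
            f"{res.fit_history.get('deviance', [])[-3:]})"
        )
    return RobustFit(
        spec=spec, params=np.asarray(res.params), names=names,
        fitted=np.asarray(res.fittedvalues), resid=np.asarray(res.resid),
        weights=np.asarray(res.weights), y=y, X=X,
        scale=float(res.scale), n=n,
    )


def robust_adjusted_r2(fit: RobustFit) -> float:
    """Weighted adjusted coefficient of determination.

    ``R2_w = 1 - sum(w e^2) / sum(w (y - ybar_w)^2)`` with the fit's final
    robustness weights, adjusted by ``(n-1)/(n-p-1)``; equals the classical
    adjusted R² when all weights are 1.
    """
    w = fit.weights
    ybar = float(np.sum(w * fit.y) / np.sum(w))
    sst = float(np.sum(w * (fit.y - ybar) ** 2))
    ssr = float(np.sum(w * fit.resid**2))
    if sst == 0.0:
        return 1.0 if ssr == 0.0 else 0.0
    r2 = 1.0 - ssr / sst
    p = fit.X.shape[1] - 1
    return 1.0 - (1.0 - r2) * (fit.n - 1) / (fit.n - p - 1)


@dataclass
class AssociationResult:
    """Point and bootstrap estimates of variance explained."""

    spec: ModelSpec
    r2_point: float
    r2_boot_median: float
    ci_low: float
    ci_high: float
    n: int
    replicates: int
    failed_replicates: int
    seed: Optional[int]
    coefficients: pd.Series = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "model": self.spec.describe(),
            "r2_point": self.r2_point,
            "r2_boot_median": self.r2_boot_median,
            "ci_95": [self.ci_low, self.ci_high],
            "n": self.n,
            "replicates": self.replicates,
            "failed_replicates": self.failed_replicates,
            "seed": self.seed,
        }


def bootstrap_r2_ci(
    spec: ModelSpec,
    cohort: pd.DataFrame,
    replicates: int = 10_000,
    seed: Optional[int] = None,
) -> AssociationResult:
    """Case-resampling bootstrap of the robust adjusted R².

    Patients are resampled with replacement; each replicate refits the
    model.  Replicates that fail (non-convergence, or a resample losing a
    factor level to rank deficiency) are dropped and counted; more than
    10% failures aborts with an error.  Deterministic given the seed (one
    root seed, per-replicate substreams).
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    fit = fit_robust_linear(spec, cohort)
    point = robust_adjusted_r2(fit)
    n = len(cohort)
    rng = np.random.default_rng(seed)
    values = []
    failed = 0
    for _ in range(replicates):
        idx = rng.integers(0, n, size=n)
        sample = cohort.iloc[idx].reset_index(drop=True)
        try:
            values.append(robust_adjusted_r2(fit_robust_linear(spec, sample)))
        except (NonConvergenceError, RankDeficientDesignError, ValueError):
            failed += 1
    if failed > 0.1 * replicates:
        raise NonConvergenceError(
            f"{failed}/{replicates} bootstrap replicates failed; the model "
            f"is unstable under resampling"
        )
    values = np.asarray(values)
    return AssociationResult(
        spec=spec,
        r2_point=point,
        r2_boot_median=float(np.median(values)),
        ci_low=float(np.percentile(values, 2.5)),
        ci_high=float(np.percentile(values, 97.5)),
        n=n,
        replicates=len(values),
        failed_replicates=failed,
        seed=seed,
        coefficients=fit.coefficients,
    )


def compare_models_deviance(
    spec_one: ModelSpec, spec_two: ModelSpec, cohort: pd.DataFrame
) -> Dict[str, float]:
    """Robust analysis of deviance between nested linear models.

    ``spec_two`` must strictly extend ``spec_one`` (same endpoint and
    covariates, additional predictors).  The comparison is a robust
    Wald-type F-test: the larger model is fit by robust IRLS and the
    joint hypothesis that the added assignment's coefficients vanish is
    tested against their estimated covariance (which carries the standard
    M-estimation correction factor).  Aliased columns of the larger model
    (two assignments of the same diplotypes are necessarily partly
    collinear) are dropped; the numerator degrees of freedom are the gain
    in design rank.
    """
    if spec_one.endpoint != spec_two.endpoint or spec_one.covariates != spec_two.covariates:
        raise ValueError("models must share endpoint and covariate set")
    preds_one, preds_two = set(spec_one.predictors), set(spec_two.predictors)
    if preds_one == preds_two:
        raise ValueError("degenerate nesting: the two specs are identical")
    if not preds_one < preds_two:
        raise ValueError(
            f"specs are not nested: {spec_one.describe()} is not a strict "
            f"sub-model of {spec_two.describe()}"
        )
    # order the larger model's predictors so the shared block comes first:
    # the aliasing drop then removes redundancy from the added block only
    ordered = tuple(spec_one.predictors) + tuple(
        p for p in spec_two.predictors if p not in preds_one
    )
    spec_two = dataclasses_replace(spec_two, predictors=ordered)
    _, X1, names1 = build_design(spec_one, cohort, drop_aliased=True)
    fit2 = fit_robust_linear(spec_two, cohort, drop_aliased=True)
    added = [j for j, name in enumerate(fit2.names) if name not in names1]
    df_num = len(added)
    df_den = fit2.n - fit2.X.shape[1]
    if df_num <= 0:
        raise ValueError("larger model adds no parameters beyond aliasing")
    if np.all(fit2.weights == 1.0):
        # degenerate/OLS fall-back: classical nested F on residual sums
        rss = {}
        for key, X in (("one", X1), ("two", fit2.X)):
            beta, *_ = np.linalg.lstsq(X, fit2.y, rcond=None)
            rss[key] = float(np.sum((fit2.y - X @ beta) ** 2))
        f_stat = ((rss["one"] - rss["two"]) / df_num) / max(rss["two"] / df_den, 1e-300)
    else:
        res = sm.RLM(
            fit2.y, fit2.X, M=sm.robust.norms.TukeyBiweight()
        ).fit(start_params=fit2.params)
        b = np.asarray(res.params)[added]
        V = np.asarray(res.cov_params())[np.ix_(added, added)]
        f_stat = float(b @ np.linalg.solve(V, b)) / df_num
    p = float(stats.f.sf(f_stat, df_num, df_den))
    return {"f": float(f_stat), "df_num": df_num, "df_den": df_den, "p": p}


def covariate_effect_screen(cohort: pd.DataFrame) -> pd.DataFrame:
    """Rank-sum screen of the covariate pharmacogenes on precursor ratios.

    For each contrast (CYP3A5 *3/*3 vs *1/*1 on DMT/TAM; CYP2C9 variant
    homozygotes vs *1/*1 on 4OH-TAM/TAM) a two-sided Wilcoxon-Mann-Whitney
    test is run and the median percent reduction reported.  Contrasts with
    an empty genotype group are skipped with a warning row.
    """
    import warnings

    dmt_tam = metabolic_ratio(cohort["dmt_ngml"].to_numpy(float), cohort["tam_ngml"].to_numpy(float))
    foh_tam = metabolic_ratio(cohort["foh_tam_ngml"].to_numpy(float), cohort["tam_ngml"].to_numpy(float))
    contrasts = [
        ("CYP3A5", "DMT/TAM", dmt_tam, cohort["cyp3a5"] == "*3/*3", cohort["cyp3a5"] == "*1/*1"),
        ("CYP2C9", "4OH-TAM/TAM", foh_tam, cohort["cyp2c9_class"] == "variant_hom", cohort["cyp2c9_class"] == "*1/*1"),
    ]
    rows = []
    for gene, ratio_name, ratio, var_mask, ref_mask in contrasts:
        gv, gr = ratio[var_mask.to_numpy()], ratio[ref_mask.to_numpy()]
        if len(gv) == 0 or len(gr) == 0:
            warnings.warn(f"{gene}: empty genotype group, contrast skipped")
            rows.append(
                {"gene": gene, "ratio": ratio_name, "n_variant": len(gv),
                 "n_ref": len(gr), "median_reduction_pct": np.nan, "p": np.nan}
            )
            continue
        stat = stats.mannwhitneyu(gv, gr, alternative="two-sided")
        reduction = 100.0 * (1.0 - np.median(gv) / np.median(gr))
        rows.append(
            {"gene": gene, "ratio": ratio_name, "n_variant": len(gv),
             "n_ref": len(gr), "median_reduction_pct": float(reduction),
             "p": float(stat.pvalue)}
        )
    return pd.DataFrame(rows)
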