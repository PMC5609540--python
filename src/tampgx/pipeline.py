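"""End-to-end orchestration: cohort -> scores -> phenotypes -> R2 -> ROC.

``run_pipeline`` sequences the full analysis behind a single
:class:`RunConfig`: generate (or load) a cohort, apply the tamoxifen
compliance filter, emit the diplotype frequency table, fit per-scheme
robust association models for both endpoints, compare schemes by analysis
of deviance, run the threshold classifier, and write everything under an
output directory.  All stochastic stages are seeded from one root seed via
named substreams, and every artifact records the config hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import numpy as np
import pandas as pd

from . import association, classify, endpoints, schemes, simulate
from .star_alleles import (
    UnsupportedAlleleError,
    UnsupportedDiplotypeError,
    parse_diplotype,
)

__all__ = ["RunConfig", "run_pipeline", "read_cohort_csv", "config_hash"]

log = logging.getLogger("tampgx")


def _jsonable(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, float) and np.isnan(o):
        return None
    return str(o)


def _dump_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_jsonable)

_MANDATORY_COLUMNS = ("diplotype", "tam_ngml", "dmt_ngml", "e_ngml")


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    mode: str = "synthetic"  # "synthetic" | "file"
    cohort_path: Optional[str] = None
    cohort_config: simulate.CohortConfig = field(default_factory=simulate.CohortConfig)
    schemes: Tuple[str, ...] = schemes.SCHEME_NAMES
    endpoints: Tuple[str, ...] = ("E", "E_over_DMT")
    replicates: int = 10_000
    seed: int = 0
    outdir: str = "results/run"
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.mode not in ("synthetic", "file"):
            raise ValueError(f"unknown input mode {self.mode!r}")
        if self.mode == "file" and not self.cohort_path:
            raise ValueError("file mode requires cohort_path")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not self.schemes:
            raise ValueError("at least one scheme required")
        if not self.endpoints:
            raise ValueError("at least one endpoint required")
        unknown = [s for s in self.schemes if s not in schemes.BUILTIN_SCHEMES]
        if unknown:
            raise ValueError(f"unknown scheme(s): {unknown}")


def config_hash(config: RunConfig) -> str:
    """Stable hash of the scientifically relevant run configuration.

    Output location and log level do not change the results and are
    excluded, so reruns into different directories hash identically.
    """

    def default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        return str(o)

    payload = dataclasses.asdict(config)
    payload.pop("outdir", None)
    payload.pop("log_level", None)
    payload = json.dumps(payload, sort_keys=True, default=default)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def read_cohort_csv(path: Union[str, Path]) -> Tuple[pd.DataFrame, Dict]:
    """Read a patient cohort CSV, validating and scoring diplotypes.

    Rows whose diplotype cannot be resolved against the supported allele
    panel are excluded and counted with their reason; the returned report
    reconciles rows-in = records-used + rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, comment="#")
    missing = [c for c in _MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing mandatory column(s): {missing}")
    rows = []
    rejected: List[Dict] = []
    for i, row in df.iterrows():
        try:
            d = parse_diplotype(str(row["diplotype"]))
        except (UnsupportedAlleleError, UnsupportedDiplotypeError) as exc:
            rejected.append({"row": int(i), "diplotype": row["diplotype"], "reason": str(exc)})
            continue
        rec = dict(row)
        rec.update(
            category=d.category,
            refinement=d.refinement,
            label=d.label,
            as_standard=d.activity_score("standard"),
            as_star10_downgrade=d.activity_score("star10_downgrade"),
            roc_activity=d.roc_activity,
        )
        rec.setdefault("id", f"R{i:05d}")
        rows.append(rec)
    cohort = pd.DataFrame(rows).reset_index(drop=True)
    if "cyp2c9" in cohort.columns and "cyp2c9_class" not in cohort.columns:
        cohort["cyp2c9_class"] = cohort["cyp2c9"].map(simulate.cyp2c9_class)
    report = {
        "rows_in": int(len(df)),
        "records_used": int(len(cohort)),
        "rejected": len(rejected),
        "rejections": rejected,
    }
    assert report["rows_in"] == report["records_used"] + report["rejected"]
    return cohort, report


def _seed_streams(root_seed: int, names: Tuple[str, ...]) -> Dict[str, int]:
    """Named 31-bit substream seeds fanned out from one root seed."""
    children = np.random.SeedSequence(root_seed).spawn(len(names))
    return {
        name: int(child.generate_state(1, dtype=np.uint64)[0] % (2**31))
        for name, child in zip(names, children)
    }


def run_pipeline(config: RunConfig) -> Dict:
    """Run the full analysis; returns the summary report (also written)."""
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    t0 = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)
    seeds = _seed_streams(config.seed, ("cohort", "bootstrap_r2", "bootstrap_roc"))
    report: Dict = {"config_hash": chash, "seed": config.seed, "stream_seeds": seeds}

    # 1. cohort
    if config.mode == "synthetic":
        cohort = simulate.generate_cohort(config.cohort_config, seed=seeds["cohort"])
        read_report = {"rows_in": len(cohort), "records_used": len(cohort), "rejected": 0}
    else:
        cohort, read_report = read_cohort_csv(config.cohort_path)
    cohort, compliance = simulate.apply_compliance_filter(
        cohort, config.cohort_config.compliance_threshold_nM
    )
    report["input"] = read_report
    report["compliance_filter"] = compliance
    log.info("stage=cohort n=%d seed=%d elapsed=%.1fs", len(cohort), seeds["cohort"], time.time() - t0)

    # 2. frequency table
    freq = endpoints.frequency_table(cohort)
    freq.insert(0, "config_hash", chash)
    freq.to_csv(outdir / "frequency_table.csv", index=False)

    # 3. association per endpoint x predictor; covariate genotypes are used
    # when the cohort carries them (mirroring the subset with available
    # CYP2C9/CYP3A5 genotypes)
    has_covariates = {"cyp2c9_class", "cyp3a5"}.issubset(cohort.columns)
    if not has_covariates:
        log.info("stage=associate covariate genotypes absent; fitting without")
    assoc_results = []
    predictors = [("diplotype", ("diplotype",))] + [
        (f"scheme:{s}", (("scheme", s),)) for s in config.schemes
    ]
    for ep in config.endpoints:
        for name, preds in predictors:
            spec = association.ModelSpec(
                endpoint=ep, predictors=preds, covariates=has_covariates
            )
            res = association.bootstrap_r2_ci(
                spec, cohort, replicates=config.replicates, seed=seeds["bootstrap_r2"]
            )
            assoc_results.append({"endpoint": ep, "predictor": name, **res.to_dict()})
            res.coefficients.rename("estimate").to_csv(
                outdir / f"coefficients_{ep}_{name.replace(':', '_').replace('/', '_')}.csv"
            )
            log.info("stage=associate model=%s r2=%.3f elapsed=%.1fs",
                     res.spec.describe(), res.r2_point, time.time() - t0)
    _dump_json({"config_hash": chash, "results": assoc_results}, outdir / "association.json")

    # 4. pairwise scheme comparisons (one vs two phenotype assignments)
    comparisons = []
    for ep in config.endpoints:
        for s1 in config.schemes:
            for s2 in config.schemes:
                if s1 == s2:
                    continue
                one = association.ModelSpec(
                    endpoint=ep, predictors=(("scheme", s1),), covariates=has_covariates
                )
                two = association.ModelSpec(
                    endpoint=ep,
                    predictors=(("scheme", s1), ("scheme", s2)),
                    covariates=has_covariates,
                )
                try:
                    cmp_res = association.compare_models_deviance(one, two, cohort)
                except (association.RankDeficientDesignError, ValueError) as exc:
                    cmp_res = {"error": str(exc)}
                comparisons.append({"endpoint": ep, "base": s1, "added": s2, **cmp_res})
    _dump_json({"config_hash": chash, "comparisons": comparisons}, outdir / "scheme_comparisons.json")

    # 5. threshold classification
    outcomes = classify.binarize_outcome(cohort)
    roc = classify.roc_over_diplotype_ranks(outcomes)
    cutoff = classify.youden_optimal_cutoff(roc)
    clf = classify.bootstrap_metric_ci(
        outcomes, cutoff, replicates=config.replicates, seed=seeds["bootstrap_roc"]
    )
    clf_dict = {"config_hash": chash, **clf.to_dict()}
    _dump_json(clf_dict, outdir / "classifier.json")
    roc.to_csv(outdir / "roc_points.csv", index=False)
    log.info("stage=classify cutoff=%.2f sens=%.3f spec=%.3f elapsed=%.1fs",
             cutoff, clf.sensitivity, clf.specificity, time.time() - t0)

    # 6. summary
    report["association"] = assoc_results
    report["classifier"] = {
        k: v for k, v in clf_dict.items() if k != "roc"
    }
    report["elapsed_s"] = round(time.time() - t0, 2)
    _dump_json(report, outdir / "summary.json")
    return report
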