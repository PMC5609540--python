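#!/usr/bin/env python
"""How much endoxifen variability does each genotype grouping explain?

Fits robust linear models of log endoxifen (E) and log metabolic ratio
(E/DMT) on the CYP2D6 diplotype factor and on each of the five phenotype
schemes (CYP2C9/CYP3A5 genotypes as covariates), with bootstrap 95%
intervals for the robust adjusted R-squared, on a default synthetic cohort
and on a *10-rich East-Asian-like cohort.  Writes results/variance_explained.csv.

The headline finding this reproduces: the full diplotype factor explains
the most variance, E/DMT is markedly better predicted than E, and the
codeine-based grouping collapses on the *10-rich cohort because it bins
the abundant *10/*10 patients as extensive metabolizers.
"""

from pathlib import Path

import pandas as pd

from tampgx.association import ModelSpec, bootstrap_r2_ci
from tampgx.simulate import (
    ASIAN_LIKE_ALLELE_FREQUENCIES,
    CohortConfig,
    generate_cohort,
)

SEED = 42
REPLICATES = 500  # bootstrap replicates per model
OUT = Path("results")


def main() -> None:
    OUT.mkdir(exist_ok=True)
    cohorts = {
        "pooled": generate_cohort(CohortConfig(), seed=SEED),
        "asian_like": generate_cohort(
            CohortConfig(
                mode="hardy_weinberg",
                allele_frequencies=dict(ASIAN_LIKE_ALLELE_FREQUENCIES),
                ethnicity="asian_like",
            ),
            seed=SEED,
        ),
    }
    predictors = [("diplotype", ("diplotype",))] + [
        (s, (("scheme", s),)) for s in ("Codeine", "TAM1", "TAM2", "TAM3", "TAM4")
    ]
    rows = []
    for cohort_name, cohort in cohorts.items():
        for endpoint in ("E", "E_over_DMT"):
            for name, preds in predictors:
                res = bootstrap_r2_ci(
                    ModelSpec(endpoint=endpoint, predictors=preds),
                    cohort,
                    replicates=REPLICATES,
                    seed=SEED,
                )
                rows.append(
                    {
                        "cohort": cohort_name,
                        "endpoint": endpoint,
                        "predictor": name,
                        "r2_point": round(res.r2_point, 4),
                        "r2_boot_median": round(res.r2_boot_median, 4),
                        "ci_low": round(res.ci_low, 4),
                        "ci_high": round(res.ci_high, 4),
                        "n": res.n,
                    }
                )
                print(f"{cohort_name:10s} {endpoint:10s} {name:9s} "
                      f"R2={res.r2_point:.3f} [{res.ci_low:.3f}, {res.ci_high:.3f}]")
    table = pd.DataFrame(rows)
    table.to_csv(OUT / "variance_explained.csv", index=False)

    pooled = table.query("cohort=='pooled' and endpoint=='E_over_DMT'").set_index("predictor")
    asian = table.query("cohort=='asian_like' and endpoint=='E_over_DMT'").set_index("predictor")
    print(f"\nE/DMT, pooled cohort: diplotype R2 {pooled.loc['diplotype','r2_point']:.2f} "
          f"vs best scheme {pooled.drop('diplotype')['r2_point'].max():.2f}")
    print(f"E/DMT, *10-rich cohort: Codeine R2 {asian.loc['Codeine','r2_point']:.2f} "
          f"vs TAM4 {asian.loc['TAM4','r2_point']:.2f}")


if __name__ == "__main__":
    main()
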