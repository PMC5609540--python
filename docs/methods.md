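# Methods

## Star alleles, diplotypes and activity scores

The allele panel is closed: PM (null) alleles `*3 *4 *5 *6 *7`, IM
(reduced-function) alleles `*9 *10 *41`, EM (fully functional) alleles
`*1 *2 *35` plus a "no variant detected" sentinel for platforms that call
EM status by exclusion. Anything else raises an error — silently treating
an uncharacterized allele as functional is precisely the misclassification
the activity-score system exists to avoid.

Per-allele activity values are 0 (PM), 0.5 (IM), 1 (EM) and 2 for a
duplicated EM allele; the diplotype score is the sum. The
`star10_downgrade` dialect scores `*10` at 0.25. Ultra-rapid (UM) status
requires a duplication *in the absence of variant alleles*: a duplicated
EM allele paired with a variant allele is treated as plain EM (score 1),
and duplications of variant alleles are scored as the un-duplicated
variant. Two duplicated EM alleles in one diplotype are rejected as
outside the supported category table.

Diplotypes carry two labels: the generic class (`EM/UM`, `EM/EM`, `EM/IM`,
`EM/PM`, `IM/IM`, `IM/PM`, `PM/PM`) and, when exactly applicable, a
`*10`-specific refinement (`EM/*10` ⊂ `EM/IM`, `*10/*10` ⊂ `IM/IM`,
`PM/*10` ⊂ `IM/PM`). Schemes that ignore the refinement read the generic
label; both are retained on the object so all five schemes read the same
diplotype.

For ROC analysis the seven generic classes sit on a numeric activity axis
equal to the standard score except that the two score-1 classes are
separated: `EM/PM` at 1 and `IM/IM` at 0.75 (two reduced-function alleles
are assumed jointly more deleterious than one null plus one functional
allele). Refined labels inherit their generic class's axis position, so
the ROC ordering always has exactly seven levels.

## Phenotype schemes

The five groupings are data (declarative tables, YAML-serializable), not
code branches, because the binning choice is itself the experimental
variable under study. `Codeine` keeps everything from `EM/EM` down to
`IM/IM` as EM; `TAM1` collapses the broad middle into IM; `TAM2` re-bins
`EM/IM` as EM and `IM/PM` as PM; `TAM3` adds the `*10` downgrade; `TAM4`
extends it with a *slow metabolizer* (SM) class between IM and PM for
`*10`-containing low-activity diplotypes. Phenotype labels carry fixed
ordinals (UM=4 … PM=0) for use as ordered factors. A consistency checker
verifies totality, label membership and monotonicity (the phenotype
ordinal never increases as diplotype activity decreases, activities taken
in the scheme's own scoring dialect).

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes; it
is explicitly not a pharmacokinetic model.

**Diplotypes** are drawn either from class frequencies (default: the
pooled study composition, N = 898, with the `*10` sub-classes nested in
their parents) with one fixed representative allele pair per class, or
from per-allele frequencies under Hardy–Weinberg random pairing (used for
the `*10`-rich East-Asian-like preset). Covariate genotypes (CYP2C9
`*1/*2/*3`, CYP3A5 `*1/*3`) are sampled under Hardy–Weinberg at
default allele frequencies of 0.81/0.12/0.07 and 0.25/0.75.

**Concentrations** are log-normal, simulated in nM and stored in ng/mL
(molar masses: TAM 371.51, DMT 357.49, 4OH-TAM 387.51, (Z)-endoxifen
373.53 g/mol — standard chemical reference values):

* TAM: median 350 nM, log-SD 0.35 (so ~1% fall under the 150 nM
  compliance threshold and are removed by the filter);
* DMT = TAM × ratio (median 1.5, log-SD 0.20) × CYP3A5 multiplier
  (0.88 for `*3/*3` on DMT/TAM, square root of that for heterozygotes);
* 4OH-TAM = TAM × ratio (median 0.015, log-SD 0.20) × CYP2C9 multiplier
  (0.74 for variant homozygotes on 4OH-TAM/TAM);
* E = DMT × r, with log r Gaussian around a per-diplotype-class location
  and common SD σ.

The class locations are linear in a generative activity axis (the ROC
axis with the `*10`-refined classes additionally downgraded: `EM/*10`
1.25, `*10/*10` 0.5, `PM/*10` 0.25 — so `*10` carries a real extra
penalty for the schemes to find), except PM/PM, whose location is pinned
separately. The free parameters (intercept, slope, σ, PM/PM location) are
solved by least squares against four targets, all stated as study
conditions:

1. fraction of log E/DMT variance attributable to diplotype class = 0.75
   (middle of the reported 68–82% range);
2. fraction of log E variance attributable to diplotype class = 0.50
   (middle of the reported 39–58% range);
3. overall P(E ≥ 5.9 ng/mL) = 0.823;
4. P(E < 5.9 ng/mL | PM/PM) = 0.90.

Variance fractions are computed in the classical (OLS) sense,
between-class variance over total; the threshold probabilities are exact
normal-mixture expressions (the CYP3A5 multiplier enters as a discrete
mixture). The solver residual is required to be < 1e-6 and the resulting
class medians monotone in activity, otherwise calibration errors out.
Making σ a solved quantity makes the variance-explained calibration
analytic and monotone, which is what the parameter-recovery tests exploit.

**What the generator does not emulate.** Within-class outlier structure
beyond log-normality (the real data show gross outliers dispersed over
AS ≥ 1); CYP2D6-inhibitor co-medication; hybrid alleles and regulatory
variation; any time-course. One measurable consequence: calibrated only
to the aggregate targets above, the population Youden optimum of the
genotype test falls at activity cutoff 0.75–1.0 (J ≈ 0.52) rather than at
0.5 (J ≈ 0.42) — the real cohort separates more sharply at low activity
than a log-linear activity model does. Tests therefore check the
operating characteristics at the published 0.5 cutoff (sensitivity ≥ 0.90)
and constrain the selected cutoff to the middle of the activity range,
rather than asserting that 0.5 is selected. Passing tests show the
pipeline recovers what the generator encodes; they do not certify the
generator as a surrogate for patient data.

## Robust association

Endpoints are log-transformed (E in ng/mL; E/DMT dimensionless). The log
is a documented default — concentration data are strictly positive and
right-skewed — and is exposed as configuration; it is a choice, not a
claim about any particular prior transformation.

The estimator is an M-type IRLS fit with the redescending Tukey bisquare
weight function at c = 4.685 (~95% Gaussian efficiency), MAD residual
scale, OLS starting values (statsmodels `RLM` underneath). Responses with
vanishing residual scale (exactly collinear data) fall back to OLS with
unit weights, which keeps the exact-fit R² = 1 case well defined.

The **robust adjusted R²** is the weighted coefficient of determination
under the fit's final robustness weights,
`1 − Σw e² / Σw (y − ȳ_w)²`, with the classical `(n−1)/(n−p−1)`
adjustment. It reduces exactly to the classical adjusted R² at unit
weights. Because the bisquare weights downweight the residual tails, this
estimator reads ≈ 0.03 above the classical variance-explained fraction on
clean Gaussian data; that bias is inherent to weighted R² definitions and
is well inside the ±0.05 recovery tolerance used in testing. Uncertainty
comes from case-resampling bootstrap (default 10,000 replicates,
percentile 95% intervals, single seeded stream; replicates that fail to
fit are dropped and counted, > 10% failures is an error). Both the point
estimate and the bootstrap median are reported, since either reading of a
"bootstrap R²" is defensible.

**Model comparison** between one- and two-assignment models is a robust
Wald-type F-test: the larger model is fit robustly and the joint nullity
of the added assignment's coefficients is tested against their estimated
covariance (which carries the standard M-estimation correction). Two
phenotype assignments of the same diplotypes are necessarily partly
collinear; aliased columns are dropped (as linear-model software does)
and the numerator df is the gain in design rank. A fixed-weight nested-F
variant was measured anticonservative under the null (rejection ~0.09–0.10
at nominal 0.05) and rejected in favour of the Wald form (measured
0.045–0.065 across n = 120–400).

**Covariate screen**: two-sided Wilcoxon–Mann–Whitney contrasts of
DMT/TAM by CYP3A5 (`*3/*3` vs `*1/*1`) and 4OH-TAM/TAM by CYP2C9 (variant
homozygotes vs `*1/*1`), reporting the median percent reduction. The
recovery test runs at n = 3000 so the small `*1/*1` reference groups give
stable medians.

## Threshold classification

Positive class: E ≥ 5.9 ng/mL ("at or above" is the documented, and
configurable, boundary convention). Test-positive: diplotype activity
strictly above a cutoff; candidates are the seven activity levels plus
the trivial all-positive endpoint. The operating cutoff maximizes
Youden's J = sensitivity + specificity − 1, ties broken toward the more
specific cutoff; selection is verified against exhaustive search.
FDR = FP/(FP+TP), the fraction of test-positive patients who do not reach
the threshold, with the closed-form identity from (sensitivity,
specificity, prevalence) used as a cross-check.

Confidence intervals use a stratified case-resampling bootstrap
(resampling within the positive and negative strata). Since the metrics
depend on a resample only through the per-stratum test-positive counts,
the resample distribution is generated exactly via binomial draws of
those sufficient counts — distributionally identical to index resampling
and fully vectorized, which is what makes the 500-cohort coverage test
cheap. Maximizing specificity instead of J is exposed only as an
alternative-selection stub and is not validated.

## Pipeline and reproducibility

One root seed fans out via named `SeedSequence` substreams (cohort,
bootstrap-R², bootstrap-ROC); every artifact records a hash of the
scientifically relevant configuration (output path and log level are
excluded). Identical configuration and seed give byte-identical JSON
results. Cohort CSVs are read with row-level diplotype validation; rows
with unresolvable diplotypes are excluded and counted, and the ledger
rows-in = records-used + rejected is asserted.

## Problem sizes used in testing

Unit and property tests run at n ≤ 1,000; parameter recovery uses 20
cohorts of n = 900 with a 500-replicate bootstrap spot-check; the
covariate screen uses one cohort of n = 3,000; bootstrap coverage uses
500 cohorts of n = 900 with 500 replicates each (feasible because the
classifier bootstrap is vectorized). Analysis scripts default to 500
bootstrap replicates except the final classification step, which uses the
full 10,000.
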