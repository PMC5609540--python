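"""CYP2D6 star alleles, diplotypes and activity scores.

The CYP2D6 gene is highly polymorphic; named haplotypes ("star alleles")
carry characterized functional consequences.  This module covers the closed
allele panel used throughout the package:

* null / poor-metabolizer (PM) alleles: *3, *4, *5, *6, *7  (activity 0)
* reduced-function / intermediate (IM) alleles: *9, *10, *41  (activity 0.5)
* fully functional / extensive (EM) alleles: *1, *2, *35, or the
  "no variant detected" sentinel  (activity 1; 2 when duplicated)

Two activity-score dialects are supported: the ``standard`` per-allele
system (0 / 0.5 / 1 / 2) and the ``star10_downgrade`` dialect in which *10,
whose product is less stable than that of the other reduced-function
alleles, contributes 0.25 instead of 0.5.

Diplotypes are labelled by the functional classes of their two alleles
(EM/PM, IM/IM, ...).  Diplotypes carrying a *10 allele additionally receive
one of the refined labels EM/*10, *10/*10 or PM/*10, which are strict
subsets of their generic class; phenotype schemes that ignore the *10
refinement simply read the generic label.

For ROC analysis the seven generic categories are placed on a numeric
activity axis that coincides with the standard activity score except that
the two score-1 categories are separated (EM/PM at 1, IM/IM at 0.75).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional

__all__ = [
    "StarAllele",
    "Diplotype",
    "UnsupportedAlleleError",
    "UnsupportedDiplotypeError",
    "NO_VARIANT",
    "PM_ALLELES",
    "IM_ALLELES",
    "EM_ALLELES",
    "SUPPORTED_ALLELES",
    "GENERIC_CATEGORIES",
    "REFINED_CATEGORIES",
    "ROC_ACTIVITY",
    "ROC_RANK",
    "classify_allele",
    "diplotype_category",
    "diplotype_activity_score",
    "roc_rank",
    "parse_diplotype",
    "REPRESENTATIVE_PAIRS",
]


class UnsupportedAlleleError(ValueError):
    """Raised for star alleles outside the supported panel."""


class UnsupportedDiplotypeError(ValueError):
    """Raised for allele pairs with no defined diplotype category."""


#: Sentinel for assays that infer EM status from the absence of variant alleles.
NO_VARIANT = "no_variant"

PM_ALLELES = frozenset({"*3", "*4", "*5", "*6", "*7"})
IM_ALLELES = frozenset({"*9", "*10", "*41"})
EM_ALLELES = frozenset({"*1", "*2", "*35"})
SUPPORTED_ALLELES = PM_ALLELES | IM_ALLELES | EM_ALLELES | {NO_VARIANT}

_ALLELE_RE = re.compile(r"^\*\d+[A-Za-z]?$")

#: Per-allele activity values of the standard dialect, keyed by class.
_CLASS_ACTIVITY = {"PM": 0.0, "IM": 0.5, "EM": 1.0}

GENERIC_CATEGORIES = (
    "EM/UM", "EM/EM", "EM/IM", "EM/PM", "IM/IM", "IM/PM", "PM/PM",
)
REFINED_CATEGORIES = ("EM/*10", "*10/*10", "PM/*10")

#: Numeric activity used for ROC cutoffs: identical to the standard AS
#: except that EM/PM (1) and IM/IM (0.75) are separated.
ROC_ACTIVITY = {
    "EM/UM": 3.0,
    "EM/EM": 2.0,
    "EM/IM": 1.5,
    "EM/PM": 1.0,
    "IM/IM": 0.75,
    "IM/PM": 0.5,
    "PM/PM": 0.0,
}

#: Ordinal rank 7 (highest activity) .. 1 (lowest).
ROC_RANK = {c: 7 - i for i, c in enumerate(GENERIC_CATEGORIES)}


@dataclass(frozen=True)
class StarAllele:
    """A named CYP2D6 haplotype with its functional class.

    ``duplicated`` records a gene duplication carried on this haplotype.
    Only a duplicated fully-functional (EM) allele drives ultra-rapid
    metabolizer status; duplications of variant alleles are scored as the
    un-duplicated variant.
    """

    name: str
    functional_class: str  # "PM" | "IM" | "EM"
    duplicated: bool = False

    @property
    def um_driving(self) -> bool:
        return self.duplicated and self.functional_class == "EM"

    @property
    def is_star10(self) -> bool:
        return self.name == "*10"

    def activity(self, scheme: str = "standard") -> float:
        """Per-allele activity value under the given dialect."""
        if scheme not in ("standard", "star10_downgrade"):
            raise ValueError(f"unknown activity-score scheme: {scheme!r}")
        if scheme == "star10_downgrade" and self.is_star10:
            return 0.25
        if self.um_driving:
            return 2.0
        return _CLASS_ACTIVITY[self.functional_class]


def classify_allele(
    name: str,
    duplicated: bool = False,
    any_variant_detected: bool = True,
) -> StarAllele:
    """Classify a star allele into its functional class.

    ``any_variant_detected=False`` together with the :data:`NO_VARIANT`
    sentinel represents platforms that call EM by the absence of variant
    alleles.  Unrecognized alleles raise :class:`UnsupportedAlleleError`
    rather than being silently treated as functional.
    """
    if name == NO_VARIANT:
        return StarAllele(NO_VARIANT, "EM", duplicated)
    if not _ALLELE_RE.match(name):
        raise UnsupportedAlleleError(f"malformed star allele name: {name!r}")
    if name in PM_ALLELES:
        cls = "PM"
    elif name in IM_ALLELES:
        cls = "IM"
    elif name in EM_ALLELES:
        cls = "EM"
    else:
        raise UnsupportedAlleleError(
            f"unsupported allele {name}: outside the supported panel "
            f"(PM: {sorted(PM_ALLELES)}, IM: {sorted(IM_ALLELES)}, "
            f"EM: {sorted(EM_ALLELES)})"
        )
    return StarAllele(name, cls, duplicated)


def _generic_category(a: StarAllele, b: StarAllele) -> str:
    if a.um_driving and b.um_driving:
        raise UnsupportedDiplotypeError(
            "two duplicated fully-functional alleles: diplotype outside the "
            "supported categories"
        )
    # UM requires a duplicated EM allele and no variant allele on the
    # partner chromosome.
    if (a.um_driving or b.um_driving) and {a.functional_class, b.functional_class} == {"EM"}:
        return "EM/UM"
    order = {"EM": 0, "IM": 1, "PM": 2}
    hi, lo = sorted((a.functional_class, b.functional_class), key=order.get)
    return f"{hi}/{lo}"


def _refinement(a: StarAllele, b: StarAllele, generic: str) -> Optional[str]:
    n10 = a.is_star10 + b.is_star10
    if n10 == 2:
        return "*10/*10"
    if n10 == 1:
        other = b if a.is_star10 else a
        if generic == "EM/IM" and other.functional_class == "EM":
            return "EM/*10"
        if generic == "IM/PM" and other.functional_class == "PM":
            return "PM/*10"
    return None


@dataclass(frozen=True)
class Diplotype:
    """An unordered pair of classified CYP2D6 star alleles."""

    allele_a: StarAllele
    allele_b: StarAllele

    @property
    def category(self) -> str:
        """Generic category label (one of the seven Table rows)."""
        return _generic_category(self.allele_a, self.allele_b)

    @property
    def refinement(self) -> Optional[str]:
        """*10-specific refined label, when exactly applicable."""
        return _refinement(self.allele_a, self.allele_b, self.category)

    @property
    def label(self) -> str:
        """Refined label when present, else the generic category."""
        return self.refinement or self.category

    def activity_score(self, scheme: str = "standard") -> float:
        """Summed per-allele activity under the requested dialect.

        The duplication bonus (EM allele scored 2) is credited only when
        the diplotype is EM/UM: a duplication in the presence of a variant
        allele does not confer ultra-rapid status and is scored as the
        un-duplicated allele.
        """
        cat = self.category  # validates the pair
        credit_dup = cat == "EM/UM"

        def value(al: StarAllele) -> float:
            if scheme == "star10_downgrade" and al.is_star10:
                return 0.25
            if scheme not in ("standard", "star10_downgrade"):
                raise ValueError(f"unknown activity-score scheme: {scheme!r}")
            if credit_dup and al.um_driving:
                return 2.0
            return _CLASS_ACTIVITY[al.functional_class]

        return value(self.allele_a) + value(self.allele_b)

    @property
    def roc_activity(self) -> float:
        return ROC_ACTIVITY[self.category]

    @property
    def roc_rank(self) -> int:
        return ROC_RANK[self.category]

    def __str__(self) -> str:
        def fmt(al: StarAllele) -> str:
            return al.name + ("x2" if al.duplicated else "")
        return f"{fmt(self.allele_a)}/{fmt(self.allele_b)}"


def diplotype_category(a: StarAllele, b: StarAllele) -> str:
    """Category label for an allele pair; symmetric in its arguments."""
    return Diplotype(a, b).label


def diplotype_activity_score(d: Diplotype, scheme: str = "standard") -> float:
    return d.activity_score(scheme)


def roc_rank(d: Diplotype) -> tuple[int, float]:
    """(ordinal rank, numeric ROC activity) of a diplotype.

    *10-refined categories inherit their generic class's rank: the ROC
    ordering has exactly seven levels.
    """
    return d.roc_rank, d.roc_activity


_DUP_RE = re.compile(r"^(?P<name>[^x]+?)(?:x(?P<copies>\d+))?$")


def parse_allele(token: str, no_variant_sentinel: str = NO_VARIANT) -> StarAllele:
    """Parse one allele token, e.g. ``"*4"`` or ``"*1x2"``."""
    token = token.strip()
    m = _DUP_RE.match(token)
    if not m:
        raise UnsupportedAlleleError(f"malformed allele token: {token!r}")
    name = m.group("name")
    duplicated = m.group("copies") is not None and int(m.group("copies")) >= 2
    if name == no_variant_sentinel:
        name = NO_VARIANT
    return classify_allele(name, duplicated=duplicated)


def parse_diplotype(text: str, no_variant_sentinel: str = NO_VARIANT) -> Diplotype:
    """Parse ``"A/B"`` diplotype text with optional ``xN`` duplication suffix.

    Examples: ``"*1/*4"`` → EM/PM; ``"*1/*1x2"`` → EM/UM.
    """
    parts = text.strip().split("/")
    if len(parts) != 2:
        raise UnsupportedDiplotypeError(
            f"diplotype text must be 'A/B': {text!r}"
        )
    a = parse_allele(parts[0], no_variant_sentinel)
    b = parse_allele(parts[1], no_variant_sentinel)
    d = Diplotype(a, b)
    d.category  # force validation of the pair
    return d


#: One representative allele pair per supported diplotype label.
REPRESENTATIVE_PAIRS = {
    "EM/UM": "*1/*1x2",
    "EM/EM": "*1/*1",
    "EM/IM": "*1/*41",
    "EM/*10": "*1/*10",
    "EM/PM": "*1/*4",
    "IM/IM": "*41/*41",
    "*10/*10": "*10/*10",
    "IM/PM": "*41/*4",
    "PM/*10": "*4/*10",
    "PM/PM": "*4/*4",
}
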