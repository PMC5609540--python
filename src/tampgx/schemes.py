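"""Diplotype-to-metabolizer-phenotype assignment schemes.

Five published/proposed groupings of CYP2D6 diplotypes into metabolizer
phenotypes are shipped as declarative tables:

* ``Codeine`` — the codeine-metabolism CPIC-style grouping (IM/IM and
  EM/PM still count as EM);
* ``TAM1``   — the assignment used in early tamoxifen intervention trials
  (everything between EM/EM and IM/PM is IM);
* ``TAM2``   — tamoxifen-specific regrouping binning EM/IM into EM and
  IM/PM into PM;
* ``TAM3``   — like a *10-aware TAM-specific grouping: the *10 allele is
  downgraded (activity 0.25) and *10-refined categories re-binned;
* ``TAM4``   — extends the *10 downgrade with a new slow-metabolizer (SM)
  class between IM and PM for *10-containing low-activity diplotypes.

Schemes are data, not code branches: the binning choice is an experimental
variable, and users can register further tables (also via YAML).  Phenotype
labels carry a fixed ordinal (UM=4 … PM=0) for use as an ordered regression
factor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Union

import yaml

from .star_alleles import (
    Diplotype,
    GENERIC_CATEGORIES,
    REFINED_CATEGORIES,
    ROC_ACTIVITY,
)

__all__ = [
    "SchemeTable",
    "PHENOTYPES",
    "PHENOTYPE_ORDINAL",
    "BUILTIN_SCHEMES",
    "SCHEME_NAMES",
    "get_scheme",
    "assign_phenotype",
    "scheme_consistency_check",
    "scheme_to_yaml",
    "scheme_from_yaml",
]

PHENOTYPES = ("UM", "EM", "IM", "SM", "PM")
PHENOTYPE_ORDINAL = {"UM": 4, "EM": 3, "IM": 2, "SM": 1, "PM": 0}


@dataclass(frozen=True)
class SchemeTable:
    """A named diplotype-category → phenotype mapping.

    ``mapping`` must be total over the seven generic categories; schemes
    with ``uses_star10_refinement`` may additionally map the refined
    labels EM/*10, *10/*10 and PM/*10, which are consulted first.
    """

    name: str
    mapping: Dict[str, str]
    uses_star10_refinement: bool = False

    def assign(self, d: Union[Diplotype, str]) -> str:
        """Phenotype label for a diplotype (or a category label)."""
        if isinstance(d, Diplotype):
            generic, refined = d.category, d.refinement
        else:
            generic, refined = d, d if d in REFINED_CATEGORIES else None
            if refined is not None:
                generic = _PARENT[refined]
        if self.uses_star10_refinement and refined in self.mapping:
            return self.mapping[refined]
        return self.mapping[generic]

    def ordinal(self, d: Union[Diplotype, str]) -> int:
        return PHENOTYPE_ORDINAL[self.assign(d)]


_PARENT = {"EM/*10": "EM/IM", "*10/*10": "IM/IM", "PM/*10": "IM/PM"}

BUILTIN_SCHEMES: Dict[str, SchemeTable] = {
    "Codeine": SchemeTable(
        "Codeine",
        {
            "EM/UM": "UM",
            "EM/EM": "EM",
            "EM/IM": "EM",
            "EM/PM": "EM",
            "IM/IM": "EM",
            "IM/PM": "IM",
            "PM/PM": "PM",
        },
    ),
    "TAM1": SchemeTable(
        "TAM1",
        {
            "EM/UM": "UM",
            "EM/EM": "EM",
            "EM/IM": "IM",
            "EM/PM": "IM",
            "IM/IM": "IM",
            "IM/PM": "IM",
            "PM/PM": "PM",
        },
    ),
    "TAM2": SchemeTable(
        "TAM2",
        {
            "EM/UM": "UM",
            "EM/EM": "EM",
            "EM/IM": "EM",
            "EM/PM": "IM",
            "IM/IM": "IM",
            "IM/PM": "PM",
            "PM/PM": "PM",
        },
    ),
    "TAM3": SchemeTable(
        "TAM3",
        {
            "EM/UM": "UM",
            "EM/EM": "EM",
            "EM/IM": "EM",
            "EM/*10": "IM",
            "EM/PM": "IM",
            "IM/IM": "IM",
            "*10/*10": "IM",
            "IM/PM": "IM",
            "PM/*10": "PM",
            "PM/PM": "PM",
        },
        uses_star10_refinement=True,
    ),
    "TAM4": SchemeTable(
        "TAM4",
        {
            "EM/UM": "UM",
            "EM/EM": "EM",
            "EM/IM": "EM",
            "EM/*10": "EM",
            "EM/PM": "IM",
            "IM/IM": "IM",
            "*10/*10": "SM",
            "IM/PM": "SM",
            "PM/*10": "SM",
            "PM/PM": "PM",
        },
        uses_star10_refinement=True,
    ),
}

SCHEME_NAMES = tuple(BUILTIN_SCHEMES)


def get_scheme(name: str) -> SchemeTable:
    try:
        return BUILTIN_SCHEMES[name]
    except KeyError:
        raise KeyError(
            f"unknown scheme {name!r}; built-in schemes: {list(BUILTIN_SCHEMES)}"
        ) from None


def assign_phenotype(d: Union[Diplotype, str], scheme: Union[SchemeTable, str]) -> str:
    """Assign the metabolizer phenotype of ``d`` under ``scheme``."""
    if isinstance(scheme, str):
        scheme = get_scheme(scheme)
    return scheme.assign(d)


def _scheme_activity(label: str, downgrade: bool) -> float:
    """Activity used for ordering categories within a scheme's dialect."""
    base = {
        "EM/UM": 3.0, "EM/EM": 2.0, "EM/IM": 1.5, "EM/PM": 1.0,
        "IM/IM": 1.0, "IM/PM": 0.5, "PM/PM": 0.0,
        "EM/*10": 1.25 if downgrade else 1.5,
        "*10/*10": 0.5 if downgrade else 1.0,
        "PM/*10": 0.25 if downgrade else 0.5,
    }
    return base[label]


def scheme_consistency_check(scheme: SchemeTable) -> dict:
    """Validate a scheme table; returns a report, never raises silently.

    Checks totality over the generic categories, phenotype-set membership,
    the SM-only-in-*10-aware-schemes convention, and monotonicity: the
    phenotype ordinal must never increase as diplotype activity decreases.
    """
    violations: List[str] = []
    for cat in GENERIC_CATEGORIES:
        if cat not in scheme.mapping:
            violations.append(f"missing generic category {cat}")
    for cat, label in scheme.mapping.items():
        if cat not in GENERIC_CATEGORIES and cat not in REFINED_CATEGORIES:
            violations.append(f"unknown category {cat}")
        if label not in PHENOTYPES:
            violations.append(f"unknown phenotype label {label} for {cat}")
    if not violations:
        # order categories by activity (scheme's own dialect), ties broken
        # by the ROC convention (EM/PM above IM/IM); ordinals must be
        # non-increasing along decreasing activity
        cats = [c for c in scheme.mapping]
        cats.sort(
            key=lambda c: (
                _scheme_activity(c, scheme.uses_star10_refinement),
                ROC_ACTIVITY[_PARENT.get(c, c)],
            ),
            reverse=True,
        )
        ordinals = [PHENOTYPE_ORDINAL[scheme.mapping[c]] for c in cats]
        for (c1, o1), (c2, o2) in zip(zip(cats, ordinals), zip(cats[1:], ordinals[1:])):
            if o2 > o1:
                violations.append(
                    f"monotonicity violation: {c2} ({scheme.mapping[c2]}) above "
                    f"{c1} ({scheme.mapping[c1]}) despite lower activity"
                )
    return {"scheme": scheme.name, "ok": not violations, "violations": violations}


def scheme_to_yaml(scheme: SchemeTable) -> str:
    return yaml.safe_dump(
        {
            "name": scheme.name,
            "mapping": dict(scheme.mapping),
            "uses_star10_refinement": scheme.uses_star10_refinement,
        },
        sort_keys=False,
    )


def scheme_from_yaml(text: str) -> SchemeTable:
    data = yaml.safe_load(text)
    return SchemeTable(
        name=data["name"],
        mapping=dict(data["mapping"]),
        uses_star10_refinement=bool(data.get("uses_star10_refinement", False)),
    )
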