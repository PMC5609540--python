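"""Analysis endpoints, unit conversions and cohort frequency tables.

The two endpoints of the association analysis are the plasma (Z)-endoxifen
concentration E (ng/mL) and the CYP2D6-specific metabolic ratio E/DMT
(endoxifen over its immediate precursor N-desmethyl-tamoxifen).  Both are
right-skewed and strictly positive; the default variance-stabilizing
transformation is the natural log (exposed as config so sensitivity to the
choice can be tested).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .star_alleles import Diplotype, GENERIC_CATEGORIES, REFINED_CATEGORIES

__all__ = [
    "MOLAR_MASS",
    "EndpointVector",
    "metabolic_ratio",
    "ngml_to_nmol",
    "nmol_to_ngml",
    "transform_endpoint",
    "frequency_table",
    "round_half_up",
]

#: Molar masses in g/mol (standard chemical reference values).
MOLAR_MASS = {
    "TAM": 371.51,       # tamoxifen
    "DMT": 357.49,       # N-desmethyl-tamoxifen
    "4OHTAM": 387.51,    # (Z)-4-hydroxy-tamoxifen
    "E": 373.53,         # (Z)-endoxifen
}


def ngml_to_nmol(conc: Union[float, np.ndarray], molar_mass: float):
    """Convert ng/mL to nmol/L (nM)."""
    if molar_mass <= 0:
        raise ValueError(f"molar mass must be positive, got {molar_mass}")
    return np.asarray(conc, dtype=float) * 1000.0 / molar_mass if np.ndim(conc) else conc * 1000.0 / molar_mass


def nmol_to_ngml(conc: Union[float, np.ndarray], molar_mass: float):
    """Convert nmol/L (nM) to ng/mL."""
    if molar_mass <= 0:
        raise ValueError(f"molar mass must be positive, got {molar_mass}")
    return np.asarray(conc, dtype=float) * molar_mass / 1000.0 if np.ndim(conc) else conc * molar_mass / 1000.0


def metabolic_ratio(e, dmt):
    """E/DMT metabolic ratio; both concentrations in the same unit."""
    e = np.asarray(e, dtype=float)
    dmt = np.asarray(dmt, dtype=float)
    if np.any(dmt <= 0):
        raise ValueError("metabolic ratio undefined: DMT must be > 0")
    out = e / dmt
    return float(out) if out.ndim == 0 else out


@dataclass
class EndpointVector:
    """Raw and transformed values of one analysis endpoint."""

    name: str                 # "E" or "E_over_DMT"
    raw: np.ndarray
    transformed: np.ndarray
    transformation: str       # "log" or "none"


def transform_endpoint(values: Sequence[float], method: str = "log", name: str = "E") -> EndpointVector:
    """Apply the variance-stabilizing transformation element-wise.

    ``method="log"`` requires strictly positive values; offending indices
    are listed in the error.
    """
    raw = np.asarray(values, dtype=float)
    if method == "log":
        bad = np.flatnonzero(~(raw > 0))
        if bad.size:
            raise ValueError(
                f"log transform undefined for non-positive values at "
                f"indices {bad.tolist()[:20]}"
            )
        transformed = np.log(raw)
    elif method == "none":
        transformed = raw.copy()
    else:
        raise ValueError(f"unknown transformation {method!r}")
    return EndpointVector(name=name, raw=raw, transformed=transformed, transformation=method)


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal half-up rounding (table formatting convention)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


_TABLE_ORDER = [
    "EM/UM", "EM/EM", "EM/IM", "EM/*10", "EM/PM",
    "IM/IM", "*10/*10", "IM/PM", "PM/*10", "PM/PM",
]


def frequency_table(
    records: Union[pd.DataFrame, Iterable[Diplotype]],
    total: Optional[int] = None,
) -> pd.DataFrame:
    """Diplotype category counts and percentages, one row per label.

    The seven generic categories are mutually exclusive and sum to N; the
    three *10-refined labels are nested subsets of their parent class and
    are reported as extra rows.  Percentages are relative to the total N,
    half-up at one decimal.

    ``records`` is either an iterable of :class:`Diplotype` or a DataFrame
    with ``category`` and ``refinement`` columns.
    """
    if isinstance(records, pd.DataFrame):
        cats = records["category"]
        refs = records["refinement"] if "refinement" in records else pd.Series([None] * len(records))
    else:
        records = list(records)
        cats = pd.Series([d.category for d in records], dtype=object)
        refs = pd.Series([d.refinement for d in records], dtype=object)
    n = total if total is not None else len(cats)
    rows = []
    for label in _TABLE_ORDER:
        if label in GENERIC_CATEGORIES:
            count = int((cats == label).sum())
            nested = False
        else:
            count = int((refs == label).sum())
            nested = True
        if n == 0:
            pct = 0.0
        else:
            pct = round_half_up(100.0 * count / n, 1)
        rows.append({"category": label, "nested": nested, "n": count, "percent": pct})
    table = pd.DataFrame(rows)
    if len(cats) == 0:
        return table.iloc[0:0]
    return table
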