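"""Compound registry: the 13 cabbage glucosinolates plus the internal standard.

Cabbage glucosinolate profiles are conventionally described by 13 compounds
falling into four structural classes — aliphatic 3-carbon (homo-methionine
derived), aliphatic 4-carbon (dihomo-methionine derived), indolyl
(tryptophan derived) and aromatic (phenylalanine derived) — quantified
against a glucotropaeolin (GTP) internal standard, which is itself an
aromatic glucosinolate absent from cabbage tissue.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable

import pandas as pd


class GSLClass(str, Enum):
    """Structural class of a glucosinolate side chain."""

    ALIPHATIC_3C = "ALIPHATIC_3C"
    ALIPHATIC_4C = "ALIPHATIC_4C"
    INDOLYL = "INDOLYL"
    AROMATIC = "AROMATIC"


@dataclass(frozen=True)
class CompoundDef:
    """One glucosinolate. Identity is the abbreviation; names are metadata."""

    abbreviation: str
    common_name: str
    side_chain_name: str
    gsl_class: GSLClass
    is_internal_standard: bool = False


# Side chain, common name, abbreviation, class; GTP flagged as the IS.
_REGISTRY_ROWS = [
    ("3-methylthiopropyl", "Glucoiberverin", "GBN", GSLClass.ALIPHATIC_3C, False),
    ("3-methylsulfinylpropyl", "Glucoiberin", "GIB", GSLClass.ALIPHATIC_3C, False),
    ("2-propenyl", "Sinigrin", "SIN", GSLClass.ALIPHATIC_3C, False),
    ("2(R)-hydroxy-3-butenyl", "Progoitrin", "PRO", GSLClass.ALIPHATIC_4C, False),
    ("2(S)-hydroxy-3-butenyl", "Epiprogoitrin", "EPRO", GSLClass.ALIPHATIC_4C, False),
    ("3-butenyl", "Gluconapin", "GNP", GSLClass.ALIPHATIC_4C, False),
    ("4-methylsulfinylbutyl", "Glucoraphanin", "GRA", GSLClass.ALIPHATIC_4C, False),
    ("4-methylthiobutyl", "Glucoerucin", "GER", GSLClass.ALIPHATIC_4C, False),
    ("indol-3-ylmethyl", "Glucobrassicin", "GBS", GSLClass.INDOLYL, False),
    ("4-methoxyindol-3-ylmethyl", "4-Methoxyglucobrassicin", "MGBS", GSLClass.INDOLYL, False),
    ("4-hydroxyindol-3-ylmethyl", "4-Hydroxyglucobrassicin", "HGBS", GSLClass.INDOLYL, False),
    ("N-methoxyindol-3-ylmethyl", "Neoglucobrassicin", "NGBS", GSLClass.INDOLYL, False),
    ("2-phenylethyl", "Gluconasturtiin", "GNS", GSLClass.AROMATIC, False),
    ("benzyl", "Glucotropaeolin", "GTP", GSLClass.AROMATIC, True),
]


def build_registry() -> list[CompoundDef]:
    """Return the standard cabbage registry: 13 analytes + GTP internal standard."""
    return [
        CompoundDef(abbr, common, side, cls, is_is)
        for side, common, abbr, cls, is_is in _REGISTRY_ROWS
    ]


def validate_registry(compounds: Iterable[CompoundDef]) -> list[CompoundDef]:
    """Check registry invariants; returns the registry as a list.

    Raises ``ValueError`` on duplicate abbreviations, a missing/duplicated
    internal standard, or a non-aromatic internal standard.
    """
    comps = list(compounds)
    abbrs = [c.abbreviation for c in comps]
    if len(set(abbrs)) != len(abbrs):
        dupes = sorted({a for a in abbrs if abbrs.count(a) > 1})
        raise ValueError(f"duplicate compound abbreviations: {dupes}")
    standards = [c for c in comps if c.is_internal_standard]
    if len(standards) != 1:
        raise ValueError(f"registry must flag exactly one internal standard, got {len(standards)}")
    if standards[0].gsl_class is not GSLClass.AROMATIC:
        raise ValueError("internal standard must be an aromatic glucosinolate")
    return comps


def analytes(compounds: Iterable[CompoundDef] | None = None) -> list[CompoundDef]:
    """The quantified compounds, i.e. the registry minus the internal standard."""
    comps = build_registry() if compounds is None else list(compounds)
    return [c for c in comps if not c.is_internal_standard]


def internal_standard(compounds: Iterable[CompoundDef] | None = None) -> CompoundDef:
    comps = build_registry() if compounds is None else list(compounds)
    (is_,) = [c for c in comps if c.is_internal_standard]
    return is_


def class_of(abbreviation: str, compounds: Iterable[CompoundDef] | None = None) -> GSLClass:
    comps = build_registry() if compounds is None else list(compounds)
    for c in comps:
        if c.abbreviation == abbreviation:
            return c.gsl_class
    raise KeyError(f"unknown compound abbreviation: {abbreviation}")


def registry_frame(compounds: Iterable[CompoundDef] | None = None) -> pd.DataFrame:
    """Registry as a DataFrame matching the compounds.csv interchange layout."""
    comps = build_registry() if compounds is None else list(compounds)
    return pd.DataFrame(
        {
            "abbreviation": [c.abbreviation for c in comps],
            "common_name": [c.common_name for c in comps],
            "side_chain": [c.side_chain_name for c in comps],
            "class": [c.gsl_class.value for c in comps],
            "is_internal_standard": [c.is_internal_standard for c in comps],
        }
    )


def registry_from_frame(df: pd.DataFrame) -> list[CompoundDef]:
    """Parse a compounds.csv-shaped DataFrame into a validated registry."""
    comps = [
        CompoundDef(
            abbreviation=str(r["abbreviation"]),
            common_name=str(r["common_name"]),
            side_chain_name=str(r["side_chain"]),
            gsl_class=GSLClass(r["class"]),
            is_internal_standard=bool(r["is_internal_standard"]),
        )
        for _, r in df.iterrows()
    ]
    return validate_registry(comps)
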