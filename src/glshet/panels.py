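"""Replicate-level panels and genotype-level summaries.

Concentrations are stored long-form (genotype, replicate, compound,
µmol g⁻¹ dry weight); agronomic traits use the same layout with trait codes
instead of compounds. Non-detection is an exact 0.0 — a biological zero, not
missing data; a truly lost sample is simply an absent record.
"""

from __future__ import annotations

from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from .registry import CompoundDef, GSLClass, analytes

TRAIT_CODES = ("HW", "HD", "HH", "ICL", "HC")

CONC_COLUMNS = ("genotype_id", "replicate", "compound", "umol_per_g_dw")
TRAIT_COLUMNS = ("genotype_id", "replicate", "trait", "value")


class GenotypeMeans(NamedTuple):
    """Genotype × variable means with matching per-cell standard errors."""

    mean: pd.DataFrame
    se: pd.DataFrame


def validate_concentration_panel(
    panel: pd.DataFrame, compounds: Iterable[CompoundDef] | None = None
) -> pd.DataFrame:
    """Validate a long-form concentration panel and return it unchanged.

    Checks: required columns, non-negative concentrations, 3 or 4 replicates
    per genotype with an identical replicate set for every compound.
    """
    missing = set(CONC_COLUMNS) - set(panel.columns)
    if missing:
        raise ValueError(f"concentration panel missing columns: {sorted(missing)}")
    if panel.empty:
        return panel
    if (panel["umol_per_g_dw"] < 0).any():
        bad = panel.loc[panel["umol_per_g_dw"] < 0]
        raise ValueError(f"negative concentrations for {sorted(bad['compound'].unique())}")
    known = {c.abbreviation for c in analytes(compounds)}
    unknown = set(panel["compound"].unique()) - known
    if unknown:
        raise ValueError(f"unknown compounds in panel: {sorted(unknown)}")
    for gid, sub in panel.groupby("genotype_id"):
        rep_sets = sub.groupby("compound")["replicate"].agg(frozenset)
        if rep_sets.nunique() != 1:
            raise ValueError(f"genotype {gid}: replicate set varies across compounds")
        n_rep = len(rep_sets.iloc[0])
        if n_rep not in (3, 4):
            raise ValueError(f"genotype {gid}: expected 3 or 4 replicates, got {n_rep}")
    return panel


def validate_trait_panel(panel: pd.DataFrame) -> pd.DataFrame:
    missing = set(TRAIT_COLUMNS) - set(panel.columns)
    if missing:
        raise ValueError(f"trait panel missing columns: {sorted(missing)}")
    if panel.empty:
        return panel
    if (panel["value"] <= 0).any():
        raise ValueError("trait values must be positive")
    unknown = set(panel["trait"].unique()) - set(TRAIT_CODES)
    if unknown:
        raise ValueError(f"unknown trait codes: {sorted(unknown)}")
    return panel


def genotype_means(
    panel: pd.DataFrame, value_col: str = "umol_per_g_dw", var_col: str = "compound"
) -> GenotypeMeans:
    """Per-genotype arithmetic means over replicates, with standard errors.

    SE uses the sample SD (ddof=1) over replicates divided by √n; a genotype
    with a single replicate gets SE = NaN for every variable.
    """
    if panel.empty:
        raise ValueError("cannot compute genotype means of an empty panel")
    grouped = panel.groupby(["genotype_id", var_col])[value_col]
    mean = grouped.mean().unstack(var_col)
    n = grouped.size().unstack(var_col)
    sd = grouped.std(ddof=1).unstack(var_col)
    se = sd / np.sqrt(n)
    return GenotypeMeans(mean=mean, se=se)


def total_gsl(values, compounds: Iterable[CompoundDef] | None = None):
    """Total glucosinolate content: sum over the 13 analytes, IS excluded.

    Accepts a Series (one genotype) or a genotype × compound DataFrame;
    raises if any analyte column is absent.
    """
    wanted = [c.abbreviation for c in analytes(compounds)]
    if isinstance(values, pd.DataFrame):
        missing = set(wanted) - set(values.columns)
    else:
        missing = set(wanted) - set(values.index)
    if missing:
        raise ValueError(f"total requires every analyte; missing {sorted(missing)}")
    if isinstance(values, pd.DataFrame):
        return values[wanted].sum(axis=1)
    return float(values[wanted].sum())


def class_proportions(
    means: pd.DataFrame, compounds: Iterable[CompoundDef] | None = None
) -> pd.DataFrame:
    """Fraction of total content per structural class, one row per genotype.

    The four classes (aliphatic 3C and 4C reported separately, indolyl,
    aromatic) sum to 1 in every row; an all-zero genotype row is an error.
    """
    comps = analytes(compounds)
    missing = {c.abbreviation for c in comps} - set(means.columns)
    if missing:
        raise ValueError(f"means matrix missing analytes: {sorted(missing)}")
    if (means < 0).any().any():
        raise ValueError("means must be non-negative")
    totals = means[[c.abbreviation for c in comps]].sum(axis=1)
    if (totals <= 0).any():
        zero = totals.index[totals <= 0].tolist()
        raise ValueError(f"genotypes with all-zero profiles: {zero}")
    out = pd.DataFrame(index=means.index)
    for cls in GSLClass:
        members = [c.abbreviation for c in comps if c.gsl_class is cls]
        out[cls.value] = means[members].sum(axis=1) / totals if members else 0.0
    return out
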