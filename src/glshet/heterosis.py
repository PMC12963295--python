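"""Mid-parent heterosis and bootstrap confidence intervals.

For a hybrid with genotype-mean value H and parental genotype means m, f,
the mid-parent value is MPV = (m + f)/2 and mid-parent heterosis is

    MPH = 100 × (H − MPV) / MPV   [percent]

computed per hybrid and trait (each compound, the total, or an agronomic
trait). MPH is undefined when MPV = 0 — e.g. a gluconasturtiin-null hybrid
from two null parents — and such cells are flagged and excluded downstream
rather than coerced to ±∞.

Because per-compound MPH across 11 hybrids is skewed with outliers, the
central tendency is summarised by the median with a nonparametric
percentile bootstrap CI (resampling hybrids with replacement); heterosis is
called consistent when the CI excludes zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panels import genotype_means, total_gsl
from .pedigree import Pedigree

TOTAL_LABEL = "TOTAL"


def mid_parent_value(mother_mean: float, father_mean: float) -> float:
    """Average of the two parental genotype means."""
    if mother_mean is None or father_mean is None or np.isnan(mother_mean) or np.isnan(father_mean):
        raise ValueError("both parental means are required for a mid-parent value")
    return (mother_mean + father_mean) / 2.0


def mph(H: float, MPV: float) -> float:
    """Percent mid-parent heterosis; NaN (undefined) when MPV = 0."""
    if H < 0 or MPV < 0:
        raise ValueError("heterosis is defined for non-negative trait values")
    if MPV == 0:
        return float("nan")
    return 100.0 * (H - MPV) / MPV


def heterosis_table(
    panel: pd.DataFrame,
    pedigree: Pedigree,
    value_col: str = "umol_per_g_dw",
    var_col: str = "compound",
    include_total: bool = True,
) -> pd.DataFrame:
    """Per-(hybrid, trait) heterosis table from a replicate-level panel.

    Returns columns (hybrid_id, trait, H, MPV, MPH, defined). Commercial
    hybrids are excluded (no pedigree); a hybrid whose parents are absent
    from the panel is skipped with a warning. For concentration panels the
    total across the analytes present is appended as trait "TOTAL".
    """
    means = genotype_means(panel, value_col=value_col, var_col=var_col).mean
    if include_total and var_col == "compound":
        try:
            means[TOTAL_LABEL] = total_gsl(means)
        except ValueError:
            means[TOTAL_LABEL] = means.sum(axis=1)  # partial compound set
    rows = []
    for hyb in pedigree.hybrids:
        mother, father = pedigree.parents_of(hyb.genotype_id)
        if hyb.genotype_id not in means.index or mother not in means.index or father not in means.index:
            warnings.warn(
                f"hybrid {hyb.genotype_id}: missing panel data for hybrid or parents; skipped",
                UserWarning,
                stacklevel=2,
            )
            continue
        for trait in means.columns:
            H = float(means.loc[hyb.genotype_id, trait])
            mpv = mid_parent_value(float(means.loc[mother, trait]), float(means.loc[father, trait]))
            value = mph(H, mpv)
            rows.append(
                {
                    "hybrid_id": hyb.genotype_id,
                    "trait": trait,
                    "H": H,
                    "MPV": mpv,
                    "MPH": value,
                    "defined": bool(np.isfinite(value)),
                }
            )
    return pd.DataFrame(rows, columns=["hybrid_id", "trait", "H", "MPV", "MPH", "defined"])


def mph_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Per-trait min/max/mean/median of defined MPH values + exclusion counts."""
    defined = table[table["defined"]]
    grouped = defined.groupby("trait")["MPH"]
    out = grouped.agg(["min", "max", "mean", "median"]).reset_index()
    n_undef = (
        table[~table["defined"]].groupby("trait").size().rename("n_undefined").reset_index()
    )
    out = out.merge(n_undef, on="trait", how="left")
    out["n_undefined"] = out["n_undefined"].fillna(0).astype(int)
    return out


@dataclass(frozen=True)
class BootstrapCi:
    trait: str
    point: float  # median MPH across hybrids
    lower: float
    upper: float
    B: int
    seed: int | None
    n: int

    @property
    def excludes_zero(self) -> bool:
        return bool(self.lower > 0 or self.upper < 0)


def bootstrap_median_ci(
    values,
    B: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
    trait: str = "",
    rng: np.random.Generator | None = None,
) -> BootstrapCi:
    """Percentile bootstrap CI for the median of ``values``.

    Resamples the n values with replacement B times; the CI is the
    (alpha/2, 1−alpha/2) percentile interval of the resampled medians.
    """
    vals = np.asarray([v for v in np.asarray(values, dtype=float) if np.isfinite(v)])
    if vals.size < 2:
        raise ValueError("bootstrap CI requires at least 2 defined values")
    if rng is None:
        rng = np.random.default_rng(seed)
    idx = rng.integers(0, vals.size, size=(B, vals.size))
    medians = np.median(vals[idx], axis=1)
    lower, upper = np.quantile(medians, [alpha / 2.0, 1.0 - alpha / 2.0])
    return BootstrapCi(
        trait=trait,
        point=float(np.median(vals)),
        lower=float(lower),
        upper=float(upper),
        B=B,
        seed=seed,
        n=int(vals.size),
    )


def bootstrap_table(
    table: pd.DataFrame, B: int = 1000, alpha: float = 0.05, seed: int | None = None
) -> pd.DataFrame:
    """Median-MPH bootstrap CI for every trait in a heterosis table."""
    rng = np.random.default_rng(seed)
    rows = []
    for trait, sub in table.groupby("trait", sort=False):
        vals = sub.loc[sub["defined"], "MPH"].to_numpy()
        if vals.size < 2:
            continue
        ci = bootstrap_median_ci(vals, B=B, alpha=alpha, trait=trait, rng=rng)
        rows.append(
            {
                "trait": trait,
                "median": ci.point,
                "lower": ci.lower,
                "upper": ci.upper,
                "B": B,
                "seed": seed,
                "n": ci.n,
                "excludes_zero": ci.excludes_zero,
            }
        )
    return pd.DataFrame(rows)


def standardized_mph_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Hybrid × trait matrix of per-trait MPH z-scores (heatmap input).

    Undefined MPH cells stay NaN and are excluded from each trait's
    mean/SD; traits with fewer than 2 defined hybrids raise.
    """
    wide = table.pivot(index="hybrid_id", columns="trait", values="MPH")
    counts = wide.notna().sum(axis=0)
    if (counts < 2).any():
        bad = counts.index[counts < 2].tolist()
        raise ValueError(f"traits with < 2 defined MPH values: {bad}")
    mu = wide.mean(axis=0, skipna=True)
    sd = wide.std(axis=0, ddof=0, skipna=True)
    flat = sd == 0
    if flat.any():
        warnings.warn(
            f"zero-variance traits set to 0: {wide.columns[flat].tolist()}",
            UserWarning,
            stacklevel=2,
        )
        sd = sd.mask(flat, 1.0)
    z = (wide - mu) / sd
    z.loc[:, flat] = 0.0
    return z


__all__ = [
    "mid_parent_value",
    "mph",
    "heterosis_table",
    "mph_summary",
    "BootstrapCi",
    "bootstrap_median_ci",
    "bootstrap_table",
    "standardized_mph_matrix",
]
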