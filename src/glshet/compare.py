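"""Line-vs-hybrid group comparisons with Bonferroni familywise control.

Genotype means (not replicates) are the experimental units: a Welch
two-sample t-test compares the line group against the hybrid group per
trait. The total-GSL test is reported unadjusted; the 13 individual
compounds are Bonferroni-adjusted as one family (m = 13) and the 5
agronomic traits as another (m = 5). Commercial check hybrids sit in the
hybrid group by default (configurable to the program hybrids only).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .composition import standardize
from .heterosis import TOTAL_LABEL
from .panels import TRAIT_CODES, genotype_means, total_gsl
from .pedigree import Pedigree


@dataclass(frozen=True)
class GroupTestResult:
    trait: str
    mean_lines: float
    mean_hybrids: float
    sd_lines: float
    sd_hybrids: float
    n_lines: int
    n_hybrids: int
    t: float
    p_raw: float
    p_adj: float
    m: int
    alpha: float

    @property
    def significant(self) -> bool:
        return self.p_adj < self.alpha


def bonferroni(p_raw: float, m: int) -> float:
    """Familywise-adjusted p: min(1, m × p)."""
    if not 0 <= p_raw <= 1:
        raise ValueError("p-value must lie in [0, 1]")
    if m < 1:
        raise ValueError("family size m must be ≥ 1")
    return min(1.0, m * p_raw)


def _group_ids(pedigree: Pedigree, include_checks: bool) -> tuple[list[str], list[str]]:
    lines = [g.genotype_id for g in pedigree.lines]
    hybrids = [g.genotype_id for g in pedigree.hybrids]
    if include_checks:
        hybrids += [g.genotype_id for g in pedigree.commercial_hybrids]
    return lines, hybrids


def ttest_groups(
    means: pd.DataFrame,
    pedigree: Pedigree,
    traits: list[str] | None = None,
    alpha: float = 0.05,
    m: int | None = None,
    include_checks: bool = True,
) -> list[GroupTestResult]:
    """Welch t-tests (lines vs hybrids) on a genotype × trait mean matrix.

    ``m`` is the Bonferroni family size; default is the number of traits
    tested, with the total-GSL column always adjusted at m = 1.
    """
    lines, hybrids = _group_ids(pedigree, include_checks)
    lines = [g for g in lines if g in means.index]
    hybrids = [g for g in hybrids if g in means.index]
    if len(lines) < 2 or len(hybrids) < 2:
        raise ValueError("each group needs at least 2 genotype means")
    traits = list(means.columns) if traits is None else traits
    family = m if m is not None else len([t for t in traits if t != TOTAL_LABEL]) or 1
    out = []
    for trait in traits:
        a = means.loc[lines, trait].to_numpy(dtype=float)
        b = means.loc[hybrids, trait].to_numpy(dtype=float)
        if np.allclose(a, a[0]) and np.allclose(b, b[0]) and np.isclose(a[0], b[0]):
            t_stat, p_raw = 0.0, 1.0  # identical degenerate groups
        else:
            t_stat, p_raw = stats.ttest_ind(a, b, equal_var=False)
        m_trait = 1 if trait == TOTAL_LABEL else family
        out.append(
            GroupTestResult(
                trait=trait,
                mean_lines=float(a.mean()),
                mean_hybrids=float(b.mean()),
                sd_lines=float(a.std(ddof=1)),
                sd_hybrids=float(b.std(ddof=1)),
                n_lines=len(a),
                n_hybrids=len(b),
                t=float(t_stat),
                p_raw=float(p_raw),
                p_adj=bonferroni(float(p_raw), m_trait),
                m=m_trait,
                alpha=alpha,
            )
        )
    return out


def tests_frame(results: list[GroupTestResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "trait": [r.trait for r in results],
            "mean_lines": [r.mean_lines for r in results],
            "mean_hybrids": [r.mean_hybrids for r in results],
            "n_lines": [r.n_lines for r in results],
            "n_hybrids": [r.n_hybrids for r in results],
            "t": [r.t for r in results],
            "p_raw": [r.p_raw for r in results],
            "p_adj": [r.p_adj for r in results],
            "m": [r.m for r in results],
            "significant": [r.significant for r in results],
        }
    )


def compare_concentrations(
    panel: pd.DataFrame,
    pedigree: Pedigree,
    alpha: float = 0.05,
    include_checks: bool = True,
) -> pd.DataFrame:
    """Group tests for total (unadjusted) and the 13 compounds (m = 13)."""
    means = genotype_means(panel).mean
    means[TOTAL_LABEL] = total_gsl(means)
    results = ttest_groups(means, pedigree, alpha=alpha, include_checks=include_checks)
    return tests_frame(results)


def agronomic_summary(
    traits: pd.DataFrame,
    pedigree: Pedigree,
    alpha: float = 0.05,
    include_checks: bool = True,
) -> dict:
    """Group comparison for the five head traits (m = 5) + heatmap matrix.

    Returns {"tests": DataFrame, "zscores": genotype × trait z-matrix,
    "missing": absent trait codes}. Missing traits produce a partial result
    rather than an error.
    """
    means = genotype_means(traits, value_col="value", var_col="trait").mean
    present = [t for t in TRAIT_CODES if t in means.columns]
    missing = [t for t in TRAIT_CODES if t not in means.columns]
    if missing:
        import warnings

        warnings.warn(f"missing agronomic traits: {missing}", UserWarning, stacklevel=2)
    results = ttest_groups(
        means[present], pedigree, alpha=alpha, m=len(TRAIT_CODES), include_checks=include_checks
    )
    return {
        "tests": tests_frame(results),
        "zscores": standardize(means[present]),
        "missing": missing,
    }
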