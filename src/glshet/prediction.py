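"""Parent-to-hybrid prediction by per-trait linear regression.

For each compound (and the total) the hybrid genotype means H are regressed
on their mid-parent values: H = a + b·MPV, by ordinary least squares across
the program hybrids. The r² measures how much hybrid variability parental
phenotypes explain; under purely additive inheritance the slope is 1 and
MPV is an unbiased predictor. The 95% band is for the mean response (a
prediction-interval mode exists for single new hybrids but defaults off).

A sensitivity refit guards against structurally trivial fits: hybrids whose
trait value and MPV are both zero (double-null pairs, the gluconasturtiin
situation) anchor the line at the origin and can manufacture significance;
the refit drops them and reports whether the p < 0.05 call flips.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, RegressorMixin

from .heterosis import heterosis_table
from .pedigree import Pedigree

ALPHA = 0.05


class ParentHybridRegressor(BaseEstimator, RegressorMixin):
    """OLS regression of hybrid value on mid-parent value.

    fit(X, y) with X the MPVs (1-d or column vector) and y the hybrid
    genotype means; exposes ``slope_``, ``intercept_``, ``r2_``, ``p_value_``
    (two-sided, for the slope) and interval-aware prediction.
    """

    def __init__(self, alpha: float = ALPHA):
        self.alpha = alpha

    def fit(self, X, y) -> "ParentHybridRegressor":
        x = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if x.size != y.size:
            raise ValueError("X and y must have the same length")
        mask = np.isfinite(x) & np.isfinite(y)
        x, y = x[mask], y[mask]
        if x.size < 3:
            raise ValueError("at least 3 finite (MPV, H) pairs are required")
        if np.ptp(x) == 0:
            raise ValueError("predictor has zero variance; model is not fittable")
        self.x_, self.y_ = x, y
        self.model_ = sm.OLS(y, sm.add_constant(x)).fit()
        self.intercept_, self.slope_ = map(float, self.model_.params)
        if np.ptp(y) == 0:
            # constant response: define r² = 0, no evidence for a slope
            self.r2_, self.p_value_ = 0.0, 1.0
        else:
            self.r2_ = float(self.model_.rsquared)
            self.p_value_ = float(self.model_.pvalues[1])
        self.n_ = int(x.size)
        return self

    @property
    def significant_(self) -> bool:
        return self.p_value_ < self.alpha

    def predict(self, X) -> np.ndarray:
        x = np.asarray(X, dtype=float).reshape(-1)
        return self.model_.predict(sm.add_constant(x, has_constant="add"))

    def predict_interval(
        self, X, level: float = 0.95, prediction: bool = False
    ) -> pd.DataFrame:
        """Point predictions with a CI for the mean response (or, with
        ``prediction=True``, a prediction interval for a new observation)."""
        x = np.asarray(X, dtype=float).reshape(-1)
        pred = self.model_.get_prediction(sm.add_constant(x, has_constant="add"))
        frame = pred.summary_frame(alpha=1.0 - level)
        lo, hi = ("obs_ci_lower", "obs_ci_upper") if prediction else ("mean_ci_lower", "mean_ci_upper")
        return pd.DataFrame(
            {"mpv": x, "fit": frame["mean"].to_numpy(), "lower": frame[lo].to_numpy(), "upper": frame[hi].to_numpy()}
        )


@dataclass
class RegressionResult:
    trait: str
    n: int
    slope: float
    intercept: float
    r2: float
    p_value: float
    significant: bool
    band: pd.DataFrame  # mpv grid, fit, lower, upper (mean-response CI)
    pairs: pd.DataFrame  # hybrid_id, mpv, H used for the fit
    fittable: bool = True
    sensitivity: Optional["RegressionResult"] = None
    excluded_hybrids: list[str] = field(default_factory=list)

    @property
    def significance_changed(self) -> bool | None:
        if self.sensitivity is None:
            return None
        if not self.sensitivity.fittable:
            return None
        return self.sensitivity.significant != self.significant


def _unfittable(trait: str, pairs: pd.DataFrame) -> RegressionResult:
    return RegressionResult(
        trait=trait,
        n=len(pairs),
        slope=float("nan"),
        intercept=float("nan"),
        r2=float("nan"),
        p_value=float("nan"),
        significant=False,
        band=pd.DataFrame(columns=["mpv", "fit", "lower", "upper"]),
        pairs=pairs,
        fittable=False,
    )


def fit_parent_hybrid(
    trait: str,
    pairs: pd.DataFrame,
    alpha: float = ALPHA,
    band_points: int = 50,
    prediction_interval: bool = False,
) -> RegressionResult:
    """Fit H = a + b·MPV for one trait; ``pairs`` has columns hybrid_id, mpv, H.

    Returns a flagged non-fittable result (rather than raising) when fewer
    than 3 finite pairs remain or the MPVs are constant, so a table of
    per-compound fits can carry partial failures.
    """
    pairs = pairs.dropna(subset=["mpv", "H"]).reset_index(drop=True)
    if len(pairs) < 3 or np.ptp(pairs["mpv"].to_numpy()) == 0:
        return _unfittable(trait, pairs)
    reg = ParentHybridRegressor(alpha=alpha).fit(pairs["mpv"], pairs["H"])
    grid = np.linspace(pairs["mpv"].min(), pairs["mpv"].max(), band_points)
    band = reg.predict_interval(grid, level=1.0 - alpha, prediction=prediction_interval)
    return RegressionResult(
        trait=trait,
        n=reg.n_,
        slope=reg.slope_,
        intercept=reg.intercept_,
        r2=reg.r2_,
        p_value=reg.p_value_,
        significant=reg.significant_,
        band=band,
        pairs=pairs,
    )


def sensitivity_refit(
    result: RegressionResult, exclude_rule: str = "both-parents-zero", alpha: float = ALPHA
) -> RegressionResult:
    """Refit after dropping double-zero (H = 0 and MPV = 0) hybrids.

    Returns a copy of ``result`` whose ``sensitivity`` holds the refit and
    whose ``excluded_hybrids`` lists what was dropped. With no exclusions the
    refit equals the original fit.
    """
    if exclude_rule != "both-parents-zero":
        raise ValueError(f"unknown exclusion rule: {exclude_rule}")
    if not result.fittable:
        return result
    mask = (result.pairs["mpv"] == 0) & (result.pairs["H"] == 0)
    excluded = result.pairs.loc[mask, "hybrid_id"].tolist()
    kept = result.pairs.loc[~mask]
    refit = fit_parent_hybrid(result.trait, kept, alpha=alpha)
    out = RegressionResult(**{**result.__dict__})
    out.sensitivity = refit
    out.excluded_hybrids = excluded
    return out


def predict_hybrid(
    result: RegressionResult, mpv_new, level: float = 0.95, prediction: bool = False
) -> pd.DataFrame:
    """Predicted hybrid value(s) at new MPVs with a 95% interval."""
    if not result.fittable:
        raise ValueError(f"model for {result.trait} is not fittable")
    reg = ParentHybridRegressor().fit(result.pairs["mpv"], result.pairs["H"])
    return reg.predict_interval(np.atleast_1d(mpv_new), level=level, prediction=prediction)


def parent_hybrid_regressions(
    panel: pd.DataFrame,
    pedigree: Pedigree,
    alpha: float = ALPHA,
    with_sensitivity: bool = True,
    prediction_interval: bool = False,
    value_col: str = "umol_per_g_dw",
    var_col: str = "compound",
) -> dict[str, RegressionResult]:
    """One regression per trait (each compound + total) across all hybrids."""
    table = heterosis_table(panel, pedigree, value_col=value_col, var_col=var_col)
    results: dict[str, RegressionResult] = {}
    for trait, sub in table.groupby("trait", sort=False):
        pairs = sub.rename(columns={"MPV": "mpv"})[["hybrid_id", "mpv", "H"]]
        res = fit_parent_hybrid(
            trait, pairs, alpha=alpha, prediction_interval=prediction_interval
        )
        if with_sensitivity:
            res = sensitivity_refit(res, alpha=alpha)
        results[trait] = res
    return results


def regressions_frame(results: dict[str, RegressionResult]) -> pd.DataFrame:
    """Flat summary table of per-trait fits (regression.csv layout)."""
    rows = []
    for trait, r in results.items():
        sens = r.sensitivity
        rows.append(
            {
                "trait": trait,
                "n": r.n,
                "slope": r.slope,
                "intercept": r.intercept,
                "r2": r.r2,
                "p": r.p_value,
                "significant": r.significant,
                "fittable": r.fittable,
                "n_excluded": len(r.excluded_hybrids),
                "sens_r2": sens.r2 if sens is not None else np.nan,
                "sens_p": sens.p_value if sens is not None else np.nan,
                "sens_changed": r.significance_changed,
            }
        )
    return pd.DataFrame(rows)
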