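"""Internal-standard MRM quantification.

Peak areas from multiple-reaction-monitoring chromatograms are converted to
tissue concentrations in two steps: a per-compound response factor corrects
for detector response (RF = calibration slope of the internal standard over
the analyte's slope), then the analyte amount is computed relative to the
spiked internal standard:

    nmol_analyte = (area_analyte / area_IS) × RF × nmol_IS

and normalised by sample dry mass. With the standard workflow constants
(50 mg tissue, 25 nmol glucotropaeolin) an analyte responding exactly like
the IS at RF = 1 reports 0.5 µmol g⁻¹ dw.

Only the ratio of calibration slopes enters; intercepts are carried for
diagnostics but never used.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .panels import validate_concentration_panel
from .registry import CompoundDef, internal_standard

DEFAULT_DRY_MASS_G = 0.050
DEFAULT_IS_AMOUNT_NMOL = 25.0


class QuantificationError(ValueError):
    """A sample cannot be quantified (e.g. missing or zero IS area)."""


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear calibration of peak area against nmol injected."""

    compound: str
    slope: float  # peak area per nmol
    intercept: float = 0.0
    n_points: int | None = None
    r2: float | None = None

    def __post_init__(self):
        if not self.slope > 0:
            raise ValueError(f"calibration slope for {self.compound} must be > 0")


@dataclass(frozen=True)
class MrmSample:
    """One extraction: peak areas plus the dry mass and IS spike amount."""

    sample_id: str
    genotype_id: str
    replicate_index: int
    areas: Mapping[str, float] = field(default_factory=dict)
    dry_mass_g: float = DEFAULT_DRY_MASS_G
    is_amount_nmol: float = DEFAULT_IS_AMOUNT_NMOL

    def __post_init__(self):
        if not self.dry_mass_g > 0:
            raise ValueError("dry_mass_g must be > 0")
        if not self.is_amount_nmol > 0:
            raise ValueError("is_amount_nmol must be > 0")


def response_factor(analyte: CalibrationCurve, is_curve: CalibrationCurve) -> float:
    """RF = slope_IS / slope_analyte; both slopes must be positive."""
    if not (analyte.slope > 0 and is_curve.slope > 0):
        raise ValueError("calibration slopes must be positive")
    return is_curve.slope / analyte.slope


def quantify_sample(
    sample: MrmSample,
    rfs: Mapping[str, float],
    is_abbreviation: str | None = None,
) -> dict[str, float]:
    """Concentrations in µmol g⁻¹ dw for every analyte area in the sample."""
    is_abbr = is_abbreviation or internal_standard().abbreviation
    area_is = sample.areas.get(is_abbr)
    if area_is is None or not area_is > 0:
        raise QuantificationError(
            f"sample {sample.sample_id}: internal-standard area missing or non-positive"
        )
    out: dict[str, float] = {}
    for compound, area in sample.areas.items():
        if compound == is_abbr:
            continue
        if area < 0:
            raise QuantificationError(f"sample {sample.sample_id}: negative area for {compound}")
        if compound not in rfs:
            raise QuantificationError(f"sample {sample.sample_id}: no response factor for {compound}")
        nmol = (area / area_is) * rfs[compound] * sample.is_amount_nmol
        # nmol / g → µmol / g
        out[compound] = nmol / sample.dry_mass_g / 1000.0
    return out


class MrmQuantifier(BaseEstimator, TransformerMixin):
    """Calibration-slope quantifier with a fit/transform surface.

    ``fit`` takes a calibration table (compound, slope, optional intercept /
    n_points / r2) whose rows include the internal standard; ``transform``
    maps a batch of :class:`MrmSample` to a validated long-form
    concentration panel. Samples that fail (IS area missing or zero,
    negative areas) are never dropped silently: they are collected in
    ``failures_`` and flagged in the returned panel's attrs.

    Parameters
    ----------
    is_abbreviation : abbreviation of the internal standard, default "GTP".
    """

    def __init__(self, is_abbreviation: str = "GTP"):
        self.is_abbreviation = is_abbreviation

    def fit(self, calibration: pd.DataFrame, y=None) -> "MrmQuantifier":
        required = {"compound", "slope"}
        if not required <= set(calibration.columns):
            raise ValueError(f"calibration table needs columns {sorted(required)}")
        curves = {
            str(r.compound): CalibrationCurve(
                compound=str(r.compound),
                slope=float(r.slope),
                intercept=float(getattr(r, "intercept", 0.0) or 0.0),
            )
            for r in calibration.itertuples(index=False)
        }
        if self.is_abbreviation not in curves:
            raise ValueError(f"calibration table lacks the internal standard {self.is_abbreviation}")
        is_curve = curves[self.is_abbreviation]
        self.curves_ = curves
        self.response_factors_ = {
            abbr: response_factor(curve, is_curve)
            for abbr, curve in curves.items()
            if abbr != self.is_abbreviation
        }
        return self

    def transform(self, samples: list[MrmSample]) -> pd.DataFrame:
        if not hasattr(self, "response_factors_"):
            raise ValueError("MrmQuantifier is not fitted; call fit(calibration) first")
        rows, failures, diagnostics = [], [], []
        for s in samples:
            diagnostics.append(
                {"sample_id": s.sample_id, "area_is": s.areas.get(self.is_abbreviation, np.nan)}
            )
            try:
                conc = quantify_sample(s, self.response_factors_, self.is_abbreviation)
            except QuantificationError as exc:
                failures.append(
                    {
                        "sample_id": s.sample_id,
                        "genotype_id": s.genotype_id,
                        "replicate": s.replicate_index,
                        "reason": str(exc),
                    }
                )
                continue
            for compound, value in conc.items():
                rows.append(
                    {
                        "genotype_id": s.genotype_id,
                        "replicate": s.replicate_index,
                        "compound": compound,
                        "umol_per_g_dw": value,
                    }
                )
        panel = pd.DataFrame(rows, columns=["genotype_id", "replicate", "compound", "umol_per_g_dw"])
        self.failures_ = pd.DataFrame(
            failures, columns=["sample_id", "genotype_id", "replicate", "reason"]
        )
        self.is_area_diagnostics_ = pd.DataFrame(diagnostics)
        panel.attrs["n_failed_samples"] = len(self.failures_)
        return panel


def quantify_batch(
    samples: list[MrmSample],
    calibration: pd.DataFrame,
    compounds: list[CompoundDef] | None = None,
    validate: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Quantify a batch; returns (concentration panel, flagged failures)."""
    q = MrmQuantifier().fit(calibration)
    panel = q.transform(samples)
    if validate and not panel.empty:
        validate_concentration_panel(panel, compounds)
    return panel, q.failures_
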