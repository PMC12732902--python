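"""HPLC calibration-curve quantification of 5'-nucleotides.

Standards are fit by unweighted ordinary least squares (area on
concentration); sample concentrations come from inverse prediction, and
tissue contents from the dilution relation content = C * V / W where C is
the extract concentration (µg/mL), V the extract volume (mL) and W the
sample mass (g).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._util import log

__all__ = [
    "CalibrationCurve",
    "ExtractionRecord",
    "fit_calibration",
    "concentration_from_area",
    "nucleotide_content",
]

#: minimum coefficient of determination for an acceptable standard curve
R2_ACCEPTANCE = 0.995


@dataclass(frozen=True)
class CalibrationCurve:
    """OLS line area = slope * conc + intercept over a concentration range."""

    compound: str
    slope: float
    intercept: float
    r_squared: float
    conc_range: tuple[float, float]

    @property
    def valid(self) -> bool:
        """Curves must exceed R^2 = 0.995 to be used for quantification."""
        return self.r_squared > R2_ACCEPTANCE and self.slope > 0


@dataclass(frozen=True)
class ExtractionRecord:
    """One extraction: measured extract concentration, volume and sample mass."""

    concentration_ug_per_ml: float
    extract_volume_ml: float
    sample_mass_g: float

    def __post_init__(self) -> None:
        if self.concentration_ug_per_ml < 0:
            raise ValueError("extract concentration must be >= 0")
        if not self.extract_volume_ml > 0:
            raise ValueError("extract volume must be > 0")
        if not self.sample_mass_g > 0:
            raise ValueError("sample mass must be > 0")


def fit_calibration(
    standards, compound: str = ""
) -> CalibrationCurve:
    """Fit a calibration line to (conc µg/mL, peak area) standard pairs.

    ``standards`` is an iterable of (conc, area) pairs or a mapping-like
    with ``conc``/``area`` fields. Requires >= 3 distinct concentrations.
    """
    arr = np.asarray(
        [(s["conc"], s["area"]) if isinstance(s, dict) else tuple(s) for s in standards],
        dtype=float,
    )
    if arr.ndim != 2 or arr.shape[0] < 3:
        raise ValueError("calibration needs at least 3 standard points")
    conc, area = arr[:, 0], arr[:, 1]
    if np.unique(conc).size < 3:
        raise ValueError("calibration needs at least 3 distinct concentrations")
    if np.ptp(conc) == 0:
        raise ValueError("zero variance in standard concentrations")

    res = stats.linregress(conc, area)
    r2 = float(res.rvalue**2)
    curve = CalibrationCurve(
        compound=compound,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=r2,
        conc_range=(float(conc.min()), float(conc.max())),
    )
    if not curve.valid:
        log.warning(
            "calibration for %s rejected: R^2 = %.4f (acceptance bound %.3f)",
            compound or "<unnamed>", r2, R2_ACCEPTANCE,
        )
    return curve


def concentration_from_area(curve: CalibrationCurve, area: float) -> float:
    """Inverse-predict extract concentration (µg/mL) from a peak area.

    Negative predictions (trace signal below the intercept) floor to 0
    with a warning; predictions beyond 1.2x the calibrated range warn.
    """
    if curve.slope == 0:
        raise ZeroDivisionError("calibration slope is zero")
    conc = (area - curve.intercept) / curve.slope
    if conc < 0:
        log.warning(
            "%s: area %.3g below intercept, flooring concentration to 0",
            curve.compound or "<unnamed>", area,
        )
        return 0.0
    if conc > 1.2 * curve.conc_range[1]:
        log.warning(
            "%s: predicted %.3g µg/mL beyond 1.2x calibrated range max %.3g",
            curve.compound or "<unnamed>", conc, curve.conc_range[1],
        )
    return float(conc)


def nucleotide_content(rec: ExtractionRecord) -> tuple[float, float]:
    """Tissue nucleotide content from an extraction record.

    Returns ``(content_ug_per_g, content_mg_per_100g)`` where
    content (µg/g) = C * V / W and mg/100 g = µg/g * 0.1.
    """
    ug_per_g = rec.concentration_ug_per_ml * rec.extract_volume_ml / rec.sample_mass_g
    return float(ug_per_g), float(ug_per_g * 0.1)
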