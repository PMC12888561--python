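"""Needle functional traits and substrate water status.

Needle water content and leaf mass per area (LMA) from fresh/dry weight
and projected area; gravimetric calibration of capacitive soil-moisture
sensors; conversion of raw sensor readings to volumetric water content
(VWC, a fraction internally); and the permanent wilting point (PWP), the
VWC at a soil water potential of -1.5 MPa.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "NeedleSample",
    "SoilCalibration",
    "VwcReading",
    "water_content",
    "lma",
    "fit_soil_calibration",
    "raw_to_vwc",
    "pwp_from_potential",
]


@dataclass(frozen=True)
class NeedleSample:
    """One destructive needle sample.

    Weights in g, projected area in cm2; ``needle_age_class`` is NAC1
    (current-year) or NAC2 (previous-year); DAT = days after
    transplantation.
    """

    fresh_weight: float
    dry_weight: float
    projected_area: float
    seedling_id: str = ""
    needle_age_class: str = "NAC2"
    dat: int = 0

    def __post_init__(self):
        if self.dry_weight <= 0:
            raise ValueError("dry weight must be positive")
        if self.fresh_weight < self.dry_weight:
            raise ValueError(
                f"fresh weight {self.fresh_weight} g below dry weight "
                f"{self.dry_weight} g"
            )
        if self.projected_area <= 0:
            raise ValueError("projected area must be positive")
        if self.needle_age_class not in ("NAC1", "NAC2"):
            raise ValueError("needle age class must be NAC1 or NAC2")


def water_content(s: NeedleSample) -> float:
    """Needle water content as relative weight loss on drying, (fresh-dry)/fresh."""
    return (s.fresh_weight - s.dry_weight) / s.fresh_weight


def lma(s: NeedleSample) -> float:
    """Leaf mass per area in g m-2 (dry weight / projected area)."""
    return s.dry_weight / (s.projected_area * 1e-4)  # cm2 -> m2


@dataclass
class SoilCalibration:
    """Fitted sensor-to-VWC calibration.

    ``coefficients`` are polynomial coefficients in increasing order
    (intercept first); ``form`` is 'linear' or 'quadratic'.
    """

    raw: np.ndarray
    vwc: np.ndarray
    coefficients: np.ndarray
    form: str
    residuals: np.ndarray = field(default_factory=lambda: np.empty(0))

    def predict(self, raw) -> np.ndarray:
        raw = np.asarray(raw, dtype=float)
        return np.polynomial.polynomial.polyval(raw, self.coefficients)

    @property
    def raw_range(self) -> tuple[float, float]:
        return float(np.min(self.raw)), float(np.max(self.raw))


def fit_soil_calibration(
    raw: Sequence[float], vwc: Sequence[float], form: str = "linear"
) -> SoilCalibration:
    """Least-squares calibration of raw sensor output against gravimetric VWC.

    Defaults to a straight line; a quadratic option is available but the
    fitted map must remain monotone over the data range.
    """
    raw = np.asarray(raw, dtype=float)
    vwc = np.asarray(vwc, dtype=float)
    if raw.shape != vwc.shape or raw.ndim != 1:
        raise ValueError("raw and vwc must be 1-D arrays of equal length")
    if np.unique(raw).size < 2:
        raise ValueError("need at least two distinct raw sensor values")
    if form not in ("linear", "quadratic"):
        raise ValueError(f"unknown calibration form {form!r}")
    deg = 1 if form == "linear" else 2
    coeffs = np.polynomial.polynomial.polyfit(raw, vwc, deg)
    cal = SoilCalibration(raw, vwc, coeffs, form)
    fitted = cal.predict(raw)
    cal.residuals = vwc - fitted
    grid = np.linspace(raw.min(), raw.max(), 256)
    diffs = np.diff(cal.predict(grid))
    if not (np.all(diffs >= -1e-12) or np.all(diffs <= 1e-12)):
        raise ValueError("fitted calibration is not monotone over the data range")
    return cal


@dataclass(frozen=True)
class VwcReading:
    """A converted sensor reading with quality flags."""

    vwc: float
    extrapolated: bool = False
    clipped: bool = False


def raw_to_vwc(raw: float, cal: SoilCalibration) -> VwcReading:
    """Convert a raw sensor value to VWC (fraction), flagging extrapolation.

    Values outside [0, 1] are clipped and flagged; readings outside the
    calibrated raw range are flagged as extrapolated.
    """
    lo, hi = cal.raw_range
    extrapolated = not (lo <= raw <= hi)
    value = float(cal.predict(raw))
    clipped = not (0.0 <= value <= 1.0)
    return VwcReading(min(max(value, 0.0), 1.0), extrapolated, clipped)


def pwp_from_potential(
    vwc_series: Sequence[float],
    potential_series_mpa: Sequence[float],
    threshold: float = -1.5,
) -> float:
    """VWC at the permanent wilting point (water potential = -1.5 MPa).

    Walks the paired series to the first crossing of ``threshold`` and
    interpolates VWC linearly between the bracketing samples.
    """
    vwc = np.asarray(vwc_series, dtype=float)
    pot = np.asarray(potential_series_mpa, dtype=float)
    if vwc.shape != pot.shape or vwc.ndim != 1 or vwc.size < 1:
        raise ValueError("series must be 1-D, paired and non-empty")
    exact = np.flatnonzero(pot == threshold)
    if exact.size:
        return float(vwc[exact[0]])
    for i in range(len(pot) - 1):
        lo, hi = pot[i], pot[i + 1]
        if (lo - threshold) * (hi - threshold) < 0:
            frac = (threshold - lo) / (hi - lo)
            return float(vwc[i] + frac * (vwc[i + 1] - vwc[i]))
    raise ValueError(
        f"water potential never crosses {threshold} MPa; cannot locate PWP"
    )
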