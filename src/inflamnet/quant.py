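"""Immunoassay quantification via four-parameter-logistic standard curves.

Raw plate signals are converted to concentrations by fitting the 4PL model

    f(x) = d + (a - d) / (1 + (x / c)^b)

to the standard series of each analyte (a: signal at zero concentration,
d: signal at saturation, c: midpoint/EC50 concentration, b: Hill slope) and
inverting the accepted curve for sample wells.  A curve is accepted only if
its coefficient of determination on the standards reaches 0.95; samples are
never quantified against a rejected curve, and signals outside the open
asymptote range are flagged ("below-range"/"above-range") rather than
extrapolated — mirroring assay practice of diluting samples into the
reference range of the standard curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import CurveNotAcceptedError, FitError

#: Minimum coefficient of determination for an accepted standard curve.
R2_TOLERANCE = 0.95


@dataclass(frozen=True)
class PlateMeasurement:
    """A single well: role is one of {standard, sample, blank}."""

    analyte: str
    role: str
    signal: float
    nominal_conc: float | None = None
    dilution: float = 1.0
    condition: str | None = None
    well: str | None = None

    def __post_init__(self):
        if self.role not in ("standard", "sample", "blank"):
            raise ValueError(f"unknown well role {self.role!r}")
        if self.role == "standard" and (
            self.nominal_conc is None or self.nominal_conc <= 0
        ):
            raise ValueError("standards require a positive nominal concentration")
        if self.dilution < 1:
            raise ValueError("dilution factor must be >= 1")
        if self.signal < 0:
            raise ValueError("raw signal must be nonnegative")


def four_pl(x, a, b, c, d):
    """Forward 4PL model; vectorized over x."""
    x = np.asarray(x, dtype=float)
    return d + (a - d) / (1.0 + (x / c) ** b)


@dataclass
class StandardCurve:
    """Fitted 4PL parameters with goodness of fit and acceptance flag."""

    analyte: str
    a: float
    b: float
    c: float
    d: float
    r_squared: float
    accepted: bool
    blank: float = 0.0

    def predict(self, x) -> np.ndarray:
        return four_pl(x, self.a, self.b, self.c, self.d)

    @property
    def signal_range(self) -> tuple[float, float]:
        """Open interval of invertible (blank-corrected) signals."""
        return (min(self.a, self.d), max(self.a, self.d))


def fit_4pl(
    standards: list[PlateMeasurement],
    blanks: list[PlateMeasurement] | None = None,
    r2_tolerance: float = R2_TOLERANCE,
    weighting: str | None = None,
) -> StandardCurve:
    """Least-squares 4PL fit to a standard series.

    Requires at least four distinct positive nominal concentrations.  If
    ``blanks`` are given, their mean signal is subtracted from every standard
    (floored at 0) before fitting and recorded on the curve.  ``weighting``
    may be ``"1/y2"`` for inverse-variance-like weighting; the default is
    ordinary least squares.

    Initialization follows the data: a from the signal at the lowest
    concentration side (min signal), d from the max signal, c from the
    geometric mean concentration, and the sign of b from the empirical
    monotone trend.
    """
    std = [m for m in standards if m.role == "standard"]
    if not std:
        raise ValueError("no standard wells supplied")
    analytes = {m.analyte for m in std}
    if len(analytes) > 1:
        raise ValueError(f"standards span multiple analytes: {sorted(analytes)}")
    analyte = std[0].analyte

    blank = 0.0
    if blanks:
        blank = float(np.mean([m.signal for m in blanks]))
    x = np.array([m.nominal_conc for m in std], dtype=float)
    y = np.maximum(np.array([m.signal for m in std], dtype=float) - blank, 0.0)
    if len(np.unique(x)) < 4:
        raise ValueError(
            f"{analyte}: 4PL fit requires >=4 distinct standard concentrations, "
            f"got {len(np.unique(x))}"
        )

    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        raise FitError(f"{analyte}: constant standard signals (SS_tot = 0)")

    # data-driven initialization
    order = np.argsort(x)
    trend_up = y[order][-1] >= y[order][0]
    a0, d0 = float(y.min()), float(y.max())
    c0 = float(np.exp(np.mean(np.log(x))))
    b0 = 1.0 if trend_up else -1.0

    sigma = None
    if weighting == "1/y2":
        sigma = np.maximum(y, 1e-12)
    elif weighting is not None:
        raise ValueError(f"unknown weighting {weighting!r}")

    lower = [-np.inf, -np.inf, 1e-12, -np.inf]
    upper = [np.inf, np.inf, np.inf, np.inf]
    try:
        popt, _ = curve_fit(
            four_pl, x, y,
            p0=[a0, b0, c0, d0],
            sigma=sigma,
            bounds=(lower, upper),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise FitError(f"{analyte}: 4PL optimizer failed: {exc}") from exc

    a, b, c, d = (float(v) for v in popt)
    resid = y - four_pl(x, a, b, c, d)
    r2 = 1.0 - float((resid**2).sum()) / ss_tot
    return StandardCurve(
        analyte=analyte, a=a, b=b, c=c, d=d,
        r_squared=r2, accepted=r2 >= r2_tolerance, blank=blank,
    )


@dataclass(frozen=True)
class BackCalcResult:
    """Back-calculated concentration with an in-range qualifier."""

    analyte: str
    concentration: float | None
    qualifier: str  # "ok" | "below-range" | "above-range"
    condition: str | None = None
    well: str | None = None


def back_calculate(curve: StandardCurve, measurement: PlateMeasurement) -> BackCalcResult:
    """Invert an accepted 4PL curve for one sample well.

    The blank recorded on the curve is subtracted from the raw signal.  The
    inverse is ``x = c * ((a - y)/(y - d))^(1/b)``, multiplied by the well's
    dilution factor.  Signals at or outside the open asymptote interval are
    flagged "below-range" or "above-range" with no numeric extrapolation —
    direction follows the curve's trend (b > 0 with d > a means low signal =
    low concentration).
    """
    if not curve.accepted:
        raise CurveNotAcceptedError(
            f"{curve.analyte}: refusing to quantify against a curve with "
            f"R^2 = {curve.r_squared:.4f} < tolerance"
        )
    y = max(measurement.signal - curve.blank, 0.0)
    lo, hi = curve.signal_range
    increasing = curve.predict(curve.c * 2) >= curve.predict(curve.c / 2)
    if y <= lo:
        qualifier = "below-range" if increasing else "above-range"
        return BackCalcResult(curve.analyte, None, qualifier,
                              measurement.condition, measurement.well)
    if y >= hi:
        qualifier = "above-range" if increasing else "below-range"
        return BackCalcResult(curve.analyte, None, qualifier,
                              measurement.condition, measurement.well)
    ratio = (curve.a - y) / (y - curve.d)
    x = curve.c * ratio ** (1.0 / curve.b)
    if not math.isfinite(x):
        return BackCalcResult(curve.analyte, None, "above-range",
                              measurement.condition, measurement.well)
    return BackCalcResult(
        curve.analyte, float(x * measurement.dilution), "ok",
        measurement.condition, measurement.well,
    )


# ------------------------------------------------------------- plate-level


def quantify_plate(
    measurements: list[PlateMeasurement],
    r2_tolerance: float = R2_TOLERANCE,
    weighting: str | None = None,
) -> tuple[pd.DataFrame, dict[str, StandardCurve]]:
    """Fit a curve per analyte and back-calculate every sample well.

    Returns a tidy DataFrame (analyte, condition, well, concentration,
    qualifier) and the fitted curves.  Analytes whose curve is rejected keep
    their curve in the report but contribute no concentrations.
    """
    by_analyte: dict[str, list[PlateMeasurement]] = {}
    for m in measurements:
        by_analyte.setdefault(m.analyte, []).append(m)
    rows, curves = [], {}
    for analyte in sorted(by_analyte):
        wells = by_analyte[analyte]
        stds = [m for m in wells if m.role == "standard"]
        blanks = [m for m in wells if m.role == "blank"]
        curve = fit_4pl(stds, blanks or None, r2_tolerance, weighting)
        curves[analyte] = curve
        if not curve.accepted:
            continue
        for m in wells:
            if m.role != "sample":
                continue
            res = back_calculate(curve, m)
            rows.append({
                "analyte": analyte,
                "condition": res.condition,
                "well": res.well,
                "concentration": res.concentration,
                "qualifier": res.qualifier,
            })
    return pd.DataFrame(
        rows, columns=["analyte", "condition", "well", "concentration", "qualifier"]
    ), curves


def read_plate_csv(path) -> list[PlateMeasurement]:
    """Read a long-format plate CSV.

    Columns: analyte, well, role, nominal_conc, signal, dilution, condition
    (nominal_conc/dilution/condition may be empty for non-standard wells).
    """
    df = pd.read_csv(path)
    out = []
    for rec in df.to_dict("records"):
        nominal = rec.get("nominal_conc")
        out.append(PlateMeasurement(
            analyte=str(rec["analyte"]),
            role=str(rec["role"]),
            signal=float(rec["signal"]),
            nominal_conc=None if pd.isna(nominal) else float(nominal),
            dilution=float(rec.get("dilution", 1.0) or 1.0),
            condition=None if pd.isna(rec.get("condition")) else str(rec["condition"]),
            well=None if pd.isna(rec.get("well")) else str(rec["well"]),
        ))
    return out


def curves_to_frame(curves: dict[str, StandardCurve]) -> pd.DataFrame:
    return pd.DataFrame([
        {"analyte": k, "a": v.a, "b": v.b, "c": v.c, "d": v.d,
         "r_squared": v.r_squared, "accepted": v.accepted}
        for k, v in sorted(curves.items())
    ])
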