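"""Weighted calibration curves and quantification limits.

External calibration with 1/x-weighted least squares: the response of each
analyte over the calibration series is fitted as a line or a parabola in
nominal concentration, weighting each non-zero level by the reciprocal of its
concentration so that the relative error is balanced across a range spanning
several orders of magnitude.  Zero-concentration standards are excluded from
the fit (the weight is undefined there); they serve only for noise
estimation.

On top of the fitted curve the module determines:

* LOD — the lowest calibration level with signal-to-noise >= 3;
* LLOQ — the lowest level with S/N >= 10, with a carryover fallback: when
  peak areas fail to grow between consecutive low levels, the LOD is reported
  undetermined and the LLOQ is the lowest level at which the area increases
  by at least a configurable factor over the previous level (and S/N >= 10);
* ULOQ — the largest level such that the fit restricted to [LLOQ, level] has
  r^2 > 0.995 and the back-calculated concentration at that level falls
  within 95-105% of nominal;
* the reference ion ratio — the mean qualifier/quantifier area ratio at three
  representative levels within the linear range.

S/N is defined as apex height above local baseline divided by the standard
deviation of the baseline noise; both quantities are supplied per
measurement (the synthetic generator emits them).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "CalibrationModel",
    "CalibrationResult",
    "CalibrationCurve",
    "fit_calibration",
    "determine_lod_lloq",
    "determine_uloq",
    "ion_ratio",
    "back_calculate",
    "OutOfRangeError",
]

#: Linear fits are kept only when the weighted r^2 reaches this bound;
#: otherwise the quadratic model is selected (also the ULOQ linearity bound).
R2_LINEAR_BOUND = 0.995


class OutOfRangeError(ValueError):
    """Signal area has no admissible back-calculated concentration."""


@dataclass
class CalibrationCurve:
    """A fitted calibration curve with its quantification limits.

    ``coefficients`` are (intercept, slope) for the linear model and
    (intercept, slope, curvature) for the quadratic one.  ``lod`` may be None
    when the carryover fallback applies; ``uloq`` may be None when no level
    passes the linearity/back-calculation test.
    """

    analyte_id: str | None
    model: str  # "linear" | "quadratic"
    coefficients: tuple[float, ...]
    r2: float
    lod: float | None = None
    lloq: float | None = None
    uloq: float | None = None
    included_levels: list[float] = field(default_factory=list)
    ion_ratio_ref: float | None = None

    @property
    def intercept(self) -> float:
        return self.coefficients[0]

    @property
    def slope(self) -> float:
        return self.coefficients[1]

    @property
    def curvature(self) -> float:
        return self.coefficients[2] if len(self.coefficients) > 2 else 0.0

    def predict(self, conc) -> np.ndarray:
        c = np.asarray(conc, dtype=float)
        return self.intercept + self.slope * c + self.curvature * c**2

    def back_calculate(self, area: float, extrapolate: bool = False) -> float:
        return back_calculate(self, area, extrapolate=extrapolate)


class CalibrationModel:
    """1/x-weighted calibration regression for one analyte.

    Parameters
    ----------
    conc : array-like
        Nominal concentrations (µg/L).  Zero levels are dropped from the fit.
    area : array-like
        Peak areas at those concentrations.
    model : {"linear", "quadratic", None}
        Fixed model order, or None to select automatically: linear when its
        weighted r^2 >= 0.995, quadratic otherwise.
    analyte_id : str, optional

    Examples
    --------
    >>> m = CalibrationModel([1, 10, 100], [3, 21, 201])
    >>> res = m.fit()
    >>> round(res.curve.slope, 6)
    2.0
    """

    def __init__(self, conc, area, model: str | None = None, analyte_id: str | None = None):
        conc = np.asarray(conc, dtype=float)
        area = np.asarray(area, dtype=float)
        if conc.shape != area.shape:
            raise ValueError("conc and area must have the same length")
        if np.any(conc < 0):
            raise ValueError("nominal concentrations must be non-negative")
        nz = conc > 0
        self.conc = conc[nz]
        self.area = area[nz]
        if model not in (None, "linear", "quadratic"):
            raise ValueError(f"unknown model {model!r}")
        self.model = model
        self.analyte_id = analyte_id
        n_unique = np.unique(self.conc).size
        min_levels = 4 if model == "quadratic" else 3
        if n_unique < min_levels:
            raise ValueError(
                f"need >= {min_levels} distinct non-zero levels, got {n_unique}"
            )

    def _fit_order(self, order: int):
        x = self.conc
        X = np.column_stack([np.ones_like(x)] + [x**k for k in range(1, order + 1)])
        w = 1.0 / x
        return sm.WLS(self.area, X, weights=w).fit()

    def fit(self) -> "CalibrationResult":
        """Fit the weighted regression; auto-select the order if unspecified."""
        if self.model == "linear":
            res, order = self._fit_order(1), 1
        elif self.model == "quadratic":
            res, order = self._fit_order(2), 2
        else:
            res, order = self._fit_order(1), 1
            if res.rsquared < R2_LINEAR_BOUND and np.unique(self.conc).size >= 4:
                res, order = self._fit_order(2), 2
        curve = CalibrationCurve(
            analyte_id=self.analyte_id,
            model="linear" if order == 1 else "quadratic",
            coefficients=tuple(float(p) for p in res.params),
            r2=float(res.rsquared),
            included_levels=sorted(set(self.conc.tolist())),
        )
        return CalibrationResult(self, res, curve)


class CalibrationResult:
    """Results of a fitted calibration regression.

    Wraps the underlying weighted-least-squares results (``.wls``) and the
    portable :class:`CalibrationCurve` (``.curve``).
    """

    def __init__(self, model: CalibrationModel, wls_results, curve: CalibrationCurve):
        self.model = model
        self.wls = wls_results
        self.curve = curve

    @property
    def params(self) -> np.ndarray:
        return np.asarray(self.wls.params, dtype=float)

    @property
    def bse(self) -> np.ndarray:
        return np.asarray(self.wls.bse, dtype=float)

    @property
    def rsquared(self) -> float:
        return self.curve.r2

    def predict(self, conc) -> np.ndarray:
        return self.curve.predict(conc)

    def back_calculate(self, area: float) -> float:
        return self.curve.back_calculate(area)

    def summary(self) -> str:
        names = ["intercept", "slope", "curvature"][: len(self.curve.coefficients)]
        lines = [
            f"Calibration fit ({self.curve.model}, 1/x weighted)"
            + (f" — {self.curve.analyte_id}" if self.curve.analyte_id else ""),
            f"  levels: {len(self.curve.included_levels)} non-zero "
            f"({min(self.curve.included_levels):g} – {max(self.curve.included_levels):g} µg/L)",
            f"  weighted r²: {self.curve.r2:.6f}",
        ]
        for name, p, se in zip(names, self.params, self.bse):
            lines.append(f"  {name:>10s}: {p: .6g}  (se {se:.3g})")
        for attr in ("lod", "lloq", "uloq"):
            v = getattr(self.curve, attr)
            if v is not None:
                lines.append(f"  {attr.upper():>10s}: {v:g} µg/L")
        if self.curve.ion_ratio_ref is not None:
            lines.append(f"   ion ratio: {self.curve.ion_ratio_ref:.3f}")
        return "\n".join(lines)


def fit_calibration(
    points: Sequence[tuple[float, float]],
    model: str | None = None,
    analyte_id: str | None = None,
) -> CalibrationCurve:
    """Fit a 1/x-weighted calibration curve from (concentration, area) pairs.

    Thin functional wrapper over :class:`CalibrationModel`; returns the
    portable curve object.
    """
    conc = [p[0] for p in points]
    area = [p[1] for p in points]
    return CalibrationModel(conc, area, model=model, analyte_id=analyte_id).fit().curve


# ---------------------------------------------------------------------------
# quantification limits


def determine_lod_lloq(
    series: pd.DataFrame,
    sn_lod: float = 3.0,
    sn_lloq: float = 10.0,
    increase_factor: float = 2.0,
) -> tuple[float | None, float | None]:
    """LOD and LLOQ from a calibration series with S/N information.

    Parameters
    ----------
    series : DataFrame
        One row per non-zero calibration level, ascending in ``level`` with
        columns ``level`` (µg/L), ``area``, ``height`` and ``noise_sd``.
    sn_lod, sn_lloq : float
        S/N bounds for detection (3) and quantification (10).
    increase_factor : float
        Carryover fallback: when areas fail to grow by at least this factor
        between consecutive low levels, the LOD is undetermined and the LLOQ
        is the lowest level with both an area increase >= factor and
        S/N >= ``sn_lloq``.

    Returns
    -------
    (lod, lloq) : floats or None where undetermined.
    """
    levels = np.asarray(series["level"], dtype=float)
    if np.any(np.diff(levels) <= 0):
        raise ValueError("levels must be strictly ascending")
    areas = np.asarray(series["area"], dtype=float)
    height = np.asarray(series["height"], dtype=float)
    noise = np.asarray(series["noise_sd"], dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        sn = np.where(noise > 0, height / noise, np.inf)

    detectable = sn >= sn_lod
    quantifiable = sn >= sn_lloq

    # carryover fallback: look for a stall in area growth among detectable
    # low levels (a blank-level plateau caused by carryover)
    stalled = False
    for i in range(1, len(levels)):
        if detectable[i - 1] and areas[i - 1] > 0 and areas[i] < increase_factor * areas[i - 1]:
            stalled = True
            break
        if detectable[i - 1]:
            # growth resumed before any stall among detectable levels
            break

    if stalled:
        lod = None
        lloq = None
        for i in range(1, len(levels)):
            grew = areas[i - 1] > 0 and areas[i] >= increase_factor * areas[i - 1]
            if grew and quantifiable[i]:
                lloq = float(levels[i])
                break
        return lod, lloq

    lod = float(levels[np.argmax(detectable)]) if detectable.any() else None
    lloq = float(levels[np.argmax(quantifiable)]) if quantifiable.any() else None
    return lod, lloq


def determine_uloq(
    points: Sequence[tuple[float, float]],
    lloq: float,
    model: str | None = None,
    r2_bound: float = R2_LINEAR_BOUND,
    accuracy_band: tuple[float, float] = (0.95, 1.05),
) -> float | None:
    """Upper limit of quantification by descending search from the top level.

    For each candidate top level L (descending), the curve is refitted on the
    levels within [lloq, L]; L is accepted when the restricted fit has
    r^2 > ``r2_bound`` and the back-calculated concentration at L lies within
    ``accuracy_band`` of nominal.  Returns None (undetermined) when no level
    qualifies.
    """
    pts = sorted((float(c), float(a)) for c, a in points if c > 0)
    levels = sorted({c for c, _ in pts})
    candidates = [L for L in levels if L >= lloq]
    for L in reversed(candidates):
        window = [(c, a) for c, a in pts if lloq <= c <= L]
        if len({c for c, _ in window}) < 3:
            continue
        try:
            curve = fit_calibration(window, model=model)
        except ValueError:
            continue
        if curve.r2 <= r2_bound:
            continue
        top_areas = [a for c, a in window if c == L]
        try:
            back = [curve.back_calculate(a) for a in top_areas]
        except OutOfRangeError:
            continue
        ratio = float(np.mean(back)) / L
        if accuracy_band[0] <= ratio <= accuracy_band[1]:
            return L
    return None


def ion_ratio(levels: Sequence[tuple[float, float]]) -> float:
    """Reference ion ratio: mean qualifier/quantifier area ratio over three
    representative calibration levels."""
    if len(levels) < 3:
        raise ValueError("ion ratio requires three representative levels")
    ratios = []
    for qual, quant in levels:
        if quant <= 0:
            raise ValueError("quantifier area must be > 0")
        ratios.append(qual / quant)
    return float(np.mean(ratios))


def back_calculate(
    curve: CalibrationCurve, area: float, extrapolate: bool = False
) -> float:
    """Invert a calibration curve: peak area -> concentration (µg/L).

    Linear curves invert directly; quadratic curves take the root on the
    monotone (pre-vertex, for saturating curvature) branch within
    [0, 1.05 x ULOQ] when an ULOQ is set.  ``extrapolate=True`` drops the
    ULOQ cap (the monotone-branch constraint remains) — used where the raw
    inverse is needed before range censoring is applied, e.g. in recovery
    assessment.

    Raises
    ------
    OutOfRangeError
        When no admissible root exists.
    ValueError
        When the slope is non-positive.
    """
    if curve.slope <= 0:
        raise ValueError("calibration slope must be positive to invert")
    # negligible curvature relative to the slope behaves linearly and the
    # quadratic formula would cancel catastrophically
    if curve.model == "linear" or abs(curve.curvature) < 1e-14 * curve.slope:
        return (area - curve.intercept) / curve.slope

    b, s, i = curve.curvature, curve.slope, curve.intercept
    c0 = i - area
    disc = s * s - 4.0 * b * c0
    if disc < 0:
        raise OutOfRangeError("area beyond the apex of the quadratic curve")
    # numerically stable quadratic roots (avoids subtracting near-equal terms)
    q = -0.5 * (s + math.copysign(math.sqrt(disc), s))
    roots = [q / b, c0 / q]
    upper = (
        curve.uloq * 1.05 if (curve.uloq is not None and not extrapolate) else math.inf
    )
    if b < 0:
        vertex = -s / (2.0 * b)  # response increases up to here
        admissible = [r for r in roots if 0.0 <= r <= min(vertex, upper)]
    else:
        admissible = [r for r in roots if 0.0 <= r <= upper]
    if not admissible:
        raise OutOfRangeError(
            f"no admissible concentration for area {area:g} "
            f"(roots {roots[0]:.4g}, {roots[1]:.4g})"
        )
    return float(min(admissible))
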