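"""Method-validation statistics: carryover, apparent recovery, repeatability.

Carryover is the signal in a pure-solvent blank injected right after a
standard, as a percentage of the standard's signal.  Apparent recovery (R_A)
from standard addition is estimated two ways, mirroring how validated
dilute-and-shoot assays handle linear vs. saturating responses:

* slope ratio — when both the spiked-plasma series and the neat-solvent
  series fit linearly with r^2 > 0.995, R_A is 100 x the ratio of the two
  regression slopes;
* level-wise — otherwise, each spiked measurement is back-calculated through
  the neat-solvent (quadratic) curve and
  ``R_A = 100 x (c_sp - c_NS) / c_A`` per observation, averaged over the
  6 levels x 3 replicates (n = 18).

Repeatability is the RSD (sample standard deviation over mean) of the 18
level-wise recoveries.  Recoveries within 70-130% are acceptable; outside
that band quantification applies a recovery correction, unless the RSD is so
large that the analyte is rejected from the method altogether.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .calibration import (
    R2_LINEAR_BOUND,
    CalibrationCurve,
    fit_calibration,
)

__all__ = [
    "CarryoverResult",
    "RecoveryResult",
    "LinearityError",
    "carryover_pct",
    "apparent_recovery_slope",
    "apparent_recovery_levels",
    "flag_recovery",
    "RECOVERY_ACCEPT_RANGE",
    "DEFAULT_RSD_REJECT",
]

#: Acceptable apparent-recovery band (percent).
RECOVERY_ACCEPT_RANGE = (70.0, 130.0)

#: Default repeatability bound above which an out-of-band recovery is
#: rejected (analyte removed from the method) instead of corrected.
DEFAULT_RSD_REJECT = 25.0


class LinearityError(ValueError):
    """The slope-ratio estimator's linearity precondition is not met."""


@dataclass(frozen=True)
class CarryoverResult:
    analyte_id: str | None
    carryover_pct: float
    reference_level: float | None = None  # µg/L of the standard used
    flag: str = "<1%"


@dataclass
class RecoveryResult:
    """Apparent recovery of one analyte at one dilution."""

    analyte_id: str | None
    dilution: int  # 5 or 100
    estimator: str  # slope_ratio | levelwise_quadratic | single_level
    ra_mean: float  # percent
    ra_per_level: list[float] = field(default_factory=list)
    rsd: float = float("nan")  # percent
    acceptance: str = "accept"  # accept | correct | reject
    c_ns: float | None = None  # native concentration, µg/L
    negative_levels: bool = False


def carryover_pct(
    blank_area: float,
    standard_area: float,
    analyte_id: str | None = None,
    reference_level: float | None = None,
) -> CarryoverResult:
    """Carryover percentage: 100 x blank area / standard area.

    The standard is the 1 mg/L injection, or the highest validation level for
    analytes whose LLOQ exceeds 1 mg/L.  Flag bins are closed on the left:
    [0, 1) -> "<1%", [1, 5) -> "<5%", [5, inf) -> ">=5%".
    """
    if standard_area <= 0:
        raise ValueError("standard area must be > 0")
    pct = 100.0 * blank_area / standard_area
    if pct < 0:
        raise ValueError("blank area must be non-negative")
    flag = "<1%" if pct < 1.0 else ("<5%" if pct < 5.0 else ">=5%")
    return CarryoverResult(
        analyte_id=analyte_id, carryover_pct=pct, reference_level=reference_level, flag=flag
    )


def apparent_recovery_slope(
    spiked_points: Sequence[tuple[float, float]],
    neat_points: Sequence[tuple[float, float]],
    c_ns: float | None = None,
    dilution: int = 5,
    analyte_id: str | None = None,
    r2_bound: float = R2_LINEAR_BOUND,
) -> RecoveryResult:
    """Apparent recovery as the ratio of spiked and neat regression slopes.

    ``spiked_points`` are (spiking concentration c_A, area) pairs from the
    standard-addition series; ``neat_points`` are (concentration, area)
    pairs of the neat-solvent standards over a matching range.  Both series
    must fit linearly with r^2 > ``r2_bound``; otherwise a
    :class:`LinearityError` directs the caller to the level-wise estimator.

    The per-level recoveries (via the level-wise formula with the neat curve)
    are computed alongside for the repeatability RSD.
    """
    spiked = fit_calibration(spiked_points, model="linear", analyte_id=analyte_id)
    neat = fit_calibration(neat_points, model="linear", analyte_id=analyte_id)
    if spiked.r2 <= r2_bound or neat.r2 <= r2_bound:
        raise LinearityError(
            f"linear r² (spiked {spiked.r2:.4f}, neat {neat.r2:.4f}) below "
            f"{r2_bound}; use the level-wise quadratic estimator"
        )
    ra_mean = 100.0 * spiked.slope / neat.slope

    # level-wise recoveries through the neat curve, for the RSD; when the
    # native concentration is not supplied, the spiked series' intercept
    # (area at zero spike) back-calculated through the neat curve serves as
    # the standard-addition estimate of it
    c_sp = [neat.back_calculate(a) for _, a in spiked_points]
    base = c_ns if c_ns is not None else neat.back_calculate(spiked.intercept)
    ra_levels = [100.0 * (s - base) / c for (c, _), s in zip(spiked_points, c_sp)]
    rsd = _rsd(ra_levels)
    result = RecoveryResult(
        analyte_id=analyte_id,
        dilution=dilution,
        estimator="slope_ratio",
        ra_mean=ra_mean,
        ra_per_level=ra_levels,
        rsd=rsd,
        c_ns=base,
        negative_levels=any(r < 0 for r in ra_levels),
    )
    result.acceptance = flag_recovery(result.ra_mean, result.rsd)
    return result


def apparent_recovery_levels(
    c_sp_list: Sequence[float],
    c_ns: float,
    c_a_list: Sequence[float],
    dilution: int = 5,
    analyte_id: str | None = None,
    single_level: bool = False,
) -> RecoveryResult:
    """Level-wise apparent recovery: R_A = 100 x (c_sp - c_NS) / c_A.

    ``c_sp_list`` are the concentrations measured in the spiked samples
    (back-calculated through neat-solvent curves), ``c_ns`` the concentration
    of the unspiked sample and ``c_a_list`` the spiking concentration of each
    observation.  Negative recoveries are retained (not truncated) so the
    RSD reflects the raw spread.
    """
    if len(c_sp_list) != len(c_a_list):
        raise ValueError("c_sp_list and c_a_list must have equal length")
    if any(c <= 0 for c in c_a_list):
        raise ValueError("spiking concentrations must be > 0")
    ras = [100.0 * (sp - c_ns) / ca for sp, ca in zip(c_sp_list, c_a_list)]
    estimator = "single_level" if single_level else "levelwise_quadratic"
    result = RecoveryResult(
        analyte_id=analyte_id,
        dilution=dilution,
        estimator=estimator,
        ra_mean=float(np.mean(ras)),
        ra_per_level=ras,
        rsd=_rsd(ras),
        c_ns=c_ns,
        negative_levels=any(r < 0 for r in ras),
    )
    result.acceptance = flag_recovery(result.ra_mean, result.rsd)
    return result


def flag_recovery(
    ra_mean: float,
    rsd: float = float("nan"),
    accept_range: tuple[float, float] = RECOVERY_ACCEPT_RANGE,
    rsd_reject: float = DEFAULT_RSD_REJECT,
) -> str:
    """Acceptance verdict for a mean apparent recovery.

    "accept" within 70-130%; outside that band "correct" (quantification
    divides by R_A/100), escalated to "reject" when the recovery is also
    erratic (RSD above ``rsd_reject``), i.e. the analyte cannot be reliably
    corrected and is removed from the method.
    """
    if not np.isfinite(ra_mean):
        raise ValueError("ra_mean must be finite")
    lo, hi = accept_range
    if lo <= ra_mean <= hi:
        return "accept"
    if np.isfinite(rsd) and rsd > rsd_reject:
        return "reject"
    return "correct"


def _rsd(values: Sequence[float]) -> float:
    """Percent RSD with the sample (n-1) standard deviation."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        return float("nan")
    mean = arr.mean()
    if mean == 0:
        return float("inf")
    return float(100.0 * arr.std(ddof=1) / mean)
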