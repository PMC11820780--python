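"""From peak areas of unknown samples to reported plasma concentrations.

The reporting chain for a dilute-and-shoot assay measuring every sample at
two dilutions (1:5 and 1:100):

1. drift correction — divide areas by a multiplicative drift factor
   interpolated over the injection index, anchored either on bracketing
   calibration slopes or on repeated pooled-QC injections;
2. back-calculation through the analyte's calibration curve at each
   dilution, with censoring against LLOQ/ULOQ;
3. dilution selection — the most dilute measurement within the quantifiable
   range wins (dilution minimizes matrix effects); compound classes known to
   fall below the LLOQ at 1:100 can be pinned to the 1:5 route;
4. recovery correction — when the matching dilution's apparent recovery is
   outside 70-130%, the concentration is corrected as c x 100 / R_A;
5. ion-ratio confirmation — the observed qualifier/quantifier ratio must
   match the reference within a relative tolerance (default 30%);
6. isomer deconvolution — a component quantified only as part of a sum
   (e.g. leucine from the leucine+isoleucine transition) is the sum minus
   the uniquely quantified partner, censored at zero;
7. trueness — measured vs. certified concentrations as integer percentages,
   counting how many analytes fall within 70-130%.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import round_half_away
from .calibration import CalibrationCurve, OutOfRangeError
from .validation import RECOVERY_ACCEPT_RANGE, RecoveryResult

__all__ = [
    "QuantResult",
    "TruenessReport",
    "drift_correct",
    "check_ion_ratio",
    "quantify_sample",
    "deconvolute_isomers",
    "combine_duplicates",
    "trueness_report",
    "LOW_ABUNDANCE_CLASSES",
]

#: Compound classes pinned to the 1:5 dilution: at 1:100 their plasma
#: concentrations fall below the LLOQ, so only the less dilute route is
#: reliable.
LOW_ABUNDANCE_CLASSES = frozenset(
    {"carboxylic acids", "eicosanoids", "ethanolamides", "nucleotides", "sugars"}
)


@dataclass
class QuantResult:
    """Reported concentration of one analyte in one sample."""

    sample_id: str | None
    analyte_id: str | None
    concentration: float | None  # µg/L in plasma (None when censored)
    dilution_used: int | None  # 5 or 100
    censoring: str = "quantified"  # quantified | <LLOQ | >ULOQ
    recovery_corrected: bool = False
    ion_ratio_observed: float | None = None
    ion_ratio_pass: str = "not evaluable"  # pass | fail | not evaluable
    drift_corrected: bool = False
    advisory: str | None = None


@dataclass
class TruenessReport:
    """Per-analyte trueness percentages against certified values."""

    table: pd.DataFrame  # analyte, certified_ugL, measured_ugL, trueness_pct
    n_evaluable: int
    n_within: int  # trueness in [70, 130]
    within_range: tuple[float, float] = (70.0, 130.0)


# ---------------------------------------------------------------------------


def drift_correct(
    areas_by_injection: pd.DataFrame,
    anchors: pd.DataFrame,
    mode: str = "qc",
) -> pd.DataFrame:
    """Correct multiplicative instrument drift over a sequence.

    Parameters
    ----------
    areas_by_injection : DataFrame
        Long table with at least ``injection_index``, ``analyte_id`` and
        ``area`` columns; returned with ``area`` replaced by the corrected
        value and a ``drift_factor`` column appended.
    anchors : DataFrame
        ``mode="qc"``: columns ``injection_index``, ``analyte_id``, ``area``
        of repeated pooled-QC injections; the relative response at each QC
        (area / first QC area, per analyte) is interpolated piecewise
        linearly in injection index.
        ``mode="bracket"``: columns ``injection_index``, ``analyte_id``,
        ``slope`` of the bracketing calibration fits (two or more rows per
        analyte); the relative response factor interpolates the slopes.
    """
    if mode not in ("qc", "bracket"):
        raise ValueError(f"unknown drift-correction mode {mode!r}")
    value_col = "area" if mode == "qc" else "slope"
    if anchors.groupby("analyte_id")["injection_index"].count().min() < 2:
        raise ValueError("drift correction needs at least 2 anchors per analyte")

    out = areas_by_injection.copy()
    out["drift_factor"] = 1.0
    for aid, grp in anchors.groupby("analyte_id"):
        grp = grp.sort_values("injection_index")
        ref = grp[value_col].iloc[0]
        if ref <= 0:
            raise ValueError(f"anchor response for {aid} must be positive")
        rel = grp[value_col] / ref
        mask = out["analyte_id"] == aid
        factors = np.interp(
            out.loc[mask, "injection_index"].astype(float),
            grp["injection_index"].astype(float),
            rel.astype(float),
        )
        out.loc[mask, "drift_factor"] = factors
        out.loc[mask, "area"] = out.loc[mask, "area"] / factors
    return out


def check_ion_ratio(
    observed: float | None,
    reference: float | None,
    tolerance_rel: float = 0.30,
) -> str:
    """Confirm compound identity from the qualifier/quantifier area ratio.

    Pass iff |observed - reference| <= tolerance_rel x reference.  Returns
    "pass", "fail" or "not evaluable" (missing qualifier, e.g. a
    single-transition analyte).
    """
    if observed is None or reference is None:
        return "not evaluable"
    if reference <= 0:
        raise ValueError("reference ion ratio must be > 0")
    return "pass" if abs(observed - reference) <= tolerance_rel * reference else "fail"


def quantify_sample(
    areas: Mapping[int, float],
    curve: CalibrationCurve,
    recovery: Mapping[int, RecoveryResult] | None = None,
    qualifier_areas: Mapping[int, float] | None = None,
    sample_id: str | None = None,
    prefer_least_dilute: bool = False,
    ion_ratio_tolerance: float = 0.30,
) -> QuantResult:
    """Quantify one analyte in one sample measured at several dilutions.

    Parameters
    ----------
    areas : mapping dilution factor -> quantifier peak area
        Typically ``{5: ..., 100: ...}`` (drift-corrected).
    curve : CalibrationCurve
        Fitted neat-solvent curve with lloq/uloq set.
    recovery : mapping dilution factor -> RecoveryResult, optional
        Apparent recoveries per dilution; the matching dilution's R_A drives
        the correction when outside 70-130%.
    qualifier_areas : mapping dilution factor -> qualifier area, optional
    prefer_least_dilute : bool
        Pin low-abundance compound classes to the least dilute in-range
        measurement (maximizes S/N) instead of the default most-dilute rule.

    Censoring: when no dilution lands within [LLOQ, ULOQ], the result is
    ">ULOQ" if even the most dilute measurement exceeds the ULOQ (with an
    advisory that a higher dilution is required) and "<LLOQ" if the least
    dilute falls below the LLOQ.
    """
    if curve is None:
        raise ValueError(f"missing calibration curve for analyte of sample {sample_id!r}")
    if curve.lloq is None:
        raise ValueError("curve needs an LLOQ to censor against")
    dilutions = sorted(areas)  # ascending: least dilute first
    measured: dict[int, float | None] = {}
    for d in dilutions:
        try:
            measured[d] = curve.back_calculate(areas[d])
        except OutOfRangeError:
            measured[d] = None  # beyond the invertible branch: above range

    uloq = curve.uloq if curve.uloq is not None else float("inf")
    in_range = [
        d
        for d in dilutions
        if measured[d] is not None and curve.lloq <= measured[d] <= uloq
    ]

    def _finish(d: int | None, conc: float | None, censoring: str, advisory=None) -> QuantResult:
        observed_ratio = None
        if qualifier_areas is not None and d is not None and areas.get(d, 0) > 0:
            observed_ratio = qualifier_areas.get(d, None)
            if observed_ratio is not None:
                observed_ratio = observed_ratio / areas[d]
        verdict = check_ion_ratio(observed_ratio, curve.ion_ratio_ref, ion_ratio_tolerance)
        corrected = False
        if conc is not None and recovery and d in recovery:
            ra = recovery[d].ra_mean
            lo, hi = RECOVERY_ACCEPT_RANGE
            if not (lo <= ra <= hi):
                conc = conc * 100.0 / ra
                corrected = True
        return QuantResult(
            sample_id=sample_id,
            analyte_id=curve.analyte_id,
            concentration=conc,
            dilution_used=d,
            censoring=censoring,
            recovery_corrected=corrected,
            ion_ratio_observed=observed_ratio,
            ion_ratio_pass=verdict,
            advisory=advisory,
        )

    if in_range:
        d = in_range[0] if prefer_least_dilute else in_range[-1]
        return _finish(d, measured[d] * d, "quantified")

    d_top = dilutions[-1]
    top_above = measured[d_top] is None or measured[d_top] > uloq
    if top_above:
        return _finish(
            None,
            None,
            ">ULOQ",
            advisory=(
                f"above ULOQ even at 1:{d_top}; a higher dilution "
                f"(e.g. 1:{d_top * 5}) is required"
            ),
        )
    return _finish(None, None, "<LLOQ")


def deconvolute_isomers(
    sum_result: QuantResult | float,
    unique_result: QuantResult | float,
) -> tuple[float | None, str]:
    """Component concentration from a sum transition minus the unique partner.

    For co-eluting isomers where one compound has a unique transition (e.g.
    isoleucine) and the pair shares a sum transition, the other component
    (leucine) is sum - unique.  Negative differences are censored at 0 with a
    flag.  Returns ``(concentration, flag)`` where flag is "ok",
    "negative_difference" or "not evaluable".
    """

    def _value(r):
        if isinstance(r, QuantResult):
            return r.concentration if r.censoring == "quantified" else None
        return float(r)

    s, u = _value(sum_result), _value(unique_result)
    if s is None or u is None:
        return None, "not evaluable"
    diff = s - u
    if diff < 0:
        return 0.0, "negative_difference"
    return diff, "ok"


def combine_duplicates(first: QuantResult, second: QuantResult) -> QuantResult:
    """Merge the duplicate randomized measurements of one sample/analyte.

    Both quantified: concentrations are averaged.  Disagreeing censoring
    classes: the quantified result wins, with an advisory recording the
    disagreement.  Both censored: the first verdict is kept.
    """
    a_q = first.censoring == "quantified"
    b_q = second.censoring == "quantified"
    if a_q and b_q:
        merged = QuantResult(**vars(first))
        merged.concentration = 0.5 * (first.concentration + second.concentration)
        return merged
    if a_q != b_q:
        winner = first if a_q else second
        loser = second if a_q else first
        merged = QuantResult(**vars(winner))
        merged.advisory = (
            f"duplicate disagreement: partner injection was {loser.censoring}"
        )
        return merged
    return first


def trueness_report(
    measured: Sequence[float] | pd.Series,
    certified: Sequence[float] | pd.Series,
    analytes: Sequence[str] | None = None,
    within_range: tuple[float, float] = (70.0, 130.0),
) -> TruenessReport:
    """Trueness against certified reference concentrations.

    Per analyte, trueness = round(100 x measured / certified) with ties away
    from zero (matching printed reference tables).  Analytes without a
    measured value (below the detection limit) are excluded from the
    evaluable count.  The summary counts trueness values inside
    ``within_range``.
    """
    measured = np.asarray(measured, dtype=float)
    certified = np.asarray(certified, dtype=float)
    if measured.shape != certified.shape:
        raise ValueError("measured and certified must have equal length")
    if np.any(certified <= 0):
        raise ValueError("certified concentrations must be > 0")
    trueness = np.array(
        [
            round_half_away(100.0 * m / c) if np.isfinite(m) else np.nan
            for m, c in zip(measured, certified)
        ]
    )
    table = pd.DataFrame(
        {
            "analyte": analytes if analytes is not None else np.arange(len(measured)),
            "certified_ugL": certified,
            "measured_ugL": measured,
            "trueness_pct": trueness,
        }
    )
    evaluable = np.isfinite(trueness)
    lo, hi = within_range
    within = evaluable & (trueness >= lo) & (trueness <= hi)
    return TruenessReport(
        table=table,
        n_evaluable=int(evaluable.sum()),
        n_within=int(within.sum()),
        within_range=within_range,
    )
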