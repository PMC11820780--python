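"""End-to-end wiring: peak-area tables -> curves -> recoveries -> results.

The lower-level modules operate on single analytes and explicit inputs; this
module runs them over the long-format peak table the synthetic generator (or
an exported instrument table with the same columns) produces:

``sample_id, injection_index, role, dilution_factor, analyte_id, transition,
area, height, noise_sd, nominal_ugL, spike_level, replicate``
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .calibration import (
    CalibrationCurve,
    determine_lod_lloq,
    determine_uloq,
    fit_calibration,
    ion_ratio,
)
from .quantify import QuantResult, combine_duplicates, drift_correct, quantify_sample
from .synthetic import SpikingDesign
from .validation import (
    LinearityError,
    RecoveryResult,
    apparent_recovery_levels,
    apparent_recovery_slope,
)

__all__ = [
    "fit_curves",
    "bracket_drift_correct",
    "estimate_recoveries",
    "quantify_run",
]


def _standards(table: pd.DataFrame, bracket: str | None = None) -> pd.DataFrame:
    std = table[(table["role"] == "standard") & (table["transition"] == "quantifier")]
    if bracket is not None:
        std = std[std["sample_id"].str.contains(f"cal_{bracket}_")]
    return std


def fit_curves(
    table: pd.DataFrame,
    bracket: str | None = None,
    model: str | None = None,
) -> dict[str, CalibrationCurve]:
    """Fit per-analyte calibration curves from the calibration standards.

    By default both brackets contribute (two injections per level, assuming
    drift-corrected areas); pass ``bracket="start"`` or ``"end"`` to restrict
    to one.  Determines LOD/LLOQ from S/N, the ULOQ by descending search, and
    the reference ion ratio from three mid-range levels.
    """
    std = _standards(table, bracket)
    qual = table[
        (table["role"] == "standard") & (table["transition"] == "qualifier")
    ]
    if bracket is not None:
        qual = qual[qual["sample_id"].str.contains(f"cal_{bracket}_")]
    curves: dict[str, CalibrationCurve] = {}
    for aid, grp in std.groupby("analyte_id"):
        grp = grp.sort_values("nominal_ugL")
        nz = grp[grp["nominal_ugL"] > 0]
        # S/N series: average replicate injections of each level
        per_level = (
            nz.groupby("nominal_ugL")[["area", "height", "noise_sd"]]
            .mean()
            .reset_index()
        )
        series = pd.DataFrame(
            {
                "level": per_level["nominal_ugL"].to_numpy(),
                "area": per_level["area"].to_numpy(),
                "height": per_level["height"].to_numpy(),
                "noise_sd": per_level["noise_sd"].to_numpy(),
            }
        )
        lod, lloq = determine_lod_lloq(series)
        points = list(zip(nz["nominal_ugL"], nz["area"]))
        if lloq is None:
            continue  # not quantifiable: no curve reported
        fit_points = [(c, a) for c, a in points if c >= lloq]
        curve = fit_calibration(fit_points, model=model, analyte_id=aid)
        curve.lod, curve.lloq = lod, lloq
        curve.uloq = determine_uloq(fit_points, lloq, model=model)

        qgrp = qual[qual["analyte_id"] == aid].sort_values("nominal_ugL")
        merged = nz.merge(
            qgrp[["nominal_ugL", "area"]],
            on="nominal_ugL",
            suffixes=("", "_qual"),
        )
        in_linear = merged[
            (merged["nominal_ugL"] >= lloq)
            & (merged["nominal_ugL"] <= (curve.uloq or merged["nominal_ugL"].max()))
        ]
        if len(in_linear) >= 3:
            mid = in_linear.iloc[
                np.linspace(0, len(in_linear) - 1, 3).round().astype(int)
            ]
            curve.ion_ratio_ref = ion_ratio(
                list(zip(mid["area_qual"], mid["area"]))
            )
        curves[aid] = curve
    return curves


def bracket_drift_correct(table: pd.DataFrame) -> pd.DataFrame:
    """Drift-correct a sequence using its start/end calibration brackets.

    Fits the linear calibration slope in each bracket per analyte and divides
    areas by the slope ratio interpolated over the injection index.
    """
    anchors = []
    for tag in ("start", "end"):
        std = _standards(table, tag)
        for aid, grp in std.groupby("analyte_id"):
            nz = grp[grp["nominal_ugL"] > 0]
            curve = fit_calibration(
                list(zip(nz["nominal_ugL"], nz["area"])), model="linear", analyte_id=aid
            )
            # The fitted slope of a drifting bracket reflects the drift at an
            # effective injection index: for a multiplicative drift linear in
            # index, slope_meas = slope_true * drift(eff) with
            # eff = sum_i k_i * inj_i * response_i / slope, where k is the
            # slope row of the WLS influence matrix (X'WX)^-1 X'W.  Anchoring
            # there (instead of at the bracket midpoint) makes the
            # interpolation exact for linear drift.
            c = nz["nominal_ugL"].to_numpy(float)
            inj = nz["injection_index"].to_numpy(float)
            X = np.column_stack([np.ones_like(c), c])
            W = 1.0 / c
            k = np.linalg.solve(X.T @ (W[:, None] * X), (X * W[:, None]).T)[1]
            response = curve.intercept + curve.slope * c
            eff = float(np.sum(k * inj * response) / curve.slope)
            anchors.append(
                {
                    "analyte_id": aid,
                    "injection_index": eff,
                    "slope": curve.slope,
                }
            )
    return drift_correct(table, pd.DataFrame(anchors), mode="bracket")


def estimate_recoveries(
    table: pd.DataFrame,
    curves: Mapping[str, CalibrationCurve],
    designs: Mapping[str, SpikingDesign],
    dilutions: tuple[int, ...] = (5, 100),
) -> dict[tuple[str, int], RecoveryResult]:
    """Standard-addition apparent recoveries per analyte and dilution.

    Tries the slope-ratio estimator first (both the spiked series and the
    neat standards over the matching range linear with r^2 > 0.995), falling
    back to the level-wise estimator through the neat curve.
    """
    results: dict[tuple[str, int], RecoveryResult] = {}
    spiked = table[(table["role"] == "spiked") & (table["transition"] == "quantifier")]
    unspiked = table[
        (table["role"] == "unspiked") & (table["transition"] == "quantifier")
    ]
    std = _standards(table)
    for aid, design in designs.items():
        curve = curves.get(aid)
        if curve is None:
            continue
        for d in dilutions:
            sp = spiked[
                (spiked["analyte_id"] == aid) & (spiked["dilution_factor"] == d)
            ]
            if sp.empty:
                continue
            c_a = np.array([design.levels[int(i)] for i in sp["spike_level"]]) / d
            spiked_points = list(zip(c_a, sp["area"]))

            uns = unspiked[
                (unspiked["analyte_id"] == aid)
                & (unspiked["dilution_factor"] == d)
            ]
            c_ns = (
                float(np.mean([curve.back_calculate(a, extrapolate=True) for a in uns["area"]]))
                if not uns.empty
                else None
            )

            neat = std[std["analyte_id"] == aid]
            lo, hi = c_a.min() * 0.3, c_a.max() * 3.0
            neat_window = neat[(neat["nominal_ugL"] >= lo) & (neat["nominal_ugL"] <= hi)]
            if len(neat_window) < 3:
                neat_window = neat[neat["nominal_ugL"] > 0]
            neat_points = list(zip(neat_window["nominal_ugL"], neat_window["area"]))

            # estimator selection keys on the analyte's response type: a
            # linear calibration model takes the slope-ratio route (robust to
            # measurement noise and to the native-concentration estimate);
            # quadratic responders use the level-wise formula with
            # back-calculation through the neat curve
            single = design.mode == "single_level"
            if not single and curve.model == "linear":
                try:
                    results[(aid, d)] = apparent_recovery_slope(
                        spiked_points,
                        neat_points,
                        c_ns=c_ns,
                        dilution=d,
                        analyte_id=aid,
                        r2_bound=0.0,
                    )
                    continue
                except LinearityError:  # pragma: no cover - r2_bound 0 never trips
                    pass
            c_sp = [curve.back_calculate(a, extrapolate=True) for a in sp["area"]]
            results[(aid, d)] = apparent_recovery_levels(
                c_sp,
                c_ns if c_ns is not None else 0.0,
                list(c_a),
                dilution=d,
                analyte_id=aid,
                single_level=single,
            )
    return results


def quantify_run(
    table: pd.DataFrame,
    curves: Mapping[str, CalibrationCurve],
    recoveries: Mapping[tuple[str, int], RecoveryResult] | None = None,
    low_abundance_analytes: frozenset[str] = frozenset(),
) -> pd.DataFrame:
    """Quantify every (sample, analyte) of the unknown samples in a run.

    Duplicate injections (replicates 0 and 1 of each sample id) are combined
    after censoring resolution.  Returns one row per sample x analyte with
    the :class:`~srmquant.quantify.QuantResult` fields.
    """
    samples = table[table["role"] == "sample"]
    rows = []
    for (sid, aid), grp in samples.groupby(["sample_id", "analyte_id"]):
        curve = curves.get(aid)
        if curve is None:
            continue
        rec = (
            {d: recoveries[(aid, d)] for d in (5, 100) if (aid, d) in recoveries}
            if recoveries
            else None
        )
        per_replicate: list[QuantResult] = []
        for rep, rgrp in grp.groupby("replicate"):
            quant = rgrp[rgrp["transition"] == "quantifier"]
            qual = rgrp[rgrp["transition"] == "qualifier"]
            areas = {
                int(r.dilution_factor): r.area for r in quant.itertuples(index=False)
            }
            qual_areas = {
                int(r.dilution_factor): r.area for r in qual.itertuples(index=False)
            }
            per_replicate.append(
                quantify_sample(
                    areas,
                    curve,
                    recovery=rec,
                    qualifier_areas=qual_areas or None,
                    sample_id=str(sid),
                    prefer_least_dilute=aid in low_abundance_analytes,
                )
            )
        result = per_replicate[0]
        for other in per_replicate[1:]:
            result = combine_duplicates(result, other)
        rows.append(
            {
                "sample_id": sid,
                "analyte_id": aid,
                "concentration_ugL": result.concentration,
                "dilution_used": result.dilution_used,
                "censoring": result.censoring,
                "recovery_corrected": result.recovery_corrected,
                "ion_ratio_pass": result.ion_ratio_pass,
                "advisory": result.advisory,
            }
        )
    return pd.DataFrame(rows)
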