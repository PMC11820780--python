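"""Synthetic peak-area tables with the statistical structure the analysis assumes.

The generator stands in for the instrument: it maps nominal concentrations
through a per-analyte response curve (linear or saturating quadratic),
applies per-dilution matrix-effect factors, multiplicative lognormal
measurement noise (constant CV), additive baseline noise, carryover of a
fraction of the previous injection's signal into following blanks, and a
slow multiplicative drift over the injection index.  Ground truth is kept
alongside so parameter-recovery tests can compare estimates with the values
that generated the data.

What this emulates — and what it does not: areas, heights and baseline-noise
estimates are drawn directly from the response model; there is no
chromatographic peak shape, no retention-time variability and no ionization
physics.  Passing tests therefore demonstrate the statistical machinery, not
robustness to peak-integration artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ResponseModel",
    "SpikingDesign",
    "SyntheticTruth",
    "VALIDATION_LEVELS_UGL",
    "WORKING_RANGE_UGL",
    "build_calibration_series",
    "build_spiking_design",
    "plan_validation_sequence",
    "simulate_peak_table",
    "make_truth",
]

#: The 14-level validation grid (µg/L): 0, 0.0001 ... 50 mg/L.
VALIDATION_LEVELS_UGL = [
    0.0, 0.1, 0.3, 1.0, 3.0, 10.0, 30.0, 100.0, 300.0,
    1_000.0, 3_000.0, 10_000.0, 25_000.0, 50_000.0,
]

#: Working calibration ranges (µg/L) of the three standard sets.
WORKING_RANGE_UGL = {
    "HILIC": (0.03, 25_000.0),
    "RP_Aqu": (0.1, 50_000.0),
    "RP_Hep": (0.1, 50_000.0),
}

#: Standard-addition multipliers: levels relative to the native concentration
#: of a detected analyte, or to the LLOQ of an undetected one.
NATIVE_MULTIPLIERS = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0)
LLOQ_MULTIPLIERS = (12.5, 25.0, 37.5, 50.0, 62.5, 75.0)


def build_calibration_series(calibration_set: str, grid: str = "validation") -> list[float]:
    """Nominal calibration levels (µg/L) for a standard set.

    ``grid="validation"`` returns the fixed 14-level series used to establish
    LOD/LLOQ/ULOQ (identical for all three sets).  ``grid="working"``
    returns a 7-level series geometrically spaced over the set's working
    range (lowest 0.03 µg/L for HILIC, 0.1 µg/L for the RP sets; highest
    25,000 and 50,000 µg/L respectively), plus the zero level.
    """
    if calibration_set not in WORKING_RANGE_UGL:
        raise ValueError(
            f"unknown calibration set {calibration_set!r}; "
            f"expected one of {sorted(WORKING_RANGE_UGL)}"
        )
    if grid == "validation":
        return list(VALIDATION_LEVELS_UGL)
    if grid == "working":
        lo, hi = WORKING_RANGE_UGL[calibration_set]
        levels = np.geomspace(lo, hi, 7)
        return [0.0] + [float(x) for x in levels]
    raise ValueError(f"unknown grid {grid!r}; expected 'validation' or 'working'")


@dataclass(frozen=True)
class SpikingDesign:
    """A standard-addition design: spiking levels (µg/L, plasma scale)."""

    analyte_id: str
    mode: str  # "native" | "lloq_based" | "single_level"
    levels: tuple[float, ...]
    replicates: int = 3

    @property
    def n(self) -> int:
        return len(self.levels) * self.replicates


def build_spiking_design(
    analyte_id: str,
    native_conc: float | None = None,
    lloq: float | None = None,
    single_level: bool = False,
) -> SpikingDesign:
    """Spiking design for one analyte.

    Detected analytes are spiked at 0.5-3x their predetermined native
    concentration; undetected ones at 12.5-75x the LLOQ (in pure solvent).
    ``single_level=True`` keeps only the highest level (used for poorly
    soluble compounds where only one high spike is feasible).  Exactly one of
    ``native_conc`` / ``lloq`` must be given.
    """
    if (native_conc is None) == (lloq is None):
        raise ValueError("provide exactly one of native_conc or lloq")
    if native_conc is not None:
        if native_conc <= 0:
            raise ValueError(
                "native_conc must be > 0; for analytes undetected in plasma "
                "use the lloq-based design (pass lloq=...)"
            )
        levels = tuple(m * native_conc for m in NATIVE_MULTIPLIERS)
        mode = "native"
    else:
        if lloq <= 0:
            raise ValueError("lloq must be > 0")
        levels = tuple(m * lloq for m in LLOQ_MULTIPLIERS)
        mode = "lloq_based"
    if single_level:
        levels = (levels[-1],)
        mode = "single_level"
    return SpikingDesign(analyte_id=analyte_id, mode=mode, levels=levels)


@dataclass
class ResponseModel:
    """True instrument response of one analyte.

    area = drift(i) * matrix_factor[dilution] * (a*c + b*c^2) * LN(1, rsd)
           + N(0, baseline_noise_sd),   floored at 0,

    where c is the concentration in the measurement solution (µg/L).
    ``matrix_factor`` maps dilution factor -> true apparent recovery / 100
    (neat solutions use factor 1).  ``ion_ratio`` scales the qualifier
    transition relative to the quantifier.
    """

    analyte_id: str
    slope: float  # area per (µg/L)
    curvature: float = 0.0  # area per (µg/L)^2, <= 0 for saturation
    baseline_noise_sd: float = 0.0
    measurement_rsd: float = 0.0
    matrix_factor: Mapping[int, float] = field(default_factory=lambda: {5: 1.0, 100: 1.0})
    carryover_fraction: float = 0.0
    ion_ratio: float = 0.5

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("slope must be > 0")
        if not 0.0 <= self.carryover_fraction < 1.0:
            raise ValueError("carryover_fraction must lie in [0, 1)")
        if self.measurement_rsd < 0:
            raise ValueError("measurement_rsd must be >= 0")
        if any(f <= 0 for f in self.matrix_factor.values()):
            raise ValueError("matrix factors must be > 0")

    def response(self, conc: float) -> float:
        return self.slope * conc + self.curvature * conc * conc


@dataclass
class SyntheticTruth:
    """Everything needed to generate — and later score — a synthetic run."""

    models: dict[str, ResponseModel]
    native_conc: dict[str, float]  # µg/L in plasma
    spiking_designs: dict[str, SpikingDesign] = field(default_factory=dict)
    drift_start: float = 1.0
    drift_end: float = 0.8
    seed: int = 0

    def drift(self, index: int, n_injections: int) -> float:
        """Multiplicative drift, piecewise linear in injection index."""
        if n_injections <= 1:
            return self.drift_start
        frac = index / (n_injections - 1)
        return self.drift_start + (self.drift_end - self.drift_start) * frac

    def spike_amount(self, analyte_id: str, level_index: int) -> float:
        """Spiking concentration (µg/L, plasma scale) for one design level."""
        design = self.spiking_designs.get(analyte_id)
        if design is None:
            design = build_spiking_design(analyte_id, native_conc=self.native_conc[analyte_id])
        return design.levels[level_index]


def make_truth(
    analyte_ids: Sequence[str],
    seed: int = 0,
    matrix_factor_range: tuple[float, float] = (0.5, 1.3),
    dilution_attenuation: float = 0.25,
    measurement_rsd: float = 0.05,
    native_range: tuple[float, float] = (2_000.0, 20_000.0),
    slope_range: tuple[float, float] = (500.0, 2_000.0),
    carryover_range: tuple[float, float] = (0.0, 0.02),
    drift_end: float = 0.8,
) -> SyntheticTruth:
    """Draw a ground-truth parameter set for a panel of analytes.

    Defaults mirror the validated assay's conditions: native plasma
    concentrations log-uniform in 2-20 mg/L (so the 1:100 dilution stays
    above typical LLOQs), 5% multiplicative measurement noise, per-analyte
    1:5 matrix factors uniform in [0.5, 1.3], and 1:100 factors pulled
    toward 1 by ``dilution_attenuation`` (the 1:100 deviation is 25% of the
    1:5 deviation), emulating the observation that dilution reduces matrix
    effects.  Baseline noise is set so typical low-level S/N limits
    quantification near 1 µg/L.
    """
    rng = np.random.default_rng(seed)
    models: dict[str, ResponseModel] = {}
    native: dict[str, float] = {}
    for aid in analyte_ids:
        slope = float(rng.uniform(*slope_range))
        f5 = float(rng.uniform(*matrix_factor_range))
        f100 = 1.0 + dilution_attenuation * (f5 - 1.0)
        models[aid] = ResponseModel(
            analyte_id=aid,
            slope=slope,
            curvature=0.0,
            baseline_noise_sd=slope * 0.3,  # S/N ~ 3 near 1 µg/L
            measurement_rsd=measurement_rsd,
            matrix_factor={5: f5, 100: f100},
            carryover_fraction=float(rng.uniform(*carryover_range)),
            ion_ratio=float(rng.uniform(0.2, 0.9)),
        )
        lo, hi = native_range
        native[aid] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    return SyntheticTruth(models=models, native_conc=native, drift_end=drift_end, seed=seed)


# ---------------------------------------------------------------------------
# sequence planning


def plan_validation_sequence(
    analyte_ids: Sequence[str],
    include_spiking: bool = True,
    n_spike_levels: int = 6,
    spike_replicates: int = 3,
    sample_ids: Sequence[str] = (),
    levels: Sequence[float] = tuple(VALIDATION_LEVELS_UGL),
    dilutions: Sequence[int] = (5, 100),
    qc_every: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Ordered injection plan for a validation run.

    The plan brackets the sequence with the full calibration series at the
    start and end, inserts a pure-solvent blank immediately after the 1 mg/L
    standard (for carryover assessment) and after the top standard, injects
    pooled-QC samples every ``qc_every`` injections, runs the spiked
    standard-addition samples plus the unspiked plasma at each dilution, and
    measures unknown samples in duplicate in a seeded randomized order.

    Spiked rows carry a ``spike_level`` index rather than a concentration:
    each analyte has its own spiking levels, resolved at simulation time via
    :meth:`SyntheticTruth.spike_amount`.

    Returns a DataFrame with columns ``sample_id, role, dilution_factor,
    nominal_ugL, spike_level, replicate``; the injection index is the row
    order.  Roles: standard, blank, qc, unspiked, spiked, sample.
    """
    rng = np.random.default_rng(seed)
    rows: list[dict] = []

    def add(sample_id, role, dilution=np.nan, nominal=np.nan, spike_level=-1, replicate=0):
        rows.append(
            {
                "sample_id": sample_id,
                "role": role,
                "dilution_factor": dilution,
                "nominal_ugL": nominal,
                "spike_level": spike_level,
                "replicate": replicate,
            }
        )

    def add_calibration(tag: str) -> None:
        top = max(levels)
        for lvl in levels:
            add(f"cal_{tag}_{lvl:g}", "standard", nominal=lvl)
            if lvl in (1_000.0, top) and lvl > 0:
                add(f"blank_after_{tag}_{lvl:g}", "blank")

    add_calibration("start")

    body: list[tuple] = []
    if include_spiking:
        for d in dilutions:
            for rep in range(spike_replicates):
                body.append(("unspiked_qc", "unspiked", d, np.nan, -1, rep))
        for li in range(n_spike_levels):
            for rep in range(spike_replicates):
                for d in dilutions:
                    body.append((f"spike_L{li}_r{rep}", "spiked", d, np.nan, li, rep))
    duplicated = [(sid, rep) for sid in sample_ids for rep in range(2)]
    order = rng.permutation(len(duplicated))
    for k in order:
        sid, rep = duplicated[k]
        for d in dilutions:
            body.append((sid, "sample", d, np.nan, -1, rep))

    since_qc = 0
    for entry in body:
        if since_qc >= qc_every:
            add("qc_pool", "qc", dilution=5)
            since_qc = 0
        add(*entry)
        since_qc += 1

    add_calibration("end")
    plan = pd.DataFrame(rows)
    plan.insert(0, "injection_index", np.arange(len(plan)))
    return plan


# ---------------------------------------------------------------------------
# peak-table simulation


def simulate_peak_table(
    truth: SyntheticTruth,
    plan: pd.DataFrame,
    seed: int | None = None,
    peak_width_s: float = 10.0,
) -> pd.DataFrame:
    """Generate a peak-area table for every (injection, analyte, transition).

    Concentration logic per role: standards carry their nominal level
    (measurement solution, matrix factor 1); blanks carry 0 plus carryover
    from the previous injection; qc/unspiked/sample rows carry the analyte's
    native plasma concentration divided by the dilution factor; spiked rows
    add the spike (plasma scale) before dilution.  Matrix factors apply to
    plasma-derived rows only.

    Heights are emitted as ``area / peak_width_s`` and the baseline-noise
    estimate on the same scale, so S/N = height / noise_sd = area-scale S/N.

    Reproducible: the same truth + plan + seed give an identical table.
    """
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    n_inj = len(plan)
    rows: list[dict] = []
    prev_area: dict[tuple[str, str], float] = {}

    for rec in plan.itertuples(index=False):
        drift = truth.drift(int(rec.injection_index), n_inj)
        for aid, model in truth.models.items():
            dilution = rec.dilution_factor
            if rec.role == "standard":
                conc = float(rec.nominal_ugL)
                mf = 1.0
            elif rec.role == "blank":
                conc = 0.0
                mf = 1.0
            elif rec.role in ("qc", "unspiked", "sample"):
                conc = truth.native_conc[aid] / dilution
                mf = model.matrix_factor[int(dilution)]
            elif rec.role == "spiked":
                spike = truth.spike_amount(aid, int(rec.spike_level))
                conc = (truth.native_conc[aid] + spike) / dilution
                mf = model.matrix_factor[int(dilution)]
            else:
                raise ValueError(f"unknown role {rec.role!r}")
            if conc < 0:
                raise ValueError("concentrations must be non-negative")

            for transition, scale in (("quantifier", 1.0), ("qualifier", model.ion_ratio)):
                clean = drift * mf * model.response(conc) * scale
                if model.measurement_rsd > 0:
                    sigma = np.sqrt(np.log1p(model.measurement_rsd**2))
                    clean *= rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma)
                carry = 0.0
                if rec.role == "blank":
                    carry = model.carryover_fraction * prev_area.get((aid, transition), 0.0)
                area = clean + carry
                if model.baseline_noise_sd > 0:
                    area += rng.normal(0.0, model.baseline_noise_sd)
                area = max(area, 0.0)
                prev_area[(aid, transition)] = area
                rows.append(
                    {
                        "sample_id": rec.sample_id,
                        "injection_index": int(rec.injection_index),
                        "role": rec.role,
                        "dilution_factor": dilution,
                        "analyte_id": aid,
                        "transition": transition,
                        "area": area,
                        "height": area / peak_width_s,
                        "noise_sd": model.baseline_noise_sd / peak_width_s,
                        "nominal_ugL": rec.nominal_ugL,
                        "spike_level": rec.spike_level,
                        "replicate": rec.replicate,
                    }
                )
    return pd.DataFrame(rows)
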