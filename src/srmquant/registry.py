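"""Assay definition: analytes, SRM transitions, LC gradient programs, solvents.

A dual-method (HILIC + reversed-phase) targeted assay is described by a flat,
row-per-transition registry table — the same layout vendor acquisition software
imports — plus gradient programs for each LC method.  This module loads and
validates that registry, and provides the registry-level arithmetic: run
duration of a gradient program and the polarity index of a solvent mixture.

Registry CSV dialect (UTF-8, comma-separated, one transition per row, analyte
metadata denormalized onto rows)::

    analyte_id,name,class,method,polarity,precursor_mz,product_mz,role,rt_min,window_s,calib_set,flags

``flags`` is a semicolon-separated list; recognized flags are
``single_transition``, ``both_polarities``, ``report_as_sum``,
``sum_partner=<analyte_id>`` and ``unique_partner=<analyte_id>``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Sequence

import pandas as pd

from ._util import round_half_away

__all__ = [
    "Method",
    "Polarity",
    "TransitionRole",
    "TransitionRecord",
    "AnalyteDefinition",
    "GradientProgram",
    "SolventComponent",
    "Registry",
    "RegistryIssue",
    "RegistryFormatError",
    "RegistryValidationError",
    "REGISTRY_COLUMNS",
    "SOLVENT_POLARITY_INDEX",
    "load_transition_registry",
    "write_transition_registry",
    "validate_registry",
    "run_duration",
    "mixture_polarity_index",
]


class Method(str, Enum):
    HILIC = "HILIC"
    RP = "RP"


class Polarity(str, Enum):
    positive = "positive"
    negative = "negative"


class TransitionRole(str, Enum):
    quantifier = "quantifier"
    qualifier = "qualifier"


#: Documented header of the registry CSV, in column order.
REGISTRY_COLUMNS = [
    "analyte_id",
    "name",
    "class",
    "method",
    "polarity",
    "precursor_mz",
    "product_mz",
    "role",
    "rt_min",
    "window_s",
    "calib_set",
    "flags",
]

#: Snyder-style polarity indices of the solvents used for standard uptake.
#: Pure-solvent values for IPA (4.3), ACN (6.2) and MeOH (6.6) are as printed
#: in assay documentation; water (9.0) and acetone (5.4) are the values that
#: reproduce all printed binary-mixture indices under volume-fraction-weighted
#: mixing and one-decimal rounding.
SOLVENT_POLARITY_INDEX = {
    "water": 9.0,
    "methanol": 6.6,
    "acetonitrile": 6.2,
    "acetone": 5.4,
    "isopropanol": 4.3,
}


class RegistryFormatError(ValueError):
    """The registry table does not conform to the documented dialect."""


class RegistryValidationError(ValueError):
    """The registry content violates a structural invariant."""


@dataclass(frozen=True)
class TransitionRecord:
    """One SRM transition of the assay.

    Parameters
    ----------
    analyte_id : str
        Identifier of the analyte the transition belongs to.
    method : Method
        LC method (HILIC or RP) in which the transition is acquired.
    polarity : Polarity
        Ionization polarity.
    precursor_mz, product_mz : float
        Precursor and product ion m/z.
    role : TransitionRole
        Quantifier (used for quantification) or qualifier (identity
        confirmation via the ion ratio).
    retention_time : float
        Expected retention time in minutes.
    window_width : float
        Scheduled detection window width in seconds (the transition is
        acquired while |t - rt| <= window/2).
    dwell_min_floor : float or None
        Optional per-transition override of the minimum dwell time (ms).
    """

    analyte_id: str
    method: Method
    polarity: Polarity
    precursor_mz: float
    product_mz: float
    role: TransitionRole
    retention_time: float
    window_width: float
    dwell_min_floor: float | None = None

    def __post_init__(self) -> None:
        if self.precursor_mz <= 0:
            raise RegistryValidationError(
                f"{self.analyte_id}: precursor_mz must be > 0, got {self.precursor_mz}"
            )
        if self.product_mz <= 0:
            raise RegistryValidationError(
                f"{self.analyte_id}: product_mz must be > 0, got {self.product_mz}"
            )
        if self.retention_time < 0:
            raise RegistryValidationError(
                f"{self.analyte_id}: retention_time must be >= 0"
            )
        if self.window_width <= 0:
            raise RegistryValidationError(
                f"{self.analyte_id}: window_width must be > 0"
            )


@dataclass
class AnalyteDefinition:
    """Analyte-level metadata shared by its transitions."""

    analyte_id: str
    name: str
    compound_class: str
    calibration_set: str = "HILIC"  # HILIC, RP_Aqu or RP_Hep
    logp: float | None = None
    single_transition: bool = False
    both_polarities: bool = False
    report_as_sum: bool = False
    sum_partner: str | None = None
    unique_partner: str | None = None


@dataclass
class GradientProgram:
    """An LC gradient as ordered (time_min, percent_B, flow_uL_min) segments."""

    method: Method
    segments: list[tuple[float, float, float]]
    oven_temp_C: float = 40.0
    injection_volume_uL: float = 1.0

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("gradient program needs at least one segment")
        times = [s[0] for s in self.segments]
        if times[0] != 0.0:
            raise ValueError("first gradient segment must start at time 0")
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("segment times must be strictly increasing")
        for _, pct_b, _ in self.segments:
            if not 0.0 <= pct_b <= 100.0:
                raise ValueError(f"percent_B must lie in [0, 100], got {pct_b}")


@dataclass(frozen=True)
class SolventComponent:
    """A solvent with its polarity index and volume fraction in a mixture."""

    name: str
    polarity_index: float
    volume_fraction: float


@dataclass(frozen=True)
class RegistryIssue:
    severity: str  # "error" | "warning" | "info"
    analyte_id: str | None
    message: str


@dataclass
class Registry:
    """A loaded assay registry: analytes plus their SRM transitions."""

    analytes: list[AnalyteDefinition]
    transitions: list[TransitionRecord]
    _by_analyte: dict[str, list[TransitionRecord]] = field(
        default_factory=dict, repr=False
    )

    def __post_init__(self) -> None:
        self._by_analyte = {}
        for t in self.transitions:
            self._by_analyte.setdefault(t.analyte_id, []).append(t)

    @property
    def n_analytes(self) -> int:
        return len(self.analytes)

    @property
    def n_transitions(self) -> int:
        return len(self.transitions)

    def transitions_for(self, analyte_id: str) -> list[TransitionRecord]:
        return list(self._by_analyte.get(analyte_id, []))

    def transitions_by_method(self, method: Method | str) -> list[TransitionRecord]:
        method = Method(method)
        return [t for t in self.transitions if t.method == method]

    def summary(self) -> dict:
        """Tallies of analytes and transitions per method and polarity."""
        per_method = Counter(t.method.value for t in self.transitions)
        per_polarity = Counter(t.polarity.value for t in self.transitions)
        return {
            "n_analytes": self.n_analytes,
            "n_transitions": self.n_transitions,
            "transitions_per_method": dict(per_method),
            "transitions_per_polarity": dict(per_polarity),
        }


# ---------------------------------------------------------------------------
# registry I/O


def _parse_flags(raw: str) -> dict:
    out: dict = {}
    if not raw or pd.isna(raw):
        return out
    for token in str(raw).split(";"):
        token = token.strip()
        if not token:
            continue
        if "=" in token:
            key, value = token.split("=", 1)
            out[key.strip()] = value.strip()
        else:
            out[token] = True
    return out


def _format_flags(a: AnalyteDefinition) -> str:
    parts = []
    if a.single_transition:
        parts.append("single_transition")
    if a.both_polarities:
        parts.append("both_polarities")
    if a.report_as_sum:
        parts.append("report_as_sum")
    if a.sum_partner:
        parts.append(f"sum_partner={a.sum_partner}")
    if a.unique_partner:
        parts.append(f"unique_partner={a.unique_partner}")
    return ";".join(parts)


def load_transition_registry(source) -> Registry:
    """Load a registry from the documented CSV dialect.

    Parameters
    ----------
    source : path-like or file-like
        CSV with the documented header (one transition per row).

    Returns
    -------
    Registry

    Raises
    ------
    RegistryFormatError
        If a required column is missing or a numeric field fails to parse.
    RegistryValidationError
        If an analyte has zero or more than two transitions without the
        matching flag, or a field violates a record invariant.
    """
    df = pd.read_csv(source, dtype=str, keep_default_na=False, na_values=[""])
    missing = [c for c in REGISTRY_COLUMNS if c not in df.columns and c != "flags"]
    if missing:
        raise RegistryFormatError(f"registry is missing required column(s): {missing}")
    if "flags" not in df.columns:
        df["flags"] = ""

    for col in ("precursor_mz", "product_mz", "rt_min", "window_s"):
        try:
            df[col] = df[col].astype(float)
        except ValueError as exc:
            raise RegistryFormatError(f"column {col!r} is not numeric: {exc}") from exc

    analytes: dict[str, AnalyteDefinition] = {}
    transitions: list[TransitionRecord] = []
    for _, row in df.iterrows():
        aid = str(row["analyte_id"])
        flags = _parse_flags(row["flags"])
        if aid not in analytes:
            analytes[aid] = AnalyteDefinition(
                analyte_id=aid,
                name=str(row["name"]),
                compound_class=str(row["class"]),
                calibration_set=str(row["calib_set"]),
                single_transition=bool(flags.get("single_transition", False)),
                both_polarities=bool(flags.get("both_polarities", False)),
                report_as_sum=bool(flags.get("report_as_sum", False)),
                sum_partner=flags.get("sum_partner"),
                unique_partner=flags.get("unique_partner"),
            )
        transitions.append(
            TransitionRecord(
                analyte_id=aid,
                method=Method(row["method"]),
                polarity=Polarity(row["polarity"]),
                precursor_mz=float(row["precursor_mz"]),
                product_mz=float(row["product_mz"]),
                role=TransitionRole(row["role"]),
                retention_time=float(row["rt_min"]),
                window_width=float(row["window_s"]),
            )
        )

    registry = Registry(analytes=list(analytes.values()), transitions=transitions)
    bad = [
        a.analyte_id
        for a in registry.analytes
        if not (
            len(registry.transitions_for(a.analyte_id)) == 2
            or (a.single_transition and len(registry.transitions_for(a.analyte_id)) == 1)
        )
    ]
    if bad:
        raise RegistryValidationError(
            "analytes must carry 2 transitions (or 1 with the single_transition "
            f"flag); offending analytes: {bad}"
        )
    return registry


def write_transition_registry(registry: Registry, target) -> None:
    """Write a registry back to the documented CSV dialect (round-trip safe)."""
    analytes = {a.analyte_id: a for a in registry.analytes}
    rows = []
    for t in registry.transitions:
        a = analytes[t.analyte_id]
        rows.append(
            {
                "analyte_id": t.analyte_id,
                "name": a.name,
                "class": a.compound_class,
                "method": t.method.value,
                "polarity": t.polarity.value,
                "precursor_mz": t.precursor_mz,
                "product_mz": t.product_mz,
                "role": t.role.value,
                "rt_min": t.retention_time,
                "window_s": t.window_width,
                "calib_set": a.calibration_set,
                "flags": _format_flags(a),
            }
        )
    df = pd.DataFrame(rows, columns=REGISTRY_COLUMNS)
    if isinstance(target, (str, Path)):
        df.to_csv(target, index=False)
    else:
        df.to_csv(target, index=False)


def validate_registry(registry: Registry) -> list[RegistryIssue]:
    """Content-level checks beyond the hard load-time invariants.

    Returns machine-readable issues; an empty list means a clean registry.
    Wide detection windows (e.g. 60 s for phospholipids with retention-time
    variability) are reported as informational, not as errors.
    """
    issues: list[RegistryIssue] = []
    for a in registry.analytes:
        trans = registry.transitions_for(a.analyte_id)
        per_method_quant = Counter(
            t.method for t in trans if t.role == TransitionRole.quantifier
        )
        for method, n in per_method_quant.items():
            if n > 1:
                issues.append(
                    RegistryIssue(
                        "error",
                        a.analyte_id,
                        f"{n} quantifier transitions in method {method.value}; "
                        "at most one is allowed",
                    )
                )
        if a.both_polarities:
            polarities = {t.polarity for t in trans}
            if len(polarities) != 2:
                issues.append(
                    RegistryIssue(
                        "error",
                        a.analyte_id,
                        "flagged both_polarities but transitions do not cover "
                        "both polarities",
                    )
                )
        for t in trans:
            if t.window_width > 30.0:
                issues.append(
                    RegistryIssue(
                        "info",
                        a.analyte_id,
                        f"detection window {t.window_width:g} s exceeds the "
                        "standard 30 s (expected for analytes with "
                        "retention-time variability)",
                    )
                )
    return issues


# ---------------------------------------------------------------------------
# registry-level arithmetic


def run_duration(program: GradientProgram) -> float:
    """Total run duration in minutes: the end of the last gradient segment."""
    return float(max(t for t, _, _ in program.segments))


def mixture_polarity_index(components: Sequence[SolventComponent]) -> float:
    """Polarity index of a solvent mixture.

    The index of a mixture is the volume-fraction-weighted mean of the
    component indices, reported rounded to one decimal (round half away from
    zero), matching how mixture indices are printed in assay documentation.
    """
    if not components:
        raise ValueError("mixture needs at least one component")
    total = sum(c.volume_fraction for c in components)
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"volume fractions must sum to 1, got {total}")
    raw = sum(c.polarity_index * c.volume_fraction for c in components)
    return round_half_away(raw, 1)
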