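"""Scheduled-SRM concurrency and dwell-time budgeting.

In scheduled SRM each transition is only acquired inside a retention-time
window, so the number of concurrent transitions varies over the run.  The
mass spectrometer divides a target cycle time among the transitions active at
any moment, after subtracting per-transition pause time and, when both
polarities are acquired in the same cycle, the polarity-switch settling time
(charged twice per cycle: once entering each polarity).  The per-transition
dwell time is the equal share of the remaining budget, floored at the
instrument's minimum dwell; where the floor binds, the realized cycle
stretches beyond the target and the schedule is flagged infeasible.

The equal-split allocation is this module's explicit model of the vendor
scheduler, which does not disclose its algorithm; it is isolated in
:func:`allocate_dwell` so alternatives can be slotted in.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .registry import Method, Polarity, Registry, TransitionRecord

__all__ = [
    "CycleConfig",
    "ConcurrencyProfile",
    "DwellProfile",
    "concurrency_profile",
    "allocate_dwell",
    "points_per_peak",
]


@dataclass(frozen=True)
class CycleConfig:
    """MS duty-cycle parameters.

    target_cycle_ms : float
        Target duration of one acquisition cycle (default 1000 ms).
    pause_ms : float
        Inter-transition pause charged once per active transition (default 5 ms).
    settling_ms : float
        Settling time charged per polarity switch (default 15 ms); two
        switches per cycle when both polarities are active.
    dwell_floor_ms : float
        Minimum per-transition dwell the instrument supports (default 3 ms).
    time_grid_step_s : float
        Resolution of the scheduling time grid (default 1 s).
    """

    target_cycle_ms: float = 1000.0
    pause_ms: float = 5.0
    settling_ms: float = 15.0
    dwell_floor_ms: float = 3.0
    time_grid_step_s: float = 1.0

    def __post_init__(self) -> None:
        for name in ("target_cycle_ms", "pause_ms", "settling_ms", "dwell_floor_ms", "time_grid_step_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.dwell_floor_ms > self.target_cycle_ms:
            raise ValueError("dwell_floor_ms cannot exceed target_cycle_ms")


@dataclass
class ConcurrencyProfile:
    """Active transitions per time-grid point, split by polarity."""

    method: Method
    time_s: np.ndarray
    active_pos: list[list[int]]  # indices into `transitions`
    active_neg: list[list[int]]
    transitions: list[TransitionRecord] = field(repr=False, default_factory=list)

    @property
    def n_pos(self) -> np.ndarray:
        return np.array([len(s) for s in self.active_pos])

    @property
    def n_neg(self) -> np.ndarray:
        return np.array([len(s) for s in self.active_neg])


@dataclass
class DwellProfile:
    """Allocated dwell per grid point, as a tidy frame.

    Columns: ``time_s, n_pos, n_neg, dwell_ms, cycle_ms, feasible``.  Grid
    points with no active transition carry NaN dwell and the target cycle.
    """

    method: Method
    config: CycleConfig
    frame: pd.DataFrame

    @property
    def min_dwell_ms(self) -> float:
        return float(self.frame["dwell_ms"].min())

    @property
    def feasible(self) -> bool:
        return bool(self.frame["feasible"].all())


def concurrency_profile(
    registry: Registry,
    method: Method | str,
    config: CycleConfig | None = None,
    run_duration_min: float | None = None,
) -> ConcurrencyProfile:
    """Active-transition sets over the run for one LC method.

    A transition is active at time t iff ``|t - retention_time| <=
    window_width / 2`` (closed interval at both edges).

    Parameters
    ----------
    registry : Registry
    method : Method or str
    config : CycleConfig, optional
    run_duration_min : float, optional
        Length of the time grid; defaults to the latest window edge.
    """
    config = config or CycleConfig()
    method = Method(method)
    transitions = registry.transitions_by_method(method)
    if not transitions:
        raise ValueError(f"registry contains no transitions for method {method.value}")

    ends_s = [t.retention_time * 60.0 + t.window_width / 2.0 for t in transitions]
    duration_s = (
        run_duration_min * 60.0 if run_duration_min is not None else max(ends_s)
    )
    time_s = np.arange(0.0, duration_s + 1e-9, config.time_grid_step_s)

    starts = np.array([t.retention_time * 60.0 - t.window_width / 2.0 for t in transitions])
    ends = np.array(ends_s)
    is_pos = np.array([t.polarity == Polarity.positive for t in transitions])

    active_pos: list[list[int]] = []
    active_neg: list[list[int]] = []
    for t in time_s:
        mask = (starts <= t) & (t <= ends)
        idx = np.nonzero(mask)[0]
        active_pos.append([int(i) for i in idx if is_pos[i]])
        active_neg.append([int(i) for i in idx if not is_pos[i]])
    return ConcurrencyProfile(
        method=method,
        time_s=time_s,
        active_pos=active_pos,
        active_neg=active_neg,
        transitions=transitions,
    )


def allocate_dwell(profile: ConcurrencyProfile, config: CycleConfig | None = None) -> DwellProfile:
    """Split the cycle-time budget equally among concurrent transitions.

    At a grid point with ``n = n_pos + n_neg > 0`` active transitions the
    polarity-switch overhead is ``2 * settling_ms`` if both polarities are
    present and 0 otherwise, and::

        dwell = (target_cycle - overhead - n * pause) / n

    floored at ``dwell_floor_ms``.  Where the floor binds, the realized cycle
    is ``overhead + n * (dwell_floor + pause)`` (> target) and the point is
    flagged infeasible.  Infeasibility is reported, never raised.
    """
    config = config or CycleConfig()
    n_pos = profile.n_pos
    n_neg = profile.n_neg
    n = n_pos + n_neg
    both = (n_pos > 0) & (n_neg > 0)
    overhead = np.where(both, 2.0 * config.settling_ms, 0.0)

    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (config.target_cycle_ms - overhead - n * config.pause_ms) / n
    dwell = np.where(n > 0, np.maximum(raw, config.dwell_floor_ms), np.nan)
    floored = (n > 0) & (raw < config.dwell_floor_ms)
    cycle = np.where(
        n > 0,
        np.where(
            floored,
            overhead + n * (config.dwell_floor_ms + config.pause_ms),
            config.target_cycle_ms,
        ),
        config.target_cycle_ms,
    )
    frame = pd.DataFrame(
        {
            "time_s": profile.time_s,
            "n_pos": n_pos,
            "n_neg": n_neg,
            "dwell_ms": dwell,
            "cycle_ms": cycle,
            "feasible": ~floored,
        }
    )
    return DwellProfile(method=profile.method, config=config, frame=frame)


def points_per_peak(peak_width_s: float, realized_cycle_ms: float) -> float:
    """Chromatographic data points across a peak: one per acquisition cycle."""
    if peak_width_s <= 0 or realized_cycle_ms <= 0:
        raise ValueError("peak width and cycle time must be strictly positive")
    return peak_width_s * 1000.0 / realized_cycle_ms
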