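"""Breath-maneuver processing: volumes, phase detection, residence time.

The single-breath protocol (the same maneuver used clinically for the CO
diffusing-capacity test) has five landmark points on the flow trace:

    I   start of the exhalation to residual volume (RV)
    II  RV reached; the four-way valve switches to the aerosol reservoir and
        inhalation begins
    III total lung capacity (TLC) reached; all valve ports close and the
        breath hold starts
    IV  the port to the sample collector opens; sampled exhalation begins
    V   the commanded collector volume has passed; the collector closes
        (the subject keeps exhaling to waste)

From a detected maneuver we derive the end-inspiratory inhaled volume V_i
(the volume integral over II->III, i.e. inspiratory vital capacity — absolute
lung volume is unobservable from a flow trace), the breath-hold time, the
aerosol residence time in the lung, and the volumetric lung-depth window of
the analyzed sample slice.

Residence time is defined as the time from when half of the test aerosol has
been inhaled to the midpoint time of the exhaled sample: the half-volume
crossing of the cumulative inhaled volume after II, to the half-collector
crossing of cumulative exhaled volume after IV.  Both crossings are located
with sub-sample linear interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .traces import FlowTrace

__all__ = [
    "ManeuverPhases",
    "ManeuverMetrics",
    "ManeuverRejectionError",
    "integrate_volume",
    "detect_phases",
    "residence_time",
    "sample_depth_window",
    "compute_metrics",
]

#: |flow| below this (L/s), sustained, counts as a hold plateau.
HOLD_FLOW_THRESHOLD = 0.05
#: Hysteresis applied when extending a plateau (L/s).
HOLD_HYSTERESIS = 0.02
#: Minimum plateau duration to qualify as a breath hold (s).
HOLD_MIN_DURATION = 0.3


class ManeuverRejectionError(ValueError):
    """The trace does not contain a valid, complete maneuver."""


@dataclass(frozen=True)
class ManeuverPhases:
    """Timestamps (s) of points I-V; strictly increasing."""

    I: float
    II: float
    III: float
    IV: float
    V: float

    def __post_init__(self) -> None:
        seq = (self.I, self.II, self.III, self.IV, self.V)
        if not all(a < b for a, b in zip(seq, seq[1:])):
            raise ManeuverRejectionError(f"phase points out of order: {seq}")

    @property
    def breath_hold(self) -> float:
        return self.IV - self.III


@dataclass(frozen=True)
class ManeuverMetrics:
    """Per-breath derived quantities."""

    V_i: float  # end-inspiratory inhaled volume, L (integral II->III)
    breath_hold_time: float  # s, III->IV
    residence_time: float  # s, half-inhaled to mid-sample
    collector_volume: float  # L
    sample_depth_window: tuple[float, float]  # L, volumetric lung depth
    mean_flow_inhale: float  # L/s over II->III
    mean_flow_exhale: float  # L/s over IV->V (magnitude)

    def __post_init__(self) -> None:
        if self.V_i <= 0 or self.collector_volume <= 0:
            raise ManeuverRejectionError("volumes must be positive")
        if self.residence_time <= self.breath_hold_time:
            raise ManeuverRejectionError(
                "residence time must exceed the breath-hold time "
                f"({self.residence_time} <= {self.breath_hold_time})"
            )


def integrate_volume(trace: FlowTrace) -> np.ndarray:
    """Cumulative trapezoidal volume (L) along the trace, starting at 0.

    Differencing the result recovers the flow at interior points to O(dt^2).
    """
    return cumulative_trapezoid(trace.flow, trace.times, initial=0.0)


def _interp_crossing(times: np.ndarray, values: np.ndarray, target: float) -> float:
    """First time at which ``values`` (piecewise-linear) reaches ``target``."""
    above = values >= target
    if not np.any(above):
        raise ManeuverRejectionError(f"series never reaches target {target}")
    j = int(np.argmax(above))
    if j == 0:
        return float(times[0])
    v0, v1 = values[j - 1], values[j]
    if v1 == v0:
        return float(times[j])
    frac = (target - v0) / (v1 - v0)
    return float(times[j - 1] + frac * (times[j] - times[j - 1]))


def _plateau_runs(
    flow: np.ndarray, enter: float, extend: float, max_gap: int = 0
) -> list[tuple[int, int]]:
    """Low-flow runs with hysteresis: enter below ``enter``, stay below ``extend``.

    Runs separated by at most ``max_gap`` samples are merged, so isolated
    sensor spikes above the hysteresis band do not split a breath hold.
    """
    runs: list[tuple[int, int]] = []
    n = flow.size
    i = 0
    while i < n:
        if abs(flow[i]) < enter:
            j = i
            while j + 1 < n and abs(flow[j + 1]) < extend:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1
    if max_gap > 0 and len(runs) > 1:
        merged = [runs[0]]
        for i0, i1 in runs[1:]:
            p0, p1 = merged[-1]
            if i0 - p1 - 1 <= max_gap:
                merged[-1] = (p0, i1)
            else:
                merged.append((i0, i1))
        runs = merged
    return runs


def detect_phases(
    trace: FlowTrace,
    *,
    hold_threshold: float = HOLD_FLOW_THRESHOLD,
    hysteresis: float = HOLD_HYSTERESIS,
    hold_min_duration: float = HOLD_MIN_DURATION,
) -> ManeuverPhases:
    """Locate points I-V on a flow trace containing one complete maneuver.

    Strategy: the breath hold (III->IV) is the low-flow plateau containing
    the global maximum of cumulative volume (TLC); II is the preceding volume
    minimum (RV); I is the last transition into sustained negative flow
    before II.  V falls back to the end of the sampled exhalation (flow
    magnitude back below threshold, or end of trace).  Valve-event
    timestamps, when present, override the flow-derived II-V — the valve,
    not the flow sensor, defines when ports actually switch.
    """
    t, q = trace.times, trace.flow
    v = integrate_volume(trace)
    dt = trace.dt

    runs = _plateau_runs(
        q, hold_threshold, hold_threshold + hysteresis, max_gap=int(round(0.1 / dt))
    )
    min_len = max(2, int(round(hold_min_duration / dt)))
    i_max = int(np.argmax(v))
    hold = None
    for i0, i1 in runs:
        if i1 - i0 + 1 >= min_len and i0 <= i_max <= i1:
            hold = (i0, i1)
            break
    if hold is None:
        # TLC sample may sit just outside the plateau under noise; accept a
        # qualifying plateau beginning within 0.5 s of the volume maximum.
        for i0, i1 in runs:
            if i1 - i0 + 1 >= min_len and 0 <= t[i0] - t[i_max] <= 0.5:
                hold = (i0, i1)
                break
    if hold is None:
        raise ManeuverRejectionError("no breath-hold plateau found")
    iIII, iIV = hold
    tIII, tIV = float(t[iIII]), float(t[iIV])

    # II: volume minimum (RV) before the hold.
    if iIII < 2:
        raise ManeuverRejectionError("no inhalation precedes the breath hold")
    iII = int(np.argmin(v[:iIII]))
    tII = float(t[iII])
    if v[iIII] - v[iII] <= 0:
        raise ManeuverRejectionError("no inhaled volume between RV and TLC")

    # I: start of the final contiguous negative-flow block before II.
    neg_idx = np.nonzero(q[:iII] < -hold_threshold)[0]
    if neg_idx.size == 0:
        raise ManeuverRejectionError("no exhalation to RV found before inhalation")
    iI = neg_idx[0]
    gaps = np.nonzero(np.diff(neg_idx) > int(0.5 / dt))[0]
    if gaps.size:
        iI = neg_idx[gaps[-1] + 1]
    tI = float(t[iI])

    # V fallback: sampled exhalation started and decayed back below threshold.
    after = q[iIV + 1 :]
    started = np.nonzero(after < -hold_threshold)[0]
    if started.size == 0:
        raise ManeuverRejectionError("no sampled exhalation after the breath hold")
    ended = np.nonzero(after[started[0] :] > -hold_threshold)[0]
    iV = iIV + 1 + started[0] + (ended[0] if ended.size else after.size - started[0] - 1)
    tV = float(t[min(iV, q.size - 1)])

    ev = trace.valve_events or {}
    return ManeuverPhases(
        I=float(ev.get("I", tI)),
        II=float(ev.get("II", tII)),
        III=float(ev.get("III", tIII)),
        IV=float(ev.get("IV", tIV)),
        V=float(ev.get("V", tV)),
    )


def _cumulative_from(trace: FlowTrace, t0: float, sign: float) -> tuple[np.ndarray, np.ndarray]:
    """Times and cumulative signed volume from t0 onward."""
    t, q = trace.times, trace.flow
    mask = t >= t0
    if mask.sum() < 2:
        raise ManeuverRejectionError(f"trace ends at/before t0={t0}")
    ts = t[mask]
    vs = cumulative_trapezoid(sign * q[mask], ts, initial=0.0)
    return ts, vs


def residence_time(trace: FlowTrace, phases: ManeuverPhases, collector_volume: float) -> float:
    """Aerosol residence time in the lung (s).

    Half-inhaled time: cumulative inhaled volume after II reaches V_i/2.
    Mid-sample time: cumulative exhaled volume after IV reaches half the
    collector volume.  Rejects the maneuver if the exhalation never fills
    the collector.
    """
    if collector_volume <= 0:
        raise ManeuverRejectionError("collector volume must be > 0")
    t_in, v_in = _cumulative_from(trace, phases.II, +1.0)
    vi = float(np.interp(phases.III, t_in, v_in))
    if vi <= 0:
        raise ManeuverRejectionError("no inhaled volume in II->III")
    t_half = _interp_crossing(t_in, np.maximum.accumulate(v_in), vi / 2.0)

    t_ex, v_ex = _cumulative_from(trace, phases.IV, -1.0)
    v_ex = np.maximum.accumulate(v_ex)
    if v_ex[-1] < collector_volume:
        raise ManeuverRejectionError(
            f"exhaled volume {v_ex[-1]:.3f} L < collector volume {collector_volume} L"
        )
    t_mid = _interp_crossing(t_ex, v_ex, collector_volume / 2.0)
    return t_mid - t_half


def sample_depth_window(
    collector_volume: float, analyzed_volume: float, dead_space: float
) -> tuple[float, float]:
    """Volumetric lung depth (L) of the analyzed slice, [shallow, deep] edge.

    The analyzed sample is drawn from the collector's inlet end, i.e. the
    last-exhaled (deepest) air: with commanded collector volume V_c, analyzed
    slice V_a and total (instrument + anatomical) dead space V_d, the slice
    spans [V_c - V_a + V_d, V_c + V_d] of volumetric lung depth.  With the
    study's nominal values (1.2 L, 0.3 L, 0.3 L) this is the 1.2-1.5 L
    window.
    """
    if analyzed_volume > collector_volume:
        raise ManeuverRejectionError("analyzed volume cannot exceed collector volume")
    if min(collector_volume, analyzed_volume) <= 0 or dead_space < 0:
        raise ManeuverRejectionError("volumes must be positive (dead space >= 0)")
    return (collector_volume - analyzed_volume + dead_space, collector_volume + dead_space)


def compute_metrics(
    trace: FlowTrace,
    phases: ManeuverPhases,
    *,
    collector_volume: float,
    analyzed_volume: float = 0.3,
    dead_space: float = 0.3,
) -> ManeuverMetrics:
    """Assemble all per-breath metrics from a trace and its phases."""
    t_in, v_in = _cumulative_from(trace, phases.II, +1.0)
    V_i = float(np.interp(phases.III, t_in, v_in))
    mean_q_in = V_i / (phases.III - phases.II)
    t_ex, v_ex = _cumulative_from(trace, phases.IV, -1.0)
    v_at_V = float(np.interp(phases.V, t_ex, v_ex))
    mean_q_ex = v_at_V / (phases.V - phases.IV)
    return ManeuverMetrics(
        V_i=V_i,
        breath_hold_time=phases.breath_hold,
        residence_time=residence_time(trace, phases, collector_volume),
        collector_volume=collector_volume,
        sample_depth_window=sample_depth_window(collector_volume, analyzed_volume, dead_space),
        mean_flow_inhale=mean_q_in,
        mean_flow_exhale=mean_q_ex,
    )
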