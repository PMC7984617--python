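"""Pacing characteristics: CL, MDP, APD90, diastolic interval and the
diastolic current integrals.

Fiducial conventions
--------------------
The upstroke reference time of a cycle is the interpolated upward crossing
of -55 mV (approximately the L-type Ca2+ activation threshold), which also
defines the end of the diastolic interval; the start of the diastolic
interval is the maximum diastolic potential (MDP, the per-cycle minimum).
The diastolic upstroke velocity is (|MDP - (-55)|) / (t2 - t1) in V/s.
APD90 runs from the upstroke crossing to the downward crossing of the
90%-repolarization level, crest - 0.9 * (crest - MDP).

For simulated records the measurement window defaults to the final 400 s
when the record is at least 800 s long, otherwise to the final half of the
record, which keeps start-up transients out of the averages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classify import WaveEvent, detect_waves, classify_state
from .integrate import Trace

__all__ = [
    "PacingMetrics",
    "UndefinedMetricError",
    "measurement_window",
    "cycle_length",
    "mdp",
    "apd90",
    "diastolic_interval",
    "di_current_integrals",
    "compute_metrics",
]

UPSTROKE_LEVEL = -55.0   # mV
VALID_CL_MAX = 1000.0    # ms; "valid pacemaking" upper bound on CL

INWARD_DI_CURRENTS = ("I_Na", "I_NaCa", "I_f_Na", "I_f_K")
OUTWARD_DI_CURRENTS = ("I_K1", "I_NaK", "I_Kr", "I_Ks")


class UndefinedMetricError(ValueError):
    """The requested quantity is undefined for this trace."""


@dataclass
class PacingMetrics:
    """Summary pacing quantities averaged over the measurement window."""

    CL: float | None = None                       # ms
    MDP: float | None = None                      # mV
    APD90: float | None = None                    # ms
    DI: float | None = None                       # ms
    t1: float | None = None                       # ms, MDP time (last cycle)
    t2: float | None = None                       # ms, -55 mV crossing (last cycle)
    diastolic_upstroke_velocity: float | None = None   # V/s
    I_in: float | None = None                     # pA/pF
    I_out: float | None = None                    # pA/pF
    n_cycles: int = 0
    valid_pacemaking: bool = False


def measurement_window(trace: Trace) -> tuple[float, float]:
    """(t_from, t_to) in ms of the default averaging window."""
    t_end = float(trace.time[-1])
    if t_end >= 800_000.0:
        return t_end - 400_000.0, t_end
    return t_end / 2.0, t_end


def _interp_crossing(t: np.ndarray, v: np.ndarray, i: int, level: float) -> float:
    """Linear-interpolated time of the crossing within [i, i+1]."""
    dv = v[i + 1] - v[i]
    if dv == 0.0:
        return float(t[i])
    return float(t[i] + (level - v[i]) / dv * (t[i + 1] - t[i]))


def _upstroke_time(trace: Trace, event: WaveEvent,
                   level: float = UPSTROKE_LEVEL) -> float | None:
    """Interpolated upward crossing of ``level`` between trough and crest."""
    t = trace.time
    v = trace.V
    i0 = int(np.searchsorted(t, event.t_trough))
    i1 = int(np.searchsorted(t, event.t_crest))
    i1 = min(i1, t.size - 1)
    if event.trough_V >= level:
        return None
    for i in range(i0, i1):
        if v[i] < level <= v[i + 1]:
            return _interp_crossing(t, v, i, level)
    return None


def _events_in_window(trace, events, window):
    if events is None:
        events = detect_waves(trace)
    if window is None:
        window = measurement_window(trace)
    t0, t1 = window
    sel = [e for e in events if t0 <= e.t_crest <= t1]
    return sel, events, window


def cycle_length(trace: Trace, events: list[WaveEvent] | None = None,
                 window: tuple[float, float] | None = None) -> float:
    """Mean inter-upstroke interval (ms) of consecutive valid waves."""
    sel, events, window = _events_in_window(trace, events, window)
    ups = []
    for prev, cur in zip(sel[:-1], sel[1:]):
        if not (prev.is_valid and cur.is_valid):
            continue
        a = _upstroke_time(trace, prev)
        b = _upstroke_time(trace, cur)
        if a is not None and b is not None:
            ups.append(b - a)
    if not ups:
        raise UndefinedMetricError(
            "cycle length requires at least two consecutive valid waves in the window")
    return float(np.mean(ups))


def mdp(trace: Trace, events: list[WaveEvent] | None = None,
        window: tuple[float, float] | None = None) -> float:
    """Mean per-cycle minimum (mV) over the window."""
    sel, _, _ = _events_in_window(trace, events, window)
    troughs = [e.trough_V for e in sel if e.is_valid]
    if not troughs:
        if sel:
            troughs = [e.trough_V for e in sel]
        else:
            # a quiescent record: its mean potential is its own "minimum"
            t0, t1 = window if window is not None else measurement_window(trace)
            m = (trace.time >= t0) & (trace.time <= t1)
            return float(np.mean(trace.V[m]))
    return float(np.mean(troughs))


def apd90(trace: Trace, events: list[WaveEvent] | None = None,
          window: tuple[float, float] | None = None) -> float:
    """Mean action-potential duration at 90 % repolarization (ms)."""
    sel, events, window = _events_in_window(trace, events, window)
    t = trace.time
    v = trace.V
    durations = []
    for e in sel:
        if not e.is_valid:
            continue
        t_up = _upstroke_time(trace, e)
        if t_up is None:
            continue
        level = e.crest_V - 0.9 * (e.crest_V - e.trough_V)
        i_pk = int(np.searchsorted(t, e.t_crest))
        t_off = None
        for i in range(i_pk, t.size - 1):
            if v[i] > level >= v[i + 1]:
                t_off = _interp_crossing(t, v, i, level)
                break
            if v[i + 1] > e.crest_V:      # ran into the next wave
                break
        if t_off is not None:
            durations.append(t_off - t_up)
    if not durations:
        raise UndefinedMetricError("APD90 requires at least one valid wave")
    return float(np.mean(durations))


def diastolic_interval(trace: Trace, events: list[WaveEvent] | None = None,
                       window: tuple[float, float] | None = None
                       ) -> tuple[float, float, float, float]:
    """(t1, t2, DI, velocity): MDP time, -55 mV crossing, their difference
    (ms) and the diastolic upstroke velocity (V/s).

    t1/t2 refer to the last complete cycle in the window; DI and velocity
    are averages over all cycles in the window.
    """
    sel, events, window = _events_in_window(trace, events, window)
    dis = []
    vels = []
    last = None
    for e in sel:
        if not e.is_valid:
            continue
        if e.trough_V >= UPSTROKE_LEVEL:
            continue   # DI undefined for this cycle
        t2 = _upstroke_time(trace, e)
        if t2 is None:
            continue
        t1 = e.t_trough
        di = t2 - t1
        if di <= 0:
            continue
        dis.append(di)
        vels.append((UPSTROKE_LEVEL - e.trough_V) / di)   # mV/ms == V/s
        last = (t1, t2)
    if not dis:
        raise UndefinedMetricError("no cycle with an MDP below -55 mV followed "
                                   "by a -55 mV upward crossing")
    return last[0], last[1], float(np.mean(dis)), float(np.mean(vels))


def di_current_integrals(trace: Trace, events: list[WaveEvent] | None = None,
                         window: tuple[float, float] | None = None
                         ) -> tuple[float, float]:
    """Mean inward and outward current averages over the diastolic interval.

    I_in averages I_Na + I_NaCa + I_f and I_out averages
    I_K1 + I_NaK + I_Kr + I_Ks over [t1, t2] of each cycle, then across
    cycles (pA/pF).
    """
    if not trace.currents:
        raise UndefinedMetricError("trace was recorded without current series")
    missing = [n for n in INWARD_DI_CURRENTS + OUTWARD_DI_CURRENTS
               if n not in trace.currents]
    if missing:
        raise UndefinedMetricError(f"missing current series: {missing}")
    sel, events, window = _events_in_window(trace, events, window)
    t = trace.time
    i_in_series = sum(trace.currents[n] for n in INWARD_DI_CURRENTS)
    i_out_series = sum(trace.currents[n] for n in OUTWARD_DI_CURRENTS)
    ins, outs = [], []
    for e in sel:
        if not e.is_valid or e.trough_V >= UPSTROKE_LEVEL:
            continue
        t2 = _upstroke_time(trace, e)
        if t2 is None:
            continue
        m = (t >= e.t_trough) & (t <= t2)
        if m.sum() < 2:
            continue
        ins.append(np.trapezoid(i_in_series[m], t[m]) / (t[m][-1] - t[m][0]))
        outs.append(np.trapezoid(i_out_series[m], t[m]) / (t[m][-1] - t[m][0]))
    if not ins:
        raise UndefinedMetricError("no measurable diastolic interval in the window")
    return float(np.mean(ins)), float(np.mean(outs))


def compute_metrics(trace: Trace, events: list[WaveEvent] | None = None,
                    window: tuple[float, float] | None = None) -> PacingMetrics:
    """All pacing metrics of a trace; undefined quantities are left None."""
    if events is None:
        events = detect_waves(trace)
    out = PacingMetrics()
    sel, _, win = _events_in_window(trace, events, window)
    out.n_cycles = sum(1 for e in sel if e.is_valid)
    try:
        out.CL = cycle_length(trace, events, window)
    except UndefinedMetricError:
        pass
    try:
        out.MDP = mdp(trace, events, window)
    except UndefinedMetricError:
        pass
    try:
        out.APD90 = apd90(trace, events, window)
    except UndefinedMetricError:
        pass
    try:
        out.t1, out.t2, out.DI, out.diastolic_upstroke_velocity = \
            diastolic_interval(trace, events, window)
    except UndefinedMetricError:
        pass
    if trace.currents:
        try:
            out.I_in, out.I_out = di_current_integrals(trace, events, window)
        except UndefinedMetricError:
            pass
    try:
        label = classify_state(events, trace)
        out.valid_pacemaking = (label.state == 5 and out.CL is not None
                                and out.CL <= VALID_CL_MAX)
    except Exception:
        out.valid_pacemaking = False
    return out
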