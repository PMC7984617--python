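"""Wave grammar and five-state classification of pacemaking traces.

A depolarization excursion is a *valid wave* (W) when its trough lies below
-20 mV and its crest above +20 mV; otherwise it is an *incomplete wave*
(alpha-W).  A *rest period* (R) is a quiet interval of at least 1000 ms
containing no wave.  Whole-trace behaviour is classified as

* State-1 - no automaticity (rest only),
* State-2 - transient pacemaking: waves followed by a terminal rest,
* State-3 - bursting: waves and rests alternating,
* State-4 - persistent pacemaking with recurring incomplete waves,
* State-5 - stable pacemaking: uninterrupted valid waves.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import median_filter
from scipy.signal import find_peaks

from .integrate import Trace

__all__ = [
    "WaveEvent",
    "StateLabel",
    "InsufficientDataError",
    "detect_waves",
    "classify_state",
    "incomplete_period",
]

#: default thresholds (mV) of the wave-validity rule
TROUGH_THRESHOLD = -20.0
CREST_THRESHOLD = 20.0
#: minimum excursion (mV) above the preceding minimum for an event
MIN_PROMINENCE = 15.0
#: minimum quiet time (ms) constituting a rest period
REST_MIN_MS = 1000.0
#: nominal duration (ms) of one wave, subtracted from inter-crest intervals
#: when measuring quiet time
NOMINAL_WAVE_MS = 600.0
#: leading transient (s) excluded from State-4/State-5 adjudication
TRANSIENT_S = 60.0
#: a terminal rest must exceed this multiple of the preceding mean cycle
#: length to certify State-2 (vs. an unfinished State-3 burst cycle)
STATE2_REST_FACTOR = 10.0


class InsufficientDataError(ValueError):
    """Trace too short to contain a grammar unit."""


@dataclass
class WaveEvent:
    """One detected depolarization excursion."""

    t_trough: float          # ms
    trough_V: float          # mV
    t_crest: float           # ms
    crest_V: float           # mV
    is_valid: bool
    alpha: float = 1.0       # completeness fraction (< 1 for incomplete waves)

    def __post_init__(self) -> None:
        if self.t_trough >= self.t_crest:
            raise ValueError("t_trough must precede t_crest")


@dataclass
class StateLabel:
    """Five-way classification with supporting evidence."""

    state: int                       # 1..5
    evidence: dict = field(default_factory=dict)
    bursts: list | None = None       # [(t_start_ms, t_end_ms, n_waves)] for State-3

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"State-{self.state}"


def detect_waves(trace: Trace,
                 min_prominence: float = MIN_PROMINENCE,
                 trough_threshold: float = TROUGH_THRESHOLD,
                 crest_threshold: float = CREST_THRESHOLD) -> list[WaveEvent]:
    """Detect every depolarization excursion in a uniformly sampled trace.

    A local maximum qualifies as an event when it rises at least
    ``min_prominence`` mV above the preceding minimum.  Validity follows the
    +/-20 mV trough/crest rule.
    """
    if trace.time.size < 2:
        raise InsufficientDataError("trace must contain at least two samples")
    v = np.asarray(trace.V, dtype=float)
    t = np.asarray(trace.time, dtype=float)

    # peak locations from a lightly median-filtered copy (suppresses isolated
    # noise spikes); crest/trough VALUES re-read from the raw trace in a
    # +/-3-sample neighbourhood so noise-free values are exact
    if v.size >= 7:
        vf = median_filter(v, size=5, mode="nearest")
    else:
        vf = v
    peaks, _ = find_peaks(vf, prominence=min_prominence)
    events: list[WaveEvent] = []
    prev_peak = 0
    for pk in peaks:
        lo = max(0, pk - 3)
        hi = min(v.size, pk + 4)
        i_pk = lo + int(np.argmax(v[lo:hi]))
        seg = slice(prev_peak, pk + 1)
        i_minf = prev_peak + int(np.argmin(vf[seg]))
        lo = max(0, i_minf - 3)
        hi = min(v.size, i_minf + 4)
        i_min = lo + int(np.argmin(v[lo:hi]))
        if i_min >= i_pk:
            i_min = max(prev_peak, i_pk - 1)
        trough_v = float(v[i_min])
        crest_v = float(v[i_pk])
        # re-check the excursion against the preceding minimum explicitly
        if crest_v - trough_v < min_prominence:
            prev_peak = pk
            continue
        valid = (trough_v < trough_threshold) and (crest_v > crest_threshold)
        events.append(WaveEvent(t_trough=float(t[i_min]), trough_V=trough_v,
                                t_crest=float(t[i_pk]), crest_V=crest_v,
                                is_valid=valid))
        prev_peak = pk

    # completeness fraction relative to the typical full wave
    full = [e.crest_V - e.trough_V for e in events if e.is_valid]
    ref = float(np.median(full)) if full else float("nan")
    for e in events:
        e.alpha = 1.0 if e.is_valid else (e.crest_V - e.trough_V) / ref
    return events


def _rest_intervals(events: list[WaveEvent], t_end: float,
                    rest_min_ms: float, nominal_wave_ms: float) -> list[tuple]:
    """Quiet intervals >= rest_min_ms, as (t_from, t_to, terminal) tuples.

    Quiet time between crests is the inter-crest interval minus a nominal
    wave duration, so that regular slow beating (CL ~ 1 s) does not register
    spurious rests.  The leading interval before the first event is the
    start-up transient, not a rest.
    """
    rests = []
    crests = [e.t_crest for e in events]
    for a, b in zip(crests[:-1], crests[1:]):
        if (b - a) - nominal_wave_ms >= rest_min_ms:
            rests.append((a + nominal_wave_ms, b, False))
    if crests and (t_end - crests[-1]) - nominal_wave_ms >= rest_min_ms:
        rests.append((crests[-1] + nominal_wave_ms, t_end, True))
    return rests


def classify_state(events: list[WaveEvent], trace: Trace,
                   rest_min_ms: float = REST_MIN_MS,
                   nominal_wave_ms: float = NOMINAL_WAVE_MS,
                   transient_s: float = TRANSIENT_S,
                   state2_rest_factor: float = STATE2_REST_FACTOR) -> StateLabel:
    """Pattern-match the wave grammar onto one of the five states.

    State-2/3 detection uses the full record; the leading transient
    (``transient_s``, capped at a quarter of the record) is excluded only
    from the State-4 vs State-5 adjudication.
    """
    t_end = float(trace.time[-1])
    if t_end - float(trace.time[0]) < 2000.0:
        raise InsufficientDataError("trace shorter than 2 s cannot be classified")

    valid = [e for e in events if e.is_valid]
    n_valid = len(valid)
    n_inc = len(events) - n_valid
    evidence = {"n_valid": n_valid, "n_incomplete": n_inc}

    if n_valid == 0:
        evidence["n_rests"] = 1
        evidence["rest_intervals"] = [(float(trace.time[0]), t_end, True)]
        return StateLabel(state=1, evidence=evidence)

    # rests are intervals with no activity at all: incomplete waves count as
    # activity, so rest detection runs over every event
    rests = _rest_intervals(events, t_end, rest_min_ms, nominal_wave_ms)
    internal = [r for r in rests if not r[2]]
    terminal = [r for r in rests if r[2]]
    evidence["n_rests"] = len(rests)
    evidence["rest_intervals"] = rests

    if internal:
        # alternation of wave runs and rests: bursting.  Segment the valid
        # wave sequence at the internal rest boundaries.
        bursts = []
        cut_times = [r[0] for r in internal]
        seg_start = valid[0].t_crest
        n_in_seg = 0
        ci = 0
        for e in valid:
            if ci < len(cut_times) and e.t_crest > cut_times[ci]:
                bursts.append((seg_start, prev_t, n_in_seg))
                seg_start = e.t_crest
                n_in_seg = 0
                ci += 1
            n_in_seg += 1
            prev_t = e.t_crest
        bursts.append((seg_start, prev_t, n_in_seg))
        return StateLabel(state=3, evidence=evidence, bursts=bursts)

    if terminal:
        # waves then quiescence to the end of the record
        ups = [e.t_crest for e in valid]
        mean_cl = float(np.mean(np.diff(ups))) if len(ups) > 1 else rest_min_ms
        quiet = t_end - valid[-1].t_crest - nominal_wave_ms
        if quiet >= max(rest_min_ms, state2_rest_factor * mean_cl):
            return StateLabel(state=2, evidence=evidence)
        # short terminal lull: treat as persistent up to the record end

    # persistent activity: adjudicate State-4 vs State-5 after the transient
    cut = min(transient_s * 1000.0, 0.25 * t_end)
    late = [e for e in events if e.t_crest >= cut]
    late_inc = [e for e in late if not e.is_valid]
    evidence["n_incomplete_after_transient"] = len(late_inc)
    if late_inc:
        return StateLabel(state=4, evidence=evidence)
    return StateLabel(state=5, evidence=evidence)


def incomplete_period(events: list[WaveEvent]) -> int | None:
    """Modal number of cycles between successive incomplete waves.

    For the periodic State-4 pattern (W^(k-1) alphaW)^M this is k, the
    "one incomplete depolarization every k cycles" count.  Returns None if
    the event list contains no incomplete wave.
    """
    idx = [i for i, e in enumerate(events) if not e.is_valid]
    if not idx:
        return None
    gaps = np.diff(idx)
    if gaps.size == 0:
        return None
    return int(Counter(gaps.tolist()).most_common(1)[0][0])
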