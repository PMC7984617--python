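"""Synthetic voltage-trace generator with prescribed wave grammar.

Produces stylized action-potential trains realizing each of the five
pacemaking patterns exactly in the noise-free limit, so the classifier and
the metrics can be tested without integrating the ionic model.  The
waveform is a piecewise-smooth caricature of a pacemaker AP - exponential
diastolic depolarization, fast linear upstroke, exponential repolarization -
not a surrogate of the ODE dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classify import StateLabel
from .integrate import Trace
from .metrics import PacingMetrics

__all__ = ["FixtureSpec", "generate", "ground_truth", "linear_ramp"]

PATTERNS = ("quiescent", "transient", "bursting", "periodic-incomplete", "stable")

_STATE_OF_PATTERN = {
    "quiescent": 1,
    "transient": 2,
    "bursting": 3,
    "periodic-incomplete": 4,
    "stable": 5,
}


@dataclass
class FixtureSpec:
    """Recipe for a synthetic pacemaking trace.

    Times are ms unless suffixed ``_s``; voltages mV.  ``incomplete_every``
    = k means every k-th cycle is an incomplete wave peaking at
    ``incomplete_crest``.  ``seed`` fixes the additive-noise stream.
    """

    pattern: str = "stable"
    CL: float = 900.0
    MDP: float = -80.0
    crest: float = 30.0
    apd: float = 300.0               # nominal repolarization span, ms
    takeoff: float = -45.0           # end of the diastolic ramp, mV
    upstroke_ms: float = 2.0
    n_waves: int = 30                # waves before the terminal rest (transient)
    incomplete_every: int | None = None
    incomplete_crest: float = 0.0
    burst_lengths: tuple = (30.0, 30.0)   # s of beating per burst (bursting)
    rest_lengths: tuple = (30.0, 30.0)    # s of rest after each burst
    duration: float = 120.0          # s
    sample_interval: float = 1.0     # ms
    noise_sd: float = 0.0            # mV
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pattern not in PATTERNS:
            raise ValueError(f"pattern must be one of {PATTERNS}")
        if self.pattern == "periodic-incomplete":
            if self.incomplete_every is None:
                self.incomplete_every = 3
            if self.incomplete_every < 2:
                raise ValueError("incomplete_every must be >= 2")
        elif self.incomplete_every is not None:
            raise ValueError(
                f"incomplete_every is contradictory with pattern {self.pattern!r}")
        if not (self.crest > 20.0 > -20.0 > self.MDP):
            raise ValueError("valid-wave patterns require crest > 20 mV and MDP < -20 mV")
        if self.incomplete_crest > 20.0:
            raise ValueError("incomplete_crest must be <= 20 mV")
        if self.CL <= self.apd + self.upstroke_ms:
            raise ValueError("CL must exceed apd + upstroke duration")
        if self.sample_interval <= 0 or self.duration <= 0:
            raise ValueError("duration and sample_interval must be positive")
        # realizability: the record must be long enough to exhibit the
        # requested grammar
        ms = self.duration * 1000.0
        if self.pattern == "transient":
            tail = ms - self.n_waves * self.CL
            if tail < max(2000.0, 11.0 * self.CL):
                raise ValueError("transient spec: terminal rest too short to "
                                 "certify State-2 (need >= ~11 CL of quiet)")
        if self.pattern == "bursting":
            if min(self.rest_lengths) * 1000.0 < 2000.0:
                raise ValueError("bursting spec: rest_lengths must be >= 2 s")
            need = (self.burst_lengths[0] + self.rest_lengths[0]) * 1000.0 + 3.0 * self.CL
            if ms < need:
                raise ValueError("bursting spec: duration too short to reach "
                                 "the second burst")
        if self.pattern in ("stable", "periodic-incomplete") and ms < 8.0 * self.CL:
            raise ValueError("spec: duration must cover at least 8 cycles")


def _full_cycle(spec: FixtureSpec, tau: np.ndarray) -> np.ndarray:
    """One valid AP cycle evaluated at in-cycle times ``tau`` (ms)."""
    d = spec.CL - spec.apd - spec.upstroke_ms      # diastole span
    v = np.empty_like(tau)
    # diastolic depolarization: accelerating exponential, exact endpoints
    td = d / 2.0
    m1 = tau < d
    v[m1] = spec.MDP + (spec.takeoff - spec.MDP) * (
        np.expm1(tau[m1] / td) / np.expm1(d / td))
    # upstroke
    m2 = (tau >= d) & (tau < d + spec.upstroke_ms)
    v[m2] = spec.takeoff + (spec.crest - spec.takeoff) * (tau[m2] - d) / spec.upstroke_ms
    # repolarization: decaying exponential back to MDP, exact endpoints
    m3 = tau >= d + spec.upstroke_ms
    tr = spec.apd / 2.303
    x = tau[m3] - d - spec.upstroke_ms
    v[m3] = spec.crest - (spec.crest - spec.MDP) * (
        -np.expm1(-x / tr) / -np.expm1(-spec.apd / tr))
    return v


def _incomplete_cycle(spec: FixtureSpec, tau: np.ndarray) -> np.ndarray:
    """A sub-threshold depolarization hump spanning one cycle."""
    return spec.MDP + (spec.incomplete_crest - spec.MDP) * \
        np.sin(np.pi * tau / spec.CL) ** 2


def _cycle_sequence(spec: FixtureSpec) -> list[str]:
    """Per-slot plan of the record: 'W', 'a' (incomplete) or 'R' (one CL of rest)."""
    total = int(np.floor(spec.duration * 1000.0 / spec.CL))
    if spec.pattern == "quiescent":
        return ["R"] * total
    if spec.pattern == "stable":
        return ["W"] * total
    if spec.pattern == "transient":
        n = min(spec.n_waves, total)
        return ["W"] * n + ["R"] * (total - n)
    if spec.pattern == "periodic-incomplete":
        k = spec.incomplete_every
        return ["a" if (i + 1) % k == 0 else "W" for i in range(total)]
    # bursting: alternate beating and rest, cycling through the lists
    plan: list[str] = []
    i = 0
    while len(plan) < total:
        nb = max(1, int(round(spec.burst_lengths[i % len(spec.burst_lengths)]
                              * 1000.0 / spec.CL)))
        nr = max(1, int(round(spec.rest_lengths[i % len(spec.rest_lengths)]
                              * 1000.0 / spec.CL)))
        plan.extend(["W"] * nb)
        plan.extend(["R"] * nr)
        i += 1
    return plan[:total]


def generate(spec: FixtureSpec) -> Trace:
    """Render the spec into a uniformly sampled :class:`Trace`."""
    n = int(np.floor(spec.duration * 1000.0 / spec.sample_interval)) + 1
    t = np.arange(n) * spec.sample_interval
    v = np.full(n, spec.MDP, dtype=float)

    plan = _cycle_sequence(spec)
    for k, kind in enumerate(plan):
        if kind == "R":
            continue
        t0 = k * spec.CL
        m = (t >= t0) & (t < t0 + spec.CL)
        tau = t[m] - t0
        v[m] = _full_cycle(spec, tau) if kind == "W" else _incomplete_cycle(spec, tau)

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        v = v + rng.normal(0.0, spec.noise_sd, size=n)

    meta = {"fixture": {k: getattr(spec, k) for k in (
        "pattern", "CL", "MDP", "crest", "duration", "sample_interval",
        "noise_sd", "seed", "incomplete_every", "n_waves")}}
    return Trace(time=t, V=v, meta=meta)


def ground_truth(spec: FixtureSpec) -> tuple[StateLabel, PacingMetrics]:
    """Label and metrics implied analytically by the spec."""
    state = _STATE_OF_PATTERN[spec.pattern]
    plan = _cycle_sequence(spec)
    n_w = plan.count("W")
    n_a = plan.count("a")
    label = StateLabel(state=state,
                       evidence={"n_valid": n_w, "n_incomplete": n_a})
    m = PacingMetrics()
    if spec.pattern in ("stable", "periodic-incomplete", "transient", "bursting"):
        m.CL = spec.CL
        m.MDP = spec.MDP
        m.n_cycles = n_w
    if spec.pattern == "stable":
        m.valid_pacemaking = spec.CL <= 1000.0
        # diastolic velocity of the analytic ramp between MDP and -55 mV
        d = spec.CL - spec.apd - spec.upstroke_ms
        td = d / 2.0
        frac = (-55.0 - spec.MDP) / (spec.takeoff - spec.MDP)
        t_55 = td * np.log1p(frac * np.expm1(d / td))
        m.DI = float(t_55)
        m.diastolic_upstroke_velocity = float((-55.0 - spec.MDP) / t_55)
    return label, m


def linear_ramp(v0: float, v1: float, duration_ms: float,
                sample_interval: float = 1.0) -> Trace:
    """A linear voltage ramp, for slope/velocity oracle tests."""
    n = int(round(duration_ms / sample_interval)) + 1
    t = np.arange(n) * sample_interval
    return Trace(time=t, V=v0 + (v1 - v0) * t / duration_ms)
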