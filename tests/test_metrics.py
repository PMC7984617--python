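"""Pacing metrics against analytic oracles."""

import numpy as np
import pytest

from biopacer import (
    FixtureSpec,
    PacingMetrics,
    Trace,
    UndefinedMetricError,
    apd90,
    compute_metrics,
    cycle_length,
    detect_waves,
    diastolic_interval,
    di_current_integrals,
    generate,
    ground_truth,
    mdp,
)


def _square_wave(baseline=-80.0, crest=30.0, width_ms=200.0, cl_ms=1000.0,
                 n_cycles=6, dt=1.0):
    t = np.arange(0.0, n_cycles * cl_ms, dt)
    v = np.full_like(t, baseline)
    for k in range(n_cycles):
        m = (t >= k * cl_ms + 300.0) & (t < k * cl_ms + 300.0 + width_ms)
        v[m] = crest
    return Trace(time=t, V=v)


def test_cycle_length_periodic_train():
    spec = FixtureSpec(pattern="stable", CL=900.0)
    trace = generate(spec)
    assert cycle_length(trace) == pytest.approx(900.0, abs=spec.sample_interval)


def test_cycle_length_requires_two_valid_waves():
    t = np.arange(0.0, 10_000.0, 1.0)
    trace = Trace(time=t, V=np.full_like(t, -80.0))
    with pytest.raises(UndefinedMetricError):
        cycle_length(trace)


def test_mdp_of_train_and_constant():
    spec = FixtureSpec(pattern="stable", MDP=-78.0)
    trace = generate(spec)
    assert mdp(trace) == pytest.approx(-78.0, abs=0.2)
    t = np.arange(0.0, 10_000.0, 1.0)
    flat = Trace(time=t, V=np.full_like(t, -64.0))
    assert mdp(flat) == pytest.approx(-64.0)


def test_apd90_square_pulse_equals_width():
    """For a square pulse the 90%-repolarization duration is the pulse width."""
    trace = _square_wave(width_ms=200.0)
    assert apd90(trace, window=(0.0, trace.time[-1])) == pytest.approx(200.0, abs=3.0)


def test_apd90_below_cycle_length():
    spec = FixtureSpec(pattern="stable", CL=900.0, apd=300.0)
    trace = generate(spec)
    events = detect_waves(trace)
    assert apd90(trace, events) < cycle_length(trace, events)


def _ramp_wave_trace(n_cycles=3):
    """Cycles with an exactly linear -75 -> -55 mV diastolic ramp (200 ms)."""
    seg_t, seg_v = [], []
    t0 = 0.0
    for _ in range(n_cycles):
        # descend, ramp, upstroke, plateau-less decay
        pieces = [(-40.0, -75.0, 50.0), (-75.0, -55.0, 200.0),
                  (-55.0, 30.0, 2.0), (30.0, -40.0, 100.0)]
        for v0, v1, dur in pieces:
            tt = np.arange(0.0, dur, 1.0)
            seg_t.append(t0 + tt)
            seg_v.append(v0 + (v1 - v0) * tt / dur)
            t0 += dur
    return Trace(time=np.concatenate(seg_t), V=np.concatenate(seg_v))


def test_diastolic_velocity_linear_ramp():
    """A 20 mV / 200 ms diastolic ramp gives exactly 0.1 V/s."""
    trace = _ramp_wave_trace()
    t1, t2, di, vel = diastolic_interval(trace, window=(0.0, trace.time[-1]))
    assert vel == pytest.approx(0.1, rel=0.02)
    assert di == pytest.approx(200.0, abs=4.0)
    assert t1 < t2


def test_diastolic_velocity_matches_fixture_ground_truth():
    spec = FixtureSpec(pattern="stable", CL=900.0, MDP=-80.0)
    trace = generate(spec)
    _, gt_metrics = ground_truth(spec)
    _, _, di, vel = diastolic_interval(trace)
    assert vel == pytest.approx(gt_metrics.diastolic_upstroke_velocity, rel=0.05)
    assert di == pytest.approx(gt_metrics.DI, rel=0.05)


def test_di_integrals_of_constant_currents():
    """With constant current series the DI averages are those constants."""
    spec = FixtureSpec(pattern="stable", CL=900.0)
    trace = generate(spec)
    n = trace.time.size
    const = {"I_Na": -0.4, "I_NaCa": -0.2, "I_f_Na": -0.25, "I_f_K": 0.05,
             "I_K1": 0.3, "I_NaK": 0.35, "I_Kr": 0.1, "I_Ks": 0.05}
    trace.currents = {k: np.full(n, v) for k, v in const.items()}
    i_in, i_out = di_current_integrals(trace)
    assert i_in == pytest.approx(-0.4 - 0.2 - 0.25 + 0.05, rel=1e-9)
    assert i_out == pytest.approx(0.3 + 0.35 + 0.1 + 0.05, rel=1e-9)


def test_di_integrals_require_current_series():
    spec = FixtureSpec(pattern="stable")
    with pytest.raises(UndefinedMetricError):
        di_current_integrals(generate(spec))


def test_compute_metrics_stable_fixture():
    spec = FixtureSpec(pattern="stable", CL=900.0, MDP=-80.0)
    m = compute_metrics(generate(spec))
    assert isinstance(m, PacingMetrics)
    assert m.CL == pytest.approx(900.0, abs=1.5)
    assert m.MDP == pytest.approx(-80.0, abs=0.2)
    assert m.valid_pacemaking
    assert m.n_cycles > 50


def test_valid_pacemaking_requires_cl_at_most_1000():
    spec = FixtureSpec(pattern="stable", CL=1200.0, duration=150.0)
    m = compute_metrics(generate(spec))
    assert m.CL == pytest.approx(1200.0, abs=2.0)
    assert not m.valid_pacemaking


def test_simulated_di_integral_signs(sim):
    """Net inward currents are negative, outward positive, over the DI."""
    trace = sim(0.099, -0.63, 60.0, currents=True)
    i_in, i_out = di_current_integrals(trace, window=(30_000.0, 60_000.0))
    assert i_in < 0.0
    assert i_out > 0.0
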