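"""Wave detection and five-state grammar classification."""

import numpy as np
import pytest

from biopacer import (
    FixtureSpec,
    InsufficientDataError,
    Trace,
    classify_state,
    detect_waves,
    generate,
    ground_truth,
    incomplete_period,
)

PATTERNS = ("quiescent", "transient", "bursting", "periodic-incomplete", "stable")


@pytest.mark.parametrize("pattern", PATTERNS)
def test_noise_free_round_trip(pattern):
    """classify(generate(spec)) reproduces the spec's state exactly."""
    spec = FixtureSpec(pattern=pattern)
    trace = generate(spec)
    label = classify_state(detect_waves(trace), trace)
    assert label.state == ground_truth(spec)[0].state


@pytest.mark.parametrize("pattern", PATTERNS)
@pytest.mark.parametrize("seed", range(5))
def test_noisy_round_trip(pattern, seed):
    """Classification is robust to 2 mV additive Gaussian noise."""
    spec = FixtureSpec(pattern=pattern, noise_sd=2.0, seed=seed)
    trace = generate(spec)
    label = classify_state(detect_waves(trace), trace)
    assert label.state == ground_truth(spec)[0].state


@pytest.mark.parametrize("sample_interval", [1.0, 2.0, 5.0])
def test_downsampling_invariance(sample_interval):
    spec = FixtureSpec(pattern="periodic-incomplete",
                       sample_interval=sample_interval)
    trace = generate(spec)
    events = detect_waves(trace)
    assert classify_state(events, trace).state == 4
    assert incomplete_period(events) == 3


def test_valid_wave_thresholds():
    """Spikes crossing both +/-20 mV thresholds are W; low crests are alpha-W."""
    spec = FixtureSpec(pattern="stable", MDP=-80.0, crest=30.0)
    trace = generate(spec)
    events = detect_waves(trace)
    assert events and all(e.is_valid for e in events)
    # excursions peaking at 0 mV from -75 mV: incomplete
    spec2 = FixtureSpec(pattern="periodic-incomplete", MDP=-75.0,
                        incomplete_crest=0.0)
    ev2 = detect_waves(generate(spec2))
    incomplete = [e for e in ev2 if not e.is_valid]
    assert incomplete
    assert all(e.crest_V <= 20.0 and 0.0 < e.alpha < 1.0 for e in incomplete)


def test_crest_threshold_sharpness():
    """Clipping crests across the +20 mV line flips W -> alpha-W."""
    spec = FixtureSpec(pattern="stable", crest=30.0)
    base = generate(spec)
    just_above = Trace(time=base.time, V=np.minimum(base.V, 20.5))
    just_below = Trace(time=base.time, V=np.minimum(base.V, 19.5))
    assert all(e.is_valid for e in detect_waves(just_above))
    assert not any(e.is_valid for e in detect_waves(just_below))
    assert classify_state(detect_waves(just_above), just_above).state == 5
    assert classify_state(detect_waves(just_below), just_below).state != 5


def test_periodic_clipping_flips_state5_to_state4():
    """Lowering every third crest below +20 mV yields the State-4 pattern."""
    spec = FixtureSpec(pattern="stable", crest=30.0, CL=900.0)
    trace = generate(spec)
    v = trace.V.copy()
    for k in range(2, int(spec.duration * 1000 / spec.CL), 3):
        m = (trace.time >= k * spec.CL) & (trace.time < (k + 1) * spec.CL)
        v[m] = np.minimum(v[m], 15.0)
    clipped = Trace(time=trace.time, V=v)
    events = detect_waves(clipped)
    assert classify_state(events, clipped).state == 4
    assert incomplete_period(events) == 3


def test_constant_trace_is_state1():
    t = np.arange(0.0, 120_000.0, 1.0)
    trace = Trace(time=t, V=np.full_like(t, -86.0))
    events = detect_waves(trace)
    assert events == []
    label = classify_state(events, trace)
    assert label.state == 1
    assert label.evidence["n_rests"] == 1


def test_error_contracts():
    with pytest.raises(InsufficientDataError):
        detect_waves(Trace(time=np.array([0.0]), V=np.array([-80.0])))
    t = np.arange(0.0, 1000.0, 1.0)
    short = Trace(time=t, V=np.full_like(t, -80.0))
    with pytest.raises(InsufficientDataError):
        classify_state([], short)


def test_incomplete_period_none_for_all_valid():
    spec = FixtureSpec(pattern="stable")
    events = detect_waves(generate(spec))
    assert incomplete_period(events) is None


def test_burst_segmentation_counts():
    spec = FixtureSpec(pattern="bursting", CL=1000.0, duration=250.0,
                       burst_lengths=(40.0,), rest_lengths=(40.0,))
    trace = generate(spec)
    label = classify_state(detect_waves(trace), trace)
    assert label.state == 3
    assert label.bursts is not None and len(label.bursts) >= 2
    # each burst holds about 40 waves of CL 1 s
    for _, _, n in label.bursts[:-1]:
        assert 35 <= n <= 45


def test_wave_event_invariant():
    from biopacer.classify import WaveEvent
    with pytest.raises(ValueError):
        WaveEvent(t_trough=100.0, trough_V=-80.0, t_crest=50.0, crest_V=30.0,
                  is_valid=True)
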