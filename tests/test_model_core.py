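"""Unit and property tests of the hybrid ionic model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from biopacer import (
    CellState,
    InvalidStateError,
    ModelParameters,
    compute_currents,
    density_to_scale,
    derivatives,
    i_f_density,
    i_k1_density,
    iv_curve,
)
from biopacer.model import (
    CURRENT_NAMES,
    REFERENCE_CONDITIONS,
    RTONF,
    _y_inf,
    gate_steady_states,
    resting_state,
)


@pytest.mark.parametrize("s_k1, expected", [(1.0, 0.99), (0.4, 0.396),
                                            (0.1, 0.099), (0.0, 0.0)])
def test_ik1_density_anchor_scaling(s_k1, expected):
    """I_K1 at -80 mV under reference conditions scales as 0.99 * S_K1."""
    p = ModelParameters(S_K1=s_k1)
    assert i_k1_density(-80.0, p) == pytest.approx(expected, abs=1e-9)


@pytest.mark.parametrize("s_f, expected", [(1.0, -0.63), (5.0, -3.15),
                                           (10.0, -6.3)])
def test_if_density_anchor_scaling(s_f, expected):
    """Steady-state I_f at -80 mV scales as -0.63 * S_f."""
    p = ModelParameters(S_f=s_f)
    i_na, i_k, i_tot = i_f_density(-80.0, _y_inf(-80.0), p)
    assert i_tot == pytest.approx(expected, abs=1e-9)
    assert i_na + i_k == pytest.approx(i_tot, abs=1e-12)


def test_if_closed_gate_and_zero_scale():
    p = ModelParameters(S_f=3.0)
    assert i_f_density(-80.0, 0.0, p) == (0.0, 0.0, 0.0)
    p0 = ModelParameters(S_f=0.0)
    assert i_f_density(-60.0, 0.5, p0)[2] == 0.0


def test_ik1_zero_at_reversal_potential():
    """No driving force at V = E_K."""
    p = ModelParameters(S_K1=1.0)
    k_i = REFERENCE_CONDITIONS["K_i"]
    e_k = RTONF * math.log(p.K_o / k_i)
    assert i_k1_density(e_k, p, k_i) == pytest.approx(0.0, abs=1e-12)


@settings(derandomize=True, max_examples=50, deadline=None)
@given(v=st.floats(-120, 40), s=st.floats(0, 10))
def test_scaling_linearity(v, s):
    """Both engineered currents are exactly linear in their scaling factor."""
    base_k1 = i_k1_density(v, ModelParameters(S_K1=1.0))
    assert i_k1_density(v, ModelParameters(S_K1=min(s / 10.0, 1.0))) == \
        pytest.approx(min(s / 10.0, 1.0) * base_k1, rel=1e-12, abs=1e-12)
    y = _y_inf(v)
    base_f = i_f_density(v, y, ModelParameters(S_f=1.0))[2]
    assert i_f_density(v, y, ModelParameters(S_f=s))[2] == \
        pytest.approx(s * base_f, rel=1e-12, abs=1e-12)


def test_current_set_component_sum():
    """I_total is the algebraic sum of all components; I_f = I_f_Na + I_f_K."""
    p = ModelParameters(S_K1=0.3, S_f=3.0, include_I_CaT=True)
    state = resting_state(p)
    cs = compute_currents(state, p)
    total = sum(getattr(cs, n) for n in CURRENT_NAMES)
    assert cs.I_total == pytest.approx(total, rel=1e-12)
    assert cs.I_f == pytest.approx(cs.I_f_Na + cs.I_f_K, rel=1e-12)


def test_icat_absent_unless_enabled():
    state = resting_state()
    on = compute_currents(state, ModelParameters(include_I_CaT=True))
    off = compute_currents(state, ModelParameters(include_I_CaT=False))
    assert off.I_CaT == 0.0
    assert on.I_CaT != 0.0


def test_derivative_additivity_of_if():
    """Adding I_f changes dV/dt by exactly -I_f (densities, C_m normalized)."""
    state = resting_state()
    p0 = ModelParameters(S_K1=0.3, S_f=0.0)
    p1 = ModelParameters(S_K1=0.3, S_f=3.0)
    dv0 = derivatives(state, p0).V
    dv1 = derivatives(state, p1).V
    i_f = compute_currents(state, p1).I_f
    assert dv1 - dv0 == pytest.approx(-i_f, rel=1e-10)


def test_cm_scaling_halves_dvdt():
    state = resting_state()
    p1 = ModelParameters(S_K1=0.3, S_f=2.0)
    p2 = ModelParameters(S_K1=0.3, S_f=2.0, C_m=2 * p1.C_m)
    assert derivatives(state, p2).V == pytest.approx(
        derivatives(state, p1).V / 2.0, rel=1e-12)


def test_resting_derivatives_tiny_after_relaxation():
    """Relaxing the unmodified model lands on a quiescent fixed point."""
    from biopacer import SimulationConfig, integrate
    p = ModelParameters(S_K1=1.0, S_f=0.0)
    relaxed = integrate(p, SimulationConfig(duration=50.0)).final_state
    ds = derivatives(relaxed, p)
    assert abs(ds.V) < 0.01          # mV/ms
    assert abs(ds.Ca_i) < 1e-5       # mM/ms
    assert abs(ds.Na_i) < 1e-4
    # and the published initial state is itself close to rest
    ds0 = derivatives(resting_state(p), p)
    assert abs(ds0.V) < 0.1


def test_invalid_state_rejected():
    p = ModelParameters()
    bad = resting_state()
    bad.V = float("nan")
    with pytest.raises(InvalidStateError):
        compute_currents(bad, p)
    bad2 = resting_state()
    bad2.m = 1.5
    with pytest.raises(InvalidStateError):
        derivatives(bad2, p)
    bad3 = resting_state()
    bad3.Ca_i = -1e-6
    with pytest.raises(InvalidStateError):
        compute_currents(bad3, p)


def test_parameter_validation():
    with pytest.raises(ValueError):
        ModelParameters(S_K1=1.2)
    with pytest.raises(ValueError):
        ModelParameters(S_f=-0.1)
    with pytest.raises(ValueError):
        ModelParameters(cell_variant="apex")


def test_density_to_scale_roundtrip_and_errors():
    assert density_to_scale("I_K1", 0.297) == pytest.approx(0.30)
    assert density_to_scale("I_f", -1.89) == pytest.approx(3.0)
    assert density_to_scale("I_K1", 0.0) == 0.0
    with pytest.raises(ValueError):
        density_to_scale("I_K1", -0.1)
    with pytest.raises(ValueError):
        density_to_scale("I_f", 0.5)
    with pytest.raises(ValueError):
        density_to_scale("I_to", 1.0)
    # round trip through the I-V curve at -80 mV
    for scale in (0.1, 0.4, 1.0):
        curve = iv_curve("I_K1", scale, v_grid=[-80.0])
        assert density_to_scale("I_K1", curve[0, 1]) == pytest.approx(scale)
    curve = iv_curve("I_f", 3.0, v_grid=[-80.0])
    assert density_to_scale("I_f", curve[0, 1]) == pytest.approx(3.0)


def test_iv_curve_linearity_and_zero():
    v = np.arange(-110.0, 10.0, 5.0)
    base = iv_curve("I_K1", 1.0, v)
    scaled = iv_curve("I_K1", 0.4, v)
    np.testing.assert_allclose(scaled[:, 1], 0.4 * base[:, 1], rtol=1e-12)
    assert np.all(iv_curve("I_f", 0.0, v)[:, 1] == 0.0)
    with pytest.raises(ValueError):
        iv_curve("I_Kr", 1.0, v)


def test_gate_steady_states_bounded():
    for v in (-120.0, -86.2, -55.0, 0.0, 40.0):
        gates = gate_steady_states(v)
        assert all(0.0 <= g <= 1.0 for g in gates.values()), gates


def test_cellstate_array_roundtrip():
    s = resting_state()
    s2 = CellState.from_array(s.as_array())
    assert s2 == s
    with pytest.raises(ValueError):
        CellState.from_array(np.zeros(5))


def test_parameters_serialize_roundtrip():
    p = ModelParameters(S_K1=0.25, S_f=4.0, include_I_CaT=True)
    q = ModelParameters.from_dict(p.to_dict())
    assert q == p
    assert isinstance(p.to_dict()["S_K1"], float)
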