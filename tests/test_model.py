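import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import asersim as a
from asersim._kernel import _deriv
from asersim.errors import InvalidStateError
from asersim.model import IntegrationPlan, integrate_plan

TAU_D = 1.4

finite = st.floats(min_value=-10, max_value=10, allow_nan=False)
signed = st.one_of(st.just(0.0), finite)


@pytest.mark.parametrize("x_d, x_a, w_d, w_a", [
    (0.3, 0.1, 0.25, 0.75),        # both positive: less active side gets more
    (-0.2, 0.4, 1.0, 0.0),         # dendrite negative, axon positive
    (0.2, -0.4, 0.0, 1.0),         # dendrite positive, axon negative
    (-0.3, -0.1, 0.75, 0.25),      # both negative: shares swap
    (0.0, 0.0, 0.0, 0.0),
    (0.3, 0.0, 0.0, 1.0),
    (-0.3, 0.0, 1.0, 0.0),
    (0.0, 0.4, 0.0, 1.0),
    (0.0, -0.4, 0.0, 1.0),
])
def test_diffusion_weight_table(x_d, x_a, w_d, w_a):
    w = a.diffusion_weights(x_d, x_a)
    assert w.W_d == pytest.approx(w_d)
    assert w.W_a == pytest.approx(w_a)


def test_diffusion_weights_reject_nonfinite():
    with pytest.raises(InvalidStateError):
        a.diffusion_weights(float("nan"), 1.0)
    with pytest.raises(InvalidStateError):
        a.diffusion_weights(1.0, float("inf"))


@given(x_d=signed, x_a=signed)
def test_weight_table_exhaustive(x_d, x_a):
    """Every sign combination returns weights in [0,1]; same-sign nonzero
    activities split the somatic share exactly in two."""
    w = a.diffusion_weights(x_d, x_a)
    assert 0.0 <= w.W_d <= 1.0 and 0.0 <= w.W_a <= 1.0
    if x_d != 0 and x_a != 0 and np.sign(x_d) == np.sign(x_a):
        assert w.W_d + w.W_a == pytest.approx(1.0)
    if x_d == 0 and x_a == 0:
        assert (w.W_d, w.W_a) == (0.0, 0.0)


def test_rest_is_fixed_point():
    d = a.derivatives(a.NeuronState(), a.ModelParameters(), I=0.0,
                      stimulus_active=True)
    assert d.as_array().tolist() == [0.0] * 6


def test_input_drives_only_dendrite_when_uncoupled():
    d = a.derivatives(a.NeuronState(), a.ModelParameters(D=0.0), I=1.0,
                      stimulus_active=True)
    assert d.x_d == pytest.approx(1.0 / TAU_D)
    assert d.x_s == 0.0 and d.x_a == 0.0


def test_inactivation_integrates_self_activity():
    state = a.NeuronState(x_d=1.0)
    d = a.derivatives(state, a.ModelParameters(A=0.1), I=0.0,
                      stimulus_active=True)
    assert d.y_d == pytest.approx(-0.1)
    d_off = a.derivatives(state, a.ModelParameters(A=0.1), I=0.0,
                          stimulus_active=False)
    assert d_off.y_d == 0.0


@given(st.lists(finite, min_size=6, max_size=6), st.booleans())
def test_python_rhs_matches_compiled_kernel(state_vals, active):
    params = a.ModelParameters(D=2.5, Y_s=0.4, Y_a=-0.3, A=0.05)
    state = a.NeuronState(*state_vals)
    ref = a.derivatives(state, params, I=0.7, stimulus_active=active)
    out = np.empty(6)
    _deriv(state.as_array(), 0.7, active, params.tau_d, params.tau_s,
           params.tau_a, params.D, params.Y_s, params.Y_a, params.A, out)
    np.testing.assert_allclose(out, ref.as_array(), rtol=1e-14, atol=1e-14)


def test_integrator_matches_first_order_closed_form(step_proto):
    """With coupling and inactivation off, the dendrite is a pure first-order
    low-pass: rise 1 - exp(-(t-onset)/tau) and exponential decay after
    offset, matched to 1e-6 at every output sample."""
    tr = a.integrate(a.ModelParameters(D=0.0, A=0.0), step_proto)
    t = tr.time
    rise = (t >= 10) & (t <= 70)
    np.testing.assert_allclose(tr.x_d[rise], 1 - np.exp(-(t[rise] - 10) / TAU_D),
                               atol=1e-6, rtol=0)
    x_off = tr.x_d[t == 70.0][0]
    assert x_off == pytest.approx(1 - np.exp(-60 / TAU_D), abs=1e-6)
    fall = t > 70
    np.testing.assert_allclose(tr.x_d[fall], x_off * np.exp(-(t[fall] - 70) / TAU_D),
                               atol=1e-6, rtol=0)


def test_uncoupled_soma_axon_stay_zero(step_proto):
    tr = a.integrate(a.ModelParameters(D=0.0, Y_s=0.5, Y_a=0.5, A=0.1), step_proto)
    assert np.all(tr.x_s == 0.0) and np.all(tr.x_a == 0.0)


def test_no_stimulus_keeps_all_state_zero():
    # zero-level protocol with an (irrelevant) epoch produces no dynamics
    proto = a.step_protocol(10.0, 60.0, 0.0, 120.0)
    tr = a.integrate(a.REFERENCE_PARAMETERS, proto)
    for arr in (tr.x_d, tr.x_s, tr.x_a, tr.y_d, tr.y_s, tr.y_a):
        assert np.all(arr == 0.0)


def test_tolerance_halving_converged(step_proto):
    t1 = a.integrate(a.REFERENCE_PARAMETERS, step_proto, tol=1e-8)
    t2 = a.integrate(a.REFERENCE_PARAMETERS, step_proto, tol=5e-9)
    for r in ("dendrite", "soma", "axon"):
        assert np.abs(t1.region(r) - t2.region(r)).max() < 1e-6


def test_finer_output_sampling_preserves_shared_samples(step_proto):
    coarse = a.integrate(a.REFERENCE_PARAMETERS, step_proto, dt_out=0.1)
    fine = a.integrate(a.REFERENCE_PARAMETERS, step_proto, dt_out=0.05)
    shared = np.isin(fine.time, coarse.time)
    np.testing.assert_allclose(fine.x_d[shared], coarse.x_d, atol=1e-6, rtol=0)


def test_inactivation_gated_to_epoch(step_proto):
    tr = a.integrate(a.REFERENCE_PARAMETERS, step_proto)
    before, after = tr.time < 10, tr.time >= 70
    for y in (tr.y_d, tr.y_s, tr.y_a):
        assert np.all(y[before] == 0.0)
        assert np.all(y[after] == 0.0)       # hard reset at epoch end
    during = (tr.time > 15) & (tr.time < 70)
    assert np.all(tr.y_d[during] < 0.0)      # integrates -A*x_d < 0


def test_post_offset_decay_closed_form_with_y_reset():
    """After the upstep, with y clamped to zero and D = 0, the dendrite
    relaxes as a bare exponential from its value at offset."""
    proto = a.step_protocol(10.0, 60.0, 1.0, 120.0)
    tr = a.integrate(a.ModelParameters(D=0.0, A=0.05), proto)
    t = tr.time
    x_off = tr.x_d[t == 70.0][0]
    fall = t > 70
    np.testing.assert_allclose(tr.x_d[fall],
                               x_off * np.exp(-(t[fall] - 70) / TAU_D),
                               atol=1e-6, rtol=0)


def test_integration_plan_validation(step_proto):
    with pytest.raises(InvalidStateError):
        IntegrationPlan(step_proto, t_end=150.0)   # beyond protocol horizon
    with pytest.raises(InvalidStateError):
        IntegrationPlan(step_proto, t_end=120.0, dt_out=0.7)  # not a divisor
    plan = IntegrationPlan(step_proto, t_end=120.0, dt_out=0.1)
    out = integrate_plan(plan, a.REFERENCE_PARAMETERS)
    assert out.shape == (1201, 6)
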