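"""Time-window normalization, fire decision, leakage and baseline logic."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mramsim import (
    AnalogConfig,
    DeviceParams,
    NeuronState,
    fire_decision,
    integrate,
    integration_window,
    leak,
    select_baseline,
    step_neuron,
)


def _deflection(w, theta, cfg):
    """Membrane deflection of a w-alpha stimulus after window substitution."""
    return (w / theta) * (cfg.V_TH - cfg.V_CM_TWG)


def _fires_from(baseline, w, theta, cfg, offset=0.0):
    return fire_decision(baseline + _deflection(w, theta, cfg), cfg, offset)


def test_integration_window_closed_form():
    """C = 1 pF, ramp span 250 mV, theta = 5, alpha = 2.5 µA: 20 ns."""
    cfg = AnalogConfig(V_TH=0.85, V_CM_COL=0.62, V_CM_TWG=0.60)
    got = integration_window(5, cfg, DeviceParams())
    assert got == pytest.approx(20e-9)
    with pytest.raises(ValueError):
        integration_window(0, cfg, DeviceParams())


def test_window_ratio_and_vth_monotonicity(analog, params):
    t5 = integration_window(5, analog, params)
    t7 = integration_window(7, analog, params)
    assert t7 / t5 == pytest.approx(5 / 7)
    windows = [
        integration_window(
            5, dataclasses.replace(analog, V_TH=v), params
        )
        for v in np.arange(0.80, 0.851, 0.01)
    ]
    assert all(b > a for a, b in zip(windows, windows[1:]))


def test_integrate_signs(analog):
    assert integrate(0.6, 0.0, 20e-9, 1e-12) == 0.6
    assert integrate(0.6, -2 * 2.5e-6, 20e-9, 1e-12) < 0.6


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    alpha_scale=st.floats(0.5, 2.0),
    c_exp=st.integers(-14, -10),
    w=st.integers(-2, 7),
    theta=st.integers(1, 7),
)
def test_deflection_is_normalized_to_weight_over_threshold(
    alpha_scale, c_exp, w, theta
):
    """After substituting T_int, ΔV = (w/θ)(V_TH − V_CM_TWG): no alpha, no C."""
    params = DeviceParams(V_READ_AMP=50e-3 * alpha_scale)
    cfg = AnalogConfig(C_int=10.0**c_exp)
    T = integration_window(theta, cfg, params)
    got = integrate(cfg.V_REST, w * params.alpha, T, cfg.C_int) - cfg.V_REST
    assert got == pytest.approx(_deflection(w, theta, cfg), rel=1e-9)


def test_fires_exactly_from_weight_equal_threshold(analog):
    """Brute force from rest: fire iff w >= theta, for every theta in range."""
    for theta in range(1, 8):
        for w in range(-4, 10):
            assert _fires_from(analog.V_REST, w, theta, analog) == (w >= theta), (
                f"w={w}, theta={theta}"
            )


def test_refractory_and_inhibited_baselines_block_threshold_weight(analog):
    assert analog.refractory_blocks_threshold()
    for theta in range(1, 8):
        assert not _fires_from(analog.V_RFR, theta, theta, analog)
        assert not _fires_from(analog.V_LAT, theta, theta, analog)


def test_oversized_margin_rejected():
    # delta = 50 mV would let w = theta_max - 1 reach V_TH
    with pytest.raises(ValueError, match="margin delta"):
        AnalogConfig(V_CM_TWG=0.550)


def test_leak_fixed_point_no_overshoot_and_convergence(analog):
    assert leak(analog.V_REST, analog) == analog.V_REST
    assert leak(analog.V_REST + 0.003, analog) == analog.V_REST  # clamped
    hi, lo = analog.V_REST + 0.1, analog.V_REST - 0.1
    assert leak(hi, analog) < hi
    assert leak(lo, analog) > lo
    v, steps = hi, 0
    while v != analog.V_REST:
        v = leak(v, analog)
        steps += 1
        assert steps < 1000
    assert v == analog.V_REST


def test_leak_step_scales_with_pulse_width_and_current(analog):
    v0 = analog.V_REST + 0.1
    base_drop = v0 - leak(v0, analog)
    double_t = dataclasses.replace(analog, t_leak=2 * analog.t_leak)
    double_i = dataclasses.replace(analog, I_LEAKAGE=2 * analog.I_LEAKAGE)
    assert v0 - leak(v0, double_t) == pytest.approx(2 * base_drop)
    assert v0 - leak(v0, double_i) == pytest.approx(2 * base_drop)


def test_baseline_selector_priority(analog):
    assert select_baseline(True, True, True, analog) == analog.V_RFR
    assert select_baseline(False, True, True, analog) == analog.V_LAT
    assert select_baseline(False, False, True, analog) == analog.V_GEN
    assert select_baseline(False, False, False, analog) == analog.V_REST


def test_baseline_ordering_enforced():
    with pytest.raises(ValueError, match="V_LAT < V_RFR < V_REST"):
        AnalogConfig(V_RFR=0.61)


def test_step_neuron_relative_refractory(analog, params):
    """A threshold-equal stimulus right after a spike cannot fire again."""
    theta = 5
    state = NeuronState.resting(analog)
    state, fired = step_neuron(state, theta * params.alpha, theta, analog, params, n_abs=0)
    assert fired and state.baseline == analog.V_RFR
    state, fired = step_neuron(state, theta * params.alpha, theta, analog, params, n_abs=0)
    assert not fired


def test_step_neuron_absolute_refractory_gates_input(analog, params):
    """During the gated interval no input fires, however strong."""
    theta = 2
    state = NeuronState.resting(analog)
    state, fired = step_neuron(state, theta * params.alpha, theta, analog, params, n_abs=3)
    assert fired and state.abs_refractory_remaining == 3
    huge = 100 * params.alpha
    for _ in range(3):
        state, fired = step_neuron(state, huge, theta, analog, params, n_abs=3)
        assert not fired
    # gate released: the strong input fires again
    state, fired = step_neuron(state, huge, theta, analog, params, n_abs=3)
    assert fired


def test_step_neuron_subthreshold_sets_generic_baseline(analog, params):
    state = NeuronState.resting(analog)
    state, fired = step_neuron(state, 2 * params.alpha, 5, analog, params)
    assert not fired
    assert state.subthreshold_last
    assert state.baseline == analog.V_GEN
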