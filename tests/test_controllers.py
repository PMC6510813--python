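"""Feedback laws: integral, linear-quadratic, generalized, bang-bang."""

import math

import numpy as np
import pytest

from homeorate.engine import SimConfig, Trajectory, integrate
from homeorate.controllers import (
    BangBangSpec,
    ControlFunction,
    DualLinQuadSpec,
    IntegralLoopState,
    bangbang_derivatives,
    check_curvature_condition,
    conductance_homeostasis_derivative,
    detect_windup,
    fixed_point_variance,
    generalized_derivatives,
    integral_feedback_derivative,
    quadlin_derivatives,
)
from homeorate.neuron import sigmoid_rate


# -- integral feedback -------------------------------------------------------

def test_integral_feedback_derivative_values():
    at_goal = IntegralLoopState(X=1.0, X_goal=1.0, tau_fb=2.0)
    assert integral_feedback_derivative(at_goal) == 0.0
    assert at_goal.E == 0.0
    below = IntegralLoopState(X=0.0, X_goal=1.0, tau_fb=1.0)
    assert integral_feedback_derivative(below) == pytest.approx(1.0)


def test_integral_loop_converges_to_set_point():
    """Closed loop X = F(I_ext + I_fb) with logistic F: after many
    feedback time constants the output sits at X_goal."""
    X_goal, I_ext, tau_fb = 0.7, -2.0, 1.0

    def F(I):
        return 1.0 / (1.0 + math.exp(-I))

    def deriv(t, y, u):
        X = F(I_ext + y[0])
        return np.array([(X_goal - X) / tau_fb])

    cfg = SimConfig(dt=1e-3, duration=30.0, record_stride=100)
    traj = integrate(deriv, {"I_fb": 0.0}, cfg)
    assert F(I_ext + traj["I_fb"][-1]) == pytest.approx(X_goal, rel=0.01)


def test_conductance_homeostasis_signs_and_convergence(neuron):
    assert conductance_homeostasis_derivative(10.0, 10.0, 5.0) == 0.0
    assert conductance_homeostasis_derivative(5.0, 10.0, 5.0) > 0  # scale up
    with pytest.raises(ValueError):
        conductance_homeostasis_derivative(5.0, 10.0, 0.0)

    # closed loop of the rate equation plus synaptic scaling: the mean
    # rate converges to the target for a slowly varying input
    r_goal, tau_g, S_E = 20.0, 1.0, 5.0

    def deriv(t, y, u):
        r, g = y
        F = sigmoid_rate(g * S_E - neuron.T, neuron.r_max, neuron.sigma)
        return np.array(
            [(-r + F) / neuron.tau_r, (r_goal - r) / tau_g]
        )

    cfg = SimConfig(dt=1e-3, duration=20.0, record_stride=100)
    traj = integrate(deriv, {"r": 1.0, "g_E": 0.1}, cfg,
                     smallest_time_constant=neuron.tau_r)
    assert traj["r"][-1] == pytest.approx(r_goal, rel=0.01)


# -- dual linear-quadratic ---------------------------------------------------

def test_quadlin_derivative_values():
    spec = DualLinQuadSpec(10.0, 15.0, tau_T=500.0, tau_g=500.0)
    assert quadlin_derivatives(10.0, spec)[0] == 0.0
    assert quadlin_derivatives(15.0, spec)[1] == 0.0
    dT, dg = quadlin_derivatives(12.0, spec)
    assert dT == pytest.approx(0.004)
    assert dg == pytest.approx((225.0 - 144.0) / 500.0)


def test_fixed_point_variance_and_feasibility():
    var, ok = fixed_point_variance(DualLinQuadSpec(10.0, 15.0))
    assert var == pytest.approx(125.0) and ok
    var, ok = fixed_point_variance(DualLinQuadSpec(15.0, 10.0))
    assert var < 0 and not ok
    var, ok = fixed_point_variance(DualLinQuadSpec(10.0, 10.0))
    assert var == 0.0 and not ok  # degenerate boundary


def test_generalized_reduces_to_quadlin_exactly():
    spec = DualLinQuadSpec(10.0, 15.0, tau_T=7.0, tau_g=13.0)
    ident, square = ControlFunction.identity(), ControlFunction.square()
    for r in np.linspace(0.0, 60.0, 121):
        expected = quadlin_derivatives(r, spec)
        got = generalized_derivatives(
            r, ident, square, 10.0, 15.0, 7.0, 13.0
        )
        assert got == expected  # exact, not approximate


def test_generalized_cubic_control_remains_bounded(neuron):
    """Identity/cube control functions with stable target ordering
    settle to bounded conductance and threshold (no wind-up)."""
    cube = ControlFunction.power(3)
    ident = ControlFunction.identity()
    assert check_curvature_condition(ident, cube, 10.0, 15.0)
    S_levels = np.random.default_rng(4).normal(15.0, 5.0, 4000)

    def deriv(t, y, u):
        r, g, T = y
        F = sigmoid_rate(g * u - T, neuron.r_max, neuron.sigma)
        dT, dg = generalized_derivatives(
            r, ident, cube, 10.0, 15.0, 2.0, 60.0
        )
        return np.array([(-r + F) / neuron.tau_r, dg, dT])

    cfg = SimConfig(dt=1e-3, duration=200.0, record_stride=20)
    drive = np.repeat(S_levels, 50)
    traj = integrate(deriv, {"r": 10.0, "g_E": 3.0, "T": 60.0}, cfg,
                     drive=drive, floors={"g_E": 0.0},
                     smallest_time_constant=neuron.tau_r)
    windup = detect_windup(traj, ["g_E", "T"], window=40.0, bound=500.0)
    assert not any(windup.values())
    assert traj["r"][len(traj.times) // 2:].mean() == pytest.approx(10.0, rel=0.15)


# -- curvature condition -----------------------------------------------------

def test_curvature_condition_cases():
    lin, sq = ControlFunction.identity(), ControlFunction.square()
    assert check_curvature_condition(lin, sq, 10.0, 15.0)
    assert not check_curvature_condition(lin, lin, 10.0, 15.0)  # fine-tuning
    assert not check_curvature_condition(sq, lin, 15.0, 10.0)  # flipped


def test_curvature_index_finite_difference_matches_analytic():
    analytic = ControlFunction.square()
    numeric = ControlFunction(lambda r: r * r)
    for r in (5.0, 10.0, 20.0):
        assert numeric.curvature_index(r) == pytest.approx(
            analytic.curvature_index(r), rel=1e-4
        )
    decreasing = ControlFunction(lambda r: -r)
    with pytest.raises(ValueError):
        decreasing.curvature_index(10.0)


# -- bang-bang ---------------------------------------------------------------

def test_bangbang_derivative_cases():
    spec = BangBangSpec(1.0, 15.0, 0.5, 0.1, tau_T=2.0, tau_g=4.0)
    assert spec.cooperative
    # below both step-points: both Heavisides are 0
    dT, dg = bangbang_derivatives(0.5, spec)
    assert dT == pytest.approx(-0.5 / 2.0)
    assert dg == pytest.approx(0.1 / 4.0)
    # above both: conductance decreases at the constant rate (1-p_g)/tau_g
    dT, dg = bangbang_derivatives(20.0, spec)
    assert dT == pytest.approx(0.5 / 2.0)
    assert dg == pytest.approx((0.1 - 1.0) / 4.0)
    # exactly at a step-point: H(0) = 1
    dT_at, _ = bangbang_derivatives(1.0, spec)
    assert dT_at == pytest.approx((1.0 - 0.5) / 2.0)


def test_bangbang_spec_flags():
    assert not BangBangSpec(15.0, 1.0, 0.5, 0.1).cooperative  # flipped steps
    assert not BangBangSpec(1.0, 15.0, 0.1, 0.5).cooperative  # flipped fracs
    with pytest.raises(ValueError):
        BangBangSpec(1.0, 15.0, 0.0, 0.1)
    with pytest.raises(ValueError):
        BangBangSpec(1.0, 15.0, 0.5, 0.1, tau_T=0.0)


# -- wind-up detector --------------------------------------------------------

def _traj(values, dt=1.0):
    values = np.asarray(values, dtype=float)
    return Trajectory(times=np.arange(len(values)) * dt, series={"x": values})


def test_windup_detector_cases(rng):
    n = 1000
    assert not detect_windup(_traj(np.full(n, 5.0)), ["x"], window=100)["x"]
    ramp = np.linspace(0.0, 50.0, n)
    assert detect_windup(_traj(ramp), ["x"], window=100)["x"]
    # converged noisy oscillation around a level: not wind-up
    osc = 20.0 + np.sin(np.arange(n) / 7.0) + rng.normal(0, 0.3, n)
    assert not detect_windup(_traj(osc), ["x"], window=100)["x"]
    # exceeding the biophysical bound flags regardless of trend
    spike = np.full(n, 5.0)
    spike[500] = 1e4
    assert detect_windup(_traj(spike), ["x"], window=100, bound=500)["x"]
    with pytest.raises(ValueError):
        detect_windup(_traj(np.ones(10)), ["x"], window=100.0)
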