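"""Biochemical cascade: kinetics, integration placement, filtering."""

import math
from dataclasses import replace

import numpy as np
import pytest

from homeorate.engine import SimConfig, integrate
from homeorate.inputs import InputRegime, RegimeSchedule, make_regime_input
from homeorate.cascade import (
    CascadeConfigError,
    CascadeParams,
    CascadeState,
    DegradationSpec,
    calcium_derivative,
    cascade_derivatives,
    classify_kinase,
    hill_loss_rate,
    simulate_cascade,
    variance_transfer_ratio,
)


# -- degradation laws --------------------------------------------------------

def test_hill_loss_rate_regimes():
    sat = DegradationSpec(kind="saturating", K_half=2.0, hill_n=1.0, V_max=6.0)
    assert hill_loss_rate(0.0, sat) == 0.0
    assert hill_loss_rate(2.0, sat) == pytest.approx(3.0)  # half-saturation
    assert hill_loss_rate(2000.0, sat) == pytest.approx(6.0, rel=1e-2)
    lin = DegradationSpec(kind="linear", rate_constant=0.5)
    assert hill_loss_rate(4.0, lin) == pytest.approx(2.0)
    const = DegradationSpec(kind="constant", V_max=7.0)
    assert hill_loss_rate(0.0, const) == 7.0  # zeroth order: P-independent
    assert hill_loss_rate(1e6, const) == 7.0
    with pytest.raises(ValueError):
        hill_loss_rate(-1.0, lin)
    with pytest.raises(CascadeConfigError):
        DegradationSpec(kind="bogus")
    with pytest.raises(CascadeConfigError):
        DegradationSpec(kind="saturating", hill_n=0.5)


def test_hill_saturating_is_monotone_and_bounded():
    sat = DegradationSpec(kind="saturating", K_half=3.0, hill_n=2.0, V_max=5.0)
    P = np.linspace(0.0, 50.0, 400)
    rate = hill_loss_rate(P, sat)
    assert np.all(np.diff(rate) >= 0)
    assert rate.min() >= 0.0 and rate.max() <= 5.0


# -- calcium stage -----------------------------------------------------------

def test_calcium_steady_state_and_decay():
    tau_C = 0.1
    cfg = SimConfig(dt=1e-3, duration=2.0)
    traj = integrate(
        lambda t, y, u: np.array([calcium_derivative(y[0], 30.0, tau_C)]),
        {"C": 0.0}, cfg,
    )
    assert traj["C"][-1] == pytest.approx(30.0 * tau_C, rel=0.01)

    decay = integrate(
        lambda t, y, u: np.array([calcium_derivative(y[0], 0.0, tau_C)]),
        {"C": 1.0}, SimConfig(dt=1e-3, duration=0.1),
    )
    assert decay["C"][-1] == pytest.approx(math.exp(-1.0), rel=0.01)


def test_calcium_filters_rate_fluctuations_by_sqrt_tau_law():
    """Slower removal damps fluctuations: increasing tau_C 100-fold
    shrinks the relative sd of calcium ~10-fold for a rapidly
    switching rate."""
    rng = np.random.default_rng(6)
    dt, hold = 5e-3, 0.1
    draws = rng.normal(20.0, 6.0, 10_000).clip(min=0.0)
    r_steps = np.repeat(draws, int(hold / dt))
    cfg = SimConfig(dt=dt, duration=len(r_steps) * dt)
    rel_sd = {}
    for tau_C in (0.1, 10.0):
        traj = integrate(
            lambda t, y, u: np.array([calcium_derivative(y[0], u, tau_C)]),
            {"C": 20.0 * tau_C}, cfg, drive=r_steps,
        )
        C = traj["C"][int(20 * tau_C / dt):]
        rel_sd[tau_C] = C.std() / C.mean()
    ratio = rel_sd[0.1] / rel_sd[10.0]
    assert rel_sd[10.0] < 0.2 * rel_sd[0.1]
    assert ratio == pytest.approx(math.sqrt(100.0), rel=0.2)


# -- pathway derivatives -----------------------------------------------------

def test_single_mode_fixed_point_has_zero_derivatives():
    params = CascadeParams.default_single()
    # rate at which the saturating cubic drive balances D_K = 18
    C = (18.0 * 40.0 / (400.0 - 18.0)) ** (1.0 / 3.0)
    r = C / params.tau_C
    K = 20.0  # any level: the integrating stage is substrate-independent
    state = CascadeState(
        C=C, K=K,
        m_g=params.f_mg(K), m_T=params.f_mT(K),
        g=params.f_mg(K) / params.D_g.rate_constant,
        T=params.f_mT(K) / params.D_T.rate_constant,
    )
    deriv = cascade_derivatives(state, params, r)
    assert np.allclose(deriv, 0.0, atol=1e-10)


def test_branch_point_topology():
    """K is the single branch point: m_g and m_T react to K only, and
    perturbing m_g never feeds back into C, K or m_T."""
    params = CascadeParams.default_dual()
    base = CascadeState(C=1.0, K=18.0, m_g=419.0, m_T=18.0, g=2.0, T=50.0)
    bumped = replace(base, m_g=500.0)
    d0 = cascade_derivatives(base, params, 12.0)
    d1 = cascade_derivatives(bumped, params, 12.0)
    # only m_g's own equation and the downstream g equation change
    changed = np.flatnonzero(d0 != d1)
    assert set(changed) <= {2, 4}


def test_mode_degradation_kind_mismatch_rejected():
    with pytest.raises(CascadeConfigError, match="D_g"):
        CascadeParams(mode="dual", D_g=DegradationSpec(kind="linear"))
    with pytest.raises(CascadeConfigError, match="D_K"):
        CascadeParams(mode="single")  # D_K defaults to a filter
    with pytest.raises(CascadeConfigError, match="mode"):
        CascadeParams(mode="triple")


def test_dual_feasibility_constraint_enforced():
    """The conductance-stage loss must satisfy D_g >= D_T**2 for the
    implied kinase variance to be nonnegative."""
    with pytest.raises(CascadeConfigError, match="D_T"):
        CascadeParams(
            mode="dual",
            D_g=DegradationSpec(kind="constant", V_max=300.0),
            D_T=DegradationSpec(kind="constant", V_max=18.0),
        )
    CascadeParams(  # boundary value is allowed
        mode="dual",
        D_g=DegradationSpec(kind="constant", V_max=324.0),
        D_T=DegradationSpec(kind="constant", V_max=18.0),
    )


def test_kinase_drive_is_cubic_at_low_calcium():
    params = CascadeParams.default_dual()
    assert params.f_K(0.2) == pytest.approx(10.0 * 0.2**3, rel=0.01)
    pure = replace(params, f_K_max=None)
    assert pure.f_K(10.0) == pytest.approx(10.0 * 1000.0)


def test_classify_kinase():
    assert classify_kinase([18.0, 18.5, 17.6, 18.2]) == "tracking"
    assert classify_kinase([18.0, 30.0, 11.0, 23.0]) == "integrating"


def test_simulate_cascade_smoke_and_nonnegativity(neuron):
    params = CascadeParams.default_dual()
    sched = RegimeSchedule(
        regimes=(InputRegime(15.0, 5.0),), regime_duration=40.0,
        switch_interval=0.1, seed=2,
    )
    signal, bounds = make_regime_input(sched)
    cfg = SimConfig(dt=1e-3, duration=40.0, record_stride=20, seed=2)
    traj, summary = simulate_cascade(
        params, signal, neuron, cfg, regime_boundaries=bounds
    )
    assert set(traj.variables) == {"r", "C", "K", "m_g", "m_T", "g", "T"}
    for name in ("r", "C", "K", "m_g", "m_T", "g"):
        assert traj[name].min() >= 0.0
    assert summary["mode"] == "dual"
    assert len(summary["regime_rate_mean"]) == 1


# -- filtering law -----------------------------------------------------------

def test_variance_transfer_equal_taus_is_unity():
    result = variance_transfer_ratio(0.5, 0.5, dt=1e-2, n_steps=200_000, seed=0)
    assert result.sd_ratio == pytest.approx(1.0)
    assert result.var_ratio == pytest.approx(1.0)


def test_variance_transfer_fourfold_tau_gives_twofold_sd():
    """White-noise-driven first-order filters: stationary variance
    scales as 1/tau, so a 4-fold tau ratio halves the sd.  The exact
    discrete-time expectation is (tau_s/tau_f)*(2-dt/tau_s)/(2-dt/tau_f)."""
    dt, tf, ts = 1e-3, 0.025, 0.1
    result = variance_transfer_ratio(tf, ts, dt=dt, n_steps=2_000_000, seed=3)
    expected_var = (ts / tf) * (2 - dt / ts) / (2 - dt / tf)
    assert result.var_ratio == pytest.approx(expected_var, rel=0.06)
    assert result.sd_ratio == pytest.approx(math.sqrt(expected_var), rel=0.03)


def test_variance_transfer_validation():
    with pytest.raises(ValueError):
        variance_transfer_ratio(1.0, 0.5)
    with pytest.raises(ValueError):
        variance_transfer_ratio(0.01, 1.0, dt=0.5)
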