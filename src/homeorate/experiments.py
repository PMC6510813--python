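"""Closed-loop experiment runners.

Each runner wires a neuron model, an input protocol and a controller
into one forward-Euler simulation and reduces the trajectory to a
summary of the homeostatic quantities of interest: per-regime rate
statistics, fixed-point feasibility, wind-up flags, time-fraction
statistics, kinase classification, mutual information, or filter
attenuation ratios.  The CLI and the acceptance analyses are thin
wrappers over these functions.
"""

from __future__ import annotations

import math

import numpy as np

from .engine import SimConfig, Trajectory, integrate, epoch_statistics
from .inputs import (
    InputSignal,
    RegimeSchedule,
    SteppedInputSpec,
    make_regime_input,
    make_stepped_input,
)
from .neuron import NeuronParams, noisy_logistic_response
from .controllers import (
    BangBangSpec,
    ControlFunction,
    DualLinQuadSpec,
    check_curvature_condition,
    detect_windup,
    fixed_point_variance,
)
from .cascade import CascadeParams, FilterRatio, simulate_cascade, variance_transfer_ratio
from .metrics import io_correlation, mutual_information

__all__ = [
    "run_quadlin",
    "run_bangbang",
    "run_cascade",
    "run_mi_sweep",
    "run_filter_ratio",
    "DEFAULT_MI_PARAM_SETS",
]


def _logistic_rate(r_max: float, sigma: float):
    exp = math.exp

    def F(X: float) -> float:
        z = X / sigma
        if z < -700.0:
            return 0.0
        if z > 700.0:
            return r_max
        return r_max / (1.0 + exp(-z))

    return F


def _quadlin_derivative(neuron: NeuronParams, spec: DualLinQuadSpec):
    F = _logistic_rate(neuron.r_max, neuron.sigma)
    tau_r = neuron.tau_r
    rT, rg2 = spec.r_goal_T, spec.r_goal_g**2
    tau_T, tau_g = spec.tau_T, spec.tau_g

    def deriv(t, y, u):
        r, g, T = y
        return np.array(
            [
                (-r + F(g * u - T)) / tau_r,
                (rg2 - r * r) / tau_g,
                (r - rT) / tau_T,
            ]
        )

    return deriv


def _bangbang_derivative(neuron: NeuronParams, spec: BangBangSpec):
    F = _logistic_rate(neuron.r_max, neuron.sigma)
    tau_r = neuron.tau_r
    sT, sg = spec.r_step_T, spec.r_step_g
    pT, pg = spec.p_T, spec.p_g
    tau_T, tau_g = spec.tau_T, spec.tau_g

    def deriv(t, y, u):
        r, g, T = y
        return np.array(
            [
                (-r + F(g * u - T)) / tau_r,
                (pg - (1.0 if r >= sg else 0.0)) / tau_g,
                (-pT + (1.0 if r >= sT else 0.0)) / tau_T,
            ]
        )

    return deriv


#: Magnitude treated as a non-physiological level by the wind-up
#: diagnostics: functioning configurations keep conductance and
#: threshold one to two orders of magnitude below this.
WINDUP_BOUND = 500.0


def _controller_run(
    deriv,
    neuron: NeuronParams,
    schedule: RegimeSchedule,
    sim: SimConfig,
    g0: float,
    T0: float,
    r0: float,
    floor_g: float | None = 0.0,
    windup_bound: float | None = WINDUP_BOUND,
) -> tuple[Trajectory, InputSignal, np.ndarray, dict]:
    signal, boundaries = make_regime_input(schedule)
    if abs(schedule.duration - sim.duration) > 1e-9:
        raise ValueError(
            f"sim duration {sim.duration} s does not match the "
            f"schedule duration {schedule.duration} s"
        )
    traj = integrate(
        deriv,
        {"r": r0, "g_E": g0, "T": T0},
        sim,
        drive=signal,
        floors={"g_E": floor_g} if floor_g is not None else None,
        smallest_time_constant=neuron.tau_r,
        meta={"noise_convention": signal.meta.get("noise_convention")},
    )
    # trend windows sit inside the final regime: regime boundaries force
    # legitimate controller transits that must not read as wind-up
    window = schedule.regime_duration / 3.0
    windup = detect_windup(
        traj, ["g_E", "T"], window=window, bound=windup_bound
    )
    return traj, signal, boundaries, windup


def run_quadlin(
    neuron: NeuronParams,
    spec: DualLinQuadSpec,
    schedule: RegimeSchedule,
    sim: SimConfig,
    g0: float = 5.0,
    T0: float = 100.0,
    discard: float = 0.5,
    floor_g: float | None = 0.0,
) -> tuple[Trajectory, dict]:
    """Dual linear-quadratic homeostasis across an input-regime schedule.

    The summary reports, per regime, the post-transient mean and RMS
    firing rate (the controller set-points when the system functions),
    the implied fixed-point variance and feasibility, and wind-up
    flags on conductance and threshold.

    With the default conductance floor at 0, an infeasible (flipped)
    target ordering ends with the conductance pinned at zero and an
    unresponsive neuron (reported as ``g_pinned_at_zero``); lifting
    the floor (``floor_g=None``) lets the same instability escape to
    non-physiological levels, the wind-up proper.
    """
    deriv = _quadlin_derivative(neuron, spec)
    traj, signal, boundaries, windup = _controller_run(
        deriv, neuron, schedule, sim, g0, T0,
        r0=spec.r_goal_T, floor_g=floor_g,
    )
    stats = epoch_statistics(traj, "r", boundaries, discard)
    mean_sq = stats["var"].to_numpy() + stats["mean"].to_numpy() ** 2
    var_target, feasible = fixed_point_variance(spec)
    g = traj["g_E"]
    tail = traj.times >= traj.times[-1] - schedule.regime_duration / 2
    g_pinned = bool(
        floor_g is not None and np.mean(g[tail] <= floor_g + 1e-9) > 0.9
    )
    summary = {
        "experiment": "quadlin",
        "r_goal_T": spec.r_goal_T,
        "r_goal_g": spec.r_goal_g,
        "feasible": feasible,
        "fixed_point_variance": var_target,
        "curvature_condition_ok": check_curvature_condition(
            ControlFunction.identity(), ControlFunction.square(),
            spec.r_goal_T, spec.r_goal_g,
        ),
        "regime_rate_mean": stats["mean"].tolist(),
        "regime_rate_var": stats["var"].tolist(),
        "regime_rate_rms": np.sqrt(mean_sq).tolist(),
        "g_pinned_at_zero": g_pinned,
        "windup": windup,
        "windup_any": any(windup.values()),
    }
    return traj, summary


def run_bangbang(
    neuron: NeuronParams,
    spec: BangBangSpec,
    schedule: RegimeSchedule,
    sim: SimConfig,
    g0: float = 5.0,
    T0: float = 220.0,
    discard: float = 0.5,
) -> tuple[Trajectory, dict]:
    """Dual bang-bang homeostasis across an input-regime schedule.

    The summary reports the long-run fractions of time the rate spends
    at or above each step-point (targets ``p_T`` and ``p_g`` when
    converged), computed per regime on post-transient samples and
    pooled, plus wind-up flags and the cooperative-configuration flag.
    """
    deriv = _bangbang_derivative(neuron, spec)
    traj, signal, boundaries, windup = _controller_run(
        deriv, neuron, schedule, sim, g0, T0, r0=spec.r_step_g,
    )
    t = traj.times
    r = traj["r"]
    per_regime_T, per_regime_g = [], []
    kept = np.zeros(len(t), dtype=bool)
    for k in range(len(boundaries) - 1):
        lo, hi = boundaries[k], boundaries[k + 1]
        lo_keep = lo + discard * (hi - lo)
        mask = (t >= lo_keep) & (t <= hi)
        kept |= mask
        per_regime_T.append(float(np.mean(r[mask] >= spec.r_step_T)))
        per_regime_g.append(float(np.mean(r[mask] >= spec.r_step_g)))
    summary = {
        "experiment": "bangbang",
        "cooperative": spec.cooperative,
        "p_T_target": spec.p_T,
        "p_g_target": spec.p_g,
        "fraction_above_r_step_T": float(np.mean(r[kept] >= spec.r_step_T)),
        "fraction_above_r_step_g": float(np.mean(r[kept] >= spec.r_step_g)),
        "regime_fraction_above_r_step_T": per_regime_T,
        "regime_fraction_above_r_step_g": per_regime_g,
        "final_g_E": float(traj["g_E"][-1]),
        "windup": windup,
        "windup_any": any(windup.values()),
    }
    return traj, summary


def run_cascade(
    params: CascadeParams,
    neuron: NeuronParams,
    schedule: RegimeSchedule,
    sim: SimConfig,
    g0: float = 2.0,
    T0: float = 50.0,
    discard: float = 0.5,
    g_max: float | None = None,
) -> tuple[Trajectory, dict]:
    """Closed-loop biochemical cascade across an input-regime schedule."""
    signal, boundaries = make_regime_input(schedule)
    if abs(schedule.duration - sim.duration) > 1e-9:
        raise ValueError(
            f"sim duration {sim.duration} s does not match the "
            f"schedule duration {schedule.duration} s"
        )
    traj, summary = simulate_cascade(
        params, signal, neuron, sim,
        regime_boundaries=boundaries, g0=g0, T0=T0, discard=discard,
        g_max=g_max,
    )
    summary["experiment"] = "cascade"
    summary["io_correlation"] = io_correlation(
        signal, traj, "r", discard=discard / len(schedule.regimes)
    )
    return traj, summary


#: Gain/threshold pairs of the four illustrative operating points of
#: the noisy logistic readout: A saturated high-rate, B low-gain
#: unresponsive, C bimodal extremes, D tuned to the responsive range.
DEFAULT_MI_PARAM_SETS: dict[str, dict[str, float]] = {
    "A": {"gain": 4.0, "threshold": -6.0},
    "B": {"gain": 0.5, "threshold": -2.0},
    "C": {"gain": 20.0, "threshold": 10.0},
    "D": {"gain": 6.0, "threshold": 3.0},
}


def run_mi_sweep(
    param_sets: dict[str, dict[str, float]] | None = None,
    n_levels: int = 10,
    switch_interval: float = 0.5,
    n_epochs: int = 1000,
    dt: float = 1e-3,
    eta_sd: float = 0.1,
    n_response_bins: int = 10,
    seed: int = 0,
) -> dict:
    """Mutual information of the noisy logistic readout per parameter set.

    For each (gain, threshold) pair the stepped-level protocol is run:
    ``n_levels`` equally spaced synaptic levels in [0, 1] switch every
    ``switch_interval`` seconds in seeded random order, the input
    current is ``I = gain * x(t)``, the response is the noisy logistic
    rate, and MI is the plug-in estimate between level labels and
    epoch-mean responses.
    """
    if param_sets is None:
        param_sets = DEFAULT_MI_PARAM_SETS
    spec = SteppedInputSpec(
        n_levels=n_levels, level_min=0.0, level_max=1.0,
        switch_interval=switch_interval, order="random", seed=seed,
    )
    duration = n_epochs * switch_interval
    signal, labels = make_stepped_input(spec, duration)
    per_epoch = int(round(switch_interval / dt))
    x_steps = np.repeat(signal.values, per_epoch)
    results = {}
    for i, (name, ps) in enumerate(sorted(param_sets.items())):
        I = ps["gain"] * x_steps
        r = noisy_logistic_response(
            I, ps["threshold"], eta_sd, seed=np.random.SeedSequence([seed, i])
        )
        means = r.reshape(n_epochs, per_epoch).mean(axis=1)
        est = mutual_information(labels, means, n_response_bins)
        results[name] = {
            "gain": ps["gain"],
            "threshold": ps["threshold"],
            "mi_nats": est.mi_nats,
            "estimate": est,
        }
    summary = {
        "experiment": "mi-sweep",
        "n_levels": n_levels,
        "n_epochs": n_epochs,
        "eta_sd": eta_sd,
        "mi_nats": {k: v["mi_nats"] for k, v in results.items()},
        "best": max(results, key=lambda k: results[k]["mi_nats"]),
    }
    return {"sets": results, "summary": summary}


def run_filter_ratio(
    tau_fast: float = 0.1,
    tau_slow: float = 10.0,
    dt: float = 1e-3,
    n_steps: int = 2_000_000,
    sd: float = 1.0,
    seed=0,
) -> dict:
    """Paired first-order filters driven by one seeded broadband drive."""
    result: FilterRatio = variance_transfer_ratio(
        tau_fast, tau_slow, dt=dt, n_steps=n_steps, sd=sd, seed=seed
    )
    return {
        "experiment": "filter-ratio",
        "tau_fast": tau_fast,
        "tau_slow": tau_slow,
        "tau_ratio": tau_slow / tau_fast,
        "sd_ratio": result.sd_ratio,
        "var_ratio": result.var_ratio,
        "n_samples": result.n,
    }


# ---------------------------------------------------------------------------
# config-driven dispatch

def run_experiment(cfg, outdir=None):
    """Run a validated :class:`homeorate.config.RunConfig`.

    Returns ``(trajectory_or_None, summary)``; when ``outdir`` (or
    ``cfg.outdir``) is set, writes the output bundle there:
    ``trajectory.csv``, ``summary.json`` and ``metadata.json``.
    Identical configurations (including seeds) produce bit-identical
    bundles.
    """
    import json
    import logging
    from pathlib import Path

    from .controllers import BangBangSpec, DualLinQuadSpec
    from .config import build_cascade_params
    from .engine import _json_default

    log = logging.getLogger("homeorate")
    ctrl = cfg.controller
    traj = None

    if cfg.experiment == "quadlin":
        spec = DualLinQuadSpec(
            r_goal_T=float(ctrl["r_goal_T"]),
            r_goal_g=float(ctrl["r_goal_g"]),
            tau_T=float(ctrl.get("tau_T", 2.0)),
            tau_g=float(ctrl.get("tau_g", 8.0)),
        )
        traj, summary = run_quadlin(
            cfg.neuron, spec, cfg.schedule, cfg.sim,
            g0=float(ctrl.get("g0", 5.0)),
            T0=float(ctrl.get("T0", 100.0)),
            discard=float(cfg.metrics.get("discard", 0.5)),
            floor_g=ctrl.get("floor_g", 0.0),
        )
    elif cfg.experiment == "bangbang":
        spec = BangBangSpec(
            r_step_T=float(ctrl["r_step_T"]),
            r_step_g=float(ctrl["r_step_g"]),
            p_T=float(ctrl["p_T"]),
            p_g=float(ctrl["p_g"]),
            tau_T=float(ctrl.get("tau_T", 0.5)),
            tau_g=float(ctrl.get("tau_g", 0.25)),
        )
        traj, summary = run_bangbang(
            cfg.neuron, spec, cfg.schedule, cfg.sim,
            g0=float(ctrl.get("g0", 5.0)),
            T0=float(ctrl.get("T0", 220.0)),
            discard=float(cfg.metrics.get("discard", 0.5)),
        )
    elif cfg.experiment == "cascade":
        params = build_cascade_params(ctrl)
        traj, summary = run_cascade(
            params, cfg.neuron, cfg.schedule, cfg.sim,
            g0=float(ctrl.get("g0", 2.0)),
            T0=float(ctrl.get("T0", 50.0)),
            discard=float(cfg.metrics.get("discard", 0.5)),
            g_max=ctrl.get("g_max"),
        )
    elif cfg.experiment == "mi-sweep":
        mi = cfg.raw.get("mi", {})
        out = run_mi_sweep(
            param_sets=mi.get("param_sets"),
            n_levels=int(mi.get("n_levels", 10)),
            switch_interval=float(mi.get("switch_interval", 0.5)),
            n_epochs=int(mi.get("n_epochs", 1000)),
            dt=cfg.sim.dt if cfg.sim else 1e-3,
            eta_sd=float(mi.get("eta_sd", 0.1)),
            n_response_bins=int(mi.get("n_response_bins", 10)),
            seed=cfg.sim.seed if cfg.sim else 0,
        )
        summary = out["summary"]
        summary["sets"] = {
            k: {kk: vv for kk, vv in v.items() if kk != "estimate"}
            for k, v in out["sets"].items()
        }
    elif cfg.experiment == "filter-ratio":
        summary = run_filter_ratio(
            tau_fast=float(ctrl["tau_fast"]),
            tau_slow=float(ctrl["tau_slow"]),
            dt=cfg.sim.dt if cfg.sim else 1e-3,
            n_steps=int(ctrl.get("n_steps", 2_000_000)),
            sd=float(ctrl.get("sd", 1.0)),
            seed=cfg.sim.seed if cfg.sim else 0,
        )
    else:  # pragma: no cover - rejected by config validation
        raise ValueError(f"unknown experiment {cfg.experiment!r}")

    outdir = outdir or cfg.outdir
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        if traj is not None:
            traj.to_csv(out / "trajectory.csv")
            traj.write_metadata(out / "metadata.json")
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, default=_json_default)
        log.info("wrote %s bundle to %s", cfg.experiment, out)
    return traj, summary
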