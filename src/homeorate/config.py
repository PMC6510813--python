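"""Run configuration: YAML schema, validation, and shipped fixtures.

A run configuration is a small YAML document selecting one experiment
and its parameter blocks::

    experiment: quadlin        # quadlin | bangbang | cascade |
                               # mi-sweep | filter-ratio
    sim:        {dt: 0.001, record_stride: 10, seed: 11}
    neuron:     {tau_r: 0.01, r_max: 100.0, sigma: 20.0}
    input:      {regimes: [{mean: 10, sd: 4}, ...],
                 regime_duration: 400.0, switch_interval: 0.05}
    controller: {...}          # per-experiment block, see FIXTURES

All physical quantities are in seconds, Hz, and the dimensionless
input/conductance units of the rate model.  The total simulated
duration is derived from the input block (regimes x regime_duration),
so configurations cannot disagree with their schedules.

The shipped fixtures are seeded, desk-scale configurations that
reproduce the qualitative regimes of the dual-controller analyses:
functioning and wound-up linear-quadratic control (``fig3a``/
``fig3b``), functioning and wound-up bang-bang control (``fig4a``/
``fig4b``), the biochemical cascade with dual or single integration
placement (``fig6a``/``fig6b``), its linear-kinase failure mode
(``fig7a``), the information-transfer sweep (``fig2-sweep``) and the
filtering law (``filter100``).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .engine import SimConfig
from .inputs import InputRegime, RegimeSchedule
from .neuron import NeuronParams
from .controllers import BangBangSpec, DualLinQuadSpec
from .cascade import CascadeParams, DegradationSpec

__all__ = [
    "ConfigError",
    "RunConfig",
    "load_config",
    "save_config",
    "generate_fixture",
    "FIXTURES",
]

EXPERIMENTS = ("quadlin", "bangbang", "cascade", "mi-sweep", "filter-ratio")


class ConfigError(ValueError):
    """Invalid run configuration; lists every offending field."""

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        super().__init__(
            "invalid configuration:\n  - " + "\n  - ".join(self.problems)
        )


@dataclass
class RunConfig:
    """Validated run configuration (raw dict plus typed blocks)."""

    experiment: str
    raw: dict
    sim: SimConfig | None = None
    neuron: NeuronParams | None = None
    schedule: RegimeSchedule | None = None
    controller: dict = field(default_factory=dict)
    metrics: dict = field(default_factory=dict)
    outdir: str | None = None

    def to_dict(self) -> dict:
        return copy.deepcopy(self.raw)


def _get_block(raw, name, problems, required=True) -> dict:
    block = raw.get(name)
    if block is None:
        if required:
            problems.append(f"{name}: missing required block")
        return {}
    if not isinstance(block, dict):
        problems.append(f"{name}: must be a mapping")
        return {}
    return block


def _known_keys(block: dict, allowed: set[str], name: str, problems):
    for key in block:
        if key not in allowed:
            problems.append(f"{name}.{key}: unknown field")


def _require(block, name, keys, problems):
    missing = [k for k in keys if k not in block]
    for k in missing:
        problems.append(f"{name}.{k}: missing required field")
    return not missing


def from_dict(raw: dict) -> RunConfig:
    """Validate a configuration mapping into a :class:`RunConfig`.

    Raises :class:`ConfigError` naming every offending field at once.
    """
    problems: list[str] = []
    if not isinstance(raw, dict):
        raise ConfigError(["configuration must be a mapping"])
    experiment = raw.get("experiment")
    if experiment not in EXPERIMENTS:
        raise ConfigError(
            [f"experiment: must be one of {EXPERIMENTS}, got {experiment!r}"]
        )

    cfg = RunConfig(experiment=experiment, raw=copy.deepcopy(raw))
    cfg.outdir = raw.get("outdir")
    cfg.metrics = _get_block(raw, "metrics", problems, required=False)

    sim_block = _get_block(raw, "sim", problems)
    needs_schedule = experiment in ("quadlin", "bangbang", "cascade")

    schedule = None
    if needs_schedule:
        inp = _get_block(raw, "input", problems)
        if inp and _require(
            inp, "input", ("regimes", "regime_duration", "switch_interval"),
            problems,
        ):
            try:
                regimes = [
                    InputRegime(
                        float(r["mean"]), float(r["sd"]),
                        str(r.get("label", f"R{i + 1}")),
                    )
                    for i, r in enumerate(inp["regimes"])
                ]
                schedule = RegimeSchedule(
                    regimes=tuple(regimes),
                    regime_duration=float(inp["regime_duration"]),
                    switch_interval=float(inp["switch_interval"]),
                    seed=int(sim_block.get("seed", 0)),
                    floor=inp.get("floor"),
                )
            except (ValueError, TypeError, KeyError) as exc:
                problems.append(f"input: {exc}")
    cfg.schedule = schedule

    if sim_block and _require(sim_block, "sim", ("dt",), problems):
        duration = None
        if schedule is not None:
            duration = schedule.duration
        elif "duration" in sim_block:
            duration = float(sim_block["duration"])
        elif experiment in ("mi-sweep", "filter-ratio"):
            duration = 1.0  # unused by these experiments
        if duration is not None:
            try:
                cfg.sim = SimConfig(
                    dt=float(sim_block["dt"]),
                    duration=duration,
                    record_stride=int(sim_block.get("record_stride", 1)),
                    seed=int(sim_block.get("seed", 0)),
                )
            except ValueError as exc:
                problems.append(f"sim: {exc}")

    neuron_block = _get_block(
        raw, "neuron", problems, required=needs_schedule
    )
    if neuron_block:
        _known_keys(
            neuron_block,
            {"tau_r", "r_max", "sigma", "g_E", "g_I", "T"},
            "neuron", problems,
        )
        try:
            cfg.neuron = NeuronParams(**neuron_block)
        except (TypeError, ValueError) as exc:
            problems.append(f"neuron: {exc}")

    ctrl_key = {
        "quadlin": "controller",
        "bangbang": "controller",
        "cascade": "cascade",
        "mi-sweep": "mi",
        "filter-ratio": "filter",
    }[experiment]
    ctrl = _get_block(raw, ctrl_key, problems, required=experiment != "mi-sweep")
    cfg.controller = ctrl

    if experiment == "quadlin" and ctrl:
        if _require(ctrl, ctrl_key, ("r_goal_T", "r_goal_g"), problems):
            try:
                DualLinQuadSpec(
                    r_goal_T=float(ctrl["r_goal_T"]),
                    r_goal_g=float(ctrl["r_goal_g"]),
                    tau_T=float(ctrl.get("tau_T", 2.0)),
                    tau_g=float(ctrl.get("tau_g", 8.0)),
                )
            except ValueError as exc:
                problems.append(f"{ctrl_key}: {exc}")
    elif experiment == "bangbang" and ctrl:
        if _require(
            ctrl, ctrl_key, ("r_step_T", "r_step_g", "p_T", "p_g"), problems
        ):
            try:
                BangBangSpec(
                    r_step_T=float(ctrl["r_step_T"]),
                    r_step_g=float(ctrl["r_step_g"]),
                    p_T=float(ctrl["p_T"]),
                    p_g=float(ctrl["p_g"]),
                    tau_T=float(ctrl.get("tau_T", 0.5)),
                    tau_g=float(ctrl.get("tau_g", 0.25)),
                )
            except ValueError as exc:
                problems.append(f"{ctrl_key}: {exc}")
    elif experiment == "cascade" and ctrl:
        try:
            build_cascade_params(ctrl)
        except (TypeError, ValueError) as exc:
            problems.append(f"{ctrl_key}: {exc}")
    elif experiment == "filter-ratio" and ctrl:
        if _require(ctrl, ctrl_key, ("tau_fast", "tau_slow"), problems):
            if not 0 < float(ctrl["tau_fast"]) <= float(ctrl["tau_slow"]):
                problems.append(
                    f"{ctrl_key}: need 0 < tau_fast <= tau_slow"
                )

    if problems:
        raise ConfigError(problems)
    return cfg


#: keys of the cascade block consumed by the runner, not the kinetics
_CASCADE_RUN_KEYS = {"mode", "g0", "T0", "g_max"}


def build_cascade_params(block: dict) -> CascadeParams:
    """Cascade kinetics from a config block (defaults per mode)."""
    mode = block.get("mode", "dual")
    base = (
        CascadeParams.default_dual()
        if mode == "dual"
        else CascadeParams.default_single()
    )
    overrides = {
        k: v for k, v in block.items() if k not in _CASCADE_RUN_KEYS
    }
    for key in ("D_K", "D_mg", "D_mT", "D_g", "D_T"):
        if key in overrides:
            overrides[key] = DegradationSpec(**overrides[key])
    from dataclasses import replace

    return replace(base, **overrides)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return from_dict(raw)


def save_config(cfg: RunConfig | dict, path) -> None:
    raw = cfg if isinstance(cfg, dict) else cfg.to_dict()
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# fixtures

_DEFAULT_REGIME_BLOCK = [
    {"mean": 10.0, "sd": 4.0, "label": "R1"},
    {"mean": 40.0, "sd": 10.0, "label": "R2"},
    {"mean": 4.0, "sd": 2.0, "label": "R3"},
    {"mean": 20.0, "sd": 6.0, "label": "R4"},
]

_NEURON_BLOCK = {"tau_r": 0.01, "r_max": 100.0, "sigma": 20.0}


def _quadlin_fixture(flipped: bool) -> dict:
    return {
        "experiment": "quadlin",
        "sim": {"dt": 1e-3, "record_stride": 10, "seed": 11},
        "neuron": dict(_NEURON_BLOCK),
        "input": {
            "regimes": copy.deepcopy(_DEFAULT_REGIME_BLOCK),
            "regime_duration": 100.0 if flipped else 400.0,
            "switch_interval": 0.05,
        },
        "controller": {
            "r_goal_T": 15.0 if flipped else 10.0,
            "r_goal_g": 10.0 if flipped else 15.0,
            "tau_T": 2.0,
            "tau_g": 8.0,
            "g0": 5.0,
            "T0": 100.0,
            # the wound-up configuration escapes to non-physiological
            # (negative) conductance; the floor would pin it at zero
            "floor_g": None if flipped else 0.0,
        },
        "metrics": {"discard": 0.5},
    }


def _bangbang_fixture(flipped: bool) -> dict:
    return {
        "experiment": "bangbang",
        "sim": {"dt": 1e-3, "record_stride": 10, "seed": 11},
        "neuron": dict(_NEURON_BLOCK),
        "input": {
            "regimes": copy.deepcopy(_DEFAULT_REGIME_BLOCK),
            "regime_duration": 150.0 if flipped else 400.0,
            "switch_interval": 0.05,
        },
        "controller": {
            "r_step_T": 1.0,
            "r_step_g": 15.0,
            "p_T": 0.1 if flipped else 0.5,
            "p_g": 0.5 if flipped else 0.1,
            "tau_T": 0.5,
            "tau_g": 0.25,
            "g0": 5.0,
            "T0": 220.0,
        },
        "metrics": {"discard": 0.5},
    }


def _cascade_fixture(mode: str, n_K: float) -> dict:
    block = {"mode": mode, "n_K": n_K, "g0": 2.0, "T0": 50.0}
    if n_K == 1.0:
        block["g_max"] = 10.0  # biophysical maximum reached under wind-up
    return {
        "experiment": "cascade",
        "sim": {"dt": 1e-3, "record_stride": 20, "seed": 11},
        "neuron": dict(_NEURON_BLOCK),
        "input": {
            "regimes": copy.deepcopy(_DEFAULT_REGIME_BLOCK),
            "regime_duration": 500.0,
            "switch_interval": 0.1,
        },
        "cascade": block,
        "metrics": {"discard": 0.5},
    }


FIXTURES: dict[str, dict] = {
    "fig3a": _quadlin_fixture(flipped=False),
    "fig3b": _quadlin_fixture(flipped=True),
    "fig4a": _bangbang_fixture(flipped=False),
    "fig4b": _bangbang_fixture(flipped=True),
    "fig6a": _cascade_fixture("dual", 3.0),
    "fig6b": _cascade_fixture("single", 3.0),
    "fig7a": _cascade_fixture("dual", 1.0),
    "fig2-sweep": {
        "experiment": "mi-sweep",
        "sim": {"dt": 1e-3, "seed": 0},
        "mi": {
            "n_levels": 10,
            "switch_interval": 0.5,
            "n_epochs": 1000,
            "eta_sd": 0.1,
            "n_response_bins": 10,
        },
    },
    "filter100": {
        "experiment": "filter-ratio",
        "sim": {"dt": 1e-3, "seed": 0},
        "filter": {
            "tau_fast": 0.1,
            "tau_slow": 10.0,
            "sd": 1.0,
            "n_steps": 2_000_000,
        },
    },
}


def generate_fixture(name: str, outdir=".") -> Path:
    """Write the named fixture configuration as YAML; returns its path."""
    if name not in FIXTURES:
        raise KeyError(
            f"unknown fixture '{name}'; available: {sorted(FIXTURES)}"
        )
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / f"{name}.yaml"
    save_config(copy.deepcopy(FIXTURES[name]), path)
    return path
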