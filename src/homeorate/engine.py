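"""Fixed-step forward-Euler simulation engine.

All closed-loop homeostasis experiments in this package are plain
time-stepped simulations of a handful of coupled state variables
(firing rate, conductance, threshold, biochemical intermediates)
driven by a piecewise-constant input.  The engine keeps the state in a
flat float64 vector, advances it with forward Euler, optionally floors
selected variables at a lower bound (conductances and concentrations
cannot go negative), and records every ``record_stride``-th step into a
:class:`Trajectory`.

Stochasticity enters only through the drive: input signals are
generated up front from a seeded RNG (see :mod:`homeorate.inputs`), so
an identical :class:`SimConfig` (including seed) yields a bit-identical
trajectory.

Noise conventions
-----------------
Piecewise-constant stepped inputs hold an independent draw for each
switch interval with the stated standard deviation (no ``1/sqrt(dt)``
scaling): they model a signal, not a diffusion term.  Broadband
white-noise drives used for the filtering analyses scale the per-step
standard deviation by ``1/sqrt(dt)`` (diffusion scaling) so that the
filtered variance is dt-independent.  The convention used by a run is
recorded in its metadata.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "Trajectory",
    "EngineError",
    "NonFiniteStateError",
    "integrate",
    "epoch_statistics",
]

SCHEME = "forward-euler"


class EngineError(ValueError):
    """Configuration or runtime error raised by the simulation engine."""


class NonFiniteStateError(EngineError):
    """A state variable became NaN or infinite during integration."""

    def __init__(self, step: int, time: float, variable: str):
        self.step = step
        self.time = time
        self.variable = variable
        super().__init__(
            f"non-finite value in variable '{variable}' at step {step} "
            f"(t = {time:.6g} s); the system diverged or dt is too large"
        )


@dataclass(frozen=True)
class SimConfig:
    """Time grid and seeding for one simulation run.

    Parameters
    ----------
    dt:
        Integration time step in seconds.
    duration:
        Total simulated time in seconds.
    record_stride:
        Number of Euler steps between recorded samples (1 records
        every step).
    seed:
        Integer seed for every random draw feeding the run.
    """

    dt: float
    duration: float
    record_stride: int = 1
    seed: int = 0

    def __post_init__(self):
        if not self.dt > 0:
            raise EngineError(f"dt must be positive, got {self.dt}")
        if self.duration < self.dt:
            raise EngineError("duration must be at least one time step")
        if self.record_stride < 1:
            raise EngineError("record_stride must be >= 1")

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt))

    def check_resolves(self, smallest_time_constant: float) -> None:
        """Require dt <= smallest time constant / 10 (Euler accuracy)."""
        if self.dt > smallest_time_constant / 10.0 + 1e-15:
            raise EngineError(
                f"dt = {self.dt} s does not resolve the fastest time "
                f"constant {smallest_time_constant} s (need dt <= tau/10)"
            )

    def metadata(self, **extra) -> dict:
        meta = {
            "dt": self.dt,
            "duration": self.duration,
            "record_stride": self.record_stride,
            "seed": self.seed,
            "scheme": SCHEME,
        }
        meta.update(extra)
        return meta


@dataclass
class Trajectory:
    """Time-indexed record of simulated state variables.

    ``times`` are the recorded time points (s, uniformly spaced by
    ``dt * record_stride``); ``series`` maps each variable name to its
    recorded values (same length as ``times``).
    """

    times: np.ndarray
    series: dict[str, np.ndarray]
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        n = len(self.times)
        for name, values in self.series.items():
            if len(values) != n:
                raise EngineError(
                    f"series '{name}' has {len(values)} samples, "
                    f"expected {n}"
                )

    def __getitem__(self, name: str) -> np.ndarray:
        return self.series[name]

    @property
    def variables(self) -> list[str]:
        return list(self.series)

    @property
    def duration(self) -> float:
        return float(self.times[-1]) if len(self.times) else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, **self.series})

    def to_csv(self, path) -> None:
        """Write the trajectory as CSV: time column then one per variable."""
        self.to_frame().to_csv(path, index=False)

    def write_metadata(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.meta, fh, indent=2, default=_json_default)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _drive_array(drive, dt: float, n_steps: int) -> np.ndarray:
    """Resolve a drive specification to one value per Euler step."""
    if drive is None:
        return np.zeros(n_steps)
    if hasattr(drive, "step_values"):
        return np.asarray(drive.step_values(dt, n_steps), dtype=float)
    arr = np.asarray(drive, dtype=float)
    if arr.ndim == 0:
        return np.full(n_steps, float(arr))
    if len(arr) < n_steps:
        raise EngineError(
            f"drive covers {len(arr)} steps but {n_steps} are required"
        )
    return arr[:n_steps]


def integrate(
    system_derivative: Callable[[float, np.ndarray, float], np.ndarray],
    initial_state: Mapping[str, float],
    config: SimConfig,
    drive=None,
    floors: Mapping[str, float] | None = None,
    ceilings: Mapping[str, float] | None = None,
    smallest_time_constant: float | None = None,
    meta: Mapping | None = None,
) -> Trajectory:
    """Forward-Euler integration of a named state vector.

    Parameters
    ----------
    system_derivative:
        Callable ``f(t, y, u) -> dy/dt`` where ``y`` is the state
        vector ordered as in ``initial_state`` and ``u`` is the drive
        value over the current step.
    initial_state:
        Ordered mapping from variable name to initial value; the order
        defines the layout of ``y``.
    config:
        Time grid and seed.
    drive:
        ``None`` (zero drive), a scalar, a per-step array, or any
        object with ``step_values(dt, n_steps)`` such as
        :class:`homeorate.inputs.InputSignal`.
    floors:
        Optional per-variable lower bounds applied after every step
        (e.g. a synaptic conductance floored at 0).
    ceilings:
        Optional per-variable upper bounds (e.g. a biophysical maximum
        conductance in wind-up demonstrations).
    smallest_time_constant:
        If given, validates ``dt <= tau/10`` before running.
    """
    if smallest_time_constant is not None:
        config.check_resolves(smallest_time_constant)

    names = list(initial_state)
    y = np.array([float(initial_state[k]) for k in names], dtype=float)
    d0 = np.asarray(system_derivative(0.0, y, 0.0), dtype=float)
    if d0.shape != y.shape:
        raise EngineError(
            f"derivative returned shape {d0.shape}, expected {y.shape}; "
            f"state variables are {names}"
        )

    dt = config.dt
    stride = config.record_stride
    n_steps = config.n_steps
    u = _drive_array(drive, dt, n_steps)

    floor_pairs: list[tuple[int, float]] = []
    if floors:
        for name, lo in floors.items():
            if name not in names:
                raise EngineError(f"floor given for unknown variable '{name}'")
            floor_pairs.append((names.index(name), float(lo)))
    ceil_pairs: list[tuple[int, float]] = []
    if ceilings:
        for name, hi in ceilings.items():
            if name not in names:
                raise EngineError(f"ceiling given for unknown variable '{name}'")
            ceil_pairs.append((names.index(name), float(hi)))

    n_rec = n_steps // stride + 1
    recorded = np.empty((n_rec, len(names)))
    recorded[0] = y

    isfinite = math.isfinite
    rec_row = 1
    for i in range(n_steps):
        y = y + dt * system_derivative(i * dt, y, u[i])
        for idx, lo in floor_pairs:
            if y[idx] < lo:
                y[idx] = lo
        for idx, hi in ceil_pairs:
            if y[idx] > hi:
                y[idx] = hi
        # cheap divergence guard: sum is non-finite iff some entry is
        if not isfinite(y.sum()):
            bad = int(np.flatnonzero(~np.isfinite(y))[0])
            raise NonFiniteStateError(i + 1, (i + 1) * dt, names[bad])
        if (i + 1) % stride == 0:
            recorded[rec_row] = y
            rec_row += 1

    times = np.arange(n_rec) * (dt * stride)
    run_meta = config.metadata()
    if meta:
        run_meta.update(meta)
    series = {name: recorded[:, j].copy() for j, name in enumerate(names)}
    return Trajectory(times=times, series=series, meta=run_meta)


def epoch_statistics(
    traj: Trajectory,
    variable: str,
    epoch_boundaries: Sequence[float],
    discard: float = 0.0,
) -> pd.DataFrame:
    """Per-epoch mean, population variance and sample count.

    ``epoch_boundaries`` are the edges of consecutive epochs (length
    ``n_epochs + 1``).  Within each epoch the first ``discard``
    fraction of its samples is dropped before computing statistics, to
    remove homeostatic transients.

    Returns a DataFrame with columns ``start, end, mean, var, n``.
    """
    if not 0.0 <= discard < 1.0:
        raise EngineError(f"discard must be in [0, 1), got {discard}")
    edges = np.asarray(epoch_boundaries, dtype=float)
    if len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise EngineError("epoch boundaries must be increasing, length >= 2")
    t = traj.times
    if edges[0] < t[0] - 1e-12 or edges[-1] > t[-1] + 1e-12:
        raise EngineError("epoch boundaries lie outside the trajectory")
    x = traj[variable]

    rows = []
    for k in range(len(edges) - 1):
        lo, hi = edges[k], edges[k + 1]
        t_lo = lo + discard * (hi - lo)
        last = hi >= edges[-1]
        mask = (t >= t_lo - 1e-12) & ((t <= hi + 1e-12) if last else (t < hi - 1e-12))
        sel = x[mask]
        if sel.size == 0:
            raise EngineError(
                f"epoch {k} [{lo}, {hi}) retains no samples after "
                f"discarding {discard:.0%}"
            )
        rows.append(
            {
                "start": lo,
                "end": hi,
                "mean": float(sel.mean()),
                "var": float(sel.var()),  # population variance
                "n": int(sel.size),
            }
        )
    return pd.DataFrame(rows)
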