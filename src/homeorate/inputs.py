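"""Synthetic input-current generators.

Two protocols drive every experiment in the package:

* **Stepped levels** — a fixed set of equally spaced input levels,
  switching every ``switch_interval`` seconds (500 ms in the
  information-transfer protocol), visited cyclically or in seeded
  random order.  Used for mutual-information measurements.
* **Regime schedules** — a sequence of input *regimes*, each a
  Gaussian distribution of piecewise-constant levels with its own mean
  and standard deviation, concatenated in time.  The default schedule
  spans a 10-fold range of mean input and a 25-fold range of input
  variance, the stress-test envelope for the homeostatic controllers.

Signals are piecewise constant: one independent draw per switch
interval, held for the whole interval (no ``1/sqrt(dt)`` scaling; see
the noise-convention note in :mod:`homeorate.engine`).  White-noise
drives for the filtering analyses use diffusion scaling and are
produced by :func:`white_noise_drive`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SteppedInputSpec",
    "InputRegime",
    "RegimeSchedule",
    "InputSignal",
    "make_stepped_input",
    "make_regime_input",
    "white_noise_drive",
    "DEFAULT_REGIMES",
]


class InputSpecError(ValueError):
    """Invalid input-generator specification."""


@dataclass(frozen=True)
class SteppedInputSpec:
    """Equally spaced input levels switching on a fixed interval."""

    n_levels: int
    level_min: float
    level_max: float
    switch_interval: float
    order: str = "random"  # "random" | "cyclic"
    seed: int = 0

    def __post_init__(self):
        if self.n_levels < 2:
            raise InputSpecError("n_levels must be >= 2")
        if not self.level_max > self.level_min:
            raise InputSpecError("level_max must exceed level_min")
        if not self.switch_interval > 0:
            raise InputSpecError("switch_interval must be positive")
        if self.order not in ("random", "cyclic"):
            raise InputSpecError(f"unknown order '{self.order}'")

    @property
    def levels(self) -> np.ndarray:
        return np.linspace(self.level_min, self.level_max, self.n_levels)


@dataclass(frozen=True)
class InputRegime:
    """One stationary input distribution (Gaussian levels)."""

    mean: float
    sd: float
    label: str = ""

    def __post_init__(self):
        if self.sd < 0:
            raise InputSpecError("regime sd must be >= 0")


#: Default four-regime stress-test schedule: means span 10-fold
#: (4 -> 40) and standard deviations 5-fold (variances 25-fold).
DEFAULT_REGIMES: tuple[InputRegime, ...] = (
    InputRegime(10.0, 4.0, "R1"),
    InputRegime(40.0, 10.0, "R2"),
    InputRegime(4.0, 2.0, "R3"),
    InputRegime(20.0, 6.0, "R4"),
)


@dataclass(frozen=True)
class RegimeSchedule:
    """Ordered regimes, each lasting ``regime_duration`` seconds."""

    regimes: tuple[InputRegime, ...] = DEFAULT_REGIMES
    regime_duration: float = 400.0
    switch_interval: float = 0.1
    seed: int = 0
    floor: float | None = None  # optional clip (inputs are currents: off)

    def __post_init__(self):
        object.__setattr__(self, "regimes", tuple(self.regimes))
        if len(self.regimes) < 1:
            raise InputSpecError("schedule needs at least one regime")
        if not self.switch_interval > 0:
            raise InputSpecError("switch_interval must be positive")
        if self.regime_duration < self.switch_interval:
            raise InputSpecError(
                "regime_duration must be at least one switch interval"
            )

    @property
    def duration(self) -> float:
        return self.regime_duration * len(self.regimes)

    @property
    def boundaries(self) -> np.ndarray:
        """Regime boundary times, length ``n_regimes + 1``."""
        return np.arange(len(self.regimes) + 1) * self.regime_duration


@dataclass
class InputSignal:
    """Piecewise-constant excitatory drive S_E(t) (S_I defaults to 0).

    ``values[k]`` is held on ``[k*interval, (k+1)*interval)``.
    """

    values: np.ndarray
    interval: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise InputSpecError("input signal contains non-finite values")
        if not self.interval > 0:
            raise InputSpecError("hold interval must be positive")

    @property
    def duration(self) -> float:
        return len(self.values) * self.interval

    def at(self, t: float) -> float:
        k = min(int(t / self.interval), len(self.values) - 1)
        return float(self.values[max(k, 0)])

    def step_values(self, dt: float, n_steps: int) -> np.ndarray:
        """One value per Euler step of size ``dt`` (engine drive hook)."""
        per = int(round(self.interval / dt))
        if per < 1 or abs(per * dt - self.interval) > 1e-9 * self.interval:
            raise InputSpecError(
                f"switch interval {self.interval} is not a multiple of dt={dt}"
            )
        idx = np.minimum(np.arange(n_steps) // per, len(self.values) - 1)
        return self.values[idx]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": np.arange(len(self.values)) * self.interval,
                "S_E": self.values,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def make_stepped_input(
    spec: SteppedInputSpec, duration: float
) -> tuple[InputSignal, np.ndarray]:
    """Stepped-level protocol: returns the signal and per-epoch labels.

    Each epoch of length ``spec.switch_interval`` holds one of the
    ``n_levels`` equally spaced values; the integer label sequence
    (0-based level indices) is returned for mutual-information
    analysis.
    """
    if duration < spec.switch_interval:
        raise InputSpecError(
            f"duration {duration} s is shorter than one switch interval"
        )
    n_epochs = int(round(duration / spec.switch_interval))
    if spec.order == "cyclic":
        labels = np.arange(n_epochs) % spec.n_levels
    else:
        rng = np.random.default_rng(spec.seed)
        labels = rng.integers(0, spec.n_levels, size=n_epochs)
    values = spec.levels[labels]
    signal = InputSignal(
        values=values,
        interval=spec.switch_interval,
        meta={
            "kind": "stepped",
            "n_levels": spec.n_levels,
            "order": spec.order,
            "seed": spec.seed,
            "noise_convention": "per-interval draw, unscaled",
        },
    )
    return signal, labels


def make_regime_input(
    schedule: RegimeSchedule,
) -> tuple[InputSignal, np.ndarray]:
    """Multi-regime protocol: returns the signal and regime boundaries.

    Within each regime one Gaussian draw (mean, sd per the regime) is
    held per switch interval.  If ``schedule.floor`` is set, draws are
    clipped from below; by default inputs are currents and may be
    negative.
    """
    rng = np.random.default_rng(schedule.seed)
    per_regime = int(round(schedule.regime_duration / schedule.switch_interval))
    chunks = []
    for regime in schedule.regimes:
        draws = regime.mean + regime.sd * rng.standard_normal(per_regime)
        if schedule.floor is not None:
            draws = np.maximum(draws, schedule.floor)
        chunks.append(draws)
    values = np.concatenate(chunks)
    signal = InputSignal(
        values=values,
        interval=schedule.switch_interval,
        meta={
            "kind": "regimes",
            "regimes": [
                {"mean": r.mean, "sd": r.sd, "label": r.label}
                for r in schedule.regimes
            ],
            "regime_duration": schedule.regime_duration,
            "seed": schedule.seed,
            "floor": schedule.floor,
            "noise_convention": "per-interval draw, unscaled",
        },
    )
    return signal, schedule.boundaries


def white_noise_drive(
    sd: float, dt: float, n_steps: int, seed
) -> np.ndarray:
    """Seeded Gaussian white noise with diffusion scaling.

    Per-step standard deviation is ``sd / sqrt(dt)`` so that a
    first-order filter of time constant tau driven by this signal has
    stationary variance ~ ``sd**2 / (2 * tau)`` independent of dt.
    ``seed`` may be an int or a ``numpy.random.SeedSequence``.
    """
    rng = np.random.default_rng(seed)
    return rng.standard_normal(n_steps) * (sd / np.sqrt(dt))
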