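"""Homeostatic feedback laws and wind-up diagnostics.

The controllers act on two slow variables of the rate neuron — the
firing threshold ``T`` (intrinsic excitability) and the excitatory
synaptic conductance ``g_E`` (synaptic scaling) — in response to the
fast-fluctuating firing rate ``r``:

* **integral feedback**: the canonical single controller, whose
  feedback accumulates the error between output and set-point;
* **dual linear-quadratic control**: the threshold controller
  integrates ``r - r_goal(T)`` while the conductance controller
  integrates ``r_goal(g)**2 - r**2``; together they pin the mean and
  the mean square of the rate, hence its variance
  ``r_goal(g)**2 - r_goal(T)**2`` (which must be positive, so the
  configuration is feasible only when ``r_goal(g) > r_goal(T)``);
* **generalized two-function control**: arbitrary monotone control
  functions ``f_T``, ``f_g``; stability without fine-tuning requires
  the function of greater curvature (``f''/f'`` at its target) to be
  assigned to the conductance controller;
* **dual bang-bang control**: each controller switches between two
  fixed drive rates depending on whether ``r`` is above or below its
  step-point, enforcing a target fraction of time spent above each
  step-point (``H(0) = 1`` by convention).

When the two set-points are mutually unsatisfiable the controllers
engage in a tug-of-war and both feedback variables grow without bound
("wind-up"); :func:`detect_windup` flags this from a trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .engine import Trajectory

__all__ = [
    "IntegralLoopState",
    "DualLinQuadSpec",
    "ControlFunction",
    "BangBangSpec",
    "integral_feedback_derivative",
    "conductance_homeostasis_derivative",
    "quadlin_derivatives",
    "fixed_point_variance",
    "generalized_derivatives",
    "check_curvature_condition",
    "bangbang_derivatives",
    "detect_windup",
]


@dataclass
class IntegralLoopState:
    """State of the canonical integral-feedback loop.

    ``X`` is the controlled output, ``X_goal`` its set-point, ``I_ext``
    the external input, ``I_fb`` the accumulated feedback and
    ``tau_fb`` the feedback time constant.
    """

    X: float
    X_goal: float
    I_ext: float = 0.0
    I_fb: float = 0.0
    tau_fb: float = 1.0

    def __post_init__(self):
        if not self.tau_fb > 0:
            raise ValueError("tau_fb must be positive")

    @property
    def E(self) -> float:
        """Instantaneous error ``X - X_goal``."""
        return self.X - self.X_goal


def integral_feedback_derivative(state: IntegralLoopState) -> float:
    """dI_fb/dt = (X_goal - X) / tau_fb (accumulated error signal)."""
    return (state.X_goal - state.X) / state.tau_fb


def conductance_homeostasis_derivative(
    r: float, r_goal: float, tau_g: float
) -> float:
    """Synaptic-scaling law dg_E/dt = (r_goal - r) / tau_g.

    Conductance scales up when the rate runs below target and down
    when above, integrating the rate error.
    """
    if not tau_g > 0:
        raise ValueError("tau_g must be positive")
    return (r_goal - r) / tau_g


@dataclass(frozen=True)
class DualLinQuadSpec:
    """Targets and time constants of the dual linear-quadratic system.

    ``r_goal_T`` is the mean-rate target enforced via the threshold,
    ``r_goal_g`` the RMS-rate target enforced via the conductance.
    """

    r_goal_T: float = 10.0
    r_goal_g: float = 15.0
    tau_T: float = 500.0
    tau_g: float = 500.0

    def __post_init__(self):
        if not (self.r_goal_T > 0 and self.r_goal_g > 0):
            raise ValueError("both goal rates must be positive")
        if not (self.tau_T > 0 and self.tau_g > 0):
            raise ValueError("both time constants must be positive")

    @property
    def feasible(self) -> bool:
        """True iff the implied rate variance is positive."""
        return self.r_goal_g > self.r_goal_T


def quadlin_derivatives(
    r: float, spec: DualLinQuadSpec
) -> tuple[float, float]:
    """(dT/dt, dg_E/dt) of the dual linear-quadratic controller.

    ``dT/dt = (r - r_goal_T)/tau_T`` and
    ``dg_E/dt = (r_goal_g**2 - r**2)/tau_g``.
    """
    dT = (r - spec.r_goal_T) / spec.tau_T
    dg = (spec.r_goal_g**2 - r * r) / spec.tau_g
    return dT, dg


_INFEASIBLE = float("nan")


def fixed_point_variance(spec: DualLinQuadSpec) -> tuple[float, bool]:
    """Rate variance required at the dual fixed point, with feasibility.

    Returns ``(r_goal_g**2 - r_goal_T**2, feasible)``: the system pins
    ``<r> = r_goal_T`` and ``<r**2> = r_goal_g**2``, so Var(r) is
    their difference; a non-positive value cannot be a variance and the
    configuration is flagged infeasible (the degenerate equal-target
    boundary included).
    """
    var = spec.r_goal_g**2 - spec.r_goal_T**2
    return var, var > 0


@dataclass
class ControlFunction:
    """Monotone control function with optional analytic derivatives.

    ``curvature_index(r) = f''(r) / f'(r)``; when ``df``/``d2f`` are
    not supplied, central finite differences with relative step 1e-4
    are used.
    """

    f: Callable[[float], float]
    df: Callable[[float], float] | None = None
    d2f: Callable[[float], float] | None = None
    name: str = ""

    def __call__(self, r: float) -> float:
        return self.f(r)

    def curvature_index(self, r: float) -> float:
        if self.df is not None and self.d2f is not None:
            d1, d2 = self.df(r), self.d2f(r)
        else:
            h = max(abs(r), 1.0) * 1e-4
            f0, fp, fm = self.f(r), self.f(r + h), self.f(r - h)
            d1 = (fp - fm) / (2 * h)
            d2 = (fp - 2 * f0 + fm) / (h * h)
        if d1 <= 0:
            raise ValueError(
                f"control function {self.name or self.f!r} must be "
                f"increasing at r={r} (f' = {d1:.3g})"
            )
        return d2 / d1

    @classmethod
    def identity(cls) -> "ControlFunction":
        return cls(lambda r: r, lambda r: 1.0, lambda r: 0.0, "identity")

    @classmethod
    def power(cls, n: float) -> "ControlFunction":
        return cls(
            lambda r: r**n,
            lambda r: n * r ** (n - 1),
            lambda r: n * (n - 1) * r ** (n - 2),
            f"power{n:g}",
        )

    @classmethod
    def square(cls) -> "ControlFunction":
        return cls.power(2)


def generalized_derivatives(
    r: float,
    f_T: ControlFunction,
    f_g: ControlFunction,
    r_goal_T: float,
    r_goal_g: float,
    tau_T: float,
    tau_g: float,
) -> tuple[float, float]:
    """(dT/dt, dg_E/dt) for arbitrary monotone control functions.

    ``dT/dt = [f_T(r) - f_T(r_goal_T)] / tau_T`` and
    ``dg_E/dt = [f_g(r_goal_g) - f_g(r)] / tau_g``; with identity and
    square functions this reduces exactly to
    :func:`quadlin_derivatives`.
    """
    dT = (f_T(r) - f_T(r_goal_T)) / tau_T
    dg = (f_g(r_goal_g) - f_g(r)) / tau_g
    return dT, dg


def check_curvature_condition(
    f_T: ControlFunction,
    f_g: ControlFunction,
    r_goal_T: float,
    r_goal_g: float,
) -> bool:
    """True iff the controller assignment is stable without fine-tuning.

    The control function with the greater curvature index ``f''/f'``
    (each evaluated at its own target rate) must be the one driving
    the synaptic conductance; equal curvatures (e.g. both linear)
    would require fine-tuned targets and are rejected.
    """
    return f_g.curvature_index(r_goal_g) > f_T.curvature_index(r_goal_T)


@dataclass(frozen=True)
class BangBangSpec:
    """Step-points and target time fractions of the dual bang-bang system.

    The threshold controller enforces a fraction ``p_T`` of time with
    ``r >= r_step_T``; the conductance controller enforces ``p_g``
    above ``r_step_g``.  Cooperation requires the conductance
    controller to own the higher step-point with the smaller fraction:
    ``r_step_g > r_step_T`` and ``p_T > p_g``.
    """

    r_step_T: float = 1.0
    r_step_g: float = 15.0
    p_T: float = 0.5
    p_g: float = 0.1
    tau_T: float = 500.0
    tau_g: float = 500.0

    def __post_init__(self):
        if not (0 < self.p_T < 1 and 0 < self.p_g < 1):
            raise ValueError("target fractions must lie in (0, 1)")
        if not (self.tau_T > 0 and self.tau_g > 0):
            raise ValueError("both time constants must be positive")

    @property
    def cooperative(self) -> bool:
        return self.r_step_g > self.r_step_T and self.p_T > self.p_g


def _heaviside(x: float) -> float:
    """H(x) = 1 if x >= 0 else 0."""
    return 1.0 if x >= 0.0 else 0.0


def bangbang_derivatives(
    r: float, spec: BangBangSpec
) -> tuple[float, float]:
    """(dT/dt, dg_E/dt) of the dual bang-bang controller.

    ``dT/dt = [-p_T + H(r - r_step_T)] / tau_T`` and
    ``dg_E/dt = [p_g - H(r - r_step_g)] / tau_g`` with H the Heaviside
    step, ``H(0) = 1``.
    """
    dT = (-spec.p_T + _heaviside(r - spec.r_step_T)) / spec.tau_T
    dg = (spec.p_g - _heaviside(r - spec.r_step_g)) / spec.tau_g
    return dT, dg


def detect_windup(
    traj: Trajectory,
    variables: list[str] | tuple[str, ...],
    window: float,
    slope_tol: float = 0.1,
    bound: float | None = None,
) -> dict[str, bool]:
    """Flag feedback variables that never stabilize (wind-up).

    A variable is flagged when the linear trends over its two trailing
    windows of length ``window`` seconds share a sign and each drifts
    by more than ``slope_tol`` times the variable's mean absolute
    level over the analysed tail (persistent one-directional growth),
    or when the variable exceeds ``bound`` in magnitude anywhere.
    Converged controllers that merely oscillate around their operating
    point produce alternating or sub-threshold window trends and are
    not flagged.
    """
    t = traj.times
    if len(t) < 4:
        raise ValueError("trajectory too short for wind-up analysis")
    total = t[-1] - t[0]
    if not 0 < 2 * window <= total:
        raise ValueError(
            f"need two windows of {window} s inside the {total} s trajectory"
        )
    flags: dict[str, bool] = {}
    for name in variables:
        x = traj[name]
        if bound is not None and np.nanmax(np.abs(x)) > bound:
            flags[name] = True
            continue
        tail = x[t >= t[-1] - max(4 * window, total / 2)]
        scale = max(float(np.mean(np.abs(tail))), 1e-12)
        drifts = []
        for k in (2, 1):  # second-to-last, then last window
            lo, hi = t[-1] - k * window, t[-1] - (k - 1) * window
            mask = (t >= lo - 1e-12) & (t <= hi + 1e-12)
            tw, xw = t[mask], x[mask]
            if len(tw) < 2:
                raise ValueError(f"window of {window} s holds < 2 samples")
            slope = np.polyfit(tw - tw[0], xw, 1)[0]
            drifts.append(slope * window)
        same_sign = drifts[0] * drifts[1] > 0
        persistent = all(abs(d) > slope_tol * scale for d in drifts)
        flags[name] = bool(same_sign and persistent)
    return flags
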