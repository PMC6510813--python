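"""Firing-rate neuron models.

Three model variants appear across the experiments:

* the **sigmoidal rate neuron**: ``tau_r dr/dt = -r + F[g_E S_E + g_I
  S_I - T]`` with logistic gain ``F[X] = r_max / (1 + exp(-X/sigma))``
  — the workhorse of every homeostasis simulation;
* the **noisy logistic readout** used by the mutual-information
  protocol: instantaneous ``r = 1/(1 + exp(T - I)) + eta`` with
  additive white noise per time step (dimensionless rate in [0, 1]
  plus noise, as opposed to Hz elsewhere);
* the **recurrent linear integrator**: the same rate equation with
  self-excitation ``S_E = alpha r + S_in``, whose effective time
  constant ``tau_r / (1 - alpha g_E)`` diverges at exact tuning
  ``alpha g_E = 1``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

__all__ = [
    "NeuronParams",
    "IntegratorParams",
    "sigmoid_rate",
    "rate_derivative",
    "noisy_logistic_response",
    "effective_time_constant",
    "EffectiveTimeConstant",
    "integrator_derivative",
]

_EXP_CLIP = 700.0  # exp argument bound avoiding float64 overflow


@dataclass(frozen=True)
class NeuronParams:
    """Sigmoidal rate-neuron parameters.

    tau_r: rate time constant (s); r_max: maximal rate (Hz); sigma:
    sigmoid width (input units); g_E/g_I: synaptic conductances
    (input-scaling units); T: threshold (input units).
    """

    tau_r: float = 0.01
    r_max: float = 100.0
    sigma: float = 20.0
    g_E: float = 1.0
    g_I: float = 0.0
    T: float = 0.0

    def __post_init__(self):
        if not self.tau_r > 0:
            raise ValueError("tau_r must be positive")
        if not self.r_max > 0:
            raise ValueError("r_max must be positive")
        if not self.sigma > 0:
            raise ValueError("sigma must be positive")
        if self.g_E < 0:
            raise ValueError("g_E must be nonnegative")


@dataclass(frozen=True)
class IntegratorParams:
    """Recurrent linear-integrator parameters (self-feedback weight alpha)."""

    tau_r: float = 0.01
    g_E: float = 1.0
    alpha: float = 1.0
    T: float = 0.0

    def __post_init__(self):
        if not self.tau_r > 0:
            raise ValueError("tau_r must be positive")


def sigmoid_rate(X, r_max: float, sigma: float):
    """Logistic firing-rate curve ``r_max / (1 + exp(-X/sigma))``.

    Accepts scalars or arrays; strictly increasing in X and bounded in
    (0, r_max) for finite arguments.
    """
    if not sigma > 0:
        raise ValueError("sigma must be positive")
    z = np.clip(np.asarray(X, dtype=float) / sigma, -_EXP_CLIP, _EXP_CLIP)
    out = r_max / (1.0 + np.exp(-z))
    if np.ndim(X) == 0:
        return float(out)
    return out


def rate_derivative(r, S_E, S_I, params: NeuronParams):
    """dr/dt of the sigmoidal rate neuron.

    ``(-r + F[g_E*S_E + g_I*S_I - T]) / tau_r`` with F the logistic
    gain of :func:`sigmoid_rate`.
    """
    X = params.g_E * S_E + params.g_I * S_I - params.T
    return (-r + sigmoid_rate(X, params.r_max, params.sigma)) / params.tau_r


def noisy_logistic_response(
    I, T: float, eta_sd: float, seed=None, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Instantaneous noisy logistic readout of the MI protocol.

    ``r(t) = 1 / (1 + exp(T - I(t))) + eta(t)`` with eta zero-mean
    white noise of standard deviation ``eta_sd`` drawn independently
    per time step (not scaled by dt).  The output is a dimensionless
    rate and is deliberately left unclipped, so it can dip slightly
    below 0 or above 1 when noisy.
    """
    if eta_sd < 0:
        raise ValueError("eta_sd must be >= 0")
    I = np.atleast_1d(np.asarray(I, dtype=float))
    z = np.clip(T - I, -_EXP_CLIP, _EXP_CLIP)
    r = 1.0 / (1.0 + np.exp(z))
    if eta_sd > 0:
        if rng is None:
            rng = np.random.default_rng(seed)
        r = r + eta_sd * rng.standard_normal(r.shape)
    return r


class EffectiveTimeConstant(NamedTuple):
    """Effective integrator time constant plus stability regime.

    ``regime`` is one of ``"stable"``, ``"perfect_integrator"``
    (tau is ``inf``) or ``"unstable"`` (tau is ``nan``).
    """

    tau: float
    regime: str


def effective_time_constant(params: IntegratorParams) -> EffectiveTimeConstant:
    """``tau_r / (1 - alpha g_E)``, with divergence flags.

    At ``alpha g_E = 1`` the time constant extends to infinity and the
    circuit is a perfect integrator; above 1 activity grows without
    bound.
    """
    loop = params.alpha * params.g_E
    if math.isclose(loop, 1.0, rel_tol=0.0, abs_tol=1e-12):
        return EffectiveTimeConstant(math.inf, "perfect_integrator")
    if loop > 1.0:
        return EffectiveTimeConstant(math.nan, "unstable")
    return EffectiveTimeConstant(params.tau_r / (1.0 - loop), "stable")


def integrator_derivative(r, S_in, params: IntegratorParams):
    """dr/dt of the recurrent integrator (``S_E = alpha r + S_in``)."""
    S_E = params.alpha * r + S_in
    return (-r + params.g_E * S_E - params.T) / params.tau_r
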