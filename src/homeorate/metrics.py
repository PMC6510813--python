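"""Quantitative evaluation of simulated responses.

The central quantity is the mutual information, in nats, between the
discrete input level presented in each stimulus epoch and the
epoch-averaged response, estimated with the plug-in formula on a joint
count table (equal-width response bins, no bias correction — epoch
counts are made large instead).  Time-fraction statistics
(:func:`fraction_above`, consistent with the bang-bang convention
``H(0) = 1``) and input-output Pearson correlation round out the
controller comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import Trajectory

__all__ = [
    "MIEstimate",
    "epoch_mean_responses",
    "mutual_information",
    "fraction_above",
    "io_correlation",
]


@dataclass
class MIEstimate:
    """Joint count table and plug-in mutual information (nats)."""

    joint_counts: np.ndarray  # shape (n_levels, n_response_bins)
    mi_nats: float
    n_epochs: int
    n_response_bins: int
    level_values: np.ndarray | None = None
    bin_edges: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        idx = (
            self.level_values
            if self.level_values is not None
            else np.arange(self.joint_counts.shape[0])
        )
        return pd.DataFrame(
            self.joint_counts,
            index=pd.Index(idx, name="level"),
            columns=[f"bin{j}" for j in range(self.joint_counts.shape[1])],
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)


def epoch_mean_responses(
    traj: Trajectory,
    epoch_boundaries,
    variable: str = "r",
    discard: float = 0.0,
) -> np.ndarray:
    """Mean response per stimulus epoch.

    ``epoch_boundaries`` are edges aligned with the input switching
    times (length ``n_epochs + 1``); the response is assumed
    instantaneous so no transient is discarded by default.
    """
    from .engine import epoch_statistics

    stats = epoch_statistics(traj, variable, epoch_boundaries, discard)
    return stats["mean"].to_numpy()


def mutual_information(
    level_labels,
    epoch_means,
    n_response_bins: int = 10,
) -> MIEstimate:
    """Plug-in MI between input levels and binned epoch-mean responses.

    Responses are discretized into ``n_response_bins`` equal-width
    bins spanning the observed range; the estimate is
    ``sum_ij p_ij * ln(p_ij / (p_i q_j))`` on the joint relative
    frequencies.  Nonnegative, invariant under relabeling of levels or
    bins, and bounded by ``min(ln n_levels, ln n_bins)``.
    """
    labels = np.asarray(level_labels)
    means = np.asarray(epoch_means, dtype=float)
    if labels.shape != means.shape or labels.ndim != 1:
        raise ValueError("labels and epoch means must be equal-length 1-D")
    uniq, codes = np.unique(labels, return_inverse=True)
    if len(uniq) < 2:
        raise ValueError("need at least 2 distinct input levels for MI")
    if len(labels) < len(uniq):
        raise ValueError("need at least one epoch per level")
    if n_response_bins < 1:
        raise ValueError("n_response_bins must be >= 1")

    lo, hi = means.min(), means.max()
    if hi > lo:
        edges = np.linspace(lo, hi, n_response_bins + 1)
        bins = np.minimum(
            np.searchsorted(edges, means, side="right") - 1,
            n_response_bins - 1,
        )
    else:  # degenerate constant response: single occupied bin, MI = 0
        edges = np.array([lo, lo])
        bins = np.zeros(len(means), dtype=int)

    joint = np.zeros((len(uniq), n_response_bins), dtype=int)
    np.add.at(joint, (codes, bins), 1)

    n = joint.sum()
    p = joint / n
    pi = p.sum(axis=1, keepdims=True)
    qj = p.sum(axis=0, keepdims=True)
    nz = p > 0
    mi = float(np.sum(p[nz] * np.log(p[nz] / (pi @ qj)[nz])))
    return MIEstimate(
        joint_counts=joint,
        mi_nats=max(mi, 0.0),
        n_epochs=int(n),
        n_response_bins=n_response_bins,
        level_values=uniq,
        bin_edges=edges,
    )


def fraction_above(
    traj: Trajectory,
    variable: str,
    threshold: float,
    discard: float = 0.0,
) -> float:
    """Fraction of retained samples with ``value >= threshold``.

    The first ``discard`` fraction of the trajectory is dropped
    (controller convergence transient); ``>=`` matches the Heaviside
    convention ``H(0) = 1`` of the bang-bang controller.
    """
    if not 0.0 <= discard < 1.0:
        raise ValueError("discard must be in [0, 1)")
    x = traj[variable]
    start = int(discard * len(x))
    kept = x[start:]
    return float(np.mean(kept >= threshold))


def io_correlation(
    input_signal,
    traj: Trajectory,
    variable: str = "r",
    discard: float = 0.0,
) -> float:
    """Pearson correlation between drive and response over retained samples.

    The input signal is sampled at the recorded time points.  Returns
    NaN when either series has zero variance (undefined correlation).
    """
    if not 0.0 <= discard < 1.0:
        raise ValueError("discard must be in [0, 1)")
    t = traj.times
    if hasattr(input_signal, "at"):
        u = np.array([input_signal.at(tk) for tk in t])
    else:
        u = np.asarray(input_signal, dtype=float)
        if len(u) != len(t):
            raise ValueError("input samples must align with recorded times")
    x = traj[variable]
    start = int(discard * len(x))
    u, x = u[start:], x[start:]
    if u.std() == 0 or x.std() == 0:
        return float("nan")
    return float(np.corrcoef(u, x)[0, 1])
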