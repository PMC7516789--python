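"""Bayesian model averaging over the (P, Q) grid.

With a uniform prior over model orders, the posterior probability of a
model is its evidence normalized over the grid, p(P,Q|d) = Z(P,Q)/sum Z.
Formant estimates are model-averaged moments of the pooled posterior
samples, whose per-model weights are reweighted by w -> w * Z/sum Z.
Models with different formant counts Q are combined per formant: the k-th
formant's estimate is conditional on models that contain it (Q >= k), with
weights renormalized within that support, and p(formant k exists) =
sum_{Q>=k} p(Q) is reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .inference import ModelGridResult

__all__ = ["AveragedPosterior", "model_posteriors", "averaged_moments", "averaged_posterior"]


@dataclass
class AveragedPosterior:
    p_joint: dict[tuple[int, int], float]
    p_P: dict[int, float]
    p_Q: dict[int, float]
    b_mean: np.ndarray  # per-formant model-averaged bandwidth means (Hz)
    b_sd: np.ndarray
    f_mean: np.ndarray  # per-formant model-averaged frequency means (Hz)
    f_sd: np.ndarray
    p_exists: np.ndarray  # probability that formant k is present
    combined_samples: list[dict] = field(default_factory=list)
    map_orders: tuple[int, int] = (0, 0)

    @property
    def Q_max(self) -> int:
        return len(self.b_mean)


def model_posteriors(grid: ModelGridResult):
    """p(P,Q|data) = Z/sum Z (uniform model-order prior), plus marginals."""
    if not grid.entries:
        raise ValueError("empty model grid")
    keys = list(grid.entries)
    log_z = np.array([grid.entries[k].log_Z for k in keys])
    w = np.exp(log_z - log_z.max())
    w /= w.sum()
    p_joint = {k: float(p) for k, p in zip(keys, w)}
    p_P: dict[int, float] = {}
    p_Q: dict[int, float] = {}
    for (P, Q), p in p_joint.items():
        p_P[P] = p_P.get(P, 0.0) + p
        p_Q[Q] = p_Q.get(Q, 0.0) + p
    return p_joint, p_P, p_Q


def averaged_moments(grid: ModelGridResult, M: int) -> tuple[np.ndarray, np.ndarray]:
    """Model-averaged M-th moments (M in {1, 2}) of (B_k, F_k) per formant.

    For formant k the average runs over models with Q >= k, with the pooled
    weights Z(P,Q) * w renormalized within that support.  Returns
    (bandwidth_moments, frequency_moments), arrays of length max Q.
    """
    if M not in (1, 2):
        raise ValueError("M must be 1 or 2")
    p_joint, _, _ = model_posteriors(grid)
    q_max = max(q for _, q in grid.entries)
    bm = np.full(q_max, np.nan)
    fm = np.full(q_max, np.nan)
    for k in range(q_max):
        num_b = num_f = den = 0.0
        for (P, Q), ev in grid.entries.items():
            if Q < k + 1:
                continue
            pw = p_joint[(P, Q)] * ev.weights
            num_b += pw @ ev.bandwidth_samples[:, k] ** M
            num_f += pw @ ev.frequency_samples[:, k] ** M
            den += pw.sum()
        if den <= 0:
            raise ValueError(f"formant {k + 1} has zero posterior support")
        bm[k] = num_b / den
        fm[k] = num_f / den
    return bm, fm


def averaged_posterior(grid: ModelGridResult) -> AveragedPosterior:
    """Full model-averaged summary: order posteriors, moments, pooled samples."""
    p_joint, p_P, p_Q = model_posteriors(grid)
    b1, f1 = averaged_moments(grid, 1)
    b2, f2 = averaged_moments(grid, 2)
    b_sd = np.sqrt(np.maximum(b2 - b1**2, 0.0))
    f_sd = np.sqrt(np.maximum(f2 - f1**2, 0.0))
    q_max = len(b1)
    p_exists = np.array(
        [sum(p for q, p in p_Q.items() if q >= k + 1) for k in range(q_max)]
    )
    combined = [
        {
            "orders": (P, Q),
            "bandwidths_hz": ev.bandwidth_samples,
            "frequencies_hz": ev.frequency_samples,
            "weights": p_joint[(P, Q)] * ev.weights,
        }
        for (P, Q), ev in grid.entries.items()
    ]
    map_orders = max(p_joint, key=p_joint.get)
    return AveragedPosterior(
        p_joint=p_joint,
        p_P=dict(sorted(p_P.items())),
        p_Q=dict(sorted(p_Q.items())),
        b_mean=b1,
        b_sd=b_sd,
        f_mean=f1,
        f_sd=f_sd,
        p_exists=p_exists,
        combined_samples=combined,
        map_orders=map_orders,
    )
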