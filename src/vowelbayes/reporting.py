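"""Derived quantities: vocal-tract transfer function, SNR, trend and flow.

The damped-sinusoid part of a period fit maps to a rational transfer
function whose conjugate pole pairs are -a_k +/- i w_k (continuous domain):
each formant contributes [c_k (s + a_k) + s_k w_k] / ((s + a_k)^2 + w_k^2),
the Laplace transform of e^{-a t}(c_k cos w t + s_k sin w t).  Periods share
the poles but differ in amplitudes, so an averaged magnitude curve is the
geometric mean over periods.  The trend-block part of the fit, integrated
over time, serves as a rough proxy for the glottal flow (modulo a bias
constant).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .basis import FormantParams, ModelOrders, trend_block
from .likelihood import PeriodFit
from .periods import PitchPeriodSet

__all__ = [
    "TransferFunction",
    "sinusoid_amplitudes",
    "vt_transfer_magnitude",
    "snr_db",
    "trend_and_flow",
]


@dataclass
class TransferFunction:
    """Continuous-domain all-pole description: poles -a_k +/- i w_k (rad/s)."""

    poles: np.ndarray  # complex, upper-half-plane member of each pair
    residues: list[np.ndarray]  # per-period complex residues
    gain_convention: str = "unit-numerator partial fractions"


def sinusoid_amplitudes(fit: PeriodFit, orders: ModelOrders) -> np.ndarray:
    """Extract the 2Q damped-sinusoid amplitudes (cos block then sin block)."""
    return np.asarray(fit.b_hat[orders.P :])


def vt_transfer_magnitude(
    theta: FormantParams,
    b_hats: list[np.ndarray],
    fs: float,
    freq_grid: np.ndarray,
):
    """Per-period and averaged |H(i 2 pi f)| on ``freq_grid`` (Hz).

    ``b_hats`` holds one length-2Q amplitude vector per period (cos
    amplitudes then sin amplitudes).  The average is the geometric mean of
    the per-period magnitudes (periods share poles, not gains or zeros).
    """
    Q = theta.Q
    a = np.asarray(theta.alpha) * fs  # rad/s
    w = np.asarray(theta.omega) * fs
    s = 1j * 2 * np.pi * np.asarray(freq_grid, dtype=float)
    curves = []
    for b in b_hats:
        b = np.asarray(b, dtype=float)
        if b.shape != (2 * Q,):
            raise ValueError(f"expected {2 * Q} amplitudes, got shape {b.shape}")
        c, sn = b[:Q], b[Q:]
        H = np.zeros_like(s, dtype=complex)
        for k in range(Q):
            H += (c[k] * (s + a[k]) + sn[k] * w[k]) / ((s + a[k]) ** 2 + w[k] ** 2)
        curves.append(np.abs(H))
    curves = np.array(curves)
    with np.errstate(divide="ignore"):
        avg = np.exp(np.mean(np.log(np.maximum(curves, 1e-300)), axis=0))
    avg[np.all(curves == 0, axis=0)] = 0.0
    return curves, avg


def snr_db(f_hat_all, N: int, sigma: float) -> float:
    """Fitted signal-to-noise ratio: 10 log10( sum f^T f / (N sigma^2) )."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    power = sum(float(np.asarray(f) @ np.asarray(f)) for f in f_hat_all)
    return 10.0 * np.log10(power / (N * sigma**2))


def trend_and_flow(
    periods: PitchPeriodSet,
    fits: list[PeriodFit],
    orders: ModelOrders,
):
    """Per-period trend vectors and the flow proxy (their cumulative integral).

    The trend is the trend-block columns times the fitted trend amplitudes;
    the glottal-flow proxy is the cumulative sum of the concatenated trend,
    left unnormalized with arbitrary offset.
    """
    if len(fits) != periods.n:
        raise ValueError("one fit per period required")
    trends = []
    for p, fit in zip(periods.periods, fits):
        T = np.asarray(trend_block(len(p), orders.P))
        trends.append(T @ fit.b_hat[: orders.P])
    flow = np.cumsum(np.concatenate(trends))
    return trends, flow
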