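"""Per-period design matrices: orthonormal polynomial trend + damped sinusoids.

The model for one pitch period of length N is

    f(j) = sum_k b_k L_k(j) + sum_l [c_l cos(j*w_l) + s_l sin(j*w_l)] e^{-j*a_l}

on the dimensionless sample grid j = 0..N-1.  The trend block uses Legendre
polynomials of degree 0..P-1 orthonormalized on the discrete grid (so the
unit-scale Gaussian amplitude prior is appropriate for any N), and each of
the Q formants contributes a cos and a sin column damped by its decay rate.
Internally the formant parameters are per-sample: a = pi*B/fs (decay) and
w = 2*pi*F/fs (angular frequency).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

__all__ = [
    "ModelOrders",
    "FormantParams",
    "DesignMatrix",
    "hz_to_internal",
    "internal_to_hz",
    "trend_block",
    "build_design_matrix",
]


@dataclass(frozen=True)
class ModelOrders:
    """Trend basis size P (polynomial degree P-1) and formant count Q."""

    P: int
    Q: int

    def __post_init__(self) -> None:
        if self.P < 1:
            raise ValueError("P must be >= 1")
        if self.Q < 0:
            raise ValueError("Q must be >= 0")

    @property
    def m(self) -> int:
        return self.P + 2 * self.Q


@dataclass(frozen=True)
class FormantParams:
    """theta = (alpha, omega): Q per-sample decay rates and angular frequencies."""

    alpha: tuple[float, ...]
    omega: tuple[float, ...]
    fs: float | None = None

    def __post_init__(self) -> None:
        if len(self.alpha) != len(self.omega):
            raise ValueError("alpha and omega must have the same length")
        if any(a <= 0 for a in self.alpha):
            raise ValueError("all alpha must be positive")
        if any(not (0.0 < w < np.pi) for w in self.omega):
            raise ValueError("all omega must lie in (0, pi)")
        if any(w2 <= w1 for w1, w2 in zip(self.omega, self.omega[1:])):
            raise ValueError("omega must be strictly increasing")

    @property
    def Q(self) -> int:
        return len(self.alpha)

    @property
    def bandwidths_hz(self) -> np.ndarray:
        if self.fs is None:
            raise ValueError("fs not set on FormantParams")
        return np.asarray(self.alpha) * self.fs / np.pi

    @property
    def frequencies_hz(self) -> np.ndarray:
        if self.fs is None:
            raise ValueError("fs not set on FormantParams")
        return np.asarray(self.omega) * self.fs / (2 * np.pi)


@dataclass
class DesignMatrix:
    values: np.ndarray
    orders: ModelOrders
    theta: FormantParams | None


def hz_to_internal(B, F, fs: float) -> FormantParams:
    """Convert bandwidths/frequencies in Hz to per-sample (alpha, omega)."""
    B = np.atleast_1d(np.asarray(B, dtype=float))
    F = np.atleast_1d(np.asarray(F, dtype=float))
    if np.any(B <= 0):
        raise ValueError("bandwidths must be positive")
    if np.any(F <= 0) or np.any(F >= fs / 2):
        raise ValueError("frequencies must lie in (0, fs/2)")
    return FormantParams(
        alpha=tuple(np.pi * B / fs), omega=tuple(2 * np.pi * F / fs), fs=fs
    )


def internal_to_hz(theta: FormantParams, fs: float | None = None):
    """Inverse of :func:`hz_to_internal`; returns (B, F) arrays in Hz."""
    fs = fs if fs is not None else theta.fs
    if fs is None:
        raise ValueError("sampling rate required")
    a = np.asarray(theta.alpha)
    w = np.asarray(theta.omega)
    return a * fs / np.pi, w * fs / (2 * np.pi)


@lru_cache(maxsize=512)
def trend_block(N: int, P: int) -> np.ndarray:
    """N x P matrix of discretely orthonormalized Legendre polynomials.

    Column k is the degree-(k-1) Legendre polynomial on the grid j=0..N-1
    mapped to [-1, 1], re-orthonormalized under the Euclidean inner product
    on the grid (QR with positive diagonal, so column 1 is 1/sqrt(N)).
    """
    if P > N:
        raise ValueError("trend block would be underdetermined (P > N)")
    x = np.linspace(-1.0, 1.0, N) if N > 1 else np.zeros(1)
    V = np.polynomial.legendre.legvander(x, P - 1)
    Qm, R = np.linalg.qr(V)
    signs = np.sign(np.diag(R))
    signs[signs == 0] = 1.0
    out = Qm * signs
    out.flags.writeable = False
    return out


def sinusoid_block(N: int, theta: FormantParams) -> np.ndarray:
    """N x 2Q matrix: cos(j*w_l)e^{-j*a_l} columns then sin(j*w_l)e^{-j*a_l}."""
    j = np.arange(N)[:, None]
    a = np.asarray(theta.alpha)[None, :]
    w = np.asarray(theta.omega)[None, :]
    damp = np.exp(-j * a)
    return np.hstack([np.cos(j * w) * damp, np.sin(j * w) * damp])


def build_design_matrix(
    N: int, orders: ModelOrders, theta: FormantParams | None
) -> DesignMatrix:
    """Assemble the N x (P + 2Q) design matrix for one pitch period."""
    if orders.Q > 0 and (theta is None or theta.Q != orders.Q):
        raise ValueError("theta must supply exactly Q formants")
    if N <= orders.m:
        raise ValueError(f"underdetermined: N={N} <= m={orders.m}")
    blocks = [np.asarray(trend_block(N, orders.P))]
    if orders.Q > 0:
        blocks.append(sinusoid_block(N, theta))
    return DesignMatrix(values=np.hstack(blocks), orders=orders, theta=theta)
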