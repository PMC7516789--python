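"""Least-squares machinery and the closed-form integrated likelihood.

For fixed formant parameters theta, each pitch period d_i is fit by linear
least squares over its m = P + 2Q amplitudes b_i.  With a unit-scale
Gaussian prior on the amplitudes and a bounded Jeffreys prior on the noise
amplitude sigma, both can be marginalized analytically, leaving the
integrated likelihood

    L_I(P, Q, theta) = C(P,Q) * [sum_i chi2_i]^((nm-N)/2)
                       * prod_i |det g_i|^(-1/2) * exp(-sum_i b_i^T b_i / 2 delta^2)

with g_i = G_i^T G_i, chi2_i the residual sum of squares at the optimum,
and C(P,Q) a pure model-order regularization constant,

    C(P,Q) = (1/2) [log(sigma_hi/sigma_lo)]^-1 * pi^((nm-N)/2)
             * Gamma((N-nm)/2) * (2 pi delta^2)^(-nm/2).

All evidence math is carried in log space.  The amplitude marginalization
drops the + I/delta^2 term from the posterior precision, which is valid
when the per-column integrated power of the basis dominates the noise power;
this validity ratio is tracked and a warning is logged when it dips below
the configured threshold.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_triangular

from .basis import (
    FormantParams,
    ModelOrders,
    hz_to_internal,
    sinusoid_block,
    trend_block,
)
from .periods import PitchPeriodSet

__all__ = [
    "PriorConfig",
    "PeriodFit",
    "IntegratedLikelihoodValue",
    "fit_period",
    "sigma_hat",
    "log_integrated_likelihood",
    "IntegratedLikelihoodEvaluator",
    "VOWEL_PRESETS",
]

logger = logging.getLogger(__name__)

# Literature-style prior boxes (Hz) for the two demo vowels: per formant a
# bandwidth range and a frequency range, frequencies ordered low to high.
VOWEL_PRESETS: dict[str, dict[str, list[tuple[float, float]]]] = {
    "gamma": {  # close-mid back unrounded vowel, 3 formants under 4 kHz
        "bandwidth_ranges": [(10, 180), (10, 250), (10, 420)],
        "frequency_ranges": [(200, 700), (700, 1500), (1500, 3000)],
    },
    "ae": {  # near-open front unrounded vowel, 4 formants under 4 kHz
        "bandwidth_ranges": [(40, 180), (40, 250), (60, 420), (60, 420)],
        "frequency_ranges": [(300, 900), (1000, 2000), (2000, 3000), (2500, 4000)],
    },
}


@dataclass(frozen=True)
class PriorConfig:
    """Priors: amplitude scale delta, sigma bounds, and theta ranges in Hz."""

    bandwidth_ranges: tuple[tuple[float, float], ...]
    frequency_ranges: tuple[tuple[float, float], ...]
    delta: float = 1.0
    sigma_lo: float = 1e-6
    sigma_hi: float = 1.0
    validity_ratio_min: float = 10.0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "bandwidth_ranges", tuple(tuple(r) for r in self.bandwidth_ranges)
        )
        object.__setattr__(
            self, "frequency_ranges", tuple(tuple(r) for r in self.frequency_ranges)
        )
        if not (0 < self.sigma_lo < self.sigma_hi):
            raise ValueError("need 0 < sigma_lo < sigma_hi")
        if self.delta <= 0:
            raise ValueError("delta must be positive")
        if len(self.bandwidth_ranges) != len(self.frequency_ranges):
            raise ValueError("need one bandwidth range per frequency range")
        for lo, hi in self.bandwidth_ranges + self.frequency_ranges:
            if not (0 < lo < hi):
                raise ValueError(f"invalid prior range [{lo}, {hi}]")
        los = [r[0] for r in self.frequency_ranges]
        his = [r[1] for r in self.frequency_ranges]
        if sorted(los) != list(los) or sorted(his) != list(his):
            raise ValueError("frequency ranges must be ordered low to high")

    @property
    def max_Q(self) -> int:
        return len(self.frequency_ranges)

    def for_Q(self, Q: int) -> "PriorConfig":
        """Restrict the prior box to the first Q formants."""
        if Q > self.max_Q:
            raise ValueError(f"only {self.max_Q} formant ranges configured")
        return PriorConfig(
            bandwidth_ranges=self.bandwidth_ranges[:Q],
            frequency_ranges=self.frequency_ranges[:Q],
            delta=self.delta,
            sigma_lo=self.sigma_lo,
            sigma_hi=self.sigma_hi,
            validity_ratio_min=self.validity_ratio_min,
        )

    @classmethod
    def preset(cls, name: str, **kwargs) -> "PriorConfig":
        p = VOWEL_PRESETS[name]
        return cls(
            bandwidth_ranges=tuple(p["bandwidth_ranges"]),
            frequency_ranges=tuple(p["frequency_ranges"]),
            **kwargs,
        )


@dataclass
class PeriodFit:
    """Least-squares fit of one pitch period at fixed theta."""

    b_hat: np.ndarray
    f_hat: np.ndarray
    chi2: float
    logdet_g: float
    col_power: np.ndarray  # diag(g): integrated power of each basis column

    def validity_ratio(self, sigma: float, delta: float = 1.0) -> float:
        """min_j [g/sigma^2]_jj * delta^2 — the approximation check."""
        return float(np.min(self.col_power) * delta**2 / sigma**2)


@dataclass
class IntegratedLikelihoodValue:
    log_LI: float
    sigma_hat: float
    per_period: list[PeriodFit] = field(default_factory=list)
    approx_ok: bool = True


def fit_period(d_i: np.ndarray, G_i) -> PeriodFit:
    """Fit b_hat = argmin ||d - G b|| via QR (never normal equations).

    chi2 is computed both as the residual sum of squares and as
    d^T d - f_hat^T f_hat; the two must agree to 1e-8 relative to d^T d.
    """
    G = G_i.values if hasattr(G_i, "values") else np.asarray(G_i)
    d = np.asarray(d_i, dtype=float)
    N, m = G.shape
    if N <= m:
        raise ValueError(f"underdetermined fit: N={N} <= m={m}")
    Qm, R = np.linalg.qr(G)
    rdiag = np.abs(np.diag(R))
    col_norm = np.linalg.norm(G, axis=0)
    bad = np.where(rdiag <= 1e-10 * np.maximum(col_norm, 1e-300))[0]
    if bad.size:
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient in column(s) {bad.tolist()}"
        )
    qtd = Qm.T @ d
    b_hat = solve_triangular(R, qtd, lower=False)
    f_hat = G @ b_hat
    resid = d - f_hat
    chi2_res = float(resid @ resid)
    dtd = float(d @ d)
    chi2_id = dtd - float(f_hat @ f_hat)
    if abs(chi2_res - chi2_id) > 1e-8 * max(dtd, 1e-300):
        raise FloatingPointError(
            "chi2 computed by residual and by identity disagree; "
            "the fit is numerically unreliable"
        )
    logdet_g = 2.0 * float(np.sum(np.log(rdiag)))
    return PeriodFit(
        b_hat=b_hat,
        f_hat=f_hat,
        chi2=max(chi2_res, 0.0),
        logdet_g=logdet_g,
        col_power=col_norm**2,
    )


def sigma_hat(chi2_list, N: int, n: int, m: int) -> float:
    """Peak of the sigma-marginal integrand: sqrt(sum chi2 / (N - n*m + 1))."""
    denom = N - n * m + 1
    if denom <= 0:
        raise ValueError(f"nonpositive degrees of freedom: N-nm+1 = {denom}")
    return math.sqrt(float(np.sum(chi2_list)) / denom)


def log_order_constant(N: int, n: int, m: int, cfg: PriorConfig) -> float:
    """log C(P,Q): the pure model-order regularization constant."""
    if N <= n * m:
        raise ValueError(f"need N > n*m, got N={N}, n*m={n * m}")
    nm = n * m
    return (
        -math.log(2.0)
        - math.log(math.log(cfg.sigma_hi / cfg.sigma_lo))
        + 0.5 * (nm - N) * math.log(math.pi)
        + math.lgamma(0.5 * (N - nm))
        - 0.5 * nm * math.log(2 * math.pi * cfg.delta**2)
    )


class IntegratedLikelihoodEvaluator:
    """Callable log L_I(theta) for one dataset and one (P, Q).

    Precomputes everything theta-independent (data vectors, their power,
    the orthonormal trend block per period) so nested sampling pays only
    for the 2Q damped-sinusoid columns and one small QR per period.
    """

    def __init__(
        self, periods: PitchPeriodSet, orders: ModelOrders, cfg: PriorConfig
    ):
        self.periods = periods
        self.orders = orders
        self.cfg = cfg
        self.n = periods.n
        self.N = periods.N
        self.m = orders.m
        if self.N <= self.n * self.m:
            raise ValueError(
                f"need N > n*m for the sigma marginalization "
                f"(N={self.N}, n*m={self.n * self.m})"
            )
        self._d = [np.asarray(p, dtype=float) for p in periods.periods]
        self._dtd = [float(d @ d) for d in self._d]
        self._trend = [np.asarray(trend_block(len(d), orders.P)) for d in self._d]
        self._log_C = log_order_constant(self.N, self.n, self.m, cfg)

    def _design(self, i: int, theta: FormantParams | None) -> np.ndarray:
        if self.orders.Q == 0 or theta is None:
            return self._trend[i]
        S = sinusoid_block(len(self._d[i]), theta)
        return np.hstack([self._trend[i], S])

    def evaluate(self, theta: FormantParams | None) -> IntegratedLikelihoodValue:
        """Full evaluation with per-period fits and the validity check."""
        fits = [
            fit_period(self._d[i], self._design(i, theta)) for i in range(self.n)
        ]
        return self._assemble(fits, warn=True)

    def _assemble(self, fits, warn: bool) -> IntegratedLikelihoodValue:
        chi2s = np.array([f.chi2 for f in fits])
        S = float(chi2s.sum())
        if S <= 0.0:
            raise ValueError("degenerate data: total chi2 is zero")
        s_hat = sigma_hat(chi2s, self.N, self.n, self.m)
        bb = sum(float(f.b_hat @ f.b_hat) for f in fits)
        log_LI = (
            self._log_C
            + 0.5 * (self.n * self.m - self.N) * math.log(S)
            - 0.5 * sum(f.logdet_g for f in fits)
            - bb / (2.0 * self.cfg.delta**2)
        )
        vr = min(f.validity_ratio(s_hat, self.cfg.delta) for f in fits)
        ok = vr >= self.cfg.validity_ratio_min
        if warn and not ok:
            logger.warning(
                "amplitude-marginalization validity ratio %.3g below threshold %.3g",
                vr,
                self.cfg.validity_ratio_min,
            )
        return IntegratedLikelihoodValue(
            log_LI=log_LI, sigma_hat=s_hat, per_period=list(fits), approx_ok=ok
        )

    def __call__(self, theta: FormantParams | None) -> float:
        """Fast path: log L_I only (used inside nested sampling)."""
        log_LI = self._log_C
        S = 0.0
        bb = 0.0
        for i in range(self.n):
            G = self._design(i, theta)
            Qm, R = np.linalg.qr(G)
            rdiag = np.abs(np.diag(R))
            if np.any(rdiag <= 1e-12):
                return -np.inf
            qtd = Qm.T @ self._d[i]
            b = solve_triangular(R, qtd, lower=False)
            S += max(self._dtd[i] - float(qtd @ qtd), 0.0)
            bb += float(b @ b)
            log_LI -= float(np.sum(np.log(rdiag)))
        if S <= 0.0:
            return -np.inf
        log_LI += 0.5 * (self.n * self.m - self.N) * math.log(S)
        log_LI -= bb / (2.0 * self.cfg.delta**2)
        return log_LI


def log_integrated_likelihood(
    periods: PitchPeriodSet,
    orders: ModelOrders,
    theta: FormantParams | None,
    cfg: PriorConfig,
) -> IntegratedLikelihoodValue:
    """Closed-form integrated likelihood of the formant parameters.

    Marginalizes the n*m period amplitudes (Gaussian, scale delta) and the
    noise amplitude sigma (Jeffreys on [sigma_lo, sigma_hi]) analytically.
    """
    return IntegratedLikelihoodEvaluator(periods, orders, cfg).evaluate(theta)
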