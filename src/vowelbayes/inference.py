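"""Nested-sampling inference of formant parameters for one or many (P, Q).

The formant parameters theta = (alpha_1..alpha_Q, omega_1..omega_Q) carry
independent Jeffreys (log-uniform) priors over user-supplied Hz ranges.
Because the amplitudes and noise are marginalized analytically, the sampled
space has exactly 2Q dimensions regardless of the number of pitch periods
or the trend order.  Draws violating the strictly-increasing-frequency
labeling constraint receive zero likelihood, which prevents label switching
when adjacent prior ranges overlap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .basis import FormantParams, ModelOrders, hz_to_internal
from .likelihood import IntegratedLikelihoodEvaluator, PriorConfig
from .periods import PitchPeriodSet
from .sampler import nested_sample

__all__ = [
    "NestedSettings",
    "ModelEvidence",
    "ModelGridResult",
    "prior_transform",
    "run_nested",
    "run_model_grid",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NestedSettings:
    n_live: int = 250
    dlogz_stop: float = 0.1
    seed: int = 0
    sampler_mode: str = "auto"  # 'auto' | 'unif' | 'rwalk'
    walks: int | None = None

    def __post_init__(self) -> None:
        if self.dlogz_stop <= 0:
            raise ValueError("dlogz_stop must be positive")


@dataclass
class ModelEvidence:
    """Evidence and weighted posterior samples for one (P, Q) model."""

    orders: ModelOrders
    log_Z: float
    log_Z_err: float
    bandwidth_samples: np.ndarray  # (L, Q) in Hz
    frequency_samples: np.ndarray  # (L, Q) in Hz
    weights: np.ndarray  # (L,), normalized to 1
    log_l: np.ndarray
    sigma_hat_map: float
    n_calls: int = 0

    @property
    def map_theta_hz(self) -> tuple[np.ndarray, np.ndarray]:
        k = int(np.argmax(self.log_l))
        return self.bandwidth_samples[k], self.frequency_samples[k]

    def posterior_mean_sd(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Weighted first/second moments -> (B_mean, B_sd, F_mean, F_sd) in Hz."""
        w = self.weights
        bm = w @ self.bandwidth_samples
        fm = w @ self.frequency_samples
        bv = w @ self.bandwidth_samples**2 - bm**2
        fv = w @ self.frequency_samples**2 - fm**2
        return bm, np.sqrt(np.maximum(bv, 0)), fm, np.sqrt(np.maximum(fv, 0))


@dataclass
class ModelGridResult:
    entries: dict[tuple[int, int], ModelEvidence]
    P_range: tuple[int, ...]
    Q_range: tuple[int, ...]
    data_fingerprint: str = ""
    failures: dict[tuple[int, int], str] = field(default_factory=dict)


def prior_transform(u: np.ndarray, cfg: PriorConfig, fs: float) -> FormantParams:
    """Map a unit-cube point (dim 2Q) to formant parameters.

    Each coordinate is log-uniform over its Hz range (Jeffreys prior):
    theta_j = lo_j * (hi_j/lo_j)**u_j — bandwidths first, then frequencies.
    Raises ValueError if the drawn frequencies are not strictly increasing
    (possible only when adjacent ranges overlap).
    """
    u = np.asarray(u, dtype=float)
    Q = cfg.max_Q
    if u.shape != (2 * Q,):
        raise ValueError(f"expected a point of dimension {2 * Q}")
    b_lo = np.array([r[0] for r in cfg.bandwidth_ranges])
    b_hi = np.array([r[1] for r in cfg.bandwidth_ranges])
    f_lo = np.array([r[0] for r in cfg.frequency_ranges])
    f_hi = np.array([r[1] for r in cfg.frequency_ranges])
    B = b_lo * (b_hi / b_lo) ** u[:Q]
    F = f_lo * (f_hi / f_lo) ** u[Q:]
    return hz_to_internal(B, F, fs)


def run_nested(
    periods: PitchPeriodSet,
    orders: ModelOrders,
    cfg: PriorConfig,
    settings: NestedSettings = NestedSettings(),
) -> ModelEvidence:
    """Evidence Z(P,Q) and weighted theta samples by static nested sampling."""
    cfg_q = cfg.for_Q(orders.Q)
    ev = IntegratedLikelihoodEvaluator(periods, orders, cfg_q)
    fs = periods.fs
    ndim = 2 * orders.Q

    def log_l(u: np.ndarray) -> float:
        try:
            theta = prior_transform(u, cfg_q, fs)
        except ValueError:  # unordered frequencies under overlapping ranges
            return -np.inf
        val = ev(theta)
        return val if np.isfinite(val) else -np.inf

    rng = np.random.default_rng(np.random.SeedSequence(settings.seed))
    res = nested_sample(
        log_l,
        ndim=ndim,
        n_live=settings.n_live,
        dlogz_stop=settings.dlogz_stop,
        rng=rng,
        mode=settings.sampler_mode,
        walks=settings.walks,
    )

    Q = orders.Q
    u = res.samples_u
    b_lo = np.array([r[0] for r in cfg_q.bandwidth_ranges])
    b_hi = np.array([r[1] for r in cfg_q.bandwidth_ranges])
    f_lo = np.array([r[0] for r in cfg_q.frequency_ranges])
    f_hi = np.array([r[1] for r in cfg_q.frequency_ranges])
    B = b_lo * (b_hi / b_lo) ** u[:, :Q]
    F = f_lo * (f_hi / f_lo) ** u[:, Q:]

    k_map = int(np.argmax(res.log_l))
    theta_map = hz_to_internal(B[k_map], F[k_map], fs)
    sigma_map = ev.evaluate(theta_map).sigma_hat

    logger.info(
        "(P=%d, Q=%d): log_Z = %.2f +/- %.2f  (%d iterations, %d likelihood calls)",
        orders.P, orders.Q, res.log_z, res.log_z_err, res.n_iter, res.n_calls,
    )
    return ModelEvidence(
        orders=orders,
        log_Z=res.log_z,
        log_Z_err=res.log_z_err,
        bandwidth_samples=B,
        frequency_samples=F,
        weights=res.weights,
        log_l=res.log_l,
        sigma_hat_map=sigma_map,
        n_calls=res.n_calls,
    )


def run_model_grid(
    periods: PitchPeriodSet,
    P_range,
    Q_range,
    cfg: PriorConfig,
    settings: NestedSettings = NestedSettings(),
) -> ModelGridResult:
    """Sweep the (P, Q) grid; one independent nested run per cell.

    Per-cell seeds are derived deterministically from the master seed, so
    cells may be computed in any order (or in parallel) with identical
    results.  Cells violating N > n*m are skipped with a recorded reason.
    """
    P_range = tuple(int(p) for p in P_range)
    Q_range = tuple(int(q) for q in Q_range)
    if not P_range or not Q_range:
        raise ValueError("model-order grids must be nonempty")
    entries: dict[tuple[int, int], ModelEvidence] = {}
    failures: dict[tuple[int, int], str] = {}
    for P in P_range:
        for Q in Q_range:
            orders = ModelOrders(P=P, Q=Q)
            if periods.N <= periods.n * orders.m:
                failures[(P, Q)] = (
                    f"skipped: N={periods.N} <= n*m={periods.n * orders.m}"
                )
                logger.warning("(P=%d, Q=%d) %s", P, Q, failures[(P, Q)])
                continue
            cell_seed = np.random.SeedSequence([settings.seed, P, Q])
            cell_settings = NestedSettings(
                n_live=settings.n_live,
                dlogz_stop=settings.dlogz_stop,
                seed=0,
                sampler_mode=settings.sampler_mode,
                walks=settings.walks,
            )
            try:
                entries[(P, Q)] = _run_nested_with_seedseq(
                    periods, orders, cfg, cell_settings, cell_seed
                )
            except Exception as exc:  # record, keep sweeping
                failures[(P, Q)] = f"failed: {exc}"
                logger.warning("(P=%d, Q=%d) %s", P, Q, failures[(P, Q)])
    if not entries:
        raise RuntimeError(f"all grid cells failed: {failures}")
    return ModelGridResult(
        entries=entries,
        P_range=P_range,
        Q_range=Q_range,
        data_fingerprint=periods.fingerprint(),
        failures=failures,
    )


def _run_nested_with_seedseq(periods, orders, cfg, settings, seedseq) -> ModelEvidence:
    # same as run_nested but seeded from a SeedSequence (grid cells)
    seed = int(seedseq.generate_state(1)[0] % (2**31))
    return run_nested(
        periods,
        orders,
        cfg,
        NestedSettings(
            n_live=settings.n_live,
            dlogz_stop=settings.dlogz_stop,
            seed=seed,
            sampler_mode=settings.sampler_mode,
            walks=settings.walks,
        ),
    )
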