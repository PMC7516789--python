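"""A compact static nested sampler.

Nested sampling estimates the evidence Z = int L(theta) p(theta) dtheta by
evolving a population of "live" points drawn from the prior, repeatedly
replacing the worst (lowest-likelihood) point with a new prior draw
constrained to exceed its likelihood.  The prior volume shrinks
geometrically, X_k ~ exp(-k/n_live), and the dead points with weights
L_k * (X_{k-1} - X_k) provide both the evidence and a weighted posterior
sample.  The reported evidence uncertainty is the classic information-based
estimate sqrt(H / n_live).

Two constrained-prior samplers are provided: 'unif' (rejection sampling
inside the axis-aligned bounding box of the live points, enlarged) for very
low dimensions, and 'rwalk' (an adaptive random walk started from a random
live point) otherwise.  Everything operates in the unit cube; the caller
supplies a prior transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = ["NSResult", "nested_sample"]


@dataclass
class NSResult:
    log_z: float
    log_z_err: float
    samples_u: np.ndarray  # dead + final live points, unit-cube coords
    log_l: np.ndarray
    log_wt: np.ndarray  # unnormalized log weights log(L_k * dX_k)
    n_iter: int
    n_calls: int
    information: float

    @property
    def weights(self) -> np.ndarray:
        """Posterior weights, normalized to sum to one."""
        w = np.exp(self.log_wt - self.log_wt.max())
        return w / w.sum()


def _logsubexp(a: float, b: float) -> float:
    # log(e^a - e^b) for a > b
    return a + np.log1p(-np.exp(b - a))


class _RWalk:
    """Adaptive random-walk constrained sampler in the unit cube."""

    def __init__(self, ndim: int, walks: int, rng: np.random.Generator):
        self.ndim = ndim
        self.walks = walks
        self.rng = rng
        self.scale = 0.5

    def propose(self, live_u, log_l_fn, l_star):
        n_live = len(live_u)
        cov = np.cov(live_u, rowvar=False) + 1e-12 * np.eye(self.ndim)
        try:
            chol = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            chol = np.diag(np.std(live_u, axis=0) + 1e-6)
        calls = 0
        for _attempt in range(50):
            u = live_u[self.rng.integers(n_live)].copy()
            lu = None
            n_acc = 0
            for _ in range(self.walks):
                step = self.scale * (chol @ self.rng.standard_normal(self.ndim))
                u_new = u + step
                if np.any(u_new <= 0.0) or np.any(u_new >= 1.0):
                    continue
                l_new = log_l_fn(u_new)
                calls += 1
                if l_new > l_star:
                    u, lu = u_new, l_new
                    n_acc += 1
            frac = n_acc / self.walks
            # steer acceptance toward ~0.4
            self.scale *= np.exp((frac - 0.4) / max(self.ndim, 1))
            self.scale = min(max(self.scale, 1e-5), 10.0)
            if n_acc > 0 and lu is not None:
                return u, lu, calls
        raise RuntimeError(
            "random-walk sampler failed to find a replacement point; "
            "the likelihood may have a plateau or the data are degenerate"
        )


class _UnifBox:
    """Rejection sampling in the enlarged bounding box of the live points."""

    def __init__(self, ndim: int, rng: np.random.Generator, enlarge: float = 1.5):
        self.ndim = ndim
        self.rng = rng
        self.enlarge = enlarge

    def propose(self, live_u, log_l_fn, l_star):
        lo = live_u.min(axis=0)
        hi = live_u.max(axis=0)
        mid = 0.5 * (lo + hi)
        half = 0.5 * (hi - lo) * self.enlarge + 1e-9
        lo = np.clip(mid - half, 0.0, 1.0)
        hi = np.clip(mid + half, 0.0, 1.0)
        calls = 0
        for _ in range(2000):
            u = lo + (hi - lo) * self.rng.random(self.ndim)
            l_new = log_l_fn(u)
            calls += 1
            if l_new > l_star:
                return u, l_new, calls
        return None  # caller falls back to the random walk


def nested_sample(
    log_l_fn: Callable[[np.ndarray], float],
    ndim: int,
    n_live: int = 250,
    dlogz_stop: float = 0.1,
    rng: np.random.Generator | None = None,
    mode: str = "auto",
    walks: int | None = None,
    max_iter: int = 200_000,
) -> NSResult:
    """Static nested sampling of ``log_l_fn`` over the unit cube.

    ``log_l_fn`` takes a unit-cube point (the prior transform is the
    caller's responsibility, folded into the likelihood callable).
    Iterates until the estimated remaining evidence contribution
    ``log(Z + L_max * X) - log(Z)`` drops below ``dlogz_stop``.
    """
    if rng is None:
        rng = np.random.default_rng()
    if n_live < 2 * ndim:
        raise ValueError("n_live must be at least 2*ndim")
    if mode == "auto":
        mode = "unif" if ndim <= 2 else "rwalk"
    if walks is None:
        walks = max(20, 4 * ndim)

    u_live = rng.random((n_live, ndim))
    logl_live = np.array([log_l_fn(u) for u in u_live])
    n_calls = n_live
    if not np.any(np.isfinite(logl_live)):
        raise RuntimeError("all initial live points have zero likelihood")

    rwalk = _RWalk(ndim, walks, rng)
    unif = _UnifBox(ndim, rng) if mode == "unif" else None

    dead_u, dead_logl, dead_logwt = [], [], []
    log_z = -np.inf
    h = 0.0
    log_vol = 0.0

    it = 0
    while it < max_iter:
        worst = int(np.argmin(logl_live))
        l_star = logl_live[worst]
        log_vol_new = -(it + 1) / n_live
        log_dvol = _logsubexp(log_vol, log_vol_new)
        log_wt = l_star + log_dvol

        log_z_new = np.logaddexp(log_z, log_wt)
        if np.isfinite(log_wt):
            prev = np.exp(log_z - log_z_new) * (h + log_z) if np.isfinite(log_z) else 0.0
            h = np.exp(log_wt - log_z_new) * l_star + prev - log_z_new
        log_z = log_z_new

        dead_u.append(u_live[worst].copy())
        dead_logl.append(l_star)
        dead_logwt.append(log_wt)

        proposal = None
        if unif is not None:
            proposal = unif.propose(u_live, log_l_fn, l_star)
        if proposal is None:
            proposal = rwalk.propose(u_live, log_l_fn, l_star)
        u_new, l_new, calls = proposal
        n_calls += calls
        u_live[worst] = u_new
        logl_live[worst] = l_new

        log_vol = log_vol_new
        it += 1

        dlogz = np.logaddexp(log_z, logl_live.max() + log_vol) - log_z
        if dlogz < dlogz_stop:
            break

    # fold in the remaining live points, each carrying volume X/n_live
    order = np.argsort(logl_live)
    log_dvol_live = log_vol - np.log(n_live)
    for idx in order:
        log_wt = logl_live[idx] + log_dvol_live
        log_z_new = np.logaddexp(log_z, log_wt)
        if np.isfinite(log_wt):
            prev = np.exp(log_z - log_z_new) * (h + log_z) if np.isfinite(log_z) else 0.0
            h = np.exp(log_wt - log_z_new) * logl_live[idx] + prev - log_z_new
        log_z = log_z_new
        dead_u.append(u_live[idx].copy())
        dead_logl.append(logl_live[idx])
        dead_logwt.append(log_wt)

    h = max(h, 0.0)
    return NSResult(
        log_z=float(log_z),
        log_z_err=float(np.sqrt(h / n_live)),
        samples_u=np.array(dead_u),
        log_l=np.array(dead_logl),
        log_wt=np.array(dead_logwt),
        n_iter=it,
        n_calls=n_calls,
        information=float(h),
    )
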