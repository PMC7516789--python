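"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's closed-form shortcuts: the amplitude
marginalization is done exactly (keeping the + I/delta^2 prior term the
closed form drops) and the noise scale is integrated by quadrature over its
Jeffreys prior range.
"""

import numpy as np
from scipy.integrate import quad


def exact_log_integrated_likelihood(d_list, G_list, cfg):
    """Exact amplitude marginalization + sigma quadrature on [lo, hi].

    For each period, with A = g/sigma^2 + I/delta^2 and h = G^T d / sigma^2:

        int db (2 pi delta^2)^(-m/2) (2 pi sigma^2)^(-N_i/2) exp(-QF/2)
          = (2 pi sigma^2)^(-N_i/2) (delta^2)^(-m/2) |A|^(-1/2)
            * exp(-d^T d / 2 sigma^2 + h^T A^-1 h / 2)

    then L_I = [log(hi/lo)]^-1 * int_lo^hi dsigma/sigma prod_i (above).
    """
    m = G_list[0].shape[1]
    delta2 = cfg.delta**2

    def log_f(sigma):
        s2 = sigma * sigma
        total = -np.log(sigma)
        for d, G in zip(d_list, G_list):
            Ni = len(d)
            g = G.T @ G
            A = g / s2 + np.eye(m) / delta2
            h = (G.T @ d) / s2
            sign, logdetA = np.linalg.slogdet(A)
            assert sign > 0
            total += (
                -0.5 * Ni * np.log(2 * np.pi * s2)
                - 0.5 * m * np.log(delta2)
                - 0.5 * logdetA
                - 0.5 * float(d @ d) / s2
                + 0.5 * float(h @ np.linalg.solve(A, h))
            )
        return total

    # peak location for stable shifted quadrature
    sig_grid = np.geomspace(cfg.sigma_lo, cfg.sigma_hi, 600)
    log_vals = np.array([log_f(s) for s in sig_grid])
    log_shift = log_vals.max()
    s_peak = sig_grid[int(np.argmax(log_vals))]

    val, _ = quad(
        lambda s: np.exp(log_f(s) - log_shift),
        cfg.sigma_lo,
        cfg.sigma_hi,
        points=[s_peak],
        limit=200,
    )
    return log_shift + np.log(val) - np.log(np.log(cfg.sigma_hi / cfg.sigma_lo))


def sigma_marginal_argmax(S, N, n, m, lo=1e-6, hi=1.0, n_grid=10_000):
    """Grid-search argmax of the sigma-marginal integrand
    sigma^-1 (2 pi sigma^2)^((nm-N)/2) exp(-S / 2 sigma^2)."""
    sig = np.geomspace(lo, hi, n_grid)
    logf = -np.log(sig) + 0.5 * (n * m - N) * np.log(2 * np.pi * sig**2) - S / (
        2 * sig**2
    )
    return sig[int(np.argmax(logf))]


def quadrature_log_evidence(log_li_fn, ranges_log, n_nodes=200):
    """Tensor-grid trapezoid integration of L_I * Jeffreys prior.

    ``ranges_log`` is a list of (log_lo, log_hi) per parameter; the Jeffreys
    prior is uniform in log theta, so Z = prod (log hi - log lo)^-1 *
    int L_I d(log theta).  Returns log Z.  2-D only.
    """
    assert len(ranges_log) == 2
    (la0, la1), (lw0, lw1) = ranges_log
    xs = np.linspace(la0, la1, n_nodes)
    ys = np.linspace(lw0, lw1, n_nodes)
    L = np.empty((n_nodes, n_nodes))
    for i, x in enumerate(xs):
        for j, y in enumerate(ys):
            L[i, j] = log_li_fn(np.exp(x), np.exp(y))
    shift = L.max()
    integral = np.trapezoid(
        np.trapezoid(np.exp(L - shift), ys, axis=1), xs, axis=0
    )
    norm = (la1 - la0) * (lw1 - lw0)
    return shift + np.log(integral) - np.log(norm)
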