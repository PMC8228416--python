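"""Independent oracles, coded separately from the package's fitters.

The brute-force GLM oracle maximizes the binomial log-likelihood of the
two-group logistic model numerically over the two logit parameters
(Nelder-Mead), never using pooled-proportion closed forms, and applies
the same dispersion rule (Pearson residuals of the full fit, df = n-2,
clamped at 1) and the same fitted-proportion clipping convention that
defines the statistic.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize

_EPS = 1e-8


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _nll(m, n, p):
    p = np.clip(p, _EPS, 1 - _EPS)
    return -np.sum(m * np.log(p) + (n - m) * np.log1p(-p))


def brute_force_test(counts_a, counts_b):
    """Numerically fitted deviance statistic, p, and dispersion.

    Returns (statistic, p_value, raw_phi).
    """
    from scipy import stats

    m = np.array([c[0] for c in counts_a] + [c[0] for c in counts_b], float)
    n = np.array([c[1] for c in counts_a] + [c[1] for c in counts_b], float)
    grp = np.array([0.0] * len(counts_a) + [1.0] * len(counts_b))

    def nll_full(theta):
        return _nll(m, n, _sigmoid(theta[0] + theta[1] * grp))

    def nll_null(theta):
        return _nll(m, n, _sigmoid(theta[0]))

    opts = dict(xatol=1e-12, fatol=1e-13, maxiter=50_000, maxfev=50_000)
    p_bar = np.clip(m.sum() / n.sum(), 0.01, 0.99)
    x0 = np.log(p_bar / (1 - p_bar))
    fit_full = min(
        (minimize(nll_full, s, method="Nelder-Mead", options=opts)
         for s in ([x0, 0.0], [0.0, 0.0], [x0, 1.0], [x0, -1.0])),
        key=lambda r: r.fun,
    )
    fit_null = min(
        (minimize(nll_null, [s], method="Nelder-Mead", options=opts)
         for s in (x0, 0.0)),
        key=lambda r: r.fun,
    )
    lr = max(2.0 * (fit_null.fun - fit_full.fun), 0.0)

    p_fit = np.clip(_sigmoid(fit_full.x[0] + fit_full.x[1] * grp), _EPS, 1 - _EPS)
    pearson2 = np.sum((m - n * p_fit) ** 2 / (n * p_fit * (1 - p_fit)))
    df = len(m) - 2
    raw_phi = pearson2 / df if df > 0 else 1.0
    phi = max(1.0, raw_phi)
    statistic = lr / phi
    return statistic, float(stats.chi2.sf(statistic, df=1)), raw_phi


def bh_qvalues(pvals):
    """Hand-rolled Benjamini-Hochberg step-up q-values."""
    p = np.asarray(pvals, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / (np.arange(m) + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def interval_member_brute(pos, intervals):
    """Point-in-any-interval by direct scan (half-open intervals)."""
    return any(s <= pos < e for s, e in intervals)
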