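"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's projected/profiled likelihood path:
the dense oracle builds the full N x N marginal covariance in long format
and maximizes the multivariate-normal likelihood directly with generic
numerical optimization, so agreement is a genuine cross-check.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize, stats


def dense_ml_fit(Y, case, batch, subject, E=None, include_batch=True, n_starts=4, seed=0):
    """Maximize the dense multivariate-normal ML likelihood of the mixed model.

    Long format obs index = sample * G + gene. Optimizes all variance
    components (residual, subject, batch if multi-level, one per factor
    column of E) on the log scale from several random starts; the fixed
    effects are profiled by GLS. Returns (max loglik, beta_hat).
    """
    Y = np.atleast_2d(np.asarray(Y, float))
    G, n = Y.shape
    N = G * n
    y = Y.T.reshape(-1)  # sample-major
    case = np.asarray(case, float)
    X = np.column_stack([np.ones(N), np.repeat(case, G)])

    subject = np.asarray(subject)
    batch = np.asarray(batch)
    Zs = [np.repeat(subject[:, None] == np.unique(subject)[None, :], G, axis=0).astype(float)]
    use_batch = include_batch and len(np.unique(batch)) > 1
    if use_batch:
        Zs.append(np.repeat(batch[:, None] == np.unique(batch)[None, :], G, axis=0).astype(float))
    if E is not None and np.size(E):
        E = np.asarray(E, float).reshape(G, -1)
        for k in range(E.shape[1]):
            Zs.append(np.kron(np.eye(n), E[:, k : k + 1]))
    grams = [Z @ Z.T for Z in Zs]

    def negll(log_var):
        var = np.exp(np.clip(log_var, -40, 40))
        Sigma = var[0] * np.eye(N)
        for v, Gm in zip(var[1:], grams):
            Sigma += v * Gm
        try:
            c = np.linalg.cholesky(Sigma)
        except np.linalg.LinAlgError:
            return 1e12
        logdet = 2.0 * np.sum(np.log(np.diag(c)))
        Si_y = np.linalg.solve(Sigma, y)
        Si_X = np.linalg.solve(Sigma, X)
        beta = np.linalg.solve(X.T @ Si_X, X.T @ Si_y)
        resid = y - X @ beta
        qf = resid @ np.linalg.solve(Sigma, resid)
        return 0.5 * (N * np.log(2 * np.pi) + logdet + qf)

    rng = np.random.default_rng(seed)
    k = 1 + len(grams)
    best = None
    for s in range(n_starts):
        x0 = np.log(np.full(k, 0.5)) if s == 0 else rng.normal(-1.0, 1.5, k)
        res = optimize.minimize(
            negll, x0, method="Nelder-Mead",
            options={"maxfev": 8000, "xatol": 1e-7, "fatol": 1e-11},
        )
        if best is None or res.fun < best.fun:
            best = res
    var = np.exp(best.x)
    Sigma = var[0] * np.eye(N)
    for v, Gm in zip(var[1:], grams):
        Sigma += v * Gm
    Si_y = np.linalg.solve(Sigma, y)
    Si_X = np.linalg.solve(Sigma, X)
    beta = np.linalg.solve(X.T @ Si_X, X.T @ Si_y)
    return -best.fun, beta


def pooled_t_pvalue(x, y):
    """Closed-form pooled-variance two-sample t-test p-value."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    nx, ny = x.size, y.size
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    t = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / nx + 1 / ny))
    return 2.0 * stats.t.sf(abs(t), nx + ny - 2)


def welch_t_pvalue(x, y):
    """Closed-form Welch two-sample t-test p-value (Satterthwaite df)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    nx, ny = x.size, y.size
    vx, vy = x.var(ddof=1) / nx, y.var(ddof=1) / ny
    t = (x.mean() - y.mean()) / np.sqrt(vx + vy)
    df = (vx + vy) ** 2 / (vx**2 / (nx - 1) + vy**2 / (ny - 1))
    return 2.0 * stats.t.sf(abs(t), df)


def bh_stepup_bruteforce(pvals):
    """Literal step-up definition of BH adjusted p-values, O(m^2)."""
    p = np.asarray(pvals, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    adj_sorted = np.empty(m)
    for i in range(m):
        candidates = [
            min(1.0, m * sorted_p[j] / (j + 1))
            for j in range(m)
            if sorted_p[j] >= sorted_p[i]
        ]
        adj_sorted[i] = min(candidates)
    out = np.empty(m)
    out[order] = adj_sorted
    return out
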