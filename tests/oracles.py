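"""Independent brute-force oracles used to validate the implementations.

Everything here is deliberately written the slow, obvious way (explicit
loops, symbolic equation solving, quadrature, full enumeration) and shares
no code with the package internals it checks.
"""

from itertools import combinations

import numpy as np
from scipy import integrate, optimize
from scipy.special import expit


def sq_euclid_oracle(a, b):
    """Squared Euclidean distance over loci scored in both rows, rescaled by
    total-locus count / shared-locus count."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    shared = ~np.isnan(a) & ~np.isnan(b)
    raw = sum((x - y) ** 2 for x, y in zip(a[shared], b[shared]))
    return raw * len(a) / shared.sum()


def amova_oracle(d, pops):
    """One-level AMOVA by explicit double loops + symbolic EMS solve.

    Returns (sigma_among, sigma_within, phi_st_raw).
    """
    import sympy

    d = np.asarray(d, float)
    pops = list(pops)
    names = sorted(set(pops), key=str)
    N = len(pops)
    P = len(names)
    ssd_total = 0.0
    for i in range(N):
        for j in range(i + 1, N):
            ssd_total += d[i, j]
    ssd_total /= N
    ssd_within = 0.0
    sizes = []
    for name in names:
        idx = [i for i, p in enumerate(pops) if p == name]
        sizes.append(len(idx))
        s = 0.0
        for i in idx:
            for j in idx:
                if i < j:
                    s += d[i, j]
        ssd_within += s / len(idx)
    ssd_among = ssd_total - ssd_within
    ms_within = ssd_within / (N - P)
    ms_among = ssd_among / (P - 1)
    n_prime = (N - sum(s**2 for s in sizes) / N) / (P - 1)
    sa, sw = sympy.symbols("sigma_a sigma_w")
    sol = sympy.solve(
        [sympy.Eq(sw, ms_within), sympy.Eq(sw + n_prime * sa, ms_among)], [sa, sw]
    )
    sigma_a, sigma_w = float(sol[sa]), float(sol[sw])
    tot = max(sigma_a, 0) + max(sigma_w, 0)
    phi = 0.0 if tot == 0 else max(sigma_a, 0) / tot
    return sigma_a, sigma_w, phi


def zhivotovsky_quadrature(a, b, m, n):
    """Posterior mean of q = sqrt(x) with x ~ Beta(a,b), m nulls of n, by
    numerical integration of q * posterior / integral of posterior."""
    post = lambda x: x ** (a + m - 1) * (1 - x) ** (b + n - m - 1)
    num = integrate.quad(lambda x: np.sqrt(x) * post(x), 0, 1, epsabs=1e-12)[0]
    den = integrate.quad(post, 0, 1, epsabs=1e-12)[0]
    return num / den


def fdist_pair_oracle(q, n):
    """Per-locus Hs/Ht/FST by explicit sums (weighted pooled frequency)."""
    q = np.asarray(q, float)
    n = np.asarray(n, float)
    hs = sum(2 * qi * (1 - qi) for qi in q) / len(q)
    qbar = sum(qi * ni for qi, ni in zip(q, n)) / n.sum()
    ht = 2 * qbar * (1 - qbar)
    return hs, ht, (ht - hs) / ht


def logistic_ml_oracle(y01, x):
    """Direct ML logistic fit (intercept + slope) via scipy optimisation."""
    y01 = np.asarray(y01, float)
    X = np.column_stack([np.ones(len(x)), np.asarray(x, float)])

    def nll(b):
        eta = X @ b
        p = np.clip(expit(eta), 1e-12, 1 - 1e-12)
        return -(y01 * np.log(p) + (1 - y01) * np.log(1 - p)).sum()

    res = optimize.minimize(nll, np.zeros(2), method="BFGS",
                            options=dict(gtol=1e-12, maxiter=500))
    return res.x  # (intercept, slope)


def ols_normal_equations(y, X):
    """OLS coefficients by the normal equations (intercept first)."""
    A = np.column_stack([np.ones(len(y)), np.asarray(X, float)])
    return np.linalg.solve(A.T @ A, A.T @ np.asarray(y, float))


def mann_whitney_exact(a, b):
    """Exact two-sided Mann-Whitney p by full enumeration of arrangements."""
    a, b = list(a), list(b)
    pooled = a + b
    n1 = len(a)
    ranks_obs = _u_stat(a, b)
    u_obs = min(ranks_obs, len(a) * len(b) - ranks_obs)
    count = 0
    total = 0
    for idx in combinations(range(len(pooled)), n1):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(len(pooled)) if i not in idx]
        u = _u_stat(ga, gb)
        u = min(u, n1 * len(gb) - u)
        if u <= u_obs:
            count += 1
        total += 1
    return count / total


def _u_stat(a, b):
    u = 0.0
    for x in a:
        for y in b:
            if x > y:
                u += 1
            elif x == y:
                u += 0.5
    return u


def pca_svd_oracle(X):
    """Principal axes and explained-variance percentages via raw SVD."""
    Xc = np.asarray(X, float) - np.asarray(X, float).mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2
    return U * s, Vt.T, 100.0 * var / var.sum()
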