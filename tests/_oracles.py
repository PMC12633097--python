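"""Independent brute-force / closed-form oracles used by the tests.

Each function re-derives its quantity from the published definition with
the most literal evaluation available (double loops, enumeration, closed
forms), deliberately sharing no code with the package implementation.
"""

from itertools import combinations

import numpy as np
from scipy.stats import hypergeom, studentized_range


def bicor_oracle(x, y):
    """Literal biweight midcorrelation of two complete vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)

    def prep(v):
        med = np.median(v)
        mad = np.median(np.abs(v - med))
        u = (v - med) / (9.0 * mad)
        w = (1.0 - u ** 2) ** 2 * (np.abs(u) < 1.0)
        return w * (v - med)

    a, b = prep(x), prep(y)
    return float(np.sum(a * b) / np.sqrt(np.sum(a ** 2) * np.sum(b ** 2)))


def tom_oracle(A, denom="mean"):
    """Double-loop topological overlap."""
    A = np.asarray(A, dtype=float)
    n = A.shape[0]
    k = np.array([sum(A[i, u] for u in range(n) if u != i) for i in range(n)])
    T = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(A[i, u] * A[u, j] for u in range(n) if u not in (i, j))
            f = (k[i] + k[j]) / 2.0 if denom == "mean" else min(k[i], k[j])
            T[i, j] = (shared + A[i, j]) / (f - A[i, j] + 1.0)
    return T


def eigenprotein_oracle(Z):
    """First principal component of a complete, row-standardised module
    matrix via the eigendecomposition of the sample-space covariance."""
    Z = np.asarray(Z, dtype=float)
    G = Z.T @ Z
    w, V = np.linalg.eigh(G)
    me = V[:, -1]
    me = me / me.std(ddof=1)
    if np.corrcoef(me, Z.mean(axis=0))[0, 1] < 0:
        me = -me
    var_expl = w[-1] / w.sum()
    return me, float(var_expl)


def tukey_oracle(groups, i, j):
    """Tukey HSD p for groups i vs j from the studentized-range tail."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    n_tot = sum(len(g) for g in groups)
    df = n_tot - k
    mse = sum(((g - g.mean()) ** 2).sum() for g in groups) / df
    se = np.sqrt(mse / 2.0 * (1.0 / len(groups[i]) + 1.0 / len(groups[j])))
    q = abs(groups[i].mean() - groups[j].mean()) / se
    return float(studentized_range.sf(q, k, df))


def fisher_upper_tail_oracle(overlap, bg, set_size, mod_size):
    """P(X >= overlap) by direct hypergeometric summation."""
    return float(sum(hypergeom.pmf(k, bg, set_size, mod_size)
                     for k in range(overlap, min(set_size, mod_size) + 1)))


def bh_oracle(p):
    """Literal Benjamini-Hochberg step-up."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


def exhaustive_perm_p(stats, module_mask):
    """Exact permutation p over all same-size subsets, with the (b+1)/(m+1)
    convention (the observed subset is part of the enumeration)."""
    stats = np.asarray(stats, dtype=float)
    k = int(np.sum(module_mask))
    T_obs = stats[np.asarray(module_mask, bool)].mean()
    T_null = [stats[list(c)].mean() for c in combinations(range(len(stats)), k)]
    b = sum(t >= T_obs for t in T_null)
    return (b + 1) / (len(T_null) + 1), T_obs, T_null
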