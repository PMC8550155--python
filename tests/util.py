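"""Shared helpers for the test suite: independent oracles and matchers."""

import itertools

import numpy as np
from scipy.optimize import linear_sum_assignment


def random_orthogonal(rng, p):
    Q, R = np.linalg.qr(rng.standard_normal((p, p)))
    return Q * np.sign(np.diag(R))[None, :]


def random_signed_permutation(rng, p):
    P = np.eye(p)[rng.permutation(p)]
    return P * rng.choice([-1.0, 1.0], size=p)[:, None]


def random_composition_series(rng, T, p):
    from ctsbss import CompositionSeries

    return CompositionSeries(np.arange(T), rng.lognormal(size=(T, p)))


def match_sources_dev(Z1, Z2):
    """Max abs deviation between two source sets after the optimal
    sign/permutation matching (assignment on absolute cross-products)."""
    C = Z1.T @ Z2 / len(Z1)
    ri, ci = linear_sum_assignment(-np.abs(C))
    s = np.sign(C[ri, ci])
    return float(np.abs(Z1[:, ri] * s - Z2[:, ci]).max())


def brute_force_md(G_hat, Omega):
    """Exhaustive MD oracle: enumerate all permutations, per-row closed-form
    scale, keep the minimum.  Only feasible for small p."""
    D = np.asarray(G_hat) @ np.asarray(Omega)
    p = D.shape[0]
    best = np.inf
    for perm in itertools.permutations(range(p)):
        total = 0.0
        for i, k in enumerate(perm):
            d = D[k]
            nrm2 = float(d @ d)
            # optimal scale c minimizing ||c d - e_i||^2 is d_i / ||d||^2
            total += 1.0 - d[i] ** 2 / nrm2
        best = min(best, total)
    return float(np.sqrt(best / (p - 1)))


def direct_autocov(X, tau, mu=None):
    """Direct-summation lag-tau autocovariance oracle (complete data)."""
    X = np.asarray(X, dtype=float)
    if mu is None:
        mu = X.mean(axis=0)
    n = len(X) - tau
    S = np.zeros((X.shape[1], X.shape[1]))
    for t in range(n):
        S += np.outer(X[t] - mu, X[t + tau] - mu)
    return S / n
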