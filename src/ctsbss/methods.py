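"""The unmixing estimators.

All methods assume the linear latent-variable model x_t = mu + Omega z_t
with a full-rank mixing matrix Omega and latent series z_t that are
uncorrelated and, depending on the method, identified through

* distinct lagged autocovariances (AMUSE, SOBI),
* distinct fourth-order lagged moment/cumulant structure when the
  autocovariances are uninformative, as for stochastic-volatility series
  (gFOBI, gJADE, vSOBI),
* time-varying variances/autocovariances (NSS-SD, NSS-JD, NSS-TD-JD), or
* any combination of the above (the weighted combined estimator
  NSS-SOBI-gFOBI).

Every estimator returns a :class:`BssResult` with the unmixing matrix
Gamma, the location estimate, the recovered sources z_t = Gamma (x_t - mu)
and diagnostics.  Components are only identified up to sign and order
(and, for the NSS family, scale); deterministic conventions are applied:
rows are ordered by the method's separation statistic, signs make each
row's largest-magnitude entry positive, and NSS sources are scaled to unit
overall variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence
import warnings

import numpy as np

from .coda import CoordinateSeries
from .jointdiag import (
    fix_row_signs,
    gevd_two_matrices,
    jacobi_ajd,
    maximize_nonquadratic,
    near_degenerate,
)
from .moments import (
    IntervalPartition,
    LagSet,
    MatrixStack,
    autocovariance,
    fourth_moment_matrix,
    cross_cumulant_matrices,
    grid_positions,
    local_autocovariance,
    partition_intervals,
    sample_mean_cov,
    whiten,
)

__all__ = [
    "BssResult",
    "amuse",
    "sobi",
    "gfobi",
    "gjade",
    "vsobi",
    "nss_sd",
    "nss_jd",
    "nss_td_jd",
    "nss_sobi_gfobi",
    "WEIGHT_SCHEMES",
]

WEIGHT_SCHEMES = ("equal", "kurtosis", "maxnorm")


@dataclass
class BssResult:
    """Unmixing estimate: sources z_t = unmixing @ (x_t - center)."""

    unmixing: np.ndarray
    center: np.ndarray
    sources: np.ndarray
    method: str
    params: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)
    positions: np.ndarray | None = None

    @property
    def n_components(self) -> int:
        return self.unmixing.shape[0]

    @property
    def mixing(self) -> np.ndarray:
        """Estimated mixing matrix, the inverse of the unmixing matrix."""
        return np.linalg.inv(self.unmixing)


def _coerce(x, positions):
    if isinstance(x, CoordinateSeries):
        X = x.values
        if positions is None:
            positions = grid_positions(x.timestamps)
    else:
        X = np.atleast_2d(np.asarray(x, dtype=float))
    if positions is None:
        positions = np.arange(len(X))
    return X, np.asarray(positions, dtype=np.int64)


_gap_flag = near_degenerate


def _finalize(X, pos, Gamma, method, params, diagnostics, order_stat=None):
    """Apply order/sign conventions and compute the sources."""
    if order_stat is not None:
        order = np.argsort(order_stat)[::-1]
        Gamma = Gamma[order]
        diagnostics = dict(diagnostics, order_stat=np.asarray(order_stat)[order])
    Gamma = fix_row_signs(Gamma)
    mu = X.mean(axis=0)
    Z = (X - mu) @ Gamma.T
    return BssResult(unmixing=Gamma, center=mu, sources=Z, method=method,
                     params=params, diagnostics=diagnostics, positions=pos)


# ---------------------------------------------------------------------------
# Stationary second-order methods

def amuse(x, tau: int = 1, positions=None) -> BssResult:
    """AMUSE: simultaneous diagonalization of the covariance and one
    symmetrized lag-tau autocovariance, via generalized eigendecomposition.

    Requires the sources to have distinct lag-tau autocorrelations; nearly
    tied eigenvalues raise the ``gap_warning`` diagnostic.
    """
    tau = int(tau)
    if tau < 1:
        raise ValueError("AMUSE requires a positive lag")
    X, pos = _coerce(x, positions)
    _, cov = sample_mean_cov(X)
    S = autocovariance(X, tau, positions=pos, sym=True)
    res = gevd_two_matrices(cov, S)
    diag = {"eigenvalues": res.eigenvalues, "gap_warning": res.gap_warning}
    return _finalize(X, pos, res.eigenvectors, "amuse", {"tau": tau}, diag)


def _ajd_unmix(X, pos, stack, method, params, extra_diag=None):
    res = jacobi_ajd(stack)
    W = params.pop("_whitener")
    Gamma = res.rotation @ W
    diag = {
        "objective": res.objective,
        "sweeps": res.sweeps,
        "converged": res.converged,
        "gap_warning": _gap_flag(res.criterion_per_component),
    }
    if extra_diag:
        diag.update(extra_diag)
    return _finalize(X, pos, Gamma, method, params, diag,
                     order_stat=res.criterion_per_component)


def sobi(x, lags: Sequence[int] = range(1, 7), positions=None) -> BssResult:
    """SOBI: whiten, then jointly diagonalize the symmetrized whitened
    autocovariance matrices over a set of positive lags."""
    lags = LagSet(lags)
    if lags.lags and lags.lags[0] < 1:
        raise ValueError("SOBI lags must be positive")
    X, pos = _coerce(x, positions)
    xst = whiten(X, positions=pos)
    mats = [autocovariance(xst.values, t, positions=pos, sym=True) for t in lags]
    labels = [("S", "global", t) for t in lags]
    stack = MatrixStack(np.stack(mats), labels=labels)
    return _ajd_unmix(X, pos, stack, "sobi",
                      {"lags": lags.lags, "_whitener": xst.whitener})


def gfobi(x, lags: Sequence[int] = range(0, 7), positions=None) -> BssResult:
    """gFOBI: whiten, then jointly diagonalize the fourth-order
    cross-moment matrices B_tau over the lag set (lag 0 gives FOBI)."""
    lags = LagSet(lags)
    X, pos = _coerce(x, positions)
    xst = whiten(X, positions=pos)
    mats = [fourth_moment_matrix(xst, t) for t in lags]
    stack = MatrixStack(np.stack(mats), labels=[("B", "global", t) for t in lags])
    return _ajd_unmix(X, pos, stack, "gfobi",
                      {"lags": lags.lags, "_whitener": xst.whitener})


def gjade(x, lags: Sequence[int] = range(0, 7), positions=None) -> BssResult:
    """gJADE: whiten, then jointly diagonalize all p^2 fourth-order
    cross-cumulant matrices C^{jk}_tau per lag (lag 0 gives JADE)."""
    lags = LagSet(lags)
    X, pos = _coerce(x, positions)
    p = X.shape[1]
    if p > 12:
        warnings.warn(
            f"gJADE diagonalizes p^2*|lags| = {p * p * len(lags)} matrices "
            f"for p={p}; this may be slow", UserWarning, stacklevel=2)
    xst = whiten(X, positions=pos)
    mats, labels = [], []
    for t in lags:
        C = cross_cumulant_matrices(xst, t)
        for j in range(p):
            for k in range(p):
                mats.append(C[j, k])
                labels.append(("C", f"{j},{k}", t))
    stack = MatrixStack(np.stack(mats), labels=labels)
    return _ajd_unmix(X, pos, stack, "gjade",
                      {"lags": lags.lags, "_whitener": xst.whitener})


def vsobi(x, lags: Sequence[int] = range(1, 7), G: str = "square",
          positions=None, seed: int | None = None, n_restarts: int = 5) -> BssResult:
    """vSOBI: whiten, then maximize the nonquadratic lagged-correlation
    contrast (G = y^2 or log cosh y) over the orthogonal group."""
    lags = LagSet(lags)
    X, pos = _coerce(x, positions)
    xst = whiten(X, positions=pos)
    res = maximize_nonquadratic(xst, lags, G=G, seed=seed, n_restarts=n_restarts)
    Gamma = res.rotation @ xst.whitener
    diag = {"objective": res.objective, "iterations": res.sweeps,
            "converged": res.converged,
            "gap_warning": _gap_flag(res.criterion_per_component)}
    return _finalize(X, pos, Gamma, "vsobi",
                     {"lags": lags.lags, "G": G, "seed": seed}, diag,
                     order_stat=res.criterion_per_component)


# ---------------------------------------------------------------------------
# Nonstationary methods

def _partition(pos, K: int, min_length: int) -> IntervalPartition:
    """K intervals over the observed range; K=1 means the whole range
    (reducing interval-based methods to their global counterparts)."""
    if int(K) == 1:
        return IntervalPartition(((int(pos[0]), int(pos[-1]) + 1),))
    return partition_intervals(pos, K, min_length=min_length)


def _default_halves(pos):
    start, stop = int(pos[0]), int(pos[-1]) + 1
    mid = start + (stop - start) // 2
    return (start, mid), (mid, stop)


def nss_sd(x, T1=None, T2=None, positions=None) -> BssResult:
    """NSS-SD: simultaneous diagonalization of the covariances of two time
    intervals (defaults: the two halves of the range).  Source scales are
    not identified; sources are normalized to unit overall variance."""
    X, pos = _coerce(x, positions)
    if T1 is None or T2 is None:
        T1, T2 = _default_halves(pos)
    S1 = local_autocovariance(X, T1, 0, positions=pos, sym=True)
    S2 = local_autocovariance(X, T2, 0, positions=pos, sym=True)
    res = gevd_two_matrices(S1, S2)
    Gamma = res.eigenvectors
    mu = X.mean(axis=0)
    sd = ((X - mu) @ Gamma.T).std(axis=0)
    Gamma = Gamma / sd[:, None]
    diag = {"eigenvalues": res.eigenvalues, "gap_warning": res.gap_warning}
    return _finalize(X, pos, Gamma, "nss_sd",
                     {"T1": tuple(T1), "T2": tuple(T2)}, diag)


def nss_jd(x, K: int = 6, positions=None) -> BssResult:
    """NSS-JD: whiten globally, then jointly diagonalize the K interval
    covariances of the whitened series."""
    X, pos = _coerce(x, positions)
    xst = whiten(X, positions=pos)
    part = partition_intervals(pos, K)
    mats = [local_autocovariance(xst.values, iv, 0, positions=pos, sym=True)
            for iv in part]
    stack = MatrixStack(np.stack(mats),
                        labels=[("S", i, 0) for i in range(len(part))])
    return _ajd_unmix(X, pos, stack, "nss_jd",
                      {"K": K, "intervals": part.intervals,
                       "_whitener": xst.whitener})


def nss_td_jd(x, K: int = 6, lags: Sequence[int] = range(0, 7),
              positions=None) -> BssResult:
    """NSS-TD-JD: whiten globally, then jointly diagonalize the local
    autocovariances over every interval x lag combination (block-stationary
    sources)."""
    lags = LagSet(lags)
    X, pos = _coerce(x, positions)
    xst = whiten(X, positions=pos)
    part = _partition(pos, K, lags.max + 1)
    mats, labels = [], []
    for i, iv in enumerate(part):
        for t in lags:
            mats.append(local_autocovariance(xst.values, iv, t,
                                             positions=pos, sym=True))
            labels.append(("S", i, t))
    stack = MatrixStack(np.stack(mats), labels=labels)
    return _ajd_unmix(X, pos, stack, "nss_td_jd",
                      {"K": K, "lags": lags.lags, "intervals": part.intervals,
                       "_whitener": xst.whitener})


def nss_sobi_gfobi(
    x,
    K: int = 6,
    lags1: Sequence[int] = range(0, 7),
    lags2: Sequence[int] = range(0, 7),
    scheme: str = "maxnorm",
    positions=None,
) -> BssResult:
    """Weighted combined estimator over interval autocovariances and
    interval fourth-order cross-moment matrices.

    Per interval T_i, the stack holds S_{T_i,tau} for tau in ``lags1`` and
    B_{T_i,tau} for tau in ``lags2``, all computed on the globally whitened
    series.  The weight schemes:

    * ``equal``    — every matrix weight 1;
    * ``kurtosis`` — B matrices divided by p + 2 (making the lag-0 fourth
      moment matrix comparable to a covariance at the Gaussian model);
    * ``maxnorm``  — per matrix, 1/max|entry| when that max exceeds 1, else
      1 (down-weights large matrices without up-weighting near-zero ones).
    """
    if scheme not in WEIGHT_SCHEMES:
        raise ValueError(f"scheme must be one of {WEIGHT_SCHEMES}, got {scheme!r}")
    lags1 = LagSet(lags1)
    lags2 = LagSet(lags2)
    X, pos = _coerce(x, positions)
    p = X.shape[1]
    max_lag = max([lags1.max] + [lags2.max])
    xst = whiten(X, positions=pos)
    part = _partition(pos, K, max_lag + 1)
    for iv in part:
        if iv[1] - iv[0] <= max_lag:
            raise ValueError(f"interval {iv} is shorter than the maximum lag {max_lag}")
    mats, labels = [], []
    for i, iv in enumerate(part):
        for t in lags1:
            mats.append(local_autocovariance(xst.values, iv, t,
                                             positions=pos, sym=True))
            labels.append(("S", i, t))
        for t in lags2:
            mats.append(fourth_moment_matrix(xst, t, interval=iv))
            labels.append(("B", i, t))
    mats = np.stack(mats)
    if scheme == "equal":
        weights = np.ones(len(mats))
    elif scheme == "kurtosis":
        weights = np.array([1.0 / (p + 2) if fam == "B" else 1.0
                            for fam, _, _ in labels])
    else:  # maxnorm
        mx = np.abs(mats).max(axis=(1, 2))
        weights = np.where(mx > 1.0, 1.0 / np.maximum(mx, 1e-300), 1.0)
    stack = MatrixStack(mats, labels=labels, weights=weights)
    return _ajd_unmix(X, pos, stack, "nss_sobi_gfobi",
                      {"K": K, "lags1": lags1.lags, "lags2": lags2.lags,
                       "scheme": scheme, "intervals": part.intervals,
                       "_whitener": xst.whitener})
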