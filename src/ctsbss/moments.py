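"""Moment matrices for time-series source separation.

Everything the estimators jointly diagonalize is computed here: the sample
covariance, (local) lagged autocovariances, fourth-order cross-moment
matrices and fourth-order cross-cumulant matrices, plus whitening by the
symmetric inverse square root of the covariance.

Series may have missing time points.  Observations live on a regular grid
of integer positions; a pair (t, t+tau) enters a lag-tau statistic only
when both grid positions were actually observed, so lags always refer to
the true sampling interval rather than to row offsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "LagSet",
    "IntervalPartition",
    "MatrixStack",
    "WhitenedSeries",
    "grid_positions",
    "sample_mean_cov",
    "autocovariance",
    "local_autocovariance",
    "fourth_moment_matrix",
    "cross_cumulant_matrices",
    "whiten",
    "partition_intervals",
    "symmetrize",
]


@dataclass(frozen=True)
class LagSet:
    """Ordered set of distinct nonnegative integer lags."""

    lags: tuple

    def __init__(self, lags: Sequence[int]):
        lags = tuple(int(t) for t in lags)
        if any(t < 0 for t in lags):
            raise ValueError("lags must be nonnegative")
        if len(set(lags)) != len(lags) or list(lags) != sorted(lags):
            raise ValueError("lags must be distinct and strictly increasing")
        object.__setattr__(self, "lags", lags)

    def __iter__(self):
        return iter(self.lags)

    def __len__(self):
        return len(self.lags)

    @property
    def max(self) -> int:
        return max(self.lags) if self.lags else 0


@dataclass(frozen=True)
class IntervalPartition:
    """K disjoint contiguous half-open grid-position ranges covering the data."""

    intervals: tuple  # of (start, stop) pairs, half-open

    def __post_init__(self):
        iv = tuple((int(a), int(b)) for a, b in self.intervals)
        for a, b in iv:
            if b <= a:
                raise ValueError(f"empty interval ({a}, {b})")
        for (a1, b1), (a2, b2) in zip(iv, iv[1:]):
            if a2 != b1:
                raise ValueError("intervals must be contiguous and ordered")
        object.__setattr__(self, "intervals", iv)

    def __iter__(self):
        return iter(self.intervals)

    def __len__(self):
        return len(self.intervals)

    @property
    def lengths(self) -> list:
        return [b - a for a, b in self.intervals]


@dataclass
class MatrixStack:
    """Symmetric p x p matrices with per-matrix labels and positive weights.

    Labels record the family (S autocovariance, B fourth moment, C cumulant),
    the interval ("global" or an interval id) and the lag.
    """

    matrices: np.ndarray  # (m, p, p)
    labels: list = field(default_factory=list)
    weights: np.ndarray | None = None

    def __post_init__(self):
        M = np.asarray(self.matrices, dtype=float)
        if M.ndim == 2:
            M = M[None]
        if M.ndim != 3 or M.shape[1] != M.shape[2]:
            raise ValueError("matrices must be a stack of square matrices")
        if not np.allclose(M, np.swapaxes(M, 1, 2), atol=1e-10):
            raise ValueError("all matrices must be symmetric")
        self.matrices = M
        if not self.labels:
            self.labels = [("S", "global", i) for i in range(M.shape[0])]
        if len(self.labels) != M.shape[0]:
            raise ValueError("one label per matrix required")
        if self.weights is None:
            self.weights = np.ones(M.shape[0])
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (M.shape[0],) or np.any(self.weights <= 0):
            raise ValueError("weights must be positive, one per matrix")

    @property
    def p(self) -> int:
        return self.matrices.shape[1]

    def weighted(self) -> np.ndarray:
        """Matrices scaled by their weights, ready for joint diagonalization."""
        return self.matrices * self.weights[:, None, None]


@dataclass
class WhitenedSeries:
    """Centred, whitened observations with the whitener that produced them."""

    values: np.ndarray
    whitener: np.ndarray  # COV^{-1/2}, symmetric
    center: np.ndarray
    positions: np.ndarray | None = None

    def __post_init__(self):
        if self.positions is None:
            self.positions = np.arange(len(self.values))
        self.positions = np.asarray(self.positions, dtype=np.int64)


def grid_positions(timestamps: np.ndarray, grid=None) -> np.ndarray:
    """Integer grid positions of (possibly gapped) timestamps.

    For datetime stamps a grid spacing (e.g. ``"10min"`` or a Timedelta)
    must be supplied; every timestamp must fall exactly on the grid.
    Integer timestamps are taken as grid positions directly (or divided by
    an integer grid step).
    """
    ts = np.asarray(timestamps)
    if np.issubdtype(ts.dtype, np.datetime64):
        if grid is None:
            raise ValueError("datetime timestamps require a grid spacing")
        import pandas as pd

        step = pd.to_timedelta(grid).to_timedelta64().astype("timedelta64[ns]")
        delta = (ts.astype("datetime64[ns]") - ts[0].astype("datetime64[ns]"))
        q, r = np.divmod(delta.astype(np.int64), step.astype(np.int64))
        if np.any(r != 0):
            k = int(np.argmax(r != 0))
            raise ValueError(f"timestamp {ts[k]!r} is off the declared grid")
        return q.astype(np.int64)
    pos = ts.astype(np.int64)
    if grid is not None:
        step = int(grid)
        q, r = np.divmod(pos - pos[0], step)
        if np.any(r != 0):
            k = int(np.argmax(r != 0))
            raise ValueError(f"timestamp {ts[k]!r} is off the declared grid")
        return q
    return pos - pos[0]


def symmetrize(M: np.ndarray) -> np.ndarray:
    return 0.5 * (M + np.swapaxes(M, -1, -2))


def _positions(values: np.ndarray, positions) -> np.ndarray:
    if positions is None:
        return np.arange(len(values), dtype=np.int64)
    pos = np.asarray(positions, dtype=np.int64)
    if pos.shape != (len(values),):
        raise ValueError("positions must match the number of rows")
    if len(pos) > 1 and np.any(np.diff(pos) <= 0):
        raise ValueError("positions must be strictly increasing")
    return pos


def _row_lookup(pos: np.ndarray) -> np.ndarray:
    """Array mapping grid position (relative to pos[0]) -> row index, -1 if absent."""
    span = int(pos[-1] - pos[0]) + 1
    lut = np.full(span, -1, dtype=np.int64)
    lut[pos - pos[0]] = np.arange(len(pos))
    return lut


def _lag_pairs(pos: np.ndarray, tau: int, interval=None):
    """Row indices (a, b) of valid pairs with positions differing by exactly tau.

    ``interval`` restricts both members of the pair to a half-open grid range.
    """
    lut = _row_lookup(pos)
    off = int(pos[0])
    lo, hi = (0, len(lut)) if interval is None else (interval[0] - off, interval[1] - off)
    lo, hi = max(lo, 0), min(hi, len(lut))
    if hi - lo <= tau:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    left = lut[lo:hi - tau] if tau > 0 else lut[lo:hi]
    right = lut[lo + tau:hi]
    ok = (left >= 0) & (right >= 0)
    return left[ok], right[ok]


def sample_mean_cov(values: np.ndarray, positions=None):
    """Sample mean and covariance over the observed rows (divisor n).

    The divisor-n convention matches the lag-0 autocovariance so that
    ``autocovariance(x, 0)`` is exactly the covariance.
    """
    X = np.atleast_2d(np.asarray(values, dtype=float))
    n, p = X.shape
    if n < p + 1:
        raise ValueError(f"need at least p+1={p + 1} observations, got {n}")
    mu = X.mean(axis=0)
    Xc = X - mu
    return mu, (Xc.T @ Xc) / n


def autocovariance(
    values: np.ndarray,
    tau: int,
    positions=None,
    center: np.ndarray | None = None,
    sym: bool = False,
) -> np.ndarray:
    """Lag-tau autocovariance over all valid (t, t+tau) pairs.

    Both members are centred by the global mean; the divisor is the number
    of valid pairs, which for complete data equals T - tau.
    """
    X = np.atleast_2d(np.asarray(values, dtype=float))
    pos = _positions(X, positions)
    tau = int(tau)
    if tau < 0:
        raise ValueError("lag must be nonnegative")
    mu = X.mean(axis=0) if center is None else np.asarray(center, dtype=float)
    a, b = _lag_pairs(pos, tau)
    if len(a) < X.shape[1] + 1:
        raise ValueError(f"too few valid pairs ({len(a)}) at lag {tau}")
    Xa = X[a] - mu
    Xb = X[b] - mu
    S = (Xa.T @ Xb) / len(a)
    return symmetrize(S) if sym else S


def local_autocovariance(
    values: np.ndarray,
    interval,
    tau: int,
    positions=None,
    sym: bool = False,
) -> np.ndarray:
    """Lag-tau autocovariance within one grid interval, centred by the
    interval mean; divisor is the number of valid pairs (|T| - tau for
    complete data)."""
    X = np.atleast_2d(np.asarray(values, dtype=float))
    pos = _positions(X, positions)
    tau = int(tau)
    lo, hi = int(interval[0]), int(interval[1])
    in_iv = (pos >= lo) & (pos < hi)
    if in_iv.sum() <= tau:
        raise ValueError(f"interval ({lo}, {hi}) too short for lag {tau}")
    mu = X[in_iv].mean(axis=0)
    a, b = _lag_pairs(pos, tau, interval=(lo, hi))
    if len(a) == 0:
        raise ValueError(f"no valid lag-{tau} pairs in interval ({lo}, {hi})")
    S = ((X[a] - mu).T @ (X[b] - mu)) / len(a)
    return symmetrize(S) if sym else S


def fourth_moment_matrix(
    xst: WhitenedSeries | np.ndarray,
    tau: int,
    interval=None,
    positions=None,
) -> np.ndarray:
    """Fourth-order cross-moment matrix B_tau = E[x_{t+tau} x_t' x_t x_{t+tau}'].

    Since x_t' x_t is scalar this is the average of squared-norm-weighted
    outer products of the lagged observation; it is symmetric by
    construction.  Expects whitened (or at least centred) input; per-interval
    variants reuse the *global* whitening and the interval's own pairs.
    """
    if isinstance(xst, WhitenedSeries):
        X, pos = xst.values, xst.positions
    else:
        X = np.atleast_2d(np.asarray(xst, dtype=float))
        pos = _positions(X, positions)
    tau = int(tau)
    a, b = _lag_pairs(pos, tau, interval=interval)
    if len(a) < X.shape[1] + 1:
        raise ValueError(f"too few valid pairs ({len(a)}) at lag {tau}")
    s = np.einsum("ij,ij->i", X[a], X[a])  # ||x_t||^2
    B = np.einsum("i,ij,ik->jk", s, X[b], X[b]) / len(a)
    return B


def cross_cumulant_matrices(
    xst: WhitenedSeries | np.ndarray,
    tau: int,
    positions=None,
) -> np.ndarray:
    """All p^2 fourth-order cross-cumulant matrices C^{jk}_tau of the
    whitened series, stacked as (p, p, p, p) with [j, k] indexing.

    C^{jk}_tau = E[x_{t+tau} x_t' E^{jk} x_t x_{t+tau}']
                 - S_tau (E^{jk} + E^{kj}) S_tau' - trace(E^{jk}) I,
    with E^{jk} = e_j e_k'; each matrix is symmetrized.
    """
    if isinstance(xst, WhitenedSeries):
        X, pos = xst.values, xst.positions
    else:
        X = np.atleast_2d(np.asarray(xst, dtype=float))
        pos = _positions(X, positions)
    p = X.shape[1]
    tau = int(tau)
    a, b = _lag_pairs(pos, tau)
    if len(a) < p + 1:
        raise ValueError(f"too few valid pairs ({len(a)}) at lag {tau}")
    X0, X1 = X[a], X[b]
    # M[j,k] = E[ x_t[j] x_t[k] * outer(x_{t+tau}, x_{t+tau}) ]
    M = np.einsum("tj,tk,ta,tb->jkab", X0, X0, X1, X1) / len(a)
    S = (X0.T @ X1) / len(a)  # S_tau = E[x_t x_{t+tau}']
    eye = np.eye(p)
    C = np.empty((p, p, p, p))
    for j in range(p):
        for k in range(p):
            Ejk = np.outer(eye[j], eye[k])
            corr = S @ (Ejk + Ejk.T) @ S.T + (1.0 if j == k else 0.0) * eye
            C[j, k] = symmetrize(M[j, k] - corr)
    return C


def whiten(values: np.ndarray, positions=None) -> WhitenedSeries:
    """Centre and whiten with the symmetric inverse square root of COV.

    Raises when the covariance is numerically singular (smallest eigenvalue
    below 1e-10 of the largest); reduce the dimension first (e.g. PCA on the
    ilr coordinates) in that case.
    """
    X = np.atleast_2d(np.asarray(values, dtype=float))
    pos = _positions(X, positions)
    mu, cov = sample_mean_cov(X)
    lam, E = np.linalg.eigh(cov)
    if lam[0] <= 1e-10 * lam[-1]:
        raise np.linalg.LinAlgError(
            "covariance is numerically singular; consider PCA pre-reduction "
            f"(eigenvalue ratio {lam[0] / lam[-1]:.2e})"
        )
    W = (E * (1.0 / np.sqrt(lam))) @ E.T
    return WhitenedSeries((X - mu) @ W.T, whitener=W, center=mu, positions=pos)


def partition_intervals(positions, K: int, min_length: int | None = None) -> IntervalPartition:
    """Split the observed grid range into K contiguous near-equal intervals.

    The remainder of the division goes to the last interval.  ``positions``
    may be an array of grid positions or a (start, stop) half-open range.
    """
    K = int(K)
    if K < 2:
        raise ValueError("K must be at least 2")
    if isinstance(positions, tuple) and len(positions) == 2:
        start, stop = int(positions[0]), int(positions[1])
    else:
        pos = np.asarray(positions, dtype=np.int64)
        start, stop = int(pos[0]), int(pos[-1]) + 1
    span = stop - start
    base = span // K
    need = base if min_length is None else max(base, 1)
    if base < 1 or (min_length is not None and base < min_length):
        raise ValueError(
            f"range of length {span} too short for K={K} intervals"
            + (f" of minimum length {min_length}" if min_length else "")
        )
    bounds = [start + i * base for i in range(K)] + [stop]
    return IntervalPartition(tuple((bounds[i], bounds[i + 1]) for i in range(K)))
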