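"""Optimization engines underlying all the unmixing estimators.

Three primitives:

* a two-matrix generalized eigendecomposition (simultaneous
  diagonalization of an SPD matrix and one symmetric matrix),
* orthogonal approximate joint diagonalization (AJD) of a stack of
  symmetric matrices by cyclic Jacobi rotations, maximizing the sum of
  squared diagonal elements, and
* a fixed-point maximizer over the orthogonal group for the nonquadratic
  lagged-correlation criterion used by vSOBI.

All are deterministic given their inputs (and seed, where randomness is
involved).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .moments import LagSet, MatrixStack, WhitenedSeries, _lag_pairs, symmetrize

__all__ = [
    "AjdResult",
    "GevdResult",
    "gevd_two_matrices",
    "jacobi_ajd",
    "maximize_nonquadratic",
    "ajd_objective",
    "fix_row_signs",
]


@dataclass
class AjdResult:
    rotation: np.ndarray          # orthogonal U, rows u_i
    objective: float              # sum_j sum_i (u_i' a_j M_j u_i)^2
    sweeps: int
    converged: bool
    criterion_per_component: np.ndarray | None = None


@dataclass
class GevdResult:
    eigenvalues: np.ndarray       # descending
    eigenvectors: np.ndarray      # rows gamma_i
    gap_warning: bool = False


def near_degenerate(values: np.ndarray, gap_rtol: float = 1e-3,
                    scale_rtol: float = 0.2) -> bool:
    """Heuristic tie detection for a separation statistic.

    Warns when the overall spread is small relative to the statistic's
    magnitude (all components nearly interchangeable — e.g. equal
    autocorrelations, or Gaussian data for fourth-moment methods) or when
    two consecutive sorted values are closer than ``gap_rtol`` times the
    spread.  ``scale_rtol`` is sized to typical sampling noise at moderate
    series lengths; the flag is advisory.
    """
    v = np.sort(np.asarray(values, dtype=float))[::-1]
    scale = np.abs(v).max()
    if scale == 0:
        return True
    spread = v[0] - v[-1]
    if spread < scale_rtol * scale:
        return True
    return bool(np.any(-np.diff(v) < gap_rtol * spread))


def fix_row_signs(U: np.ndarray) -> np.ndarray:
    """Flip row signs so each row's largest-magnitude entry is positive."""
    U = np.asarray(U, dtype=float).copy()
    idx = np.argmax(np.abs(U), axis=1)
    signs = np.sign(U[np.arange(U.shape[0]), idx])
    signs[signs == 0] = 1.0
    return U * signs[:, None]


def ajd_objective(U: np.ndarray, matrices: np.ndarray) -> float:
    """Sum over matrices of the squared diagonal of U M U'."""
    d = np.einsum("ip,mpq,iq->mi", U, matrices, U)
    return float(np.sum(d**2))


def gevd_two_matrices(A: np.ndarray, B: np.ndarray, gap_rtol: float = 1e-3) -> GevdResult:
    """Simultaneously diagonalize SPD A and symmetric B.

    The rows gamma_i satisfy Gamma A Gamma' = I and Gamma B Gamma' =
    diag(descending).  Computed by whitening with the symmetric A^{-1/2}
    and eigendecomposing the whitened B.  ``gap_warning`` is set when two
    consecutive eigenvalues are closer than ``gap_rtol`` times the spread,
    signalling poorly identified components.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if not np.allclose(A, A.T, atol=1e-8):
        raise ValueError("A must be symmetric")
    lam, E = np.linalg.eigh(A)
    if lam[0] <= 1e-12 * max(lam[-1], 1.0):
        raise ValueError("A is not positive definite")
    W = (E * (1.0 / np.sqrt(lam))) @ E.T
    Bw = symmetrize(W @ B @ W.T)
    ev, U = np.linalg.eigh(Bw)
    order = np.argsort(ev)[::-1]
    ev = ev[order]
    Gamma = fix_row_signs(U[:, order].T @ W)
    return GevdResult(eigenvalues=ev, eigenvectors=Gamma,
                      gap_warning=near_degenerate(ev, gap_rtol=gap_rtol))


def jacobi_ajd(
    stack: MatrixStack | np.ndarray,
    tol: float = 1e-10,
    max_sweeps: int = 100,
) -> AjdResult:
    """Orthogonal approximate joint diagonalization by cyclic Jacobi sweeps.

    Maximizes sum_j sum_i (u_i' a_j M_j u_i)^2 over orthogonal U; weights
    are applied by scaling each matrix by its a_j up front.  Each pairwise
    (i, k) subproblem has a closed-form optimal rotation angle (principal
    eigenvector of the 2x2 quadratic form built from the diagonal
    difference and twice the off-diagonal of every matrix).  Stops when the
    largest rotation angle in a sweep drops below ``tol``.
    """
    if not isinstance(stack, MatrixStack):
        stack = MatrixStack(np.asarray(stack, dtype=float))
    M = stack.weighted().copy()
    m, p, _ = M.shape
    U = np.eye(p)
    if p == 1:
        return AjdResult(U, ajd_objective(U, M), 0, True,
                         criterion_per_component=np.array([M[:, 0, 0] @ M[:, 0, 0]]))
    sweeps = 0
    converged = False
    for sweep in range(max_sweeps):
        max_angle = 0.0
        for i in range(p - 1):
            for k in range(i + 1, p):
                h1 = M[:, i, i] - M[:, k, k]
                h2 = M[:, i, k] + M[:, k, i]
                g11 = h1 @ h1
                g12 = h1 @ h2
                g22 = h2 @ h2
                # principal eigenvector (cos 2t, sin 2t) of [[g11,g12],[g12,g22]]
                psi = 0.5 * np.arctan2(2.0 * g12, g11 - g22)
                v0, v1 = np.cos(psi), np.sin(psi)
                if v0 < 0:  # inner rotation |theta| <= pi/4
                    v0, v1 = -v0, -v1
                c = np.sqrt(0.5 * (1.0 + v0))
                s = v1 / (2.0 * c)
                if abs(s) <= tol:
                    continue
                max_angle = max(max_angle, abs(np.arcsin(np.clip(s, -1, 1))))
                # rotate rows and columns i, k of every matrix
                Mi, Mk = M[:, i, :].copy(), M[:, k, :].copy()
                M[:, i, :] = c * Mi + s * Mk
                M[:, k, :] = -s * Mi + c * Mk
                Mi, Mk = M[:, :, i].copy(), M[:, :, k].copy()
                M[:, :, i] = c * Mi + s * Mk
                M[:, :, k] = -s * Mi + c * Mk
                Ui, Uk = U[i].copy(), U[k].copy()
                U[i] = c * Ui + s * Uk
                U[k] = -s * Ui + c * Uk
        sweeps = sweep + 1
        if max_angle < tol:
            converged = True
            break
    diag = np.einsum("mii->mi", M)
    per_comp = np.sum(diag**2, axis=0)
    return AjdResult(rotation=U, objective=float(per_comp.sum()), sweeps=sweeps,
                     converged=converged, criterion_per_component=per_comp)


# ---------------------------------------------------------------------------
# vSOBI criterion: nonquadratic lagged correlations.

_CONTRASTS = {
    "square": (lambda y: y**2, lambda y: 2.0 * y),
    "logcosh": (lambda y: np.log(np.cosh(y)), np.tanh),
}


def maximize_nonquadratic(
    xst: WhitenedSeries,
    lags: LagSet | list,
    G: str = "square",
    n_restarts: int = 5,
    max_iter: int = 1000,
    tol: float = 1e-6,
    seed: int | None = None,
) -> AjdResult:
    """Maximize the vSOBI contrast over the orthogonal group.

    The criterion is, summed over lags tau and components i,

        ( E[G(u_i'x_t) G(u_i'x_{t+tau})] - E[G(u_i'x_t)]^2 )^2 ,

    with G either y^2 or log cosh y.  The maximizer is found by a
    fixed-point iteration: the matrix of row gradients is orthogonalized
    symmetrically (polar factor) to give the next iterate.  The best of
    ``n_restarts`` random orthogonal starts plus the identity start is
    returned.  Expectations use only valid timestamp pairs, as for the
    autocovariances.  Non-convergence in every restart is flagged on the
    result, not raised.
    """
    if G not in _CONTRASTS:
        raise ValueError(f"G must be one of {sorted(_CONTRASTS)}, got {G!r}")
    gfun, gprime = _CONTRASTS[G]
    if not isinstance(lags, LagSet):
        lags = LagSet(lags)
    X, pos = xst.values, xst.positions
    n, p = X.shape
    pairs = {tau: _lag_pairs(pos, tau) for tau in lags}
    for tau, (a, b) in pairs.items():
        if len(a) < p + 1:
            raise ValueError(f"too few valid pairs at lag {tau}")

    def crit_and_grad(U):
        Y = X @ U.T                     # (n, p) projections
        GY = gfun(Y)
        gY = gprime(Y)
        m = GY.mean(axis=0)             # E[G(u_i'x_t)] per component
        Eg_x = (gY.T @ X) / n           # E[g(u_i'x_t) x_t'] rows
        crit = 0.0
        grad = np.zeros((p, p))
        for tau in lags:
            a, b = pairs[tau]
            npair = len(a)
            c = (GY[a] * GY[b]).mean(axis=0) - m**2
            crit += float(np.sum(c**2))
            d1 = ((gY[a] * GY[b]).T @ X[a]) / npair
            d2 = ((GY[a] * gY[b]).T @ X[b]) / npair
            dc = d1 + d2 - 2.0 * m[:, None] * Eg_x
            grad += 2.0 * c[:, None] * dc
        return crit, grad

    def polar(Mat):
        Uu, _, Vt = np.linalg.svd(Mat)
        return Uu @ Vt

    rng = np.random.default_rng(seed)
    starts = [np.eye(p)]
    for _ in range(n_restarts):
        Q, R = np.linalg.qr(rng.standard_normal((p, p)))
        starts.append(Q * np.sign(np.diag(R))[None, :])

    best = None
    for U0 in starts:
        U = U0
        converged = False
        iters = 0
        for it in range(max_iter):
            iters = it + 1
            _, grad = crit_and_grad(U)
            if not np.all(np.isfinite(grad)) or np.linalg.norm(grad) < 1e-14:
                break
            U_new = polar(grad)
            D = U_new @ U.T
            diff = np.linalg.norm(np.abs(D) - np.eye(p))
            U = U_new
            if diff < tol:
                converged = True
                break
        crit, _ = crit_and_grad(U)
        cand = (crit, U, converged, iters)
        if best is None or crit > best[0]:
            best = cand
    crit, U, converged, iters = best
    # per-component contribution at the optimum
    Y = U @ X.T
    GY = gfun(Y.T)
    m = GY.mean(axis=0)
    per_comp = np.zeros(p)
    for tau in lags:
        a, b = pairs[tau]
        c = (GY[a] * GY[b]).mean(axis=0) - m**2
        per_comp += c**2
    return AjdResult(rotation=U, objective=float(crit), sweeps=iters,
                     converged=converged, criterion_per_component=per_comp)
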