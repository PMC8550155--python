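"""Performance evaluation and synthetic latent-process generators.

The minimum distance (MD) index quantifies how close an estimated
unmixing matrix comes to inverting the true mixing matrix, modulo the
model indeterminacies (sign, order, and scale of the components):

    MD(G, Omega) = (p-1)^{-1/2} inf_C || C G Omega - I ||_F,

minimized over matrices C having exactly one nonzero element in each row
and column.  Zero means perfect separation; values approach one when the
estimate carries no information.

The generators emulate three latent scenarios on the ilr scale:

* LP  — all components are stationary linear (ARMA) processes,
* SV  — all components are stochastic-volatility processes (GARCH(1,1)
  or a log-AR(1) volatility recursion),
* MIX — half linear, half stochastic volatility,

with Gaussian or (heavier-tailed, unit-variance) logistic innovations.
Latent sources are mixed in ilr space and mapped back to strictly
positive compositions, so a study run exercises the full pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.signal import lfilter

from .coda import (
    CoordinateSeries,
    ilr_inverse,
    ilr_transform,
    make_pivot_contrast_matrix,
)
from . import methods as _methods

__all__ = [
    "MdResult",
    "ScenarioSpec",
    "md_index",
    "generate_lp_source",
    "generate_sv_source",
    "generate_ns_source",
    "generate_sources",
    "generate_scenario",
    "default_roster",
    "run_study",
    "replicate_seed",
    "default_lp_params",
    "default_sv_params",
]


# ---------------------------------------------------------------------------
# Minimum distance index

@dataclass
class MdResult:
    value: float
    permutation: np.ndarray  # permutation[i] = row of G@Omega matched to i
    scales: np.ndarray       # optimal nonzero scale per matched row

    def __float__(self):
        return self.value


def md_index(G_hat: np.ndarray, Omega: np.ndarray) -> MdResult:
    """Minimum distance index between an unmixing estimate and the truth.

    The inner minimization is solved exactly: for a candidate matching of
    row k of D = G_hat @ Omega to identity row i, the optimal scale is
    D[k,i]/||D_k||^2 with cost 1 - D[k,i]^2/||D_k||^2; the optimal
    matching is then a linear assignment problem.
    """
    G = np.asarray(G_hat, dtype=float)
    Om = np.asarray(Omega, dtype=float)
    if G.shape != Om.shape or G.ndim != 2 or G.shape[0] != G.shape[1]:
        raise ValueError("G_hat and Omega must be square matrices of equal size")
    p = G.shape[0]
    D = G @ Om
    row_norm2 = np.sum(D**2, axis=1)
    if np.any(row_norm2 <= 0) or not np.all(np.isfinite(D)):
        raise ValueError("singular or non-finite unmixing/mixing product")
    cost = 1.0 - D**2 / row_norm2[:, None]   # cost[k, i]
    rows, cols = linear_sum_assignment(cost)
    total = float(cost[rows, cols].sum())
    perm = np.empty(p, dtype=int)
    perm[cols] = rows
    scales = D[perm, np.arange(p)] / row_norm2[perm]
    value = float(np.sqrt(max(total, 0.0) / (p - 1)))
    return MdResult(value=value, permutation=perm, scales=scales)


# ---------------------------------------------------------------------------
# Innovations and univariate process generators

def _innovations(rng: np.random.Generator, kind: str, size: int) -> np.ndarray:
    if kind == "gaussian":
        return rng.standard_normal(size)
    if kind == "logistic":
        # scale sqrt(3)/pi gives unit variance; excess kurtosis 1.2
        return rng.logistic(scale=np.sqrt(3.0) / np.pi, size=size)
    raise ValueError(f"unknown innovation distribution {kind!r}")


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def generate_lp_source(
    params: dict,
    T: int,
    seed=None,
    innovations: str = "gaussian",
    burn: int | None = None,
) -> np.ndarray:
    """Simulate a stationary ARMA process, standardized to unit sample variance.

    ``params`` holds ``ar`` (phi coefficients) and ``ma`` (theta
    coefficients); both default to empty (white noise).  Non-stationary AR
    coefficients raise.
    """
    rng = _as_rng(seed)
    ar = np.asarray(params.get("ar", []), dtype=float)
    ma = np.asarray(params.get("ma", []), dtype=float)
    if ar.size:
        # stationarity: roots of 1 - phi_1 z - ... - phi_q z^q outside unit circle
        roots = np.roots(np.r_[-ar[::-1], 1.0])
        if np.any(np.abs(roots) <= 1.0 + 1e-10):
            raise ValueError(f"non-stationary AR coefficients {ar.tolist()}")
    order = max(len(ar), len(ma))
    if burn is None:
        burn = 10 * (order + 1) + 100
    eps = _innovations(rng, innovations, T + burn)
    y = lfilter(np.r_[1.0, ma], np.r_[1.0, -ar], eps)[burn:]
    sd = y.std()
    return y / sd if sd > 0 else y


def generate_sv_source(
    params: dict,
    T: int,
    seed=None,
    innovations: str = "gaussian",
    burn: int = 500,
) -> np.ndarray:
    """Simulate a stochastic-volatility process, standardized to unit variance.

    ``params["family"]`` selects the recursion:

    * ``"garch"`` (default): GARCH(1,1) with parameters ``a`` (ARCH) and
      ``b`` (GARCH), ``omega = 1 - a - b`` so the unconditional variance is
      one; requires a + b < 1.
    * ``"logvol"``: log-variance AR(1), h_t = mu + phi (h_{t-1} - mu) +
      sigma xi_t, observation z_t = exp(h_t / 2) eta_t; requires |phi| < 1.

    Levels are serially uncorrelated; squares are positively autocorrelated.
    """
    rng = _as_rng(seed)
    family = params.get("family", "garch")
    eta = _innovations(rng, innovations, T + burn)
    if family == "garch":
        a = float(params.get("a", 0.1))
        b = float(params.get("b", 0.85))
        if a < 0 or b < 0 or a + b >= 1.0:
            raise ValueError(f"explosive GARCH parameters a={a}, b={b}")
        omega = float(params.get("omega", 1.0 - a - b))
        y = np.empty(T + burn)
        sig2 = omega / max(1.0 - a - b, 1e-12)
        for t in range(T + burn):
            y[t] = np.sqrt(sig2) * eta[t]
            sig2 = omega + a * y[t] ** 2 + b * sig2
        y = y[burn:]
    elif family == "logvol":
        mu = float(params.get("mu", -0.5))
        phi = float(params.get("phi", 0.95))
        sigma = float(params.get("sigma", 0.2))
        if abs(phi) >= 1.0:
            raise ValueError(f"explosive log-volatility phi={phi}")
        xi = rng.standard_normal(T + burn)
        h = np.empty(T + burn)
        h[0] = mu
        for t in range(1, T + burn):
            h[t] = mu + phi * (h[t - 1] - mu) + sigma * xi[t]
        y = (np.exp(h / 2.0) * eta)[burn:]
    else:
        raise ValueError(f"unknown stochastic-volatility family {family!r}")
    sd = y.std()
    return y / sd if sd > 0 else y


def generate_ns_source(
    T: int,
    seed=None,
    n_blocks: int = 8,
    ar: float = 0.0,
    innovations: str = "gaussian",
    log_sd_range: tuple = (-1.0, 1.0),
) -> np.ndarray:
    """Simulate a nonstationary (variance-modulated) source.

    An AR(1) base process (white noise for ``ar=0``) is multiplied by a
    blockwise-constant standard-deviation profile drawn log-uniformly, then
    standardized to unit overall sample variance.  Distinct random profiles
    across sources make them separable by the NSS estimators.
    """
    rng = _as_rng(seed)
    base = generate_lp_source({"ar": [ar] if ar else []}, T, rng,
                              innovations=innovations)
    edges = np.linspace(0, T, n_blocks + 1).astype(int)
    profile = np.empty(T)
    sds = np.exp(rng.uniform(*log_sd_range, size=n_blocks))
    for b in range(n_blocks):
        profile[edges[b]:edges[b + 1]] = sds[b]
    y = base * profile
    return y / y.std()


# ---------------------------------------------------------------------------
# Scenario generation

def default_lp_params(m: int) -> list:
    """ARMA parameter sets for m linear-process sources: AR(1) coefficients
    evenly spread over [0.2, 0.9], with an MA(1) theta = 0.3 added on
    even-indexed sources so all autocorrelation functions are distinct."""
    phis = np.linspace(0.2, 0.9, m)
    out = []
    for i, phi in enumerate(phis):
        out.append({"ar": [float(phi)], "ma": [0.3] if i % 2 == 0 else []})
    return out


def default_sv_params(m: int, family: str = "garch") -> list:
    """GARCH(1,1) parameter sets for m stochastic-volatility sources:
    (a, b) pairs spread over a in [0.05, 0.2], b in [0.7, 0.9] with
    a + b <= 0.97, giving distinct fourth-order structure."""
    a = np.linspace(0.05, 0.2, m)
    b = np.linspace(0.9, 0.7, m)
    return [{"family": family, "a": float(ai), "b": float(bi)}
            for ai, bi in zip(a, b)]


_SETTINGS = {1: ("gaussian", 4), 2: ("logistic", 4), 3: ("gaussian", 8)}


@dataclass
class ScenarioSpec:
    """One cell of the simulation design.

    ``scenario`` is LP, SV or MIX; ``setting`` 1 (Gaussian, p=4), 2
    (logistic innovations, p=4) or 3 (Gaussian, p=8); ``p`` is the number
    of latent ilr components (the composition then has p+1 parts); MIX
    uses p/2 linear + p/2 stochastic-volatility sources.
    """

    scenario: str
    setting: int = 1
    T: int = 1000
    seed: object = None
    p: int | None = None
    innovations: str | None = None
    lp_params: list | None = None
    sv_params: list | None = None
    sv_family: str = "garch"

    def __post_init__(self):
        self.scenario = self.scenario.upper()
        if self.scenario not in ("LP", "SV", "MIX"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.setting not in _SETTINGS:
            raise ValueError(f"setting must be 1, 2 or 3, got {self.setting}")
        innov, p = _SETTINGS[self.setting]
        if self.innovations is None:
            self.innovations = innov
        if self.p is None:
            self.p = p
        if self.scenario == "MIX" and self.p % 2:
            raise ValueError("MIX requires an even number of components")
        n_lp = self.p if self.scenario == "LP" else (
            self.p // 2 if self.scenario == "MIX" else 0)
        n_sv = self.p - n_lp
        if self.lp_params is None:
            self.lp_params = default_lp_params(n_lp) if n_lp else []
        if self.sv_params is None:
            self.sv_params = default_sv_params(n_sv, self.sv_family) if n_sv else []


def generate_sources(spec: ScenarioSpec, seed=None) -> np.ndarray:
    """Latent source matrix (T x p): LP sources first, then SV sources."""
    rng = _as_rng(spec.seed if seed is None else seed)
    cols = []
    for par in spec.lp_params:
        cols.append(generate_lp_source(par, spec.T, rng,
                                       innovations=spec.innovations))
    for par in spec.sv_params:
        cols.append(generate_sv_source(par, spec.T, rng,
                                       innovations=spec.innovations))
    return np.column_stack(cols)


def generate_scenario(spec: ScenarioSpec, Omega: np.ndarray | None = None,
                      seed=None):
    """Generate a compositional time series from latent ilr sources.

    Sources are mixed by ``Omega`` (identity by default) in ilr space and
    mapped through the inverse pivot-ilr transform to a strictly positive,
    closed composition with p+1 parts.  Returns (composition, sources,
    Omega).
    """
    Z = generate_sources(spec, seed=seed)
    p = spec.p
    Omega = np.eye(p) if Omega is None else np.asarray(Omega, dtype=float)
    if Omega.shape != (p, p):
        raise ValueError(f"Omega must be {p}x{p}")
    Y = Z @ Omega.T
    basis = make_pivot_contrast_matrix(p + 1)
    coords = CoordinateSeries(np.arange(spec.T), Y, space="ilr", basis=basis)
    comp = ilr_inverse(coords)
    return comp, Z, Omega


# ---------------------------------------------------------------------------
# Study harness

def default_roster() -> dict:
    """The method roster of the comparison study.

    SOBI uses lags {1..6}, gFOBI lags {0..6}, NSS-JD K=6, and the three
    combined estimators use K=6 with both lag sets {0..6} and the equal /
    kurtosis / maxnorm weight schemes (COMB-1/2/3).
    """
    L1 = range(0, 7)
    return {
        "SOBI": lambda X, pos, s: _methods.sobi(X, range(1, 7), positions=pos),
        "gFOBI": lambda X, pos, s: _methods.gfobi(X, range(0, 7), positions=pos),
        "NSS.JD": lambda X, pos, s: _methods.nss_jd(X, K=6, positions=pos),
        "COMB-1": lambda X, pos, s: _methods.nss_sobi_gfobi(
            X, K=6, lags1=L1, lags2=L1, scheme="equal", positions=pos),
        "COMB-2": lambda X, pos, s: _methods.nss_sobi_gfobi(
            X, K=6, lags1=L1, lags2=L1, scheme="kurtosis", positions=pos),
        "COMB-3": lambda X, pos, s: _methods.nss_sobi_gfobi(
            X, K=6, lags1=L1, lags2=L1, scheme="maxnorm", positions=pos),
    }


def replicate_seed(master_seed: int, cell_index: int, rep: int) -> np.random.SeedSequence:
    """Counter-based per-replicate seed derivation (parallel-safe,
    recorded in provenance as (master, cell, rep))."""
    return np.random.SeedSequence([int(master_seed), int(cell_index), int(rep)])


def run_study(
    methods: dict | None = None,
    cells: Sequence[tuple] | None = None,
    reps: int = 200,
    seed: int = 0,
    progress: Callable[[str], None] | None = None,
) -> pd.DataFrame:
    """Run the MD-index comparison study at configurable scale.

    ``cells`` is a sequence of (scenario, setting, T) triples; ``methods``
    maps names to callables ``f(X, positions, seed) -> BssResult`` acting
    on the ilr coordinate matrix.  Each replicate draws fresh sources with
    a counter-derived seed, maps them through composition space and back
    (exercising the full representation chain), runs every method on the
    same data and records MD(unmixing, Omega).  Returns one row per
    (method, cell) with the mean MD and its Monte-Carlo standard error.
    """
    if methods is None:
        methods = default_roster()
    if cells is None:
        cells = [(sc, 1, T) for sc in ("LP", "SV", "MIX")
                 for T in (1000, 2000, 10000)]
    out = []
    for ci, (scenario, setting, T) in enumerate(cells):
        md_vals = {name: np.empty(reps) for name in methods}
        for r in range(reps):
            ss = replicate_seed(seed, ci, r)
            spec = ScenarioSpec(scenario, setting=setting, T=int(T), seed=ss)
            comp, Z, Omega = generate_scenario(spec)
            coords = ilr_transform(comp)
            X = coords.values
            pos = np.arange(len(X))
            mseed = int(ss.generate_state(1)[0] % (2**31))
            for name, fn in methods.items():
                res = fn(X, pos, mseed)
                md_vals[name][r] = md_index(res.unmixing, Omega).value
        for name in methods:
            v = md_vals[name]
            out.append({
                "method": name, "scenario": scenario, "setting": setting,
                "T": int(T), "mean_md": float(v.mean()),
                "se_md": float(v.std(ddof=1) / np.sqrt(reps)) if reps > 1 else 0.0,
                "reps": reps, "seed": seed,
            })
        if progress is not None:
            progress(f"cell {scenario}/setting {setting}/T={T} done")
    return pd.DataFrame(out)


def pivot_table(results: pd.DataFrame) -> pd.DataFrame:
    """Arrange study results as methods x (scenario, T), mirroring the
    usual presentation of MD comparison tables."""
    return results.pivot_table(index="method", columns=["scenario", "T"],
                               values="mean_md")
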