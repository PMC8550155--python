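"""End-to-end decomposition of compositional time series.

The recipe: (1) express the composition series in ilr coordinates,
(2) optionally reduce dimension by covariance PCA when the coordinates
are nearly singular, (3) run a blind source separation method on the
(reduced) coordinates, and (4) interpret components via clr loadings or
map selected components back to the simplex.

The user-facing surface is a model/results pair:
:class:`CompositionalBSS` holds the data and configuration, its
:meth:`~CompositionalBSS.fit` returns a :class:`CtsDecomposition` with
the sources, the unmixing matrix, clr loadings, diagnostics and a
``summary()``.  The functional :func:`decompose` wrapper does both in one
call.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from . import methods as _methods
from .coda import (
    CompositionSeries,
    ContrastMatrix,
    CoordinateSeries,
    ilr_inverse,
    ilr_transform,
    make_pivot_contrast_matrix,
    multiplicative_replacement,
)
from .methods import BssResult
from .moments import grid_positions

__all__ = [
    "CompositionalBSS",
    "CtsDecomposition",
    "PcaReduction",
    "decompose",
    "pca_reduce",
    "METHODS",
]

METHODS = {
    "amuse": _methods.amuse,
    "sobi": _methods.sobi,
    "gfobi": _methods.gfobi,
    "gjade": _methods.gjade,
    "vsobi": _methods.vsobi,
    "nss_sd": _methods.nss_sd,
    "nss_jd": _methods.nss_jd,
    "nss_td_jd": _methods.nss_td_jd,
    "nss_sobi_gfobi": _methods.nss_sobi_gfobi,
}


class PcaReduction(NamedTuple):
    scores: np.ndarray       # T x q
    loadings: np.ndarray     # d x q, orthonormal columns
    mean: np.ndarray         # d
    explained: np.ndarray    # descending fractions, all d of them


def pca_reduce(y, threshold: float = 0.999) -> PcaReduction:
    """Covariance PCA on ilr coordinates, keeping the smallest number of
    components whose cumulative explained variance reaches ``threshold``.

    No per-coordinate scaling is applied: ilr coordinates share a unit.
    ``threshold=1`` keeps the full rank.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (0, 1]")
    Y = y.values if isinstance(y, CoordinateSeries) else np.atleast_2d(
        np.asarray(y, dtype=float))
    mean = Y.mean(axis=0)
    Yc = Y - mean
    cov = (Yc.T @ Yc) / len(Yc)
    lam, E = np.linalg.eigh(cov)
    lam, E = lam[::-1], E[:, ::-1]
    lam = np.clip(lam, 0.0, None)
    frac = lam / lam.sum() if lam.sum() > 0 else np.full_like(lam, 1.0 / len(lam))
    cum = np.cumsum(frac)
    q = int(np.searchsorted(cum, threshold - 1e-12) + 1)
    q = min(q, len(lam))
    W = E[:, :q]
    return PcaReduction(scores=Yc @ W, loadings=W, mean=mean, explained=frac)


@dataclass
class CtsDecomposition:
    """Results of a compositional BSS decomposition.

    ``clr_loadings`` (q x p) maps sources to clr space: row i shows the
    weight each original part receives in source i, and rows sum to zero.
    """

    bss: BssResult
    basis: ContrastMatrix
    timestamps: np.ndarray
    pca: PcaReduction | None = None
    provenance: dict | None = None

    @property
    def unmixing(self) -> np.ndarray:
        return self.bss.unmixing

    @property
    def n_components(self) -> int:
        return self.bss.n_components

    @property
    def clr_loadings(self) -> np.ndarray:
        W = self.pca.loadings if self.pca is not None else np.eye(self.basis.p - 1)
        return self.bss.unmixing @ W.T @ self.basis.values.T

    @property
    def sources(self) -> pd.DataFrame:
        cols = [f"z{i + 1}" for i in range(self.n_components)]
        return pd.DataFrame(self.bss.sources,
                            index=pd.Index(self.timestamps, name="time"),
                            columns=cols)

    def explained_variance(self) -> np.ndarray | None:
        return None if self.pca is None else self.pca.explained

    def reconstruct(
        self,
        components: Sequence[int] | None = None,
        sources: np.ndarray | None = None,
        timestamps=None,
    ) -> CompositionSeries:
        """Map sources back to closed compositions.

        ``components`` selects a subset (all by default, zero-based);
        alternatively ``sources`` supplies replacement source values (e.g.
        model predictions) of shape (T', q).  The chain inverts each fitted
        step: sources -> (PCA scores) -> ilr -> composition.
        """
        if sources is None:
            Z = self.bss.sources.copy()
            if components is not None:
                keep = np.zeros(self.n_components, dtype=bool)
                keep[list(components)] = True
                Z[:, ~keep] = 0.0
            ts = self.timestamps
        else:
            Z = np.atleast_2d(np.asarray(sources, dtype=float))
            if Z.shape[1] != self.n_components:
                raise ValueError(
                    f"sources must have {self.n_components} columns")
            ts = np.arange(len(Z)) if timestamps is None else timestamps
        S = self.bss.center + Z @ np.linalg.inv(self.bss.unmixing).T
        if self.pca is not None:
            ilr_vals = self.pca.mean + S @ self.pca.loadings.T
        else:
            ilr_vals = S
        coords = CoordinateSeries(ts, ilr_vals, space="ilr", basis=self.basis)
        return ilr_inverse(coords)

    def summary(self) -> str:
        b = self.bss
        lines = []
        title = "Compositional BSS decomposition"
        lines.append(title)
        lines.append("=" * len(title))
        lines.append(f"Method:          {b.method}")
        lines.append(f"Observations:    {len(b.sources)}")
        lines.append(f"Components:      {b.n_components}")
        lines.append(f"Parts:           {self.basis.p} (basis: {self.basis.kind})")
        if self.pca is not None:
            q = self.pca.loadings.shape[1]
            ev = float(np.sum(self.pca.explained[:q]))
            lines.append(f"PCA reduction:   {self.basis.p - 1} -> {q} "
                         f"coordinates ({100 * ev:.2f}% variance)")
        for key in ("lags", "lags1", "lags2", "K", "scheme", "tau", "G"):
            if key in b.params:
                lines.append(f"  {key:<14} {b.params[key]}")
        diag = b.diagnostics
        if "objective" in diag:
            lines.append(f"Objective:       {diag['objective']:.6g}")
        if diag.get("gap_warning"):
            lines.append("Warning: nearly tied separation statistics; "
                         "component identification may be weak")
        if "converged" in diag and not diag["converged"]:
            lines.append("Warning: optimizer did not converge")
        lines.append("")
        lines.append("clr loadings (sources x parts):")
        L = pd.DataFrame(
            self.clr_loadings,
            index=[f"z{i + 1}" for i in range(self.n_components)],
            columns=self.provenance.get("parts") if self.provenance else None,
        )
        lines.append(L.round(4).to_string())
        return "\n".join(lines)

    def save(self, outdir) -> None:
        """Write sources.csv, clr_loadings.csv, unmixing.csv, provenance.json."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.sources.to_csv(out / "sources.csv")
        parts = self.provenance.get("parts") if self.provenance else None
        pd.DataFrame(self.clr_loadings, columns=parts,
                     index=[f"z{i + 1}" for i in range(self.n_components)]
                     ).to_csv(out / "clr_loadings.csv")
        pd.DataFrame(self.unmixing).to_csv(out / "unmixing.csv", index=False)
        prov = dict(self.provenance or {})
        (out / "provenance.json").write_text(json.dumps(prov, default=str, indent=2))

    def plot_sources(self, ax=None):
        """Line plot of the recovered sources over time."""
        import matplotlib.pyplot as plt

        df = self.sources
        q = df.shape[1]
        if ax is None:
            _, axes = plt.subplots(q, 1, sharex=True, figsize=(8, 1.8 * q))
        else:
            axes = ax
        axes = np.atleast_1d(axes)
        for i, col in enumerate(df.columns):
            axes[i].plot(df.index, df[col], lw=0.6)
            axes[i].set_ylabel(col)
        axes[-1].set_xlabel("time")
        return axes

    def plot_loadings(self, ax=None):
        """Line plot of clr loadings across parts, one line per source."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 4))
        L = self.clr_loadings
        parts = (self.provenance or {}).get("parts") or [
            str(i + 1) for i in range(L.shape[1])]
        for i in range(L.shape[0]):
            ax.plot(range(L.shape[1]), L[i], label=f"z{i + 1}")
        ax.set_xticks(range(len(parts)), parts, rotation=90, fontsize=7)
        ax.axhline(0.0, color="grey", lw=0.5)
        ax.set_ylabel("clr loading")
        ax.legend()
        return ax


class CompositionalBSS:
    """Blind source separation model for a compositional time series.

    Parameters
    ----------
    data : CompositionSeries or DataFrame
        Strictly positive parts; a DataFrame must carry timestamps in its
        index (or be passed through :meth:`from_dataframe`).
    method : str
        One of ``amuse, sobi, gfobi, gjade, vsobi, nss_sd, nss_jd,
        nss_td_jd, nss_sobi_gfobi`` (hyphens accepted).
    basis : ContrastMatrix, optional
        ilr basis; defaults to pivot coordinates.  The choice only
        permutes/flips the recovered sources.
    pca : float or None
        Explained-variance threshold in (0, 1] for PCA pre-reduction of
        the ilr coordinates; ``None`` (default) disables it.
    grid : str, Timedelta or int, optional
        Declared sampling step used to place timestamps on the regular
        grid; required for datetime timestamps.  Lag statistics then pair
        only observations exactly tau grid steps apart.
    replace_zeros : bool
        Apply multiplicative replacement to nonpositive entries instead of
        raising (logged loudly).
    **method_kwargs
        Passed to the chosen estimator (lags, K, scheme, tau, G, ...).
    """

    def __init__(self, data, method: str = "nss_sobi_gfobi",
                 basis: ContrastMatrix | None = None, pca: float | None = None,
                 grid=None, replace_zeros: bool = False, **method_kwargs):
        if isinstance(data, pd.DataFrame):
            if replace_zeros:
                data = multiplicative_replacement(
                    data.index.to_numpy(), data.to_numpy(dtype=float),
                    list(data.columns))
            else:
                data = CompositionSeries.from_frame(data)
        if not isinstance(data, CompositionSeries):
            raise TypeError("data must be a CompositionSeries or DataFrame")
        name = method.replace("-", "_").lower()
        if name not in METHODS:
            raise ValueError(
                f"unknown method {method!r}; choose from {sorted(METHODS)}")
        self.data = data
        self.method = name
        self.basis = basis or make_pivot_contrast_matrix(data.n_parts)
        if self.basis.p != data.n_parts:
            raise ValueError("basis dimension does not match the data")
        self.pca_threshold = pca
        self.grid = grid
        self.method_kwargs = dict(method_kwargs)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, timestamp_col: str | None = None,
                       **kwargs) -> "CompositionalBSS":
        if timestamp_col is not None:
            df = df.set_index(timestamp_col)
        return cls(df, **kwargs)

    def fit(self, seed: int | None = None) -> CtsDecomposition:
        """Run the ilr -> (PCA) -> BSS chain and package the results."""
        coords = ilr_transform(self.data, self.basis)
        positions = grid_positions(self.data.timestamps, self.grid)
        pca = None
        if self.pca_threshold is not None:
            pca = pca_reduce(coords, self.pca_threshold)
            X = pca.scores
        else:
            X = coords.values
        fn = METHODS[self.method]
        kwargs = dict(self.method_kwargs)
        if self.method == "vsobi":
            kwargs.setdefault("seed", seed)
        try:
            bss = fn(X, positions=positions, **kwargs)
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(
                f"{err} — the ilr covariance is nearly singular; "
                "set pca=<threshold> to reduce the dimension first"
            ) from None
        prov = {
            "method": self.method,
            "method_kwargs": {k: (list(v) if isinstance(v, range) else v)
                              for k, v in self.method_kwargs.items()},
            "pca_threshold": self.pca_threshold,
            "basis_kind": self.basis.kind,
            "grid": str(self.grid) if self.grid is not None else None,
            "seed": seed,
            "parts": list(self.data.parts),
            "n_obs": self.data.n_obs,
        }
        return CtsDecomposition(bss=bss, basis=self.basis,
                                timestamps=self.data.timestamps,
                                pca=pca, provenance=prov)


def decompose(x, method: str = "nss_sobi_gfobi", pca: float | None = None,
              basis: ContrastMatrix | None = None, grid=None,
              seed: int | None = None, **method_kwargs) -> CtsDecomposition:
    """One-call decomposition: build a :class:`CompositionalBSS` and fit it."""
    model = CompositionalBSS(x, method=method, basis=basis, pca=pca,
                             grid=grid, **method_kwargs)
    return model.fit(seed=seed)
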