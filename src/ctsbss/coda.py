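"""Compositional geometry: clr coefficients, pivot ilr coordinates and their inverses.

A composition carries only relative information; its sample space is the
simplex.  The centred log-ratio (clr) transform maps a strictly positive
p-part composition to the zero-sum hyperplane of R^p, and isometric
log-ratio (ilr) coordinates express the same information in an orthonormal
(p-1)-dimensional basis of that hyperplane.  The two are linked through a
p x (p-1) contrast matrix V with orthonormal, zero-sum columns:

    clr(x) = V @ ilr(x)      and      ilr(x) = V.T @ clr(x).

The pivot basis used by default isolates, in its first coordinate, all
relative information about the first part.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CompositionSeries",
    "ContrastMatrix",
    "CoordinateSeries",
    "closure",
    "clr_transform",
    "ilr_transform",
    "ilr_inverse",
    "make_pivot_contrast_matrix",
    "multiplicative_replacement",
    "read_composition_csv",
    "write_composition_csv",
    "write_coordinate_csv",
    "read_coordinate_csv",
]

_ORTHO_TOL = 1e-10


def _as_timestamps(timestamps: Sequence) -> np.ndarray:
    ts = np.asarray(timestamps)
    if ts.ndim != 1:
        raise ValueError("timestamps must be one-dimensional")
    if np.issubdtype(ts.dtype, np.datetime64):
        diffs = np.diff(ts.astype("datetime64[ns]").astype(np.int64))
    else:
        ts = ts.astype(np.int64)
        diffs = np.diff(ts)
    if len(ts) > 1 and not np.all(diffs > 0):
        raise ValueError("timestamps must be strictly increasing")
    return ts


@dataclass
class CompositionSeries:
    """A timestamped T x p matrix of strictly positive parts.

    Timestamps are integers or datetimes, strictly increasing; gaps are
    allowed and are respected downstream by the lag-pairing logic.
    """

    timestamps: np.ndarray
    values: np.ndarray
    parts: Sequence[str] = None

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.timestamps = _as_timestamps(self.timestamps)
        if self.values.shape[0] != len(self.timestamps):
            raise ValueError(
                f"{self.values.shape[0]} rows but {len(self.timestamps)} timestamps"
            )
        if self.parts is None:
            self.parts = [f"part_{i + 1}" for i in range(self.values.shape[1])]
        self.parts = list(self.parts)
        if len(self.parts) != self.values.shape[1]:
            raise ValueError("number of part labels does not match columns")
        bad = np.argwhere(~(self.values > 0))
        if bad.size:
            t, i = bad[0]
            raise ValueError(
                f"composition entries must be strictly positive; "
                f"found {self.values[t, i]} at time {self.timestamps[t]}, "
                f"part {self.parts[i]!r}"
            )

    @property
    def n_parts(self) -> int:
        return self.values.shape[1]

    @property
    def n_obs(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.timestamps, name="time"),
                            columns=self.parts)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CompositionSeries":
        return cls(df.index.to_numpy(), df.to_numpy(dtype=float), list(df.columns))


@dataclass
class ContrastMatrix:
    """p x (p-1) matrix with orthonormal, zero-sum columns linking clr and ilr."""

    values: np.ndarray
    kind: str = "custom"

    def __post_init__(self):
        V = np.asarray(self.values, dtype=float)
        if V.ndim != 2 or V.shape[1] != V.shape[0] - 1:
            raise ValueError(f"contrast matrix must be p x (p-1), got {V.shape}")
        if not np.allclose(V.T @ V, np.eye(V.shape[1]), atol=_ORTHO_TOL):
            raise ValueError("contrast matrix columns are not orthonormal")
        if not np.allclose(V.sum(axis=0), 0.0, atol=_ORTHO_TOL):
            raise ValueError("contrast matrix columns must each sum to zero")
        self.values = V

    @property
    def p(self) -> int:
        return self.values.shape[0]


@dataclass
class CoordinateSeries:
    """Real-coordinate representation of a composition series (ilr or clr)."""

    timestamps: np.ndarray
    values: np.ndarray
    space: str = "ilr"
    basis: ContrastMatrix | None = None

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.timestamps = _as_timestamps(self.timestamps)
        if self.space not in ("ilr", "clr"):
            raise ValueError("space must be 'ilr' or 'clr'")
        if self.space == "clr" and not np.allclose(
            self.values.sum(axis=1), 0.0, atol=1e-8
        ):
            raise ValueError("clr rows must sum to zero")

    @property
    def n_coords(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{self.space}_{i + 1}" for i in range(self.values.shape[1])]
        return pd.DataFrame(self.values, index=pd.Index(self.timestamps, name="time"),
                            columns=cols)


def closure(v: np.ndarray) -> np.ndarray:
    """Rescale positive vectors (rows) to sum to one."""
    v = np.asarray(v, dtype=float)
    if np.any(v <= 0):
        raise ValueError("closure requires strictly positive entries")
    return v / v.sum(axis=-1, keepdims=True)


def multiplicative_replacement(
    timestamps,
    values=None,
    parts=None,
    delta: np.ndarray | float | None = None,
) -> CompositionSeries:
    """Build a CompositionSeries from a table that may contain nonpositive
    entries, replacing each by a small positive value, per part.

    Default delta is 65% of the smallest positive value observed in that
    part.  This is a pragmatic zero-handling device, applied only on
    explicit request; it is logged loudly because it changes the data.
    A DataFrame may be passed as the single first argument.
    """
    if isinstance(timestamps, pd.DataFrame) and values is None:
        df = timestamps
        timestamps, values, parts = df.index.to_numpy(), df.to_numpy(float), list(df.columns)
    vals = np.atleast_2d(np.asarray(values, dtype=float)).copy()
    mask = ~(vals > 0)
    if mask.any():
        if delta is None:
            delta = np.full(vals.shape[1], np.nan)
            for j in range(vals.shape[1]):
                pos = vals[vals[:, j] > 0, j]
                if pos.size == 0:
                    raise ValueError(f"column {j} has no positive values")
                delta[j] = 0.65 * pos.min()
        delta = np.broadcast_to(np.asarray(delta, dtype=float), (vals.shape[1],))
        warnings.warn(
            f"multiplicative replacement applied to {int(mask.sum())} "
            "nonpositive entries",
            UserWarning,
            stacklevel=2,
        )
        for j in range(vals.shape[1]):
            vals[mask[:, j], j] = delta[j]
    return CompositionSeries(timestamps, vals, parts)


def clr_transform(x: CompositionSeries) -> CoordinateSeries:
    """Centred log-ratio coefficients: ln x_i minus the mean log over parts."""
    logx = np.log(x.values)
    vals = logx - logx.mean(axis=1, keepdims=True)
    return CoordinateSeries(x.timestamps, vals, space="clr")


def make_pivot_contrast_matrix(p: int) -> ContrastMatrix:
    """Pivot-coordinate contrast matrix.

    Column j (1-based) is sqrt((p-j)/(p-j+1)) * (0,...,0, 1, -1/(p-j), ...,
    -1/(p-j)) with j-1 leading zeros, so the first ilr coordinate aggregates
    all log-ratios involving the first part.
    """
    if not isinstance(p, (int, np.integer)) or p < 2:
        raise ValueError(f"p must be an integer >= 2, got {p!r}")
    V = np.zeros((p, p - 1))
    for j in range(1, p):
        r = p - j
        V[j - 1, j - 1] = np.sqrt(r / (r + 1))
        V[j:, j - 1] = -np.sqrt(r / (r + 1)) / r
    return ContrastMatrix(V, kind="pivot")


def ilr_transform(
    x: CompositionSeries, basis: ContrastMatrix | None = None
) -> CoordinateSeries:
    """Isometric log-ratio coordinates, ilr(x) = V.T @ clr(x) per time point."""
    if basis is None:
        basis = make_pivot_contrast_matrix(x.n_parts)
    if basis.p != x.n_parts:
        raise ValueError(
            f"basis is for {basis.p} parts but series has {x.n_parts}"
        )
    clr = clr_transform(x)
    return CoordinateSeries(x.timestamps, clr.values @ basis.values,
                            space="ilr", basis=basis)


def ilr_inverse(y: CoordinateSeries) -> CompositionSeries:
    """Map ilr coordinates back to closed compositions via clr = V @ ilr."""
    if y.space != "ilr":
        raise ValueError("ilr_inverse expects an ilr CoordinateSeries")
    basis = y.basis or make_pivot_contrast_matrix(y.n_coords + 1)
    if basis.p != y.n_coords + 1:
        raise ValueError("basis dimension does not match coordinates")
    clr = y.values @ basis.values.T
    comp = closure(np.exp(clr))
    return CompositionSeries(y.timestamps, comp)


# ---------------------------------------------------------------------------
# File I/O: wide CSV/TSV, first column the timestamp.

def read_composition_csv(
    path, sep: str = ",", parse_dates: bool | None = None
) -> CompositionSeries:
    """Read a wide table: first column timestamps (ISO-8601 or integer),
    remaining columns the parts."""
    df = pd.read_csv(path, sep=sep)
    tcol = df.columns[0]
    ts = df[tcol]
    if parse_dates or (parse_dates is None and ts.dtype == object):
        ts = pd.to_datetime(ts)
    df = df.drop(columns=[tcol])
    return CompositionSeries(np.asarray(ts), df.to_numpy(dtype=float),
                             list(df.columns))


def write_composition_csv(x: CompositionSeries, path, sep: str = ",") -> None:
    x.to_frame().to_csv(path, sep=sep)


def write_coordinate_csv(y: CoordinateSeries, path, sep: str = ",") -> None:
    """Write a coordinate table; the basis kind travels in a sidecar JSON."""
    path = Path(path)
    y.to_frame().to_csv(path, sep=sep)
    meta = {"space": y.space}
    if y.basis is not None:
        meta["basis_kind"] = y.basis.kind
        meta["basis"] = y.basis.values.tolist()
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta))


def read_coordinate_csv(path, sep: str = ",") -> CoordinateSeries:
    path = Path(path)
    df = pd.read_csv(path, sep=sep, index_col=0)
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    space, basis = "ilr", None
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        space = meta.get("space", "ilr")
        if "basis" in meta:
            basis = ContrastMatrix(np.asarray(meta["basis"]),
                                   kind=meta.get("basis_kind", "custom"))
    ts = df.index.to_numpy()
    if df.index.dtype == object:
        ts = pd.to_datetime(df.index).to_numpy()
    return CoordinateSeries(ts, df.to_numpy(dtype=float), space=space, basis=basis)
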