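"""Data model for incomplete spatiotemporal series and adjacency construction.

A dataset is the triple ``(X, A, M)``: an N-series × T-step value matrix, a
nonnegative N×N adjacency over the sensors/genes, and a binary observation
mask (1 = observed).  Masked-out cells of ``X`` are stored as 0 and are never
read by the model — the input projection replaces them with a learned
missing-value token.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "SpatioTemporalSeries",
    "CompleteSeries",
    "DistanceSpec",
    "build_adjacency",
    "load_series",
    "save_series",
    "load_adjacency",
    "validate_series",
    "SeriesParseError",
]

MISSING_SENTINEL = 0.0


class SeriesParseError(ValueError):
    """Raised when a series/adjacency file cannot be parsed; names the cell."""


@dataclass
class SpatioTemporalSeries:
    """Incomplete spatiotemporal series: values, adjacency and mask."""

    X: np.ndarray                 # (N, T) float, masked cells hold the sentinel
    A: np.ndarray                 # (N, N) nonnegative weights
    M: np.ndarray                 # (N, T) in {0, 1}
    node_ids: list[str] = field(default_factory=list)
    time_index: list = field(default_factory=list)

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=np.float64)
        self.A = np.asarray(self.A, dtype=np.float64)
        self.M = np.asarray(self.M)
        if not self.node_ids:
            self.node_ids = [f"n{i}" for i in range(self.X.shape[0])]
        if len(self.time_index) == 0:
            self.time_index = list(range(self.X.shape[1]))
        # enforce the sentinel on masked cells so downstream code can rely on it
        self.X = np.where(self.M.astype(bool), self.X, MISSING_SENTINEL)

    @property
    def n_series(self) -> int:
        return self.X.shape[0]

    @property
    def n_steps(self) -> int:
        return self.X.shape[1]

    def copy(self) -> "SpatioTemporalSeries":
        return SpatioTemporalSeries(self.X.copy(), self.A.copy(), self.M.copy(),
                                    list(self.node_ids), list(self.time_index))


@dataclass
class CompleteSeries:
    """Fully observed ground truth, when it is known (synthetic data)."""

    Y: np.ndarray  # (N, T)

    def __post_init__(self):
        self.Y = np.asarray(self.Y, dtype=np.float64)

    def observe(self, A: np.ndarray, M: np.ndarray,
                node_ids: list[str] | None = None) -> SpatioTemporalSeries:
        """Mask the truth into an incomplete series: X = M ⊙ Y."""
        M = np.asarray(M)
        return SpatioTemporalSeries(self.Y * M, A, M, node_ids or [])


@dataclass
class DistanceSpec:
    """Pairwise distances plus Gaussian-kernel parameters for adjacency."""

    D: np.ndarray       # (N, N) symmetric, zero diagonal
    sigma: float        # kernel bandwidth, > 0
    kappa: float = 0.1  # weight threshold in [0, 1]

    def __post_init__(self):
        self.D = np.asarray(self.D, dtype=np.float64)


def build_adjacency(spec: DistanceSpec) -> np.ndarray:
    """Thresholded Gaussian kernel: A_ij = exp(-D_ij²/σ²), zeroed below κ.

    The self distance is zero, so the diagonal is always 1.
    """
    D = spec.D
    if spec.sigma <= 0:
        raise ValueError(f"sigma must be positive, got {spec.sigma}")
    if np.any(D < 0):
        i, j = np.argwhere(D < 0)[0]
        raise ValueError(f"negative distance at ({i}, {j})")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.diag(D) != 0):
        raise ValueError("distance matrix must have a zero diagonal")
    W = np.exp(-(D ** 2) / spec.sigma ** 2)
    W[W < spec.kappa] = 0.0
    return W


# ----------------------------------------------------------------------- I/O
def _read_table(path: Path, sep: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, index_col=0)
    for r, (_, row) in enumerate(df.iterrows()):
        for c, val in enumerate(row):
            if isinstance(val, str):
                try:
                    float(val)
                except ValueError:
                    raise SeriesParseError(
                        f"non-numeric token {val!r} at row {r} "
                        f"(node {df.index[r]!r}), column {c} "
                        f"({df.columns[c]!r}) of {path}") from None
    return df.apply(pd.to_numeric, errors="coerce")


def load_series(path: str | Path, format: str | None = None,
                adjacency: np.ndarray | str | Path | None = None,
                mask_path: str | Path | None = None) -> SpatioTemporalSeries:
    """Load a series from delimited text (CSV/TSV) or HDF5.

    Text layout: rows = nodes, first column = node id, header = time labels;
    empty cells are missing.  HDF5 layout: datasets ``/X``, ``/M``, ``/A``,
    ``/node_ids``, ``/time_index``.
    """
    path = Path(path)
    if format is None:
        format = {"h5": "hdf5", "hdf5": "hdf5", "tsv": "tsv"}.get(
            path.suffix.lstrip(".").lower(), "csv")
    if format == "hdf5":
        with h5py.File(path, "r") as f:
            X = f["/X"][...]
            M = f["/M"][...]
            A = f["/A"][...]
            node_ids = [s.decode() if isinstance(s, bytes) else str(s)
                        for s in f["/node_ids"][...]]
            time_index = list(f["/time_index"][...]) if "/time_index" in f \
                else list(range(X.shape[1]))
        return SpatioTemporalSeries(X, A, M, node_ids, time_index)

    sep = "\t" if format == "tsv" else ","
    df = _read_table(path, sep)
    X = df.to_numpy(dtype=np.float64)
    M = (~np.isnan(X)).astype(np.int64)
    X = np.nan_to_num(X, nan=MISSING_SENTINEL)
    if mask_path is not None:
        M_df = _read_table(Path(mask_path), sep)
        M_ext = M_df.to_numpy(dtype=np.float64)
        if M_ext.shape != X.shape:
            raise SeriesParseError(
                f"mask shape {M_ext.shape} does not match series {X.shape}")
        M = M & (M_ext != 0).astype(np.int64)
        X = X * M

    if adjacency is None:
        A = np.eye(X.shape[0])
    elif isinstance(adjacency, (str, Path)):
        A = load_adjacency(adjacency, n=X.shape[0],
                           node_ids=[str(i) for i in df.index])
    else:
        A = np.asarray(adjacency, dtype=np.float64)
    if A.shape != (X.shape[0], X.shape[0]):
        raise SeriesParseError(
            f"adjacency shape {A.shape} does not match {X.shape[0]} nodes")
    return SpatioTemporalSeries(X, A, M, [str(i) for i in df.index],
                                list(df.columns))


def save_series(series: SpatioTemporalSeries, path: str | Path,
                format: str | None = None) -> None:
    """Write a series; missing cells become empty in text output."""
    path = Path(path)
    if format is None:
        format = "hdf5" if path.suffix.lower() in {".h5", ".hdf5"} else "csv"
    if format == "hdf5":
        with h5py.File(path, "w") as f:
            f["/X"] = series.X
            f["/M"] = series.M.astype(np.int64)
            f["/A"] = series.A
            f["/node_ids"] = np.array(series.node_ids, dtype="S")
            f["/time_index"] = np.array([str(t) for t in series.time_index],
                                        dtype="S")
        return
    sep = "\t" if format == "tsv" else ","
    vals = series.X.astype(object)
    vals[~series.M.astype(bool)] = ""
    df = pd.DataFrame(vals, index=series.node_ids,
                      columns=[str(t) for t in series.time_index])
    df.to_csv(path, sep=sep)


def load_adjacency(path: str | Path, n: int | None = None,
                   node_ids: list[str] | None = None) -> np.ndarray:
    """Dense CSV (N×N, with header/index) or 3-column edge-list TSV."""
    path = Path(path)
    if path.suffix.lower() == ".tsv":
        first = pd.read_csv(path, sep="\t", nrows=1)
        if first.shape[1] == 3:  # edge list: src, dst, weight
            edges = pd.read_csv(path, sep="\t",
                                names=["src", "dst", "weight"], header=0)
            if node_ids is None:
                nodes = sorted(set(edges.src.astype(str)) |
                               set(edges.dst.astype(str)))
            else:
                nodes = node_ids
            idx = {v: i for i, v in enumerate(nodes)}
            n = n or len(nodes)
            A = np.zeros((n, n))
            for _, e in edges.iterrows():
                try:
                    A[idx[str(e.src)], idx[str(e.dst)]] = float(e.weight)
                except KeyError as err:
                    raise SeriesParseError(f"edge references unknown node {err}")
            np.fill_diagonal(A, np.maximum(np.diag(A), 1.0))
            return A
    df = pd.read_csv(path, index_col=0)
    A = df.to_numpy(dtype=np.float64)
    if A.shape[0] != A.shape[1]:
        raise SeriesParseError(f"adjacency in {path} is not square: {A.shape}")
    return A


def save_adjacency(A: np.ndarray, path: str | Path,
                   node_ids: list[str] | None = None) -> None:
    ids = node_ids or [f"n{i}" for i in range(A.shape[0])]
    pd.DataFrame(A, index=ids, columns=ids).to_csv(path)


# ----------------------------------------------------------------- validation
def validate_series(s: SpatioTemporalSeries) -> list[str]:
    """Return human-readable invariant violations (empty list = valid)."""
    violations: list[str] = []
    N = len(s.node_ids)
    if s.X.shape != s.M.shape:
        violations.append(f"shape: X {s.X.shape} != M {s.M.shape}")
    if s.X.shape[0] != N:
        violations.append(f"shape: X has {s.X.shape[0]} rows, {N} node_ids")
    if s.A.shape != (N, N):
        violations.append(f"shape: A {s.A.shape} is not ({N}, {N})")
    bad_m = np.argwhere(~np.isin(s.M, (0, 1)))
    if bad_m.size:
        i, t = bad_m[0]
        violations.append(
            f"M-binarity: M[{i},{t}] = {s.M[i, t]!r} not in {{0, 1}}")
    if s.A.shape == (N, N):
        bad_a = np.argwhere(s.A < 0)
        if bad_a.size:
            i, j = bad_a[0]
            violations.append(f"A-nonnegativity: A[{i},{j}] = {s.A[i, j]}")
    if len(s.time_index) != s.X.shape[1]:
        violations.append(
            f"shape: time_index has {len(s.time_index)} labels, "
            f"X has {s.X.shape[1]} steps")
    return violations
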