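"""Correlation adjacency and signed weighted topological overlap (wTO).

The wTO score augments the direct correlation a_ij between two nodes with
the agreement of their correlation profiles across *all* N nodes:

    omega_ij = (sum_u a_iu * a_uj + a_ij) / (min(k_i, k_j) + 1 - |a_ij|)

with node strength k_i = sum_j |a_ij| and a zero-diagonal correlation
adjacency a_ij.  Because correlations keep their sign, omega can be
negative (co-repression); the "unsigned" variant feeds |a_ij| into the
same formula and is an upper bound on |omega| (term cancellation can only
shrink the signed score).

A designated subset of nodes of interest (e.g. transcription factors)
restricts which *pairs* are reported; the sums always run over all N
nodes, so context outside the subset still shapes every score.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger("wtonet")

__all__ = [
    "ExpressionMatrix",
    "CorrelationConfig",
    "AdjacencyMatrix",
    "WTONetwork",
    "correlation_adjacency",
    "node_strength",
    "wto",
    "wto_self",
]


@dataclass(frozen=True)
class ExpressionMatrix:
    """Node x sample numeric matrix with identifiers.

    Rows are nodes (genes, OTUs, ...), columns are samples or time points.
    When ``is_time_series`` is true the columns are assumed to be in
    temporal order, which the blocked bootstrap relies on.
    """

    node_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray
    is_time_series: bool = False

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "node_ids", tuple(str(n) for n in self.node_ids))
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        if vals.ndim != 2:
            raise ValueError("values must be a 2-D node x sample matrix")
        n, s = vals.shape
        if len(self.node_ids) != n:
            raise ValueError(f"{len(self.node_ids)} node ids for {n} rows")
        if len(self.sample_ids) != s:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {s} columns")
        if len(set(self.node_ids)) != n:
            dupes = sorted({x for x in self.node_ids if self.node_ids.count(x) > 1})
            raise ValueError(f"duplicate node ids: {dupes}")
        if n < 3 or s < 3:
            raise ValueError(f"need at least 3 nodes and 3 samples, got {n} x {s}")
        if not np.all(np.isfinite(vals)):
            bad = np.argwhere(~np.isfinite(vals))[0]
            raise ValueError(
                f"non-finite value at node {self.node_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def drop_zero_variance(self) -> "ExpressionMatrix":
        """Remove constant rows (undefined correlation) with a logged warning."""
        sd = self.values.std(axis=1)
        keep = sd > 0
        if keep.all():
            return self
        dropped = [n for n, k in zip(self.node_ids, keep) if not k]
        msg = f"dropping {len(dropped)} zero-variance node(s): {dropped}"
        logger.warning(msg)
        warnings.warn(msg, UserWarning, stacklevel=2)
        return replace(
            self,
            node_ids=tuple(n for n, k in zip(self.node_ids, keep) if k),
            values=self.values[keep],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.node_ids),
                            columns=list(self.sample_ids))

    @classmethod
    def from_frame(cls, df: pd.DataFrame, is_time_series: bool = False) -> "ExpressionMatrix":
        return cls(tuple(map(str, df.index)), tuple(map(str, df.columns)),
                   df.to_numpy(dtype=float), is_time_series)


@dataclass(frozen=True)
class CorrelationConfig:
    method: Literal["pearson", "spearman"] = "pearson"
    sign_mode: Literal["signed", "absolute"] = "signed"

    def __post_init__(self):
        if self.method not in ("pearson", "spearman"):
            raise ValueError(f"unknown correlation method {self.method!r}; "
                             "choose 'pearson' or 'spearman'")
        if self.sign_mode not in ("signed", "absolute"):
            raise ValueError(f"unknown sign mode {self.sign_mode!r}; "
                             "choose 'signed' or 'absolute'")


@dataclass(frozen=True)
class AdjacencyMatrix:
    """Symmetric correlation matrix with zero diagonal."""

    node_ids: tuple[str, ...]
    A: np.ndarray

    def __post_init__(self):
        A = np.asarray(self.A, dtype=float)
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "node_ids", tuple(str(n) for n in self.node_ids))
        n = len(self.node_ids)
        if A.shape != (n, n):
            raise ValueError(f"adjacency shape {A.shape} does not match {n} node ids")
        if not np.allclose(A, A.T, atol=1e-12):
            raise ValueError("adjacency must be symmetric")
        if np.abs(np.diagonal(A)).max(initial=0.0) > 1e-12:
            raise ValueError("adjacency diagonal must be zero")
        if np.abs(A).max(initial=0.0) > 1 + 1e-9:
            raise ValueError("adjacency entries must lie in [-1, 1]")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def index_of(self, ids: Sequence[str]) -> np.ndarray:
        lookup = {n: i for i, n in enumerate(self.node_ids)}
        missing = [x for x in ids if x not in lookup]
        if missing:
            raise KeyError(f"node id(s) not in adjacency: {missing}")
        return np.asarray([lookup[x] for x in ids], dtype=int)


@dataclass(frozen=True)
class WTONetwork:
    """Signed and unsigned wTO for every unordered pair in the subset."""

    subset_ids: tuple[str, ...]
    omega_signed: np.ndarray
    omega_abs_input: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "subset_ids", tuple(str(n) for n in self.subset_ids))

    @property
    def n_pairs(self) -> int:
        m = len(self.subset_ids)
        return m * (m - 1) // 2

    def as_edge_list(self) -> pd.DataFrame:
        """One row per unordered pair; endpoints lexicographically sorted."""
        m = len(self.subset_ids)
        iu, ju = np.triu_indices(m, k=1)
        a = np.asarray(self.subset_ids)[iu]
        b = np.asarray(self.subset_ids)[ju]
        swap = a > b
        a2 = np.where(swap, b, a)
        b2 = np.where(swap, a, b)
        return pd.DataFrame({
            "Node.1": a2,
            "Node.2": b2,
            "wTO_sign": self.omega_signed[iu, ju],
            "wTO_abs": self.omega_abs_input[iu, ju],
        })


def correlation_adjacency(expr: ExpressionMatrix,
                          cfg: CorrelationConfig = CorrelationConfig()) -> AdjacencyMatrix:
    """Pairwise row correlation with zero diagonal.

    Spearman is the Pearson correlation of average-rank-transformed rows.
    In absolute mode the entrywise absolute value is applied after the
    diagonal is zeroed.
    """
    vals = expr.values
    sd = vals.std(axis=1)
    if np.any(sd == 0):
        bad = [n for n, s in zip(expr.node_ids, sd) if s == 0]
        raise ValueError(f"zero-variance node(s) {bad}; drop them before correlating")
    if cfg.method == "spearman":
        vals = rankdata(vals, axis=1)  # average ranks for ties
    with np.errstate(invalid="ignore"):
        A = np.corrcoef(vals)
    A = np.clip(A, -1.0, 1.0)
    A = (A + A.T) / 2.0
    np.fill_diagonal(A, 0.0)
    if cfg.sign_mode == "absolute":
        A = np.abs(A)
    return AdjacencyMatrix(expr.node_ids, A)


def node_strength(A: AdjacencyMatrix) -> np.ndarray:
    """Node strength k_i = sum_j |a_ij|; lies in [0, N-1]."""
    return np.abs(A.A).sum(axis=1)


def _wto_from_matrix(A: np.ndarray, idx: np.ndarray) -> np.ndarray:
    k = np.abs(A).sum(axis=1)
    Asub = A[np.ix_(idx, idx)]
    numer = (A[idx, :] @ A[:, idx]) + Asub
    denom = np.minimum.outer(k[idx], k[idx]) + 1.0 - np.abs(Asub)
    # denom hits 0 only when two nodes connect solely to each other with
    # |a| = 1; the continuity limit there is a_ij itself
    degenerate = denom <= 1e-300
    with np.errstate(divide="ignore", invalid="ignore"):
        omega = np.where(degenerate, Asub, numer / np.where(degenerate, 1.0, denom))
    omega = (omega + omega.T) / 2.0
    np.fill_diagonal(omega, 0.0)
    return omega


def wto(A: AdjacencyMatrix, subset: Sequence[str] | None = None) -> WTONetwork:
    """Signed and unsigned wTO for every unordered pair within ``subset``.

    The numerator matrix product and the node strengths always run over
    all N nodes; the subset only restricts which pairs are reported.
    """
    if subset is None:
        subset = A.node_ids
    subset = tuple(str(s) for s in subset)
    if len(subset) < 2:
        raise ValueError("subset must contain at least 2 nodes")
    if len(set(subset)) != len(subset):
        raise ValueError("subset contains duplicate node ids")
    idx = A.index_of(subset)
    return WTONetwork(
        subset_ids=subset,
        omega_signed=_wto_from_matrix(A.A, idx),
        omega_abs_input=_wto_from_matrix(np.abs(A.A), idx),
    )


def wto_self(A: AdjacencyMatrix, node: str) -> float:
    """Diagnostic self-overlap omega_ii = sum_u a_iu^2 / (k_i + 1).

    For a binary network with degree k this is k / (k + 1), approaching 1
    for hubs.  Never emitted in edge lists.
    """
    i = A.index_of([node])[0]
    row = A.A[i]
    return float((row ** 2).sum() / (np.abs(row).sum() + 1.0))
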