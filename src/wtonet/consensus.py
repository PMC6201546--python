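"""Sign-aware consensus of k >= 2 wTO networks.

Each link's consensus weight is the magnitude-weighted convex combination

    Omega_ij = sum_k alpha_ij^k * omega_ij^k,
    alpha_ij^k = |omega_ij^k| / sum_k |omega_ij^k|,

which pulls same-sign links toward the strongest network and shrinks
sign-conflicting links toward zero.  Per-link p-values are combined with
Fisher's method (-2 sum ln p ~ chi-square with 2k df).  Nodes absent from
any input network are removed before combining; a pair missing from a
subset of networks (both endpoints present) is zero-filled by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

__all__ = [
    "NetworkStack",
    "ConsensusNetwork",
    "align_node_sets",
    "zero_insignificant",
    "consensus_weights",
    "fisher_combine",
    "threshold_consensus",
]

_EDGE_COLS = ["Node.1", "Node.2", "wTO", "pval"]


def _normalize_edges(df: pd.DataFrame) -> pd.DataFrame:
    """Lexicographically order endpoints, validate ranges, check duplicates."""
    df = df.copy()
    df.columns = _EDGE_COLS
    a = df["Node.1"].astype(str)
    b = df["Node.2"].astype(str)
    swap = a > b
    df["Node.1"] = a.where(~swap, b)
    df["Node.2"] = b.where(~swap, a)
    if (df["Node.1"] == df["Node.2"]).any():
        bad = df.loc[df["Node.1"] == df["Node.2"], "Node.1"].iloc[0]
        raise ValueError(f"self-link on node {bad!r}")
    w = df["wTO"].to_numpy(dtype=float)
    p = df["pval"].to_numpy(dtype=float)
    if np.any(np.abs(w) > 1 + 1e-9):
        raise ValueError("weights must lie in [-1, 1]")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    if df.duplicated(subset=["Node.1", "Node.2"]).any():
        pair = df.loc[df.duplicated(subset=["Node.1", "Node.2"]),
                      ["Node.1", "Node.2"]].iloc[0]
        raise ValueError(f"duplicate unordered pair {tuple(pair)}")
    return df.reset_index(drop=True)


@dataclass
class NetworkStack:
    """k edge tables (Node.1, Node.2, wTO, pval), endpoints normalized."""

    networks: list[pd.DataFrame]

    def __post_init__(self):
        if len(self.networks) < 2:
            raise ValueError("consensus needs at least 2 networks")
        self.networks = [_normalize_edges(n) for n in self.networks]

    @property
    def k(self) -> int:
        return len(self.networks)

    def node_sets(self) -> list[set[str]]:
        return [set(n["Node.1"]) | set(n["Node.2"]) for n in self.networks]


@dataclass
class ConsensusNetwork:
    """Per-link consensus weight Omega with Fisher-combined p-value."""

    edges: pd.DataFrame                      # Node.1, Node.2, CN, pval.fisher
    alphas: pd.DataFrame | None = None       # optional per-network contributions


def align_node_sets(stack: NetworkStack,
                    zero_fill_missing_links: bool = True) -> NetworkStack:
    """Restrict every network to the intersection of the node sets.

    Links touching nodes outside the intersection are dropped.  A pair
    present in some networks but not others (endpoints present
    everywhere) is treated as omega = 0, p = 1 in the missing networks
    when ``zero_fill_missing_links`` (default); otherwise such pairs are
    dropped entirely.
    """
    sets = stack.node_sets()
    common = set.intersection(*sets)
    if not common:
        counts = ", ".join(f"net{i + 1}: {len(s)} nodes"
                           for i, s in enumerate(sets))
        raise ValueError(f"node-set intersection is empty ({counts})")
    restricted = []
    for net in stack.networks:
        keep = net["Node.1"].isin(common) & net["Node.2"].isin(common)
        restricted.append(net.loc[keep].reset_index(drop=True))

    pair_sets = [set(zip(n["Node.1"], n["Node.2"])) for n in restricted]
    pairs = set.union(*pair_sets) if zero_fill_missing_links \
        else set.intersection(*pair_sets)
    pairs = sorted(pairs)
    filled = []
    for net in restricted:
        net = net.set_index(["Node.1", "Node.2"]).reindex(pairs)
        net["wTO"] = net["wTO"].fillna(0.0)
        net["pval"] = net["pval"].fillna(1.0)
        filled.append(net.reset_index())
    out = NetworkStack.__new__(NetworkStack)   # already normalized
    out.networks = filled
    return out


def zero_insignificant(stack: NetworkStack, alpha: float) -> NetworkStack:
    """Set omega = 0 for links with p > alpha (they then carry alpha-weight 0)."""
    if not 0 < alpha <= 1:
        raise ValueError(f"alpha must lie in (0, 1], got {alpha}")
    zeroed = []
    for net in stack.networks:
        net = net.copy()
        net.loc[net["pval"] > alpha, "wTO"] = 0.0
        zeroed.append(net)
    out = NetworkStack.__new__(NetworkStack)
    out.networks = zeroed
    return out


def fisher_combine(pvals) -> float:
    """Fisher's method: X = -2 sum ln p, combined p = chi2.sf(X, 2k)."""
    p = np.asarray(pvals, dtype=float)
    if np.any(p <= 0):
        raise ValueError("Fisher combination requires p > 0 (floor zeros upstream)")
    if np.any(p > 1):
        raise ValueError("p-values must be <= 1")
    x = -2.0 * np.log(p).sum()
    return float(chi2.sf(x, df=2 * p.size))


def consensus_weights(stack: NetworkStack,
                      keep_alphas: bool = False) -> ConsensusNetwork:
    """Combine an aligned stack into one consensus network (Omega, Fisher p)."""
    aligned = align_node_sets(stack)
    k = aligned.k
    base = aligned.networks[0][["Node.1", "Node.2"]]
    W = np.column_stack([n["wTO"].to_numpy(dtype=float)
                         for n in aligned.networks])
    P = np.column_stack([n["pval"].to_numpy(dtype=float)
                         for n in aligned.networks])
    absW = np.abs(W)
    total = absW.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        alpha = np.where(total[:, None] > 0, absW / total[:, None], 0.0)
    omega_cn = (alpha * W).sum(axis=1)
    x = -2.0 * np.log(P).sum(axis=1)
    p_comb = chi2.sf(x, df=2 * k)
    edges = base.copy()
    edges["CN"] = omega_cn
    edges["pval.fisher"] = p_comb
    alphas = None
    if keep_alphas:
        alphas = base.copy()
        for i in range(k):
            alphas[f"alpha.{i + 1}"] = alpha[:, i]
    return ConsensusNetwork(edges, alphas)


def threshold_consensus(cn: ConsensusNetwork,
                        min_abs_omega: float) -> ConsensusNetwork:
    """Drop links with |Omega| below the threshold (near-zero consensus)."""
    if min_abs_omega < 0:
        raise ValueError("threshold must be nonnegative")
    keep = cn.edges["CN"].abs() >= min_abs_omega
    edges = cn.edges.loc[keep].reset_index(drop=True)
    alphas = cn.alphas.loc[keep].reset_index(drop=True) if cn.alphas is not None else None
    return ConsensusNetwork(edges, alphas)
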