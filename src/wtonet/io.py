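"""Delimited-matrix and edge-table readers/writers plus run provenance.

Expression input: delimited text (TSV default, CSV accepted), first
column = node id, header row = sample ids; `transpose` handles
samples-in-rows layouts.  Edge tables follow the significance-table
dialect (Node.1, Node.2, weight, p-value) with endpoint pairs stored in
lexicographic order everywhere, which keeps A-B / B-A duplicates from
slipping through consensus.  Numeric output uses 12 significant digits.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ExpressionMatrix

logger = logging.getLogger("wtonet")

FLOAT_FMT = "%.12g"

__all__ = ["read_expression", "write_expression", "read_edge_table",
            "write_edge_table", "read_subset", "write_provenance"]


def _delimiter_for(path: str | Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if str(path).lower().endswith(".csv") else "\t"


def read_expression(path: str | Path, delimiter: str | None = None,
                    transpose: bool = False,
                    is_time_series: bool = False) -> ExpressionMatrix:
    """Read a node x sample matrix; drops zero-variance rows with a warning."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = _delimiter_for(path, delimiter)
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, header=0)
    except pd.errors.ParserError as e:
        raise ValueError(f"{path}: malformed table ({e})") from e
    if transpose:
        df = df.T
    if df.index.has_duplicates:
        dupes = sorted(df.index[df.index.duplicated()].unique().tolist())
        raise ValueError(f"{path}: duplicate node id(s): {dupes}")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.argmax()]
            raise ValueError(f"{path}: non-numeric cell at node {row!r}, "
                             f"sample {col!r}: {df.loc[row, col]!r}")
        if coerced.isna().any():
            row = df.index[coerced.isna().argmax()]
            raise ValueError(f"{path}: missing value at node {row!r}, "
                             f"sample {col!r}")
        df[col] = coerced
    expr = ExpressionMatrix.from_frame(df, is_time_series=is_time_series)
    return expr.drop_zero_variance()


def write_expression(expr: ExpressionMatrix, path: str | Path,
                     delimiter: str | None = None) -> None:
    sep = _delimiter_for(path, delimiter)
    expr.to_frame().to_csv(path, sep=sep, float_format=FLOAT_FMT)


def read_subset(path: str | Path) -> list[str]:
    """One node id per line; blank lines ignored."""
    lines = Path(path).read_text().splitlines()
    return [ln.strip() for ln in lines if ln.strip()]


def read_edge_table(path: str | Path, delimiter: str | None = None,
                    columns: tuple[str, str, str, str] | None = None) -> pd.DataFrame:
    """Read an edge table into (Node.1, Node.2, wTO, pval).

    ``columns`` maps custom (node1, node2, weight, pval) column names; by
    default the significance-table / consensus dialects are recognized.
    """
    path = Path(path)
    sep = _delimiter_for(path, delimiter)
    df = pd.read_csv(path, sep=sep)
    if columns is None:
        for cand in (("Node.1", "Node.2", "wTO_sign", "padj_sig"),
                     ("Node.1", "Node.2", "CN", "pval.fisher"),
                     ("Node.1", "Node.2", "wTO", "pval")):
            if all(c in df.columns for c in cand):
                columns = cand
                break
        else:
            if len(df.columns) >= 4:
                columns = tuple(df.columns[:4])
            else:
                raise ValueError(f"{path}: need >= 4 mappable columns, "
                                 f"found {list(df.columns)}")
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: column(s) {missing} not found")
    out = df[list(columns)].copy()
    out.columns = ["Node.1", "Node.2", "wTO", "pval"]
    w = out["wTO"].to_numpy(dtype=float)
    p = out["pval"].to_numpy(dtype=float)
    for i, val in enumerate(w):
        if not -1 - 1e-9 <= val <= 1 + 1e-9:
            raise ValueError(f"{path}: weight {val} out of [-1, 1] at row {i + 2}")
    for i, val in enumerate(p):
        if not 0 <= val <= 1:
            raise ValueError(f"{path}: p-value {val} out of [0, 1] at row {i + 2}")
    a = out["Node.1"].astype(str)
    b = out["Node.2"].astype(str)
    swap = a > b
    out["Node.1"] = a.where(~swap, b)
    out["Node.2"] = b.where(~swap, a)
    dup = out.duplicated(subset=["Node.1", "Node.2"], keep=False)
    if dup.any():
        grp = out.loc[dup].groupby(["Node.1", "Node.2"])["wTO"].nunique()
        conflict = grp[grp > 1]
        if len(conflict):
            raise ValueError(f"{path}: conflicting duplicate pair(s) "
                             f"{list(conflict.index)[:3]} with differing weights")
        out = out.drop_duplicates(subset=["Node.1", "Node.2"])
    return out.reset_index(drop=True)


def write_edge_table(df: pd.DataFrame, path: str | Path,
                     delimiter: str | None = None) -> None:
    sep = _delimiter_for(path, delimiter)
    df.to_csv(path, sep=sep, index=False, float_format=FLOAT_FMT)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_provenance(out_path: str | Path, config: dict,
                     inputs: list[str | Path]) -> None:
    """Emit a provenance record (config, seed, version, input checksums)."""
    from . import __version__
    record = {
        "package": "wtonet",
        "version": __version__,
        "config": config,
        "inputs": {str(p): _sha256(p) for p in inputs if Path(p).exists()},
    }
    prov = Path(str(out_path) + ".provenance.json")
    prov.write_text(json.dumps(record, indent=2, default=str) + "\n")
    logger.info("wrote provenance record to %s", prov)
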