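"""Readers, writers and validated containers for expression data and
interaction networks.

Expression matrices are plain :class:`pandas.DataFrame` objects with gene
symbols as the index (rows) and sample identifiers as columns, holding
log2-scale expression values.  :func:`validate_expression` enforces the
container contract; the loaders call it on every file they read.

Interaction networks are held in :class:`Network`, a canonicalized,
confidence-filtered undirected edge list: every edge is stored with its two
endpoints in lexicographic order, self-loops removed and duplicate unordered
pairs collapsed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "Network",
    "validate_expression",
    "load_expression",
    "write_expression",
    "load_gene_universe",
    "network_from_edges",
    "load_network",
    "write_network",
    "restrict_to_measured",
    "degree_summary",
    "edge_id",
]

DEFAULT_MIN_CONFIDENCE = 0.7  # edges must score strictly above this

EDGE_SEP = "|"


def edge_id(gene_a: str, gene_b: str) -> str:
    """Canonical string identifier ``"A|B"`` for an undirected edge."""
    return f"{gene_a}{EDGE_SEP}{gene_b}"


@dataclass(frozen=True)
class Network:
    """Canonical, confidence-filtered undirected interaction network.

    Attributes
    ----------
    edges:
        DataFrame with columns ``gene_a``, ``gene_b``, ``confidence``;
        ``gene_a`` is strictly before ``gene_b`` lexicographically, there are
        no self-loops and no duplicate unordered pairs.
    """

    edges: pd.DataFrame

    def __post_init__(self) -> None:
        e = self.edges
        required = ["gene_a", "gene_b", "confidence"]
        if list(e.columns[:3]) != required:
            raise ValueError(f"network edges need columns {required}")
        if len(e) == 0:
            raise ValueError("network has no edges")
        if (e["gene_a"] >= e["gene_b"]).any():
            raise ValueError("edges must be canonicalized (gene_a < gene_b)")
        pairs = e["gene_a"] + EDGE_SEP + e["gene_b"]
        if pairs.duplicated().any():
            dup = pairs[pairs.duplicated()].iloc[0]
            raise ValueError(f"duplicate edge {dup!r}")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self.edges["gene_a"]) | frozenset(self.edges["gene_b"])

    @property
    def edge_ids(self) -> pd.Index:
        return pd.Index(self.edges["gene_a"] + EDGE_SEP + self.edges["gene_b"])


def validate_expression(expr: pd.DataFrame) -> pd.DataFrame:
    """Validate an expression matrix (genes x samples, finite log2 values)."""
    if expr.index.has_duplicates:
        dup = expr.index[expr.index.duplicated()][0]
        raise ValueError(f"duplicate gene id {dup!r}")
    if expr.columns.has_duplicates:
        dup = expr.columns[expr.columns.duplicated()][0]
        raise ValueError(f"duplicate sample id {dup!r}")
    if expr.shape[0] < 2:
        raise ValueError("expression matrix needs at least 2 genes")
    values = expr.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValueError("expression matrix contains non-numeric values")
    if not np.isfinite(values).all():
        g, s = np.argwhere(~np.isfinite(values))[0]
        raise ValueError(
            f"non-finite value at gene {expr.index[g]!r}, sample {expr.columns[s]!r}"
        )
    return expr


def load_expression(path: str | Path, delimiter: str = "\t") -> pd.DataFrame:
    """Load a genes-x-samples expression matrix from delimited text.

    The first column holds gene ids, the header row sample ids.  Row and
    column order are preserved from the file.
    """
    raw = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str)
    raw.index = raw.index.astype(str)
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & raw.notna()
    if bad.to_numpy().any():
        g, s = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric cell at gene {raw.index[g]!r}, sample {raw.columns[s]!r}: "
            f"{raw.iat[g, s]!r}"
        )
    if numeric.isna().to_numpy().any():
        g, s = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(
            f"missing value at gene {raw.index[g]!r}, sample {raw.columns[s]!r}"
        )
    return validate_expression(numeric.astype(float))


def write_expression(expr: pd.DataFrame, path: str | Path, delimiter: str = "\t") -> None:
    expr.to_csv(path, sep=delimiter, index_label="gene")


def load_gene_universe(path: str | Path) -> set[str]:
    """Load a gene universe: one symbol per line, blank lines ignored."""
    symbols = [line.strip() for line in Path(path).read_text().splitlines()]
    symbols = [s for s in symbols if s]
    if not symbols:
        raise ValueError("gene universe is empty")
    universe = set(symbols)
    if len(universe) != len(symbols):
        raise ValueError("gene universe contains duplicate symbols")
    return universe


def network_from_edges(
    rows: Iterable[tuple[str, str, float]],
    min_confidence: float = DEFAULT_MIN_CONFIDENCE,
    universe: set[str] | None = None,
) -> Network:
    """Canonicalize and filter an edge list into a :class:`Network`.

    Self-loops are dropped, each pair is oriented lexicographically,
    duplicate unordered pairs collapse to the maximum confidence, and only
    edges with confidence strictly greater than ``min_confidence`` (and, if a
    universe is given, both endpoints inside it) are retained.  First-seen
    order of the surviving unordered pairs is preserved.
    """
    best: dict[tuple[str, str], float] = {}
    order: list[tuple[str, str]] = []
    for a, b, conf in rows:
        if not (0.0 <= conf <= 1.0):
            raise ValueError(f"confidence {conf} for ({a}, {b}) outside [0, 1]")
        if a == b:
            continue
        key = (a, b) if a < b else (b, a)
        if universe is not None and (key[0] not in universe or key[1] not in universe):
            continue
        if key in best:
            best[key] = max(best[key], conf)
        else:
            best[key] = conf
            order.append(key)
    kept = [(a, b, best[(a, b)]) for a, b in order if best[(a, b)] > min_confidence]
    if not kept:
        raise ValueError(
            f"no edges remain after filtering at confidence > {min_confidence}"
        )
    edges = pd.DataFrame(kept, columns=["gene_a", "gene_b", "confidence"])
    return Network(edges)


def load_network(
    path: str | Path,
    min_confidence: float = DEFAULT_MIN_CONFIDENCE,
    universe: set[str] | None = None,
    delimiter: str = "\t",
) -> Network:
    """Load a 3-column (gene_a, gene_b, confidence) edge list from text.

    Lines starting with ``#`` are treated as comments/header.  Malformed rows
    raise with their 1-based line number.
    """
    rows: list[tuple[str, str, float]] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        parts = stripped.split(delimiter) if delimiter != " " else stripped.split()
        if len(parts) != 3:
            raise ValueError(f"line {lineno}: expected 3 columns, got {len(parts)}")
        a, b, conf_str = (p.strip() for p in parts)
        try:
            conf = float(conf_str)
        except ValueError:
            raise ValueError(
                f"line {lineno}: confidence {conf_str!r} is not a number"
            ) from None
        rows.append((a, b, conf))
    return network_from_edges(rows, min_confidence=min_confidence, universe=universe)


def write_network(net: Network, path: str | Path, delimiter: str = "\t") -> None:
    header = "#" + delimiter.join(["gene_a", "gene_b", "confidence"])
    body = net.edges.to_csv(None, sep=delimiter, index=False, header=False)
    Path(path).write_text(header + "\n" + body)


def restrict_to_measured(net: Network, expr: pd.DataFrame) -> Network:
    """Keep only edges whose both endpoints are measured in ``expr``."""
    measured = set(expr.index)
    mask = net.edges["gene_a"].isin(measured) & net.edges["gene_b"].isin(measured)
    if not mask.any():
        raise ValueError("no network edge has both endpoints in the expression matrix")
    return Network(net.edges.loc[mask].reset_index(drop=True))


def degree_summary(net: Network) -> tuple[Mapping[str, int], int, int]:
    """Per-gene degree plus (n_nodes, n_edges). Degree sum equals 2 x edges."""
    counts = pd.concat([net.edges["gene_a"], net.edges["gene_b"]]).value_counts()
    degrees = counts.to_dict()
    return degrees, len(degrees), net.n_edges
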