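"""Readers and writers for the external text formats.

Expression matrices arrive as delimited text (genes in rows, samples in
columns, header required); PPI edge lists in the STRING export dialect (two
node columns plus a numeric confidence column, whitespace- or tab-separated);
gene sets as one identifier per line with ``#`` comments; protein-RNA edges as
two-column text. Graphs are written as edge-list TSV or GraphML.

Identifiers are opaque case-sensitive strings; no symbol/accession mapping is
attempted, but :func:`read_id_map` accepts a user-supplied two-column mapping
that :func:`apply_id_map` applies as an optional pre-step.
"""

from __future__ import annotations

import csv
import io as _stdio
import logging
import warnings
from os import PathLike
from typing import Iterable, TextIO

import networkx as nx
import numpy as np
import pandas as pd

from .types import CONDITIONS, ExpressionMatrix, GeneSet

logger = logging.getLogger(__name__)

_GRAPH_FORMATS = ("tsv", "graphml")


def _open(source: str | PathLike | TextIO, mode: str = "r"):
    """Return (file, needs_close) for a path or an already-open text stream."""
    if hasattr(source, "read") or hasattr(source, "write"):
        return source, False
    return open(source, mode), True


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def read_labels(source: str | PathLike | TextIO):
    """Read a sample-label table: ``sample<TAB>condition[<TAB>pair_id]``.

    Lines starting with ``#`` are ignored. Returns ``(label_map, pair_map)``
    where ``pair_map`` is ``None`` if no third column is present.
    """
    fh, close = _open(source)
    try:
        label_map: dict[str, str] = {}
        pair_map: dict[str, str] = {}
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", "\t").split("\t")
            parts = [p.strip() for p in parts if p.strip()]
            if len(parts) < 2:
                raise ValueError(f"malformed label line: {line!r}")
            label_map[parts[0]] = parts[1].lower()
            if len(parts) >= 3:
                pair_map[parts[0]] = parts[2]
    finally:
        if close:
            fh.close()
    return label_map, (pair_map or None)


def read_expression(
    source: str | PathLike | TextIO,
    label_map: dict[str, str],
    *,
    sep: str | None = None,
    pair_map: dict[str, str] | None = None,
) -> ExpressionMatrix:
    """Read a genes x samples delimited matrix into an :class:`ExpressionMatrix`.

    The first column holds gene ids, the header row sample ids; ``label_map``
    assigns every sample a condition in ``{"tumor", "normal"}``. Rows with any
    unparseable or missing value are dropped with a logged report (correlation
    with missing data is undefined here, so incomplete genes are excluded).

    Raises
    ------
    ValueError
        On a duplicated gene id (named), a header sample absent from
        ``label_map``, or an empty data section.
    """
    fh, close = _open(source)
    try:
        raw = pd.read_csv(fh, sep=sep, engine="python", index_col=0, dtype=str)
    finally:
        if close:
            fh.close()
    raw.index = raw.index.astype(str).str.strip()
    raw.columns = raw.columns.astype(str).str.strip()
    if raw.shape[0] == 0:
        raise ValueError("no genes in expression input")
    if raw.index.has_duplicates:
        dup = raw.index[raw.index.duplicated()][0]
        raise ValueError(f"duplicate gene id: {dup!r}")
    missing = [s for s in raw.columns if s not in label_map]
    if missing:
        raise ValueError(f"sample {missing[0]!r} missing from label map")

    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1)
    if bad.any():
        dropped = list(numeric.index[bad])
        logger.warning(
            "dropped %d gene row(s) with unparseable/missing values: %s",
            len(dropped),
            ", ".join(dropped[:10]) + ("..." if len(dropped) > 10 else ""),
        )
        numeric = numeric.loc[~bad]
    if numeric.shape[0] == 0:
        raise ValueError("no genes with complete numeric values")

    condition = pd.Series(
        [str(label_map[s]).lower() for s in numeric.columns], index=numeric.columns
    )
    pair = None
    if pair_map is not None:
        pair = pd.Series([pair_map.get(s) for s in numeric.columns], index=numeric.columns)
    return ExpressionMatrix(values=numeric.astype(float), condition=condition, pair_id=pair)


# ---------------------------------------------------------------------------
# PPI
# ---------------------------------------------------------------------------

def read_ppi(
    source: str | PathLike | TextIO,
    *,
    node_cols: tuple = (0, 1),
    score_col=2,
    sep: str | None = None,
) -> nx.Graph:
    """Read a STRING-dialect edge list into an undirected confidence graph.

    Columns may be addressed by 0-based index or by header name; a header row
    is auto-detected (first row whose score field is non-numeric). Reversed
    duplicates ``(a,b)``/``(b,a)`` collapse to one edge keeping the *maximum*
    confidence; self-loops are dropped and counted; rows with a non-numeric
    confidence are rejected and counted. Confidence is kept on its raw scale
    (STRING 0-1000 integers or 0-1 reals both work: discretization downstream
    is rank-based, hence scale-invariant).

    Returns a :class:`networkx.Graph` with per-edge ``confidence`` and graph
    attributes ``self_loops_dropped`` / ``rows_rejected``.
    """
    fh, close = _open(source)
    try:
        text = fh.read()
    finally:
        if close:
            fh.close()

    rows: list[list[str]] = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if sep is not None:
            parts = [p.strip() for p in line.split(sep)]
        elif "\t" in line:
            parts = [p.strip() for p in line.split("\t")]
        elif "," in line:
            parts = [p.strip() for p in line.split(",")]
        else:
            parts = line.split()
        rows.append(parts)
    if not rows:
        raise ValueError("empty PPI input")

    header: list[str] | None = None

    def _resolve(col, header_row):
        if isinstance(col, int):
            return col
        if header_row is None or col not in header_row:
            raise ValueError(f"column {col!r} not found in PPI header")
        return header_row.index(col)

    # header detection: the score field of the first row is neither a number
    # nor a missing-value token (a missing score is a bad data row, not a header)
    first = rows[0]
    probe_idx = score_col if isinstance(score_col, int) else -1
    probe = first[probe_idx] if -len(first) <= probe_idx < len(first) else ""
    missing_tokens = {"", "na", "nan", "null", "none", "-", "."}
    try:
        float(probe)
        has_header = False
    except ValueError:
        has_header = probe.lower() not in missing_tokens
    if has_header or not isinstance(score_col, int) or not all(
        isinstance(c, int) for c in node_cols
    ):
        header = rows[0]
        rows = rows[1:]
    ia = _resolve(node_cols[0], header)
    ib = _resolve(node_cols[1], header)
    isc = _resolve(score_col, header)

    g = nx.Graph(self_loops_dropped=0, rows_rejected=0)
    for parts in rows:
        if len(parts) <= max(ia, ib, isc):
            g.graph["rows_rejected"] += 1
            continue
        a, b = parts[ia], parts[ib]
        try:
            conf = float(parts[isc])
        except ValueError:
            g.graph["rows_rejected"] += 1
            continue
        if not np.isfinite(conf):
            g.graph["rows_rejected"] += 1
            continue
        if a == b:
            g.graph["self_loops_dropped"] += 1
            continue
        if g.has_edge(a, b):
            g[a][b]["confidence"] = max(g[a][b]["confidence"], conf)
        else:
            g.add_edge(a, b, confidence=conf)
    if g.number_of_edges() == 0:
        raise ValueError("no usable PPI rows")
    if g.graph["self_loops_dropped"]:
        logger.info("dropped %d self-loop(s)", g.graph["self_loops_dropped"])
    if g.graph["rows_rejected"]:
        logger.info("rejected %d malformed PPI row(s)", g.graph["rows_rejected"])
    return g


# ---------------------------------------------------------------------------
# gene sets, id maps, protein-RNA edges
# ---------------------------------------------------------------------------

def read_gene_set(source: str | PathLike | TextIO, name: str) -> GeneSet:
    """Read a one-identifier-per-line gene set; ``#`` comments allowed.

    Duplicates are removed with a logged count; an empty file yields an empty
    set with a warning (not an error).
    """
    fh, close = _open(source)
    try:
        members: list[str] = []
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                members.append(line)
    finally:
        if close:
            fh.close()
    unique = set(members)
    n_dup = len(members) - len(unique)
    if n_dup:
        logger.info("gene set %r: %d duplicate id(s) removed", name, n_dup)
    if not unique:
        warnings.warn(f"gene set {name!r} is empty", stacklevel=2)
    return GeneSet(name=name, members=frozenset(unique))


def read_id_map(source: str | PathLike | TextIO) -> dict[str, str]:
    """Two-column ``from<TAB>to`` identifier mapping (optional pre-step)."""
    fh, close = _open(source)
    try:
        mapping: dict[str, str] = {}
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", "\t").split("\t")
            parts = [p.strip() for p in parts if p.strip()]
            if len(parts) >= 2:
                mapping[parts[0]] = parts[1]
    finally:
        if close:
            fh.close()
    return mapping


def apply_id_map(graph: nx.Graph, mapping: dict[str, str]) -> nx.Graph:
    """Relabel graph nodes through a mapping; unmapped ids pass through."""
    return nx.relabel_nodes(graph, {n: mapping.get(n, n) for n in graph.nodes})


def read_rna_edges(source: str | PathLike | TextIO) -> list[tuple[str, str]]:
    """Read ``protein<TAB>rna`` interaction pairs (StarBase-style export)."""
    fh, close = _open(source)
    try:
        pairs: list[tuple[str, str]] = []
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", "\t").split("\t")
            parts = [p.strip() for p in parts if p.strip()]
            if len(parts) >= 2:
                pairs.append((parts[0], parts[1]))
    finally:
        if close:
            fh.close()
    return pairs


# ---------------------------------------------------------------------------
# graph output
# ---------------------------------------------------------------------------

_WEIGHT_ATTR_PRIORITY = ("weight", "w_dn", "confidence")


def _edge_weight(data: dict) -> float:
    for attr in _WEIGHT_ATTR_PRIORITY:
        if attr in data:
            return float(data[attr])
    return 1.0


def write_graph(graph: nx.Graph, target: str | PathLike | TextIO, fmt: str | None = None) -> None:
    """Write a weighted graph as edge-list TSV or GraphML.

    TSV columns are ``node1  node2  weight`` with weights printed at full
    precision (``%.17g``) so a write/read round trip is the identity on the
    node set, edge set and weights. GraphML carries node attributes (e.g. the
    ``role`` of protein vs rna nodes) as well.
    """
    if fmt is None:
        fmt = "graphml" if str(target).endswith(".graphml") else "tsv"
    if fmt not in _GRAPH_FORMATS:
        raise ValueError(f"unknown graph format {fmt!r}; expected one of {_GRAPH_FORMATS}")
    if fmt == "graphml":
        if hasattr(target, "write"):
            buf = _stdio.BytesIO()
            nx.write_graphml(graph, buf)
            target.write(buf.getvalue().decode())
        else:
            nx.write_graphml(graph, target)
        return
    fh, close = _open(target, "w")
    try:
        fh.write("node1\tnode2\tweight\n")
        for u, v, data in graph.edges(data=True):
            fh.write(f"{u}\t{v}\t{_edge_weight(data):.17g}\n")
        # isolated nodes survive the round trip via a sentinel row
        for n in graph.nodes:
            if graph.degree(n) == 0:
                fh.write(f"{n}\t{n}\t0\n")
    finally:
        if close:
            fh.close()


def read_graph(source: str | PathLike | TextIO, fmt: str | None = None) -> nx.Graph:
    """Read a graph written by :func:`write_graph`."""
    if fmt is None:
        fmt = "graphml" if str(source).endswith(".graphml") else "tsv"
    if fmt not in _GRAPH_FORMATS:
        raise ValueError(f"unknown graph format {fmt!r}; expected one of {_GRAPH_FORMATS}")
    if fmt == "graphml":
        return nx.read_graphml(source)
    fh, close = _open(source)
    try:
        g = nx.Graph()
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        for row in reader:
            if not row:
                continue
            u, v, w = row[0], row[1], float(row[2])
            if u == v:
                g.add_node(u)
            else:
                g.add_edge(u, v, weight=w)
    finally:
        if close:
            fh.close()
    return g
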