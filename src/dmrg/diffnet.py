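"""Statistics-based differential co-expression network (S-DN).

For every gene pair the Spearman rank correlation (SPCC) is computed
separately in the tumour and normal conditions. A pair enters the
differential network when the absolute difference of the two condition
correlations,

    dPCC(g1, g2) = | PCC_T(g1, g2) - PCC_N(g1, g2) |,

strictly exceeds the threshold ``tau`` (default 0.8); the edge then carries
``w_dn = dPCC``. dPCC lies in [0, 2]; a pair whose correlation is undefined in
either condition (a gene constant within that condition) is excluded rather
than imputed, since an imputed correlation would fabricate a dPCC.

Spearman is computed as the Pearson correlation of mid-rank (average-rank)
transformed vectors, the standard tie-handling estimator; it is invariant to
monotone transforms of the expression scale, which is why it is preferred over
plain Pearson on raw intensities here.

All O(p^2) gene pairs are scanned; no variance pre-filter is applied. The
``restrict_to`` option can bound cost by keeping only genes present in a
given collection (e.g. the PPI node set); it is off by default.
"""

from __future__ import annotations

from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .types import NORMAL, TUMOR, ExpressionMatrix

MIN_SAMPLES = 3  # a rank correlation on fewer points is not informative


def spearman(x, y) -> float:
    """Spearman rank correlation of two equal-length vectors.

    Returns ``nan`` (the "undefined" flag) if either vector is constant;
    downstream edge construction treats undefined correlations as no edge.

    Raises
    ------
    ValueError
        If the vectors differ in length or have fewer than 3 entries.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < MIN_SAMPLES:
        raise ValueError(f"need at least {MIN_SAMPLES} observations, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    rx = rankdata(x)
    ry = rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def _rank_correlation_matrix(values: np.ndarray) -> np.ndarray:
    """Gene x gene Spearman matrix for a genes x samples array.

    Rows constant across samples yield ``nan`` off-diagonal entries (the
    undefined flag); the diagonal is forced to 1.
    """
    ranks = rankdata(values, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(ranks)
    corr = np.atleast_2d(corr)
    np.fill_diagonal(corr, 1.0)
    return corr


def condition_correlations(expr: ExpressionMatrix) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-condition gene x gene Spearman matrices ``(tumor, normal)``.

    Both matrices are symmetric with unit diagonal; entries involving a gene
    constant within that condition are ``nan``.

    Raises
    ------
    ValueError
        If a condition has fewer than 3 samples (named in the message).
    """
    for cond in (TUMOR, NORMAL):
        n = len(expr.samples_in(cond))
        if n < MIN_SAMPLES:
            raise ValueError(
                f"condition {cond!r} has {n} samples; need at least {MIN_SAMPLES}"
            )
    genes = expr.gene_ids
    ct = _rank_correlation_matrix(expr.values_in(TUMOR))
    cn = _rank_correlation_matrix(expr.values_in(NORMAL))
    return (
        pd.DataFrame(ct, index=genes, columns=genes),
        pd.DataFrame(cn, index=genes, columns=genes),
    )


def dn_from_correlations(
    pcc_t: pd.DataFrame,
    pcc_n: pd.DataFrame,
    tau: float = 0.8,
) -> nx.Graph:
    """Build the differential network from precomputed condition correlations.

    An edge (g1, g2) is present iff both correlations are defined and
    ``|PCC_T - PCC_N| > tau`` (strict inequality: a pair sitting exactly at
    the threshold gets no edge). Edge attributes: ``w_dn``, ``pcc_t``,
    ``pcc_n``. Every gene appears as a node, edge-bearing or not.
    """
    if not (0.0 <= tau < 2.0):
        raise ValueError(f"tau must be in [0, 2), got {tau}")
    genes = list(pcc_t.index)
    if list(pcc_n.index) != genes or list(pcc_t.columns) != genes:
        raise ValueError("correlation matrices must share the same gene ordering")
    ct = pcc_t.to_numpy(dtype=float)
    cn = pcc_n.to_numpy(dtype=float)
    delta = np.abs(ct - cn)
    iu, ju = np.triu_indices(len(genes), k=1)
    defined = np.isfinite(ct[iu, ju]) & np.isfinite(cn[iu, ju])
    hit = defined & (delta[iu, ju] > tau)

    dn = nx.Graph(tau=float(tau))
    dn.add_nodes_from(genes)
    for i, j in zip(iu[hit], ju[hit]):
        dn.add_edge(
            genes[i],
            genes[j],
            w_dn=float(delta[i, j]),
            pcc_t=float(ct[i, j]),
            pcc_n=float(cn[i, j]),
        )
    return dn


def build_dn(
    expr: ExpressionMatrix,
    tau: float = 0.8,
    *,
    restrict_to: Iterable[str] | None = None,
) -> nx.Graph:
    """Differential network of an expression matrix at threshold ``tau``.

    Computes the two condition-wise Spearman matrices and applies the strict
    dPCC threshold pairwise. ``restrict_to`` optionally limits the scan to the
    given genes (intersected with the matrix) to bound the O(p^2) cost.
    """
    if not (0.0 <= tau < 2.0):
        raise ValueError(f"tau must be in [0, 2), got {tau}")
    if restrict_to is not None:
        keep = [g for g in expr.gene_ids if g in set(restrict_to)]
        expr = ExpressionMatrix(
            values=expr.values.loc[keep],
            condition=expr.condition,
            pair_id=expr.pair_id,
        )
    pcc_t, pcc_n = condition_correlations(expr)
    return dn_from_correlations(pcc_t, pcc_n, tau=tau)
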