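"""Ego (first-neighbour) subnetworks, gene-set overlap, protein-RNA overlay.

A seed gene's subnetwork is the seed plus its W-K-DN neighbours with the
seed's incident edges (non-induced by default; induced mode also keeps
neighbour-neighbour fused edges). Neighbours can be annotated against any
number of gene sets (differentially expressed genes, disease genes, ...),
reporting per-set intersections and the genes common to all sets. A
protein-RNA interaction list can be overlaid as a second, bipartite edge
type, turning the subnetwork into a mixed protein/RNA view.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .types import ExpressionMatrix, GeneSet

ROLE_PROTEIN = "protein"
ROLE_RNA = "rna"
EDGE_PPI_DN = "ppi_dn"
EDGE_PROTEIN_RNA = "protein_rna"


def first_neighbor_subnetwork(
    wkdn: nx.Graph, seed: str, induced: bool = False
) -> nx.Graph:
    """Extract the first-neighbour subnetwork of ``seed`` from the W-K-DN.

    Non-induced (default): nodes are the seed and its neighbours, edges the
    seed's incident edges only. Induced: neighbour-neighbour W-K-DN edges are
    kept as well. All nodes get ``role="protein"``; edges are typed
    ``ppi_dn`` with their fused weights carried over.
    """
    if seed not in wkdn:
        raise KeyError(f"unknown seed gene: {seed!r}")
    nodes = {seed} | set(wkdn.neighbors(seed))
    sub = nx.Graph(seed=seed, induced=bool(induced), rna_pairs_ignored=0)
    for n in sorted(nodes):
        sub.add_node(n, role=ROLE_PROTEIN)
    if induced:
        edge_iter = ((u, v, wkdn[u][v]) for u, v in wkdn.subgraph(nodes).edges)
    else:
        edge_iter = ((seed, v, wkdn[seed][v]) for v in wkdn.neighbors(seed))
    for u, v, data in edge_iter:
        sub.add_edge(u, v, kind=EDGE_PPI_DN, **{k: data[k] for k in data})
    return sub


def neighbors_of_seed(sub: nx.Graph) -> set[str]:
    """The seed's protein neighbours within a subnetwork (seed excluded)."""
    seed = sub.graph["seed"]
    return {
        n
        for n in sub.nodes
        if n != seed and sub.nodes[n].get("role") == ROLE_PROTEIN
    }


def annotate_overlap(sub: nx.Graph, sets: Sequence[GeneSet]) -> dict:
    """Overlap of the seed's neighbours with each gene set.

    Returns ``{"per_set": {name: {"count", "members"}}, "all_sets": {...}}``
    where ``all_sets`` is the genes lying in *every* provided set (e.g.
    "differentially expressed AND disease-related"), an empty universe when
    no sets are given.
    """
    neigh = neighbors_of_seed(sub)
    per_set = {}
    common: set[str] | None = None
    for gs in sets:
        inter = neigh & gs.members
        per_set[gs.name] = {"count": len(inter), "members": sorted(inter)}
        common = inter if common is None else (common & inter)
    common = common if common is not None else set()
    return {
        "per_set": per_set,
        "all_sets": {"count": len(common), "members": sorted(common)},
    }


def overlay_protein_rna(
    sub: nx.Graph, rna_edges: Iterable[tuple[str, str]]
) -> nx.Graph:
    """Overlay protein-RNA interaction pairs on a subnetwork (idempotent).

    For each ``(protein, rna)`` pair whose protein is already a node, the RNA
    node is added with ``role="rna"`` (namespaced as ``rna:<id>`` if the raw
    id collides with a protein node, keeping the bipartite edge invariant)
    plus an unweighted ``protein_rna`` edge. Pairs whose protein is absent
    are ignored and counted in ``graph["rna_pairs_ignored"]``.
    """
    out = sub.copy()
    ignored = 0
    for protein, rna in rna_edges:
        if protein not in out or out.nodes[protein].get("role") != ROLE_PROTEIN:
            ignored += 1
            continue
        rna_id = rna
        if rna_id in out and out.nodes[rna_id].get("role") != ROLE_RNA:
            rna_id = f"rna:{rna}"
        if rna_id not in out:
            out.add_node(rna_id, role=ROLE_RNA)
        if not out.has_edge(protein, rna_id):
            out.add_edge(protein, rna_id, kind=EDGE_PROTEIN_RNA)
    out.graph["rna_pairs_ignored"] = ignored
    return out


def gene_metabolite_correlation(
    expr: ExpressionMatrix,
    metabolites,
    genes: Sequence[str],
) -> pd.DataFrame:
    """Gene x metabolite Spearman correlations over the shared samples.

    ``metabolites`` is a metabolite x sample table (DataFrame or
    ExpressionMatrix); only samples present in both tables, in the expression
    matrix's order, are used. Entries involving a constant vector are ``nan``
    (undefined). Fewer than 3 shared samples is a hard error.
    """
    met = metabolites.values if isinstance(metabolites, ExpressionMatrix) else metabolites
    shared = [s for s in expr.sample_ids if s in met.columns]
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared samples; need at least 3")
    missing = [g for g in genes if g not in expr.values.index]
    if missing:
        raise KeyError(f"unknown gene: {missing[0]!r}")
    gx = expr.values.loc[list(genes), shared].to_numpy(dtype=float)
    mx = met.loc[:, shared].to_numpy(dtype=float)
    gr = rankdata(gx, axis=1)
    mr = rankdata(mx, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(gr, mr)
    block = corr[: len(genes), len(genes):]
    return pd.DataFrame(block, index=list(genes), columns=list(met.index))
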