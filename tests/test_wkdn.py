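import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from dmrg import (
    discretize_confidence,
    fuse,
    gene_auc,
    metabolic_shortlist,
    node_importance,
    rank_genes,
    GeneSet,
)
from dmrg.types import NORMAL, TUMOR

from conftest import make_expr, oracle_auc, oracle_quantile_bins


def ppi_from(conf: dict) -> nx.Graph:
    g = nx.Graph()
    for (u, v), c in conf.items():
        g.add_edge(u, v, confidence=float(c))
    return g


def dn_from(weights: dict) -> nx.Graph:
    g = nx.Graph()
    for (u, v), w in weights.items():
        g.add_edge(u, v, w_dn=float(w))
    return g


class TestDiscretize:
    def test_decile_ladder_on_ten_distinct_scores(self):
        conf = {(f"a{i}", f"b{i}"): 100 * (i + 1) for i in range(10)}
        g = discretize_confidence(ppi_from(conf), n_bins=10)
        got = sorted(
            (g.edges[e]["confidence"], g.edges[e]["w_ppi"]) for e in g.edges
        )
        assert [w for _, w in got] == pytest.approx(
            [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0]
        )

    def test_all_tied_scores_share_one_bin(self):
        g = discretize_confidence(
            ppi_from({("A", "B"): 500, ("B", "C"): 500, ("C", "D"): 500}), n_bins=10
        )
        vals = {g.edges[e]["w_ppi"] for e in g.edges}
        assert len(vals) == 1

    def test_single_edge_gets_top_weight(self):
        g = discretize_confidence(ppi_from({("A", "B"): 42}), n_bins=10)
        assert g["A"]["B"]["w_ppi"] == 1.0

    def test_matches_fraction_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            m = int(rng.integers(1, 25))
            n_bins = int(rng.integers(1, 12))
            conf = {(f"a{i}", f"b{i}"): float(rng.integers(1, 8)) for i in range(m)}
            g = discretize_confidence(ppi_from(conf), n_bins=n_bins)
            order = [(f"a{i}", f"b{i}") for i in range(m)]
            got = [g.edges[e]["w_ppi"] for e in order]
            want = oracle_quantile_bins([conf[e] for e in order], n_bins)
            assert got == pytest.approx(want, abs=1e-12)

    def test_scale_invariance_and_monotonicity(self):
        rng = np.random.default_rng(5)
        conf = {(f"a{i}", f"b{i}"): float(rng.uniform(1, 1000)) for i in range(40)}
        g1 = discretize_confidence(ppi_from(conf), n_bins=7)
        g2 = discretize_confidence(
            ppi_from({e: 7.3 * c for e, c in conf.items()}), n_bins=7
        )
        for e in conf:
            assert g1.edges[e]["w_ppi"] == g2.edges[e]["w_ppi"]
        ranked = sorted(conf, key=conf.get)
        ws = [g1.edges[e]["w_ppi"] for e in ranked]
        assert all(a <= b for a, b in zip(ws, ws[1:]))

    def test_bad_bin_count(self):
        with pytest.raises(ValueError):
            discretize_confidence(ppi_from({("A", "B"): 1}), n_bins=0)


class TestFuse:
    def test_weight_is_product(self):
        dn = dn_from({("A", "B"): 1.0})
        ppi = ppi_from({("A", "B"): 900})
        wk = fuse(dn, discretize_confidence(ppi, n_bins=2))
        assert wk["A"]["B"]["weight"] == pytest.approx(1.0 * 1.0)
        ppi2 = ppi_from({("A", "B"): 100, ("C", "D"): 900})
        wk2 = fuse(dn, discretize_confidence(ppi2, n_bins=2))
        assert wk2["A"]["B"]["weight"] == pytest.approx(0.5)

    def test_intersection_semantics(self):
        dn = dn_from({("A", "B"): 1.2, ("B", "C"): 0.9})
        ppi = discretize_confidence(ppi_from({("A", "B"): 700, ("C", "D"): 300}), 10)
        wk = fuse(dn, ppi)
        assert wk.has_edge("A", "B")
        assert not wk.has_edge("B", "C")   # dn-only
        assert not wk.has_edge("C", "D")   # ppi-only
        assert set(wk.nodes) == {"A", "B", "C"}  # dn nodes retained

    def test_undiscretized_ppi_rejected(self):
        with pytest.raises(ValueError, match="discretize"):
            fuse(dn_from({("A", "B"): 1.0}), ppi_from({("A", "B"): 900}))


class TestNodeImportance:
    def test_sum_of_incident_weights_and_isolated_zero(self):
        wk = nx.Graph()
        wk.add_edge("A", "B", weight=0.5)
        wk.add_edge("B", "C", weight=0.45)
        wk.add_node("Z")
        assert node_importance(wk, "B") == pytest.approx(0.95)
        assert node_importance(wk, "Z") == 0.0
        with pytest.raises(KeyError, match="NOPE"):
            node_importance(wk, "NOPE")

    def test_handshake_identity(self):
        rng = np.random.default_rng(9)
        g = nx.gnm_random_graph(30, 80, seed=4)
        wk = nx.Graph()
        for u, v in g.edges:
            wk.add_edge(str(u), str(v), weight=float(rng.uniform(0.01, 2.0)))
        total = sum(node_importance(wk, n) for n in wk.nodes)
        assert total == pytest.approx(
            2 * sum(d["weight"] for _, _, d in wk.edges(data=True)), rel=1e-12
        )


class TestGeneAUC:
    def test_perfect_separation(self):
        expr = make_expr({"A": [5, 6, 1, 2], "B": [0, 1, 2, 3]}, 2, 2)
        assert gene_auc(expr, "A") == 1.0

    def test_unfolded_quarter_case(self):
        # tumour [1,3] vs normal [2,4]: one concordant pair of four
        expr = make_expr({"A": [1, 3, 2, 4]}, 2, 2)
        assert gene_auc(expr, "A") == pytest.approx(0.25)

    def test_all_ties_is_half(self):
        expr = make_expr({"A": [2, 2, 2, 2]}, 2, 2)
        assert gene_auc(expr, "A") == pytest.approx(0.5)

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(21)
        for _ in range(40):
            nt, nn = int(rng.integers(1, 11)), int(rng.integers(1, 11))
            vals = list(rng.integers(0, 6, nt + nn).astype(float))
            expr = make_expr({"A": vals}, nt, nn)
            assert gene_auc(expr, "A") == pytest.approx(
                oracle_auc(vals[:nt], vals[nt:]), abs=1e-12
            )

    def test_label_permutation_mean_near_half(self):
        rng = np.random.default_rng(33)
        vals = list(rng.normal(size=48))
        aucs = []
        for _ in range(200):
            perm = rng.permutation(48)
            nt = 24
            tumor = [vals[i] for i in perm[:nt]]
            normal = [vals[i] for i in perm[nt:]]
            expr = make_expr({"A": tumor + normal}, nt, 48 - nt)
            aucs.append(gene_auc(expr, "A"))
        assert 0.45 <= np.mean(aucs) <= 0.55


class TestRankGenes:
    @staticmethod
    def _path_wkdn():
        wk = nx.Graph()
        wk.add_edge("A", "B", weight=0.9)
        wk.add_edge("B", "C", weight=0.4)
        return wk

    def test_path_graph_scores_and_order(self):
        expr = make_expr(
            {"A": [1, 2, 3, 3, 2, 1], "B": [2, 3, 1, 1, 3, 2], "C": [3, 1, 2, 2, 1, 3]},
            3, 3,
        )
        table = rank_genes(self._path_wkdn(), expr, GeneSet("enz", {"C"}))
        assert list(table["gene"]) == ["B", "A", "C"]
        assert list(table["score"]) == pytest.approx([1.3, 0.9, 0.4])
        assert list(table["rank"]) == [1, 2, 3]
        assert list(table["is_metabolic"]) == [False, False, True]

    def test_lexicographic_tie_break(self):
        wk = nx.Graph()
        wk.add_edge("B", "Z", weight=0.5)
        wk.add_edge("A", "Y", weight=0.5)
        expr = make_expr(
            {g: [1, 2, 3, 3, 2, 1] for g in "ABYZ"}, 3, 3
        )
        table = rank_genes(wk, expr, None)
        assert list(table["gene"]) == ["A", "B", "Y", "Z"]

    def test_empty_enzyme_set_leaves_ranking_intact(self):
        expr = make_expr({"A": [1, 2, 3, 3, 2, 1], "B": [2, 3, 1, 1, 3, 2],
                          "C": [3, 1, 2, 2, 1, 3]}, 3, 3)
        full = rank_genes(self._path_wkdn(), expr, GeneSet("enz", set()))
        assert metabolic_shortlist(full).empty
        assert list(full["gene"]) == ["B", "A", "C"]
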