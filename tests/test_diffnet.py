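import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dmrg import build_dn, condition_correlations, dn_from_correlations, spearman
from dmrg.types import NORMAL, TUMOR

from conftest import make_expr, oracle_dn_edges, oracle_spearman


class TestSpearman:
    def test_perfect_anti_monotone(self):
        assert spearman([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_sum_d_squared_example(self):
        # one adjacent swap among four ranks: 1 - 6*2/(4*15) = 0.8
        assert spearman([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_ties_equal_pearson_on_midranks(self):
        x, y = [1, 1, 2], [1, 2, 3]
        assert spearman(x, y) == pytest.approx(oracle_spearman(x, y), abs=1e-12)

    def test_constant_vector_flagged_undefined(self):
        assert math.isnan(spearman([5, 5, 5], [1, 2, 3]))

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            spearman([1, 2], [2, 1])

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(
        st.lists(st.integers(0, 6), min_size=3, max_size=9),
        st.data(),
    )
    def test_matches_midrank_oracle_and_is_symmetric(self, x, data):
        y = data.draw(st.lists(st.integers(0, 6), min_size=len(x), max_size=len(x)))
        got = spearman(x, y)
        want = oracle_spearman(x, y)
        if math.isnan(want):
            assert math.isnan(got)
        else:
            assert got == pytest.approx(want, abs=1e-12)
            assert got == pytest.approx(spearman(y, x), abs=1e-12)


class TestConditionCorrelations:
    def test_perfectly_correlated_pair(self):
        expr = make_expr(
            {"A": [1, 2, 3, 1, 2, 3], "B": [2, 4, 6, 2, 4, 6]}, 3, 3
        )
        ct, cn = condition_correlations(expr)
        assert np.allclose(ct.to_numpy(), 1.0)
        assert np.allclose(cn.to_numpy(), 1.0)

    def test_constant_in_one_condition_flagged_only_there(self):
        expr = make_expr(
            {"A": [7, 7, 7, 1, 2, 3], "B": [1, 2, 3, 3, 2, 1]}, 3, 3
        )
        ct, cn = condition_correlations(expr)
        assert math.isnan(ct.loc["A", "B"])
        assert cn.loc["A", "B"] == pytest.approx(-1.0)
        assert ct.loc["A", "A"] == 1.0  # unit diagonal regardless

    def test_sample_order_within_condition_irrelevant(self):
        from dmrg import ExpressionMatrix

        base = make_expr(
            {"A": [1, 3, 2, 4, 5, 6], "B": [2, 1, 3, 6, 5, 4]}, 3, 3
        )
        perm_cols = ["s2", "s0", "s1", "s5", "s3", "s4"]  # within-condition shuffle
        shuffled = ExpressionMatrix(
            values=base.values[perm_cols], condition=base.condition[perm_cols]
        )
        ct1, cn1 = condition_correlations(base)
        ct2, cn2 = condition_correlations(shuffled)
        assert np.allclose(ct1.to_numpy(), ct2.to_numpy())
        assert np.allclose(cn1.to_numpy(), cn2.to_numpy())

    def test_small_condition_named_in_error(self):
        expr = make_expr({"A": [1, 2, 3, 4, 5], "B": [5, 4, 3, 2, 1]}, 2, 3)
        with pytest.raises(ValueError, match="tumor"):
            condition_correlations(expr)


class TestBuildDN:
    def test_edge_weight_is_absolute_difference(self):
        pcc_t = pd.DataFrame([[1.0, 0.9], [0.9, 1.0]], index=list("AB"), columns=list("AB"))
        pcc_n = pd.DataFrame([[1.0, -0.2], [-0.2, 1.0]], index=list("AB"), columns=list("AB"))
        dn = dn_from_correlations(pcc_t, pcc_n, tau=0.8)
        assert dn["A"]["B"]["w_dn"] == pytest.approx(1.1)

    def test_copied_samples_give_empty_edge_set(self):
        expr = make_expr(
            {"A": [1, 2, 3, 4] * 2, "B": [4, 1, 3, 2] * 2, "C": [2, 3, 1, 4] * 2},
            4, 4,
        )
        dn = build_dn(expr, tau=0.8)
        assert dn.number_of_edges() == 0
        assert set(dn.nodes) == {"A", "B", "C"}

    def test_undefined_pairs_excluded_not_imputed(self):
        expr = make_expr(
            {"A": [7, 7, 7, 7, 1, 2, 3, 4], "B": [1, 2, 3, 4, 4, 3, 2, 1]}, 4, 4
        )
        dn = build_dn(expr, tau=0.8)  # |nan - (-1)| must not create an edge
        assert dn.number_of_edges() == 0

    def test_tau_domain_enforced(self):
        expr = make_expr({"A": [1, 2, 3, 1, 2, 3], "B": [3, 2, 1, 1, 2, 3]}, 3, 3)
        for bad in (-0.1, 2.0, 2.5):
            with pytest.raises(ValueError):
                build_dn(expr, tau=bad)

    def test_matches_bruteforce_oracle_on_small_matrices(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            p = rng.integers(2, 8)
            nt, nn = rng.integers(3, 6), rng.integers(3, 6)
            rows = {f"g{i}": list(rng.integers(0, 5, nt + nn)) for i in range(p)}
            expr = make_expr(rows, int(nt), int(nn))
            tau = float(rng.uniform(0.2, 1.2))
            dn = build_dn(expr, tau=tau)
            want = oracle_dn_edges(expr, tau)
            got = {tuple(sorted(e)): dn.edges[e]["w_dn"] for e in dn.edges}
            assert set(got) == set(want)
            for e in want:
                assert got[e] == pytest.approx(want[e], abs=1e-12)


class TestDNProperties:
    @staticmethod
    def _random_expr(rng):
        p = rng.integers(3, 7)
        nt, nn = rng.integers(3, 6), rng.integers(3, 6)
        rows = {f"g{i}": list(rng.normal(size=nt + nn)) for i in range(p)}
        return make_expr(rows, int(nt), int(nn))

    def test_threshold_monotonicity_over_many_matrices(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            expr = self._random_expr(rng)
            lo = set(map(frozenset, build_dn(expr, tau=0.4).edges))
            hi = set(map(frozenset, build_dn(expr, tau=0.9).edges))
            assert hi <= lo

    def test_condition_swap_symmetry_over_many_matrices(self):
        rng = np.random.default_rng(13)
        for _ in range(100):
            expr = self._random_expr(rng)
            swapped = expr.with_condition(
                expr.condition.map({TUMOR: NORMAL, NORMAL: TUMOR})
            )
            a = build_dn(expr, tau=0.6)
            b = build_dn(swapped, tau=0.6)
            assert set(map(frozenset, a.edges)) == set(map(frozenset, b.edges))
            for u, v in a.edges:
                assert a[u][v]["w_dn"] == pytest.approx(b[u][v]["w_dn"], abs=1e-12)
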