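"""Shared fixtures and independent brute-force oracles.

The oracle functions here re-derive the statistics from first principles
(hand rank transforms, exhaustive pair enumeration, Fraction arithmetic) and
are deliberately independent of the package's implementation paths.
"""

from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from dmrg import ExpressionMatrix, NORMAL, TUMOR


def make_expr(gene_rows: dict, n_tumor: int, n_normal: int) -> ExpressionMatrix:
    """Build an ExpressionMatrix from {gene: list-of-values} row dicts.

    The first ``n_tumor`` columns are tumour samples, the rest normal.
    """
    values = pd.DataFrame(
        {f"s{i}": [gene_rows[g][i] for g in gene_rows] for i in range(n_tumor + n_normal)},
        index=list(gene_rows),
        dtype=float,
    )
    condition = pd.Series(
        [TUMOR] * n_tumor + [NORMAL] * n_normal, index=values.columns
    )
    return ExpressionMatrix(values=values, condition=condition)


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def oracle_midranks(x):
    """Average (mid) ranks computed by counting, not by library call."""
    x = list(x)
    ranks = []
    for xi in x:
        less = sum(1 for xj in x if xj < xi)
        ties = sum(1 for xj in x if xj == xi)
        ranks.append(less + (ties + 1) / 2.0)
    return ranks


def oracle_spearman(x, y):
    """Pearson correlation of hand-computed mid-ranks."""
    rx = np.array(oracle_midranks(x))
    ry = np.array(oracle_midranks(y))
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx * rx).sum() * (ry * ry).sum())
    if denom == 0:
        return float("nan")
    return float((rx * ry).sum() / denom)


def oracle_spearman_no_ties(x, y):
    """Classic 1 - 6*sum(d^2)/(n(n^2-1)) formula; valid only without ties."""
    rx = oracle_midranks(x)
    ry = oracle_midranks(y)
    n = len(x)
    d2 = sum((a - b) ** 2 for a, b in zip(rx, ry))
    return 1.0 - 6.0 * d2 / (n * (n * n - 1))


def oracle_auc(tumor, normal):
    """Exhaustive Mann-Whitney pair enumeration, ties count one half."""
    wins = sum(
        1.0 if t > n else (0.5 if t == n else 0.0) for t in tumor for n in normal
    )
    return wins / (len(tumor) * len(normal))


def oracle_quantile_bins(confidences, n_bins):
    """Expected w_ppi values via exact Fraction mid-rank quantile binning."""
    m = len(confidences)
    ranks = oracle_midranks(confidences)
    out = []
    for r in ranks:
        frac = Fraction(r).limit_denominator(2) * n_bins / m
        b = int(frac) if frac == int(frac) else int(frac) + 1  # ceil
        out.append(Fraction(b, n_bins))
    return [float(v) for v in out]


def oracle_dn_edges(expr: ExpressionMatrix, tau: float):
    """Pairwise Eq.-style scan using the hand-rank Spearman oracle."""
    genes = expr.gene_ids
    xt = expr.values_in(TUMOR)
    xn = expr.values_in(NORMAL)
    edges = {}
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            ct = oracle_spearman(xt[i], xt[j])
            cn = oracle_spearman(xn[i], xn[j])
            if np.isnan(ct) or np.isnan(cn):
                continue
            delta = abs(ct - cn)
            if delta > tau:
                edges[(genes[i], genes[j])] = delta
    return edges


@pytest.fixture
def toy_expr():
    """4 genes x (4 tumour + 4 normal): a pair that flips sign, plus noise."""
    return make_expr(
        {
            "A": [1, 2, 3, 4, 1, 2, 3, 4],
            "B": [4, 3, 2, 1, 1, 2, 3, 4],   # anti in tumour, perfect in normal
            "C": [2, 1, 4, 3, 4, 2, 3, 1],
            "D": [1, 3, 2, 4, 2, 4, 1, 3],
        },
        n_tumor=4,
        n_normal=4,
    )
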