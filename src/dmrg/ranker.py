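"""scikit-learn style estimator wrapping the full ranking pipeline.

:class:`DMRGRanker` is a feature-scoring transformer: ``fit(X, y, ppi=...)``
builds the differential network from the samples x genes matrix ``X`` and
condition labels ``y``, discretizes the PPI confidences, fuses the two
networks and scores every gene by weighted degree centrality; ``transform``
then selects the top-ranked gene columns, so the estimator composes with
sklearn pipelines and model selection.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from . import diffnet, wkdn
from .types import CONDITIONS, NORMAL, TUMOR, ExpressionMatrix, GeneSet


def _as_condition_series(y, sample_ids) -> pd.Series:
    y = np.asarray(y).ravel()
    labels = set(pd.unique(y))
    if labels <= set(CONDITIONS):
        cond = [str(v) for v in y]
    elif labels <= {0, 1} or labels <= {False, True}:
        cond = [TUMOR if v else NORMAL for v in y]
    else:
        raise ValueError(
            f"labels must be {CONDITIONS} or binary 0/1 (1 = tumor); got {sorted(map(str, labels))}"
        )
    return pd.Series(cond, index=sample_ids)


class DMRGRanker(BaseEstimator, TransformerMixin):
    """Rank genes by differential-network weighted degree centrality.

    Parameters
    ----------
    tau : float, default 0.8
        Strict threshold on the absolute difference of the per-condition
        Spearman correlations; a gene pair enters the differential network
        only when |PCC_T - PCC_N| > tau.
    n_bins : int, default 10
        Quantile bins for discretizing PPI confidences into w_ppi in (0, 1].
    top_k : int or None, default None
        Number of top-ranked genes kept by :meth:`transform`; ``None`` keeps
        every gene with a positive score.

    Attributes
    ----------
    ranking_ : pandas.DataFrame
        Gene score table (gene, score, auc, rank, is_metabolic), sorted by
        descending score with lexicographic tie-breaking.
    scores_ : ndarray of shape (n_features,)
        Importance score per input gene column.
    auc_ : ndarray of shape (n_features,)
        Unfolded per-gene ROC AUC for the tumour label.
    diffnet_, wkdn_ : networkx.Graph
        The thresholded differential network and the fused W-K-DN.
    """

    def __init__(self, tau: float = 0.8, n_bins: int = 10, top_k: int | None = None):
        self.tau = tau
        self.n_bins = n_bins
        self.top_k = top_k

    # ------------------------------------------------------------------
    def fit(self, X, y, *, ppi, enzymes: GeneSet | None = None, gene_ids=None):
        """Fit from a samples x genes matrix, condition labels and a PPI.

        ``ppi`` is a confidence-scored :class:`networkx.Graph` (raw STRING
        scale or 0-1; discretization is rank-based). ``gene_ids`` names the
        columns of an array ``X``; a DataFrame's columns are used directly.
        """
        if isinstance(X, pd.DataFrame):
            genes = [str(c) for c in X.columns]
            samples = [str(i) for i in X.index]
            values = X.to_numpy(dtype=float)
        else:
            values = np.asarray(X, dtype=float)
            if values.ndim != 2:
                raise ValueError("X must be 2-D (samples x genes)")
            genes = (
                [str(g) for g in gene_ids]
                if gene_ids is not None
                else [f"g{i}" for i in range(values.shape[1])]
            )
            samples = [f"s{i}" for i in range(values.shape[0])]
        if len(genes) != values.shape[1]:
            raise ValueError("gene_ids length does not match X")
        expr = ExpressionMatrix(
            values=pd.DataFrame(values.T, index=genes, columns=samples),
            condition=_as_condition_series(y, samples),
        )

        self.diffnet_ = diffnet.build_dn(expr, tau=self.tau)
        ppi_d = wkdn.discretize_confidence(ppi, n_bins=self.n_bins)
        self.wkdn_ = wkdn.fuse(self.diffnet_, ppi_d)
        self.ranking_ = wkdn.rank_genes(self.wkdn_, expr, enzymes)

        order = self.ranking_.set_index("gene")
        self.gene_ids_ = list(genes)
        self.scores_ = order.loc[genes, "score"].to_numpy(dtype=float)
        self.auc_ = order.loc[genes, "auc"].to_numpy(dtype=float)
        self.ranks_ = order.loc[genes, "rank"].to_numpy(dtype=int)
        self.n_features_in_ = len(genes)
        return self

    # ------------------------------------------------------------------
    def get_support(self, indices: bool = False):
        """Mask (or indices) of the gene columns kept by :meth:`transform`."""
        check_is_fitted(self, "scores_")
        if self.top_k is None:
            mask = self.scores_ > 0
        else:
            mask = self.ranks_ <= int(self.top_k)
        return np.where(mask)[0] if indices else mask

    def transform(self, X):
        """Restrict a samples x genes matrix to the selected gene columns."""
        check_is_fitted(self, "scores_")
        values = X.to_numpy() if isinstance(X, pd.DataFrame) else np.asarray(X)
        if values.ndim != 2 or values.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {values.shape[-1] if values.ndim else 0} features; "
                f"expected {self.n_features_in_}"
            )
        return values[:, self.get_support()]

    def metabolic_shortlist(self, k: int | None = None) -> pd.DataFrame:
        """Ranking restricted to metabolic-enzyme members (top ``k``)."""
        check_is_fitted(self, "ranking_")
        return wkdn.metabolic_shortlist(self.ranking_, k)


def rank_genes_dmrg(
    expr: ExpressionMatrix,
    ppi,
    enzymes: GeneSet | None = None,
    tau: float = 0.8,
    n_bins: int = 10,
) -> tuple[pd.DataFrame, "DMRGRanker"]:
    """Thin functional wrapper: run the full ranking on an ExpressionMatrix."""
    ranker = DMRGRanker(tau=tau, n_bins=n_bins)
    ranker.fit(
        expr.values.to_numpy(dtype=float).T,
        expr.condition.to_numpy(),
        ppi=ppi,
        enzymes=enzymes,
        gene_ids=expr.gene_ids,
    )
    return ranker.ranking_, ranker
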