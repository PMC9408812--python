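"""Core in-memory containers: condition-labelled expression matrices and gene sets.

An :class:`ExpressionMatrix` holds a genes x samples real matrix together with a
per-sample condition label (``tumor`` / ``normal``) and an optional pairing key
for paired tissue designs. It is the substrate for the per-condition Spearman
correlations and the per-gene ROC AUC; the pairing key is carried through for
reporting but the differential-network statistics are condition-wise only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TUMOR = "tumor"
NORMAL = "normal"
CONDITIONS = (TUMOR, NORMAL)


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with per-sample condition labels.

    Parameters
    ----------
    values : pandas.DataFrame
        Real matrix with gene identifiers as the index and sample identifiers
        as the columns. No missing entries are allowed (the readers apply the
        missing-data policy before construction).
    condition : pandas.Series
        Label per sample, values in ``{"tumor", "normal"}``, indexed like the
        columns of ``values``.
    pair_id : pandas.Series, optional
        Pairing key per sample for paired designs (e.g. tumour/normal tissue
        from the same patient). Carried, never used by the statistics.
    """

    values: pd.DataFrame
    condition: pd.Series
    pair_id: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate gene id: {dup!r}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id: {dup!r}")
        if len(self.values.index) == 0:
            raise ValueError("no genes")
        self.condition = self.condition.reindex(self.values.columns)
        if self.condition.isna().any():
            missing = self.condition.index[self.condition.isna()][0]
            raise ValueError(f"sample {missing!r} has no condition label")
        bad = set(self.condition.unique()) - set(CONDITIONS)
        if bad:
            raise ValueError(
                f"unknown condition label(s) {sorted(bad)!r}; expected {CONDITIONS}"
            )
        vals = self.values.to_numpy()
        if not np.isfinite(vals).all():
            raise ValueError("expression values contain missing/non-finite entries")
        if self.pair_id is not None:
            self.pair_id = self.pair_id.reindex(self.values.columns)

    # -- identifiers ---------------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    # -- condition access ----------------------------------------------------
    def samples_in(self, condition: str) -> list[str]:
        """Sample ids carrying the given condition label, in column order."""
        mask = (self.condition == condition).to_numpy()
        return [s for s, m in zip(self.values.columns, mask) if m]

    def values_in(self, condition: str) -> np.ndarray:
        """Genes x samples array restricted to one condition."""
        return self.values.loc[:, self.samples_in(condition)].to_numpy(dtype=float)

    def require_both_conditions(self, min_per_condition: int = 1) -> None:
        """Raise if either condition has fewer than ``min_per_condition`` samples."""
        for cond in CONDITIONS:
            n = len(self.samples_in(cond))
            if n < min_per_condition:
                raise ValueError(
                    f"condition {cond!r} has {n} samples; "
                    f"need at least {min_per_condition}"
                )

    def with_condition(self, condition: pd.Series) -> "ExpressionMatrix":
        """Copy with a replacement condition labelling (e.g. a permutation)."""
        return ExpressionMatrix(
            values=self.values, condition=condition, pair_id=self.pair_id
        )


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene identifiers (metabolic enzymes, DE genes, ...)."""

    name: str
    members: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("gene set name must be non-empty")
        object.__setattr__(self, "members", frozenset(self.members))

    def __contains__(self, gene: str) -> bool:
        return gene in self.members

    def __len__(self) -> int:
        return len(self.members)
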