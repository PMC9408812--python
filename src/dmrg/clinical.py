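"""Per-group high-expression proportion summaries (e.g. by Gleason score)."""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from os import PathLike
from typing import Iterable, Sequence

import pandas as pd


@dataclass(frozen=True)
class GroupCounts:
    """Count of high-scoring samples within one clinical group."""

    group: str
    n_high: int
    n_total: int

    def __post_init__(self) -> None:
        if self.n_total < 1:
            raise ValueError(f"group {self.group!r}: n_total must be >= 1")
        if not (0 <= self.n_high <= self.n_total):
            raise ValueError(
                f"group {self.group!r}: need 0 <= n_high <= n_total, "
                f"got {self.n_high}/{self.n_total}"
            )


def percentage(n_high: int, n_total: int) -> float:
    """100 * n_high / n_total, rounded half-up to one decimal place."""
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    pct = Decimal(100) * Decimal(n_high) / Decimal(n_total)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def group_proportions(counts: Sequence[GroupCounts]) -> pd.DataFrame:
    """Percentage of high-scoring samples per group, one decimal place."""
    rows = [
        {
            "group": c.group,
            "n_high": c.n_high,
            "n_total": c.n_total,
            "pct_high": percentage(c.n_high, c.n_total),
        }
        for c in counts
    ]
    return pd.DataFrame(rows, columns=["group", "n_high", "n_total", "pct_high"])


def read_group_counts(source: str | PathLike) -> list[GroupCounts]:
    """Read a ``group  n_high  n_total`` table (TSV/CSV, header optional)."""
    df = pd.read_csv(source, sep=None, engine="python", header=None, comment="#")
    if df.shape[1] < 3:
        raise ValueError("counts table needs columns: group, n_high, n_total")
    first = df.iloc[0]
    try:
        int(first[1]), int(first[2])
    except (ValueError, TypeError):
        df = df.iloc[1:]
    return [
        GroupCounts(group=str(r[0]), n_high=int(r[1]), n_total=int(r[2]))
        for r in df.itertuples(index=False)
    ]
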