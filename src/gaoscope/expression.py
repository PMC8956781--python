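"""Metatranscriptome fold changes versus a baseline timepoint.

Fold change is a plain ratio of relative transcript abundance to the
abundance at the baseline (first timepoint by default).  Tiers follow
the strict "more than" convention: >4-fold, >2-fold (but <=4), or
down/flat.  A gene with zero baseline abundance is not quantifiable —
no pseudo-count is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

TIER_DOWN_OR_FLAT = "down_or_flat"
TIER_GT2 = "gt2"
TIER_GT4 = "gt4"

_TIER_ORDER = {TIER_DOWN_OR_FLAT: 0, TIER_GT2: 1, TIER_GT4: 2}


class UndefinedBaselineError(ValueError):
    """The baseline abundance is zero, so fold change is undefined."""


@dataclass
class ExpressionSeries:
    gene: str
    abundance: pd.Series  # index = timepoints, strictly increasing

    def __post_init__(self) -> None:
        t = self.abundance.index.to_numpy()
        if len(t) and not (t[1:] > t[:-1]).all():
            raise ValueError(f"timepoints for {self.gene!r} must be strictly increasing")
        if (self.abundance < 0).any():
            raise ValueError(f"negative abundance for {self.gene!r}")


@dataclass
class FoldChangeResult:
    gene: str
    fold_change: pd.Series  # index = timepoints
    tier: pd.Series

    @property
    def max_tier(self) -> str:
        return max(self.tier, key=_TIER_ORDER.__getitem__)


def classify_tier(fc: float) -> str:
    if fc < 0:
        raise ValueError("fold change cannot be negative")
    if fc > 4:
        return TIER_GT4
    if fc > 2:
        return TIER_GT2
    return TIER_DOWN_OR_FLAT


def fold_change(series: ExpressionSeries, baseline=None) -> FoldChangeResult:
    """Per-timepoint abundance ratio to the baseline timepoint.

    ``baseline`` defaults to the first timepoint; it must carry nonzero
    abundance.
    """
    if baseline is None:
        baseline = series.abundance.index[0]
    if baseline not in series.abundance.index:
        raise KeyError(f"baseline timepoint {baseline!r} not in series")
    base = series.abundance.loc[baseline]
    if base <= 0:
        raise UndefinedBaselineError(
            f"gene {series.gene!r} has zero abundance at baseline {baseline!r}"
        )
    fc = series.abundance / base
    tiers = fc.map(classify_tier)
    return FoldChangeResult(gene=series.gene, fold_change=fc, tier=tiers)


def read_expression(source: str | Path) -> dict[str, ExpressionSeries]:
    """Read a ``gene<TAB>timepoint<TAB>abundance`` TSV into series per gene."""
    df = pd.read_csv(
        source, sep="\t", header=None, names=["gene", "timepoint", "abundance"],
        comment="#",
    )
    out = {}
    for gene, sub in df.groupby("gene", sort=False):
        sub = sub.sort_values("timepoint")
        out[gene] = ExpressionSeries(
            gene=gene, abundance=sub.set_index("timepoint")["abundance"]
        )
    return out


def fold_change_table(
    series_by_gene: dict[str, ExpressionSeries], baseline=None
) -> pd.DataFrame:
    """Tidy fold-change table; zero-baseline genes flagged, not errored."""
    rows = []
    for gene, series in series_by_gene.items():
        try:
            res = fold_change(series, baseline)
        except UndefinedBaselineError:
            for t in series.abundance.index:
                rows.append(
                    {"gene": gene, "timepoint": t, "fold_change": float("nan"),
                     "tier": "not_quantifiable"}
                )
            continue
        for t in res.fold_change.index:
            rows.append(
                {"gene": gene, "timepoint": t,
                 "fold_change": float(res.fold_change.loc[t]),
                 "tier": res.tier.loc[t]}
            )
    return pd.DataFrame(rows)
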