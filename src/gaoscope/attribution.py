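"""Gene-source attribution: which genera carry each functional gene.

A unigene that carries both a KO assignment and a taxonomic assignment
attributes that KO to its taxon — co-location on the same unigene is
the evidence of contribution.  Contributions are aggregated at a chosen
rank (genus by default); assignments below the rank roll up via the
lineage, assignments above it (or unassigned) fall into an explicit
``unassigned`` bucket so that shares always total 100%.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .annotation import UNASSIGNED, UnigeneAnnotations
from .taxonomy import TaxonomyTree


@dataclass
class HostRanking:
    ko_id: str
    # list of (genus_taxon_id, mean_share_percent), non-increasing
    hosts: list[tuple[str, float]]


def _rank_of(tree: TaxonomyTree, taxon_id: str, rank: str) -> str:
    if taxon_id == UNASSIGNED or taxon_id not in tree:
        return UNASSIGNED
    ancestor = tree.rank_ancestor(taxon_id, rank)
    return ancestor if ancestor is not None else UNASSIGNED


def attribute(
    annotations: UnigeneAnnotations, tree: TaxonomyTree, rank: str = "genus"
) -> pd.DataFrame:
    """Per (sample, ko, genus) abundance and share of that KO's total.

    Returns a tidy frame with columns ``sample``, ``ko_id``,
    ``genus_taxon_id`` (or the chosen rank; ``unassigned`` bucket
    included), ``abundance`` and ``share_percent``.  Shares within one
    (sample, ko) group sum to 100.
    """
    assign = annotations.assignments
    with_ko = assign[assign["ko_id"] != UNASSIGNED]
    if with_ko.empty:
        return pd.DataFrame(
            columns=["sample", "ko_id", "genus_taxon_id", "abundance", "share_percent"]
        )
    genus = with_ko["taxon_id"].map(lambda t: _rank_of(tree, t, rank))
    ab = annotations.abundance.loc[with_ko.index]
    long = ab.copy()
    long["ko_id"] = with_ko["ko_id"]
    long["genus_taxon_id"] = genus
    tidy = long.melt(
        id_vars=["ko_id", "genus_taxon_id"], var_name="sample", value_name="abundance"
    )
    grouped = (
        tidy.groupby(["sample", "ko_id", "genus_taxon_id"], as_index=False)["abundance"]
        .sum()
    )
    totals = grouped.groupby(["sample", "ko_id"])["abundance"].transform("sum")
    grouped["share_percent"] = 100.0 * grouped["abundance"] / totals
    return grouped[["sample", "ko_id", "genus_taxon_id", "abundance", "share_percent"]]


def top_hosts(table: pd.DataFrame, ko_id: str, n: int = 5) -> HostRanking:
    """Top-``n`` host genera of a KO by mean share across samples.

    Ties break by total abundance, then by genus id.  The
    ``unassigned`` bucket never ranks.
    """
    sub = table[(table["ko_id"] == ko_id) & (table["genus_taxon_id"] != UNASSIGNED)]
    if table[table["ko_id"] == ko_id].empty:
        raise KeyError(f"KO {ko_id!r} not present in contribution table")
    if sub.empty:
        return HostRanking(ko_id=ko_id, hosts=[])
    n_samples = table.loc[table["ko_id"] == ko_id, "sample"].nunique()
    agg = sub.groupby("genus_taxon_id").agg(
        total_share=("share_percent", "sum"), total_abundance=("abundance", "sum")
    )
    # mean over all samples: a genus absent from a sample contributes 0
    agg["mean_share"] = agg["total_share"] / n_samples
    ordered = agg.sort_values(
        by=["mean_share", "total_abundance", "genus_taxon_id"],
        ascending=[False, False, True],
        kind="mergesort",
    )
    hosts = [(gid, float(row.mean_share)) for gid, row in ordered.head(n).iterrows()]
    return HostRanking(ko_id=ko_id, hosts=hosts)


def genus_profile(
    annotations: UnigeneAnnotations, tree: TaxonomyTree, rank: str = "genus"
) -> pd.DataFrame:
    """Per-sample community composition at the chosen rank.

    Rows are genera (plus the ``unassigned`` bucket), columns are
    samples; every column sums to one because abundances do.
    """
    genus = annotations.assignments["taxon_id"].map(lambda t: _rank_of(tree, t, rank))
    return annotations.abundance.groupby(genus).sum().rename_axis("genus_taxon_id")
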