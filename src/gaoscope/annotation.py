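"""Alignment-hit parsing, taxonomic and functional assignment, abundance.

Taxonomy assignment follows the filtered-LCA convention of metagenome
catalogue pipelines: discard hits above an e-value cutoff (default
1e-5), keep only hits whose e-value lies within a multiplicative window
(default x10) of the best surviving e-value, map the retained subjects
to taxa, and assign the lowest common ancestor of that taxon set.
Function assignment takes the single best hit (bitscore, then e-value,
then subject id) among hits passing the same cutoff.

Relative abundance is length-normalised: reads/length per unigene,
renormalised to sum to one per sample.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .taxonomy import TaxonomyTree

logger = logging.getLogger(__name__)

DEFAULT_EVALUE_CUTOFF = 1e-5
DEFAULT_LCA_FACTOR = 10.0

UNASSIGNED = "unassigned"

HIT_COLUMNS = (
    "query_id",
    "subject_id",
    "percent_identity",
    "align_len",
    "mismatches",
    "gap_opens",
    "q_start",
    "q_end",
    "s_start",
    "s_end",
    "evalue",
    "bitscore",
)


class HitParseError(ValueError):
    """Malformed row in a 12-column tabular alignment file."""


@dataclass(frozen=True)
class AlignmentHit:
    query_id: str
    subject_id: str
    percent_identity: float
    align_len: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise HitParseError(f"negative evalue for query {self.query_id!r}")
        if not 0 <= self.percent_identity <= 100:
            raise HitParseError(f"percent identity out of range for {self.query_id!r}")
        if self.q_start > self.q_end:
            raise HitParseError(f"q_start > q_end for {self.query_id!r}")


@dataclass
class UnigeneAnnotations:
    """Per-unigene taxon/KO assignments plus per-sample relative abundance.

    ``assignments`` is indexed by unigene id with columns ``taxon_id``,
    ``ko_id`` and ``length``; ``abundance`` shares the index and has one
    column per sample, each summing to one.
    """

    assignments: pd.DataFrame
    abundance: pd.DataFrame

    @property
    def samples(self) -> list[str]:
        return list(self.abundance.columns)


def read_hit_table(source: str | Path | io.TextIOBase) -> dict[str, list[AlignmentHit]]:
    """Parse a 12-column tabular alignment file, grouped by query id.

    ``#``-prefixed comment lines and blank lines are ignored.  Malformed
    rows raise :class:`HitParseError` carrying the line number.
    """
    if isinstance(source, (str, Path)):
        with open(source, "rt", encoding="utf-8") as fh:
            return read_hit_table(fh)
    grouped: dict[str, list[AlignmentHit]] = {}
    for lineno, raw in enumerate(source, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 12:
            raise HitParseError(f"line {lineno}: expected 12 columns, got {len(fields)}")
        try:
            hit = AlignmentHit(
                query_id=fields[0],
                subject_id=fields[1],
                percent_identity=float(fields[2]),
                align_len=int(fields[3]),
                mismatches=int(fields[4]),
                gap_opens=int(fields[5]),
                q_start=int(fields[6]),
                q_end=int(fields[7]),
                s_start=int(fields[8]),
                s_end=int(fields[9]),
                evalue=float(fields[10]),
                bitscore=float(fields[11]),
            )
        except (ValueError, HitParseError) as exc:
            raise HitParseError(f"line {lineno}: {exc}") from None
        grouped.setdefault(hit.query_id, []).append(hit)
    return grouped


def write_hit_table(hits: Iterable[AlignmentHit], path: str | Path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for h in hits:
            # repr round-trips floats exactly, so written tables reload verbatim
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.percent_identity!r}\t{h.align_len}"
                f"\t{h.mismatches}\t{h.gap_opens}\t{h.q_start}\t{h.q_end}"
                f"\t{h.s_start}\t{h.s_end}\t{h.evalue!r}\t{h.bitscore!r}\n"
            )


def read_subject_map(source: str | Path) -> dict[str, str]:
    """Read a 2-column TSV mapping subject_id to taxon_id or KO id."""
    mapping: dict[str, str] = {}
    with open(source, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise HitParseError(f"line {lineno}: expected 2 columns, got {len(fields)}")
            subject, target = fields
            if subject in mapping and mapping[subject] != target:
                raise HitParseError(f"line {lineno}: conflicting mapping for {subject!r}")
            mapping[subject] = target
    return mapping


def filter_hits_for_lca(
    hits: Iterable[AlignmentHit],
    cutoff: float = DEFAULT_EVALUE_CUTOFF,
    factor: float = DEFAULT_LCA_FACTOR,
) -> list[AlignmentHit]:
    """Cutoff filter, then the multiplicative e-value window.

    Hits with evalue > ``cutoff`` are discarded first; among the
    survivors with minimum e-value ``e_min``, exactly those with
    evalue <= ``e_min * factor`` are retained.
    """
    surviving = [h for h in hits if h.evalue <= cutoff]
    if not surviving:
        return []
    e_min = min(h.evalue for h in surviving)
    return [h for h in surviving if h.evalue <= e_min * factor]


def assign_taxonomy(
    hits_by_query: Mapping[str, list[AlignmentHit]],
    tree: TaxonomyTree,
    subject_to_taxon: Mapping[str, str],
    cutoff: float = DEFAULT_EVALUE_CUTOFF,
    factor: float = DEFAULT_LCA_FACTOR,
) -> dict[str, str]:
    """Filtered-LCA taxon per query; ``unassigned`` when nothing maps.

    Subjects missing from the map are dropped from the LCA input (their
    count is logged); a mapped taxon absent from the tree is an error.
    """
    result: dict[str, str] = {}
    n_unmappable = 0
    for query, hits in hits_by_query.items():
        retained = filter_hits_for_lca(hits, cutoff=cutoff, factor=factor)
        taxa = set()
        for hit in retained:
            taxon = subject_to_taxon.get(hit.subject_id)
            if taxon is None:
                n_unmappable += 1
                continue
            if taxon not in tree:
                raise KeyError(
                    f"subject {hit.subject_id!r} maps to taxon {taxon!r} absent from the tree"
                )
            taxa.add(taxon)
        result[query] = tree.lca(taxa) if taxa else UNASSIGNED
    if n_unmappable:
        logger.info("dropped %d hits with unmappable subjects from LCA input", n_unmappable)
    return result


def assign_function(
    hits_by_query: Mapping[str, list[AlignmentHit]],
    subject_to_ko: Mapping[str, str],
    cutoff: float = DEFAULT_EVALUE_CUTOFF,
) -> dict[str, str]:
    """Best-hit KO per query: max bitscore, then min e-value, then subject id."""
    result: dict[str, str] = {}
    for query, hits in hits_by_query.items():
        qualifying = [
            h for h in hits if h.evalue <= cutoff and h.subject_id in subject_to_ko
        ]
        if not qualifying:
            result[query] = UNASSIGNED
            continue
        best = min(qualifying, key=lambda h: (-h.bitscore, h.evalue, h.subject_id))
        result[query] = subject_to_ko[best.subject_id]
    return result


def compute_abundance(
    counts: pd.DataFrame, lengths: pd.Series | Mapping[str, float]
) -> pd.DataFrame:
    """Length-normalised relative abundance.

    abundance(i, s) = (count(i,s)/length(i)) / sum_j count(j,s)/length(j),
    so each sample column sums to one.  A sample with no reads at all is
    rejected as degenerate.
    """
    lengths = pd.Series(lengths, dtype=float)
    counts = counts.astype(float)
    missing = counts.index.difference(lengths.index)
    if len(missing):
        raise ValueError(f"missing lengths for unigenes: {list(missing)[:5]}")
    lengths = lengths.reindex(counts.index)
    if (lengths <= 0).any():
        raise ValueError("unigene lengths must be positive")
    if (counts < 0).any().any():
        raise ValueError("read counts must be non-negative")
    rate = counts.div(lengths, axis=0)
    totals = rate.sum(axis=0)
    dead = totals[totals <= 0]
    if len(dead):
        raise ValueError(f"sample(s) with zero total reads: {list(dead.index)}")
    return rate.div(totals, axis=1)


def read_counts_table(source: str | Path) -> pd.DataFrame:
    """TSV matrix, rows = unigenes (first column), columns = samples."""
    return pd.read_csv(source, sep="\t", index_col=0, comment="#")


def read_lengths_table(source: str | Path) -> pd.Series:
    """2-column TSV of unigene id and nucleotide length."""
    df = pd.read_csv(
        source, sep="\t", header=None, names=["unigene_id", "length"], comment="#"
    )
    return df.set_index("unigene_id")["length"].astype(float)


def annotate(
    tax_hits: Mapping[str, list[AlignmentHit]],
    ko_hits: Mapping[str, list[AlignmentHit]],
    tree: TaxonomyTree,
    subject_to_taxon: Mapping[str, str],
    subject_to_ko: Mapping[str, str],
    counts: pd.DataFrame,
    lengths: pd.Series,
    cutoff: float = DEFAULT_EVALUE_CUTOFF,
    factor: float = DEFAULT_LCA_FACTOR,
) -> UnigeneAnnotations:
    """Full per-unigene annotation: taxon, KO, length and abundance."""
    taxa = assign_taxonomy(tax_hits, tree, subject_to_taxon, cutoff=cutoff, factor=factor)
    kos = assign_function(ko_hits, subject_to_ko, cutoff=cutoff)
    abundance = compute_abundance(counts, lengths)
    assignments = pd.DataFrame(
        {
            "taxon_id": [taxa.get(u, UNASSIGNED) for u in counts.index],
            "ko_id": [kos.get(u, UNASSIGNED) for u in counts.index],
            "length": pd.Series(lengths).reindex(counts.index).astype(float),
        },
        index=counts.index,
    )
    return UnigeneAnnotations(assignments=assignments, abundance=abundance)
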