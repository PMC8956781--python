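"""Propionyl-CoA pathway definitions and per-taxon completeness scoring.

Two routes can supply propionyl-CoA for PHV synthesis in
glycogen-accumulating organisms:

* the ethylmalonyl-CoA (EMC) pathway — seven marker genes
  (phbB, phaJ, ccr, ecm, mcd, mch, mcl) converting acetyl-CoA toward
  propionyl-CoA via crotonyl-CoA/ethylmalonyl-CoA intermediates;
* the succinate–propionate pathway — three steps from succinyl-CoA
  (MUT, MCEEepi, and the carboxytransferase step labelled E2.1.3.1-5s).

Gene symbols are matched to KO identifiers through an explicit mapping;
by default a gene's KO key is its own symbol, which is how the bundled
synthetic data labels its functional hits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

EMC_GENES = ("phbB", "phaJ", "ccr", "ecm", "mcd", "mch", "mcl")
SUCPROP_GENES = ("MUT", "MCEEepi", "E2.1.3.1-5s")


@dataclass(frozen=True)
class PathwayGene:
    symbol: str
    ko_id: str | None = None

    @property
    def ko_key(self) -> str:
        return self.ko_id if self.ko_id is not None else self.symbol


@dataclass(frozen=True)
class PathwayDefinition:
    name: str
    genes: tuple[PathwayGene, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"pathway {self.name!r} has no genes")
        symbols = [g.symbol for g in self.genes]
        if len(set(symbols)) != len(symbols):
            raise ValueError(f"duplicate gene symbols in pathway {self.name!r}")

    @property
    def symbols(self) -> tuple[str, ...]:
        return tuple(g.symbol for g in self.genes)


@dataclass(frozen=True)
class CompletenessReport:
    taxon_id: str
    pathway: str
    present_genes: frozenset[str]
    n_present: int
    n_defined: int
    completeness: float
    complete: bool


def make_pathway(name: str, genes, ko_map: dict[str, str] | None = None) -> PathwayDefinition:
    ko_map = ko_map or {}
    return PathwayDefinition(
        name=name, genes=tuple(PathwayGene(g, ko_map.get(g)) for g in genes)
    )


def builtin_pathways(ko_map: dict[str, str] | None = None) -> dict[str, PathwayDefinition]:
    """The two built-in pathway definitions (EMC and succinate–propionate)."""
    return {
        "EMC": make_pathway("EMC", EMC_GENES, ko_map),
        "SucProp": make_pathway("SucProp", SUCPROP_GENES, ko_map),
    }


def presence(
    table: pd.DataFrame,
    pathway: PathwayDefinition,
    taxon_id: str,
    min_share: float = 0.0,
) -> frozenset[str]:
    """Genes of ``pathway`` present in ``taxon_id``.

    A gene counts as present when the taxon's share of that gene's KO
    exceeds ``min_share`` percent in at least one sample (strictly — the
    default 0 means any nonzero share).
    """
    present = set()
    for gene in pathway.genes:
        shares = table.loc[
            (table["ko_id"] == gene.ko_key) & (table["genus_taxon_id"] == taxon_id),
            "share_percent",
        ]
        if (shares > min_share).any():
            present.add(gene.symbol)
    return frozenset(present)


def completeness(present: frozenset[str] | set[str], pathway: PathwayDefinition,
                 taxon_id: str = "") -> CompletenessReport:
    """Fraction of the pathway's genes present, with a complete flag."""
    defined = set(pathway.symbols)
    extra = set(present) - defined
    if extra:
        raise ValueError(f"genes not in pathway {pathway.name!r}: {sorted(extra)}")
    frac = len(present) / len(defined)
    return CompletenessReport(
        taxon_id=taxon_id,
        pathway=pathway.name,
        present_genes=frozenset(present),
        n_present=len(present),
        n_defined=len(defined),
        completeness=frac,
        complete=frac == 1.0,
    )


def completeness_table(
    table: pd.DataFrame,
    pathways: dict[str, PathwayDefinition],
    taxa: list[str],
    min_share: float = 0.0,
) -> pd.DataFrame:
    """Completeness report rows for every (taxon, pathway) pair."""
    rows = []
    for taxon in taxa:
        for pw in pathways.values():
            rep = completeness(presence(table, pw, taxon, min_share), pw, taxon)
            rows.append(
                {
                    "taxon_id": rep.taxon_id,
                    "pathway": rep.pathway,
                    "n_present": rep.n_present,
                    "n_defined": rep.n_defined,
                    "completeness": rep.completeness,
                    "complete": rep.complete,
                    "present_genes": ",".join(
                        g for g in pw.symbols if g in rep.present_genes
                    ),
                }
            )
    return pd.DataFrame(rows)
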