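"""End-to-end orchestration: annotate -> attribute -> pathway -> expression -> stoich.

A run is driven by a :class:`RunConfig` naming every input file and the
analysis parameters.  All stage outputs are TSVs derived from nothing
but the inputs and the manifest parameters, so an identical manifest
reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import annotation, attribution, expression, pathway_profile, stoichiometry
from .annotation import UNASSIGNED
from .taxonomy import load_taxonomy

logger = logging.getLogger(__name__)


class RunConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    taxonomy: Path
    tax_hits: Path
    ko_hits: Path
    subject_to_taxon: Path
    subject_to_ko: Path
    counts: Path
    lengths: Path
    cycle: Path | None = None
    expression: Path | None = None
    outdir: Path = Path("gaoscope_out")
    evalue_cutoff: float = annotation.DEFAULT_EVALUE_CUTOFF
    lca_factor: float = annotation.DEFAULT_LCA_FACTOR
    top_n: int = 5
    min_share: float = 0.0
    mlss_g_L: float = 3.0
    ratio_window: str = "full"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "rt", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for key, value in raw.items():
            if key not in cls.__dataclass_fields__:
                raise RunConfigError(f"unknown config key {key!r}")
            kwargs[key] = value
        for key in ("taxonomy", "tax_hits", "ko_hits", "subject_to_taxon",
                    "subject_to_ko", "counts", "lengths", "cycle",
                    "expression", "outdir"):
            if kwargs.get(key) is not None:
                kwargs[key] = Path(kwargs[key])
        return cls(**kwargs)

    def validate(self) -> None:
        required = {
            "taxonomy": self.taxonomy, "tax_hits": self.tax_hits,
            "ko_hits": self.ko_hits, "subject_to_taxon": self.subject_to_taxon,
            "subject_to_ko": self.subject_to_ko, "counts": self.counts,
            "lengths": self.lengths,
        }
        optional = {"cycle": self.cycle, "expression": self.expression}
        for name, path in {**required,
                           **{k: v for k, v in optional.items() if v is not None}}.items():
            if not Path(path).is_file():
                raise RunConfigError(f"input {name!r} not found: {path}")
        if not 0 < self.evalue_cutoff:
            raise RunConfigError("evalue_cutoff must be positive")
        if self.lca_factor < 1:
            raise RunConfigError("lca_factor must be >= 1")
        if self.ratio_window not in ("full", "to-depletion"):
            raise RunConfigError(f"unknown ratio window {self.ratio_window!r}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def compare_to_literature(ratios: stoichiometry.RatioSet) -> pd.DataFrame:
    """Measured ratios against the bundled literature panel."""
    return stoichiometry.compare_to_literature(ratios)


def run_all(config: RunConfig) -> dict:
    """Execute every stage and write the report bundle under ``outdir``.

    Returns a summary dict with the key results (genus profile, pathway
    verdicts, ratios, fold-change tiers) for programmatic use.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    def stage(name):
        logger.info("stage: %s", name)

    stage("annotate")
    tree = load_taxonomy(config.taxonomy)
    tax_hits = annotation.read_hit_table(config.tax_hits)
    ko_hits = annotation.read_hit_table(config.ko_hits)
    s2t = annotation.read_subject_map(config.subject_to_taxon)
    s2k = annotation.read_subject_map(config.subject_to_ko)
    counts = annotation.read_counts_table(config.counts)
    lengths = annotation.read_lengths_table(config.lengths)
    ann = annotation.annotate(
        tax_hits, ko_hits, tree, s2t, s2k, counts, lengths,
        cutoff=config.evalue_cutoff, factor=config.lca_factor,
    )
    n_tax = (ann.assignments["taxon_id"] != UNASSIGNED).sum()
    n_ko = (ann.assignments["ko_id"] != UNASSIGNED).sum()
    logger.info("annotated %d unigenes: %d with taxon, %d with KO",
                len(ann.assignments), n_tax, n_ko)

    stage("attribute")
    table = attribution.attribute(ann, tree)
    profile = attribution.genus_profile(ann, tree)
    table.to_csv(outdir / "contribution.tsv", sep="\t", index=False)
    profile.to_csv(outdir / "genus_profile.tsv", sep="\t")
    kos = sorted(table["ko_id"].unique())
    ranking_rows = []
    for ko in kos:
        ranking = attribution.top_hosts(table, ko, n=config.top_n)
        for rank, (genus, share) in enumerate(ranking.hosts, start=1):
            ranking_rows.append({"ko_id": ko, "rank": rank,
                                 "genus_name": tree.name(genus),
                                 "genus_taxon_id": genus,
                                 "mean_share_percent": share})
    pd.DataFrame(ranking_rows).to_csv(outdir / "top_hosts.tsv", sep="\t", index=False)

    stage("pathway")
    pathways = pathway_profile.builtin_pathways()
    genera = [g for g in profile.index if g != UNASSIGNED]
    comp = pathway_profile.completeness_table(table, pathways, genera,
                                             min_share=config.min_share)
    comp.to_csv(outdir / "completeness.tsv", sep="\t", index=False)

    fold_changes = None
    if config.expression is not None:
        stage("expression")
        series = expression.read_expression(config.expression)
        fold_changes = expression.fold_change_table(series)
        fold_changes.to_csv(outdir / "fold_changes.tsv", sep="\t", index=False)

    ratios = None
    comparison = None
    if config.cycle is not None:
        stage("stoich")
        cycle = stoichiometry.read_cycle(config.cycle)
        ratios = stoichiometry.ratios_from_cycle(
            cycle, mlss_g_per_L=config.mlss_g_L, window=config.ratio_window
        )
        pd.DataFrame([ratios.rounded()]).to_csv(outdir / "ratios.tsv", sep="\t",
                                                index=False)
        comparison = compare_to_literature(ratios)
        comparison.to_csv(outdir / "literature_comparison.tsv", sep="\t",
                          index=False)

    manifest = {
        "parameters": {
            "evalue_cutoff": config.evalue_cutoff,
            "lca_factor": config.lca_factor,
            "top_n": config.top_n,
            "min_share": config.min_share,
            "mlss_g_L": config.mlss_g_L,
            "ratio_window": config.ratio_window,
        },
        "inputs": {
            name: {"path": str(path), "sha256": _sha256(Path(path))}
            for name, path in (
                ("taxonomy", config.taxonomy), ("tax_hits", config.tax_hits),
                ("ko_hits", config.ko_hits),
                ("subject_to_taxon", config.subject_to_taxon),
                ("subject_to_ko", config.subject_to_ko),
                ("counts", config.counts), ("lengths", config.lengths),
                ("cycle", config.cycle), ("expression", config.expression),
            )
            if path is not None
        },
    }
    with open(outdir / "manifest.json", "wt", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")

    _write_summary(outdir, tree, profile, comp, ratios, comparison, fold_changes)
    return {
        "annotations": ann, "contribution": table, "genus_profile": profile,
        "completeness": comp, "ratios": ratios, "fold_changes": fold_changes,
        "literature_comparison": comparison, "tree": tree,
    }


def _write_summary(outdir, tree, profile, completeness, ratios, comparison,
                   fold_changes) -> None:
    lines = ["# Run summary", "", "## Community (genus relative abundance)", ""]
    named = profile.rename(
        index=lambda g: tree.name(g) if g in tree else g
    )
    lines.append(named.round(4).to_string())
    lines += ["", "## Pathway completeness", ""]
    for _, row in completeness.iterrows():
        verdict = "complete" if row["complete"] else (
            f"{row['n_present']}/{row['n_defined']}"
        )
        name = tree.name(row["taxon_id"]) if row["taxon_id"] in tree else row["taxon_id"]
        lines.append(f"- {name} / {row['pathway']}: {verdict}"
                     f" ({row['present_genes'] or 'none'})")
    if ratios is not None:
        lines += ["", "## Cycle stoichiometry (C-mol basis)", ""]
        for key, value in ratios.rounded().items():
            lines.append(f"- {key}: {value:.2f}")
        from .stoichiometry import classify_metabolism
        lines.append(f"- phenotype: {classify_metabolism(ratios)}")
        if comparison is not None:
            nearest = comparison[comparison["nearest"] == True]  # noqa: E712
            if len(nearest):
                row = nearest.iloc[0]
                lines.append(
                    f"- nearest literature model: {row['reference']}"
                    f" ({row['model']}), distance {row['distance']:.3f}"
                )
    if fold_changes is not None and len(fold_changes):
        lines += ["", "## Transcript fold-change tiers (max over timepoints)", ""]
        tier_rank = {"not_quantifiable": -1, "down_or_flat": 0, "gt2": 1, "gt4": 2}
        for gene, sub in fold_changes.groupby("gene"):
            best = max(sub["tier"], key=lambda t: tier_rank.get(t, -1))
            lines.append(f"- {gene}: {best}")
    with open(Path(outdir) / "summary.md", "wt", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")
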