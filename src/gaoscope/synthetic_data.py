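"""Synthetic GAO-enrichment study generator with planted ground truth.

Emulates every input the pipeline consumes — taxonomy table, alignment
hit tables against a taxonomy and a functional database, subject maps,
per-unigene read counts and lengths, a reactor cycle time series and a
transcript abundance series — without simulating reads or sequences.
The defaults plant the study conditions the pipeline is meant to
recover: a dominant GAO genus rising from 2.6% to 6.9% of the
community (a second GAO from 1.0% to 2.0%) over five sampling days, a
dominant genus carrying all seven EMC-pathway genes plus MUT, a second
GAO carrying five EMC genes plus MUT, cycle kinetics with configured
C-mol yields (glycogen 1.32, PHB 1.72, PHV 0.37 per C-mol acetate,
acetate depleted at 60 min of a 90-min anaerobic phase, phosphate flat
at 5 mg/L), and transcript trajectories placing ccr/mcd/mch above
4-fold, ecm/mcl between 2- and 4-fold, and phbB/phaJ at or below
2-fold induction.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import AlignmentHit, write_hit_table
from .expression import ExpressionSeries
from .stoichiometry import ANALYTES, CYCLE_COLUMNS
from .taxonomy import TaxonNode, TaxonomyTree, write_taxonomy

logger = logging.getLogger(__name__)

EMC_PLACEMENT_FULL = ("phbB", "phaJ", "ccr", "ecm", "mcd", "mch", "mcl", "MUT")
EMC_PLACEMENT_PARTIAL = ("phaJ", "ccr", "ecm", "mcd", "mch", "MUT")

_BASE_GENERA = (
    "Ca_Contendobacter",
    "Ca_Competibacter",
    "Thauera",
    "Nitrospira",
    "Dechloromonas",
    "Ca_Accumulibacter",
)
_BASE_WEIGHTS = {
    "Thauera": 0.34,
    "Nitrospira": 0.16,
    "Dechloromonas": 0.14,
    "Ca_Accumulibacter": 0.12,
}


@dataclass
class SyntheticConfig:
    seed: int = 0
    n_genera: int = 8
    days: tuple[int, ...] = (1, 20, 39, 52, 75)
    dominant_genus: str = "Ca_Contendobacter"
    dominant_initial: float = 0.026
    dominant_final: float = 0.069
    second_genus: str = "Ca_Competibacter"
    second_initial: float = 0.010
    second_final: float = 0.020
    community_noise: float = 0.005  # 0 disables Dirichlet jitter
    gene_placements: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {
            "Ca_Contendobacter": EMC_PLACEMENT_FULL,
            "Ca_Competibacter": EMC_PLACEMENT_PARTIAL,
        }
    )
    unigenes_per_genus: int = 20
    read_depth: int = 200_000
    taxonomy_noise: float = 0.0  # P(a sibling-genus hit lands in the LCA window)
    # cycle kinetics
    vfa_0_mg_L: float = 420.0
    depletion_minute: float = 60.0
    anaerobic_minutes: float = 90.0
    aerobic_minutes: float = 240.0
    y_gly: float = 1.32  # C-mol glycogen consumed per C-mol acetate
    y_phb: float = 1.72  # C-mol PHB formed per C-mol acetate
    y_phv: float = 0.37  # C-mol PHV formed per C-mol acetate
    mlss_g_L: float = 3.0
    glycogen_0_g_gSS: float = 0.30
    phb_0_g_gSS: float = 0.010
    phv_0_g_gSS: float = 0.002
    phosphate_mgP_L: float = 5.0
    noise_sd: float = 0.02  # fractional measurement noise per reading
    # expression
    expression_final_fold: dict[str, float] = field(
        default_factory=lambda: {
            "ccr": 6.0, "mcd": 5.5, "mch": 5.0,
            "ecm": 3.0, "mcl": 2.8,
            "phbB": 1.3, "phaJ": 0.9,
        }
    )
    expression_noise_sd: float = 0.05  # lognormal sigma, 0 disables

    def __post_init__(self) -> None:
        for frac in (self.dominant_initial, self.dominant_final,
                     self.second_initial, self.second_final):
            if not 0 < frac < 1:
                raise ValueError("planted genus fractions must lie in (0, 1)")
        if min(self.y_gly, self.y_phb, self.y_phv) < 0:
            raise ValueError("yields must be non-negative")
        if not 0 < self.depletion_minute <= self.anaerobic_minutes:
            raise ValueError("depletion must fall within the anaerobic phase")
        if self.read_depth <= 0:
            raise ValueError("read depth must be positive")
        if self.n_genera < 4 or self.n_genera % 2:
            raise ValueError("n_genera must be an even number >= 4")

    def genera(self) -> list[str]:
        names = list(_BASE_GENERA)
        while len(names) < self.n_genera:
            names.append(f"Genus_{len(names) + 1:02d}")
        return names[: self.n_genera]

    def _rngs(self) -> list[np.random.Generator]:
        return [np.random.default_rng(s)
                for s in np.random.SeedSequence(self.seed).spawn(4)]


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    taxonomy_nodes: dict[str, TaxonNode]
    composition: pd.DataFrame  # genera x sample days, columns "day_N"
    counts: pd.DataFrame
    lengths: pd.Series
    tax_hits: list[AlignmentHit]
    ko_hits: list[AlignmentHit]
    subject_to_taxon: dict[str, str]
    subject_to_ko: dict[str, str]
    cycle: pd.DataFrame
    expression: dict[str, ExpressionSeries]
    truth: dict

    def tree(self) -> TaxonomyTree:
        return TaxonomyTree(self.taxonomy_nodes.values())


def _logistic_fraction(day: float, d0: float, d1: float, lo: float, hi: float,
                       steepness: float = 0.12) -> float:
    """Logistic interpolation rescaled to hit ``lo`` at d0 and ``hi`` at d1."""
    mid = 0.5 * (d0 + d1)
    s = 1.0 / (1.0 + math.exp(-steepness * (day - mid)))
    s0 = 1.0 / (1.0 + math.exp(-steepness * (d0 - mid)))
    s1 = 1.0 / (1.0 + math.exp(-steepness * (d1 - mid)))
    u = (s - s0) / (s1 - s0)
    return lo * (1.0 - u) + hi * u  # hits lo and hi exactly at the endpoints


def build_taxonomy(config: SyntheticConfig) -> dict[str, TaxonNode]:
    """Small NCBI-style tree: genera paired under families, one lineage spine.

    The two planted GAO genera share the first family, so sibling-hit
    noise drives their LCA to the family level.  An unranked clade sits
    between class and order to exercise rank-projection transparency.
    """
    nodes = {
        "1": TaxonNode("1", "1", "root", "root"),
        "d_Bacteria": TaxonNode("d_Bacteria", "1", "domain", "Bacteria"),
        "p_Proteobacteria": TaxonNode("p_Proteobacteria", "d_Bacteria", "phylum",
                                      "Proteobacteria"),
        "c_Gammaproteobacteria": TaxonNode("c_Gammaproteobacteria", "p_Proteobacteria",
                                           "class", "Gammaproteobacteria"),
        "x_unranked_clade": TaxonNode("x_unranked_clade", "c_Gammaproteobacteria",
                                      "no_rank", "environmental clade"),
        "o_Order01": TaxonNode("o_Order01", "x_unranked_clade", "order", "Order01"),
    }
    genera = config.genera()
    for i in range(0, len(genera), 2):
        fam = f"f_Family{i // 2 + 1:02d}"
        nodes[fam] = TaxonNode(fam, "o_Order01", "family", f"Family{i // 2 + 1:02d}")
        for genus in genera[i : i + 2]:
            nodes[genus] = TaxonNode(genus, fam, "genus", genus.replace("_", " "))
    return nodes


def sibling_genus(config: SyntheticConfig, genus: str) -> str:
    genera = config.genera()
    i = genera.index(genus)
    return genera[i + 1] if i % 2 == 0 else genera[i - 1]


def simulate_community(config: SyntheticConfig,
                       rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Per-sample genus composition (rows genera, columns ``day_N``).

    The two planted GAO genera follow deterministic logistic
    trajectories between their initial and final fractions; the rest of
    the community splits the remaining mass by fixed base weights, with
    Dirichlet jitter when ``community_noise`` > 0.
    """
    if rng is None:
        rng = config._rngs()[0]
    genera = config.genera()
    others = [g for g in genera
              if g not in (config.dominant_genus, config.second_genus)]
    base = np.array([_BASE_WEIGHTS.get(g, 0.05) for g in others])
    base = base / base.sum()
    d0, d1 = config.days[0], config.days[-1]
    cols = {}
    for day in config.days:
        dom = _logistic_fraction(day, d0, d1, config.dominant_initial,
                                 config.dominant_final)
        sec = _logistic_fraction(day, d0, d1, config.second_initial,
                                 config.second_final)
        rest = 1.0 - dom - sec
        if config.community_noise > 0:
            weights = rng.dirichlet(base / config.community_noise)
        else:
            weights = base
        frac = dict(zip(others, rest * weights))
        frac[config.dominant_genus] = dom
        frac[config.second_genus] = sec
        cols[f"day_{day}"] = [frac[g] for g in genera]
    return pd.DataFrame(cols, index=pd.Index(genera, name="genus"))


def _loguniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def simulate_metagenome(
    composition: pd.DataFrame, config: SyntheticConfig,
    rng: np.random.Generator | None = None,
):
    """Unigene catalogue, counts, hit tables and subject maps.

    Each genus gets one unigene per planted gene plus background
    unigenes.  Read counts are multinomial with probability
    proportional to genus fraction x within-genus weight x length, so
    that length-normalised abundance recovers the planted composition.
    Every unigene emits 1–5 taxonomy hits: the best hit maps to the
    true genus at a log-uniform e-value in [1e-40, 1e-20]; extra hits
    either corroborate (same genus, inside the x10 window), miss the
    1e-5 cutoff, or map to no known subject — except that with
    probability ``taxonomy_noise`` a sibling-genus hit lands inside the
    window and drags the LCA up to the family.  Planted-gene unigenes
    also emit a dominant functional hit to their gene's KO and a
    lower-bitscore decoy hit.
    """
    if rng is None:
        rng = config._rngs()[1]
    genera = list(composition.index)
    tax_nodes = build_taxonomy(config)

    subject_to_taxon: dict[str, str] = {}
    for genus in genera:
        for j in range(3):
            subject_to_taxon[f"SUB_{genus}_{j}"] = genus
    gene_symbols = sorted({g for genes in config.gene_placements.values()
                           for g in genes})
    subject_to_ko = {f"KSUB_{sym}": sym for sym in gene_symbols}

    unigenes: list[tuple[str, str, str | None]] = []  # (id, genus, gene)
    for genus in genera:
        planted = list(config.gene_placements.get(genus, ()))
        for gene in planted:
            unigenes.append((f"UG_{genus}_{gene}", genus, gene))
        n_background = max(config.unigenes_per_genus - len(planted), 1)
        for i in range(n_background):
            unigenes.append((f"UG_{genus}_bg{i:03d}", genus, None))

    ids = [u[0] for u in unigenes]
    lengths = pd.Series(rng.integers(300, 3001, size=len(ids)).astype(float),
                        index=ids, name="length")
    # within-genus weights, fixed across samples
    raw_w = rng.lognormal(mean=0.0, sigma=0.6, size=len(ids))
    weights = pd.Series(raw_w, index=ids)
    genus_of = pd.Series([u[1] for u in unigenes], index=ids)
    weights = weights / weights.groupby(genus_of).transform("sum")

    counts = {}
    genus_frac = composition
    for sample in composition.columns:
        target_abund = weights * genus_of.map(genus_frac[sample])
        p = target_abund * lengths
        p = p / p.sum()
        counts[sample] = rng.multinomial(config.read_depth, p.to_numpy())
    counts_df = pd.DataFrame(counts, index=ids)

    tax_hits: list[AlignmentHit] = []
    ko_hits: list[AlignmentHit] = []
    for uid, genus, gene in unigenes:
        length = int(lengths[uid])
        e_best = _loguniform(rng, 1e-40, 1e-20)
        bits = float(rng.uniform(200, 400))

        def mk(subject: str, evalue: float, bitscore: float) -> AlignmentHit:
            alen = max(30, length // 3 - int(rng.integers(0, 20)))
            return AlignmentHit(
                query_id=uid, subject_id=subject,
                percent_identity=float(np.round(rng.uniform(60, 100), 1)),
                align_len=alen, mismatches=int(rng.integers(0, 30)),
                gap_opens=int(rng.integers(0, 4)),
                q_start=1, q_end=alen, s_start=1, s_end=alen,
                evalue=evalue, bitscore=float(np.round(bitscore, 1)),
            )

        tax_hits.append(mk(f"SUB_{genus}_{rng.integers(0, 3)}", e_best, bits))
        if rng.random() < config.taxonomy_noise:
            sib = sibling_genus(config, genus)
            tax_hits.append(
                mk(f"SUB_{sib}_{rng.integers(0, 3)}", e_best * 3.0, bits - 5)
            )
        for _ in range(int(rng.integers(0, 4))):
            kind = rng.random()
            if kind < 0.4:  # corroborating same-genus hit inside the window
                tax_hits.append(
                    mk(f"SUB_{genus}_{rng.integers(0, 3)}",
                       e_best * rng.uniform(1.0, 9.0), bits - 10)
                )
            elif kind < 0.7:  # fails the 1e-5 cutoff
                other = genera[int(rng.integers(0, len(genera)))]
                tax_hits.append(
                    mk(f"SUB_{other}_{rng.integers(0, 3)}",
                       _loguniform(rng, 2e-5, 1e-2), bits - 100)
                )
            else:  # unmappable subject, dropped from the LCA input
                tax_hits.append(
                    mk(f"SUB_unknown_{rng.integers(0, 50)}",
                       e_best * rng.uniform(1.0, 9.0), bits - 20)
                )

        if gene is not None:
            e_fun = _loguniform(rng, 1e-60, 1e-30)
            fbits = float(rng.uniform(300, 500))
            ko_hits.append(mk(f"KSUB_{gene}", e_fun, fbits))
            decoy = gene_symbols[int(rng.integers(0, len(gene_symbols)))]
            if decoy != gene:
                ko_hits.append(mk(f"KSUB_{decoy}", e_fun * 100, fbits - 60))

    return (tax_nodes, counts_df, lengths, tax_hits, ko_hits,
            subject_to_taxon, subject_to_ko)


def simulate_cycle(config: SyntheticConfig,
                   rng: np.random.Generator | None = None) -> pd.DataFrame:
    """One anaerobic–aerobic SBR cycle time series.

    Anaerobic (90 min): acetate falls linearly to zero at the
    depletion minute; glycogen falls and PHB/PHV rise in proportion to
    the acetate C-mol consumed, per the configured yields; dissolved
    phosphate stays flat.  Aerobic (240 min): PHAs decay first-order
    and glycogen recovers toward its initial level.  Multiplicative
    Gaussian measurement noise (sd ``noise_sd``) perturbs every
    reading; negatives are clamped to zero with a logged count.
    """
    if rng is None:
        rng = config._rngs()[2]
    c = config
    ac_mono, gly_mono = ANALYTES["acetate"], ANALYTES["glycogen"]
    phb_mono, phv_mono = ANALYTES["PHB"], ANALYTES["PHV"]

    def anaerobic_state(t: float) -> tuple[float, float, float, float]:
        ac = c.vfa_0_mg_L * max(0.0, 1.0 - t / c.depletion_minute)
        consumed_g_gSS = (c.vfa_0_mg_L - ac) / 1000.0 / c.mlss_g_L
        cmol = consumed_g_gSS / ac_mono.monomer_formula_mass * ac_mono.carbons_per_monomer
        gly = c.glycogen_0_g_gSS - c.y_gly * cmol * gly_mono.monomer_formula_mass / gly_mono.carbons_per_monomer
        phb = c.phb_0_g_gSS + c.y_phb * cmol * phb_mono.monomer_formula_mass / phb_mono.carbons_per_monomer
        phv = c.phv_0_g_gSS + c.y_phv * cmol * phv_mono.monomer_formula_mass / phv_mono.carbons_per_monomer
        return ac, gly, phb, phv

    rows = []
    for t in np.arange(0.0, c.anaerobic_minutes + 1e-9, 10.0):
        ac, gly, phb, phv = anaerobic_state(t)
        rows.append((t, "anaerobic", ac, gly, phb, phv, c.phosphate_mgP_L))
    _, gly_end, phb_end, phv_end = anaerobic_state(c.anaerobic_minutes)
    t0 = c.anaerobic_minutes
    for t, phase in ((t0 + 5, "settle"), (t0 + 15, "settle"),
                     (t0 + 17, "decant"), (t0 + 21, "decant")):
        rows.append((t, phase, 0.0, gly_end, phb_end, phv_end, c.phosphate_mgP_L))
    aero_start = t0 + 25
    tau_decay = 80.0  # min, first-order PHA consumption / glycogen recovery
    for t in np.arange(aero_start, aero_start + c.aerobic_minutes + 1e-9, 20.0):
        tau = t - aero_start
        decay = math.exp(-tau / tau_decay)
        gly = c.glycogen_0_g_gSS - (c.glycogen_0_g_gSS - gly_end) * decay
        phb = c.phb_0_g_gSS + (phb_end - c.phb_0_g_gSS) * decay
        phv = c.phv_0_g_gSS + (phv_end - c.phv_0_g_gSS) * decay
        rows.append((t, "aerobic", 0.0, gly, phb, phv, c.phosphate_mgP_L))
    t_end = aero_start + c.aerobic_minutes
    rows.append((t_end + 4, "idle", 0.0, rows[-1][3], rows[-1][4], rows[-1][5],
                 c.phosphate_mgP_L))
    rows.append((t_end + 9, "idle", 0.0, rows[-1][3], rows[-1][4], rows[-1][5],
                 c.phosphate_mgP_L))

    df = pd.DataFrame(rows, columns=CYCLE_COLUMNS)
    if c.noise_sd > 0:
        analyte_cols = CYCLE_COLUMNS[2:]
        noise = rng.normal(1.0, c.noise_sd, size=(len(df), len(analyte_cols)))
        noisy = df[analyte_cols].to_numpy() * noise
        n_clamped = int((noisy < 0).sum())
        if n_clamped:
            logger.info("clamped %d negative noisy readings to zero", n_clamped)
        df[analyte_cols] = np.clip(noisy, 0.0, None)
    return df


def simulate_expression(config: SyntheticConfig,
                        rng: np.random.Generator | None = None
                        ) -> dict[str, ExpressionSeries]:
    """Transcript abundance per EMC gene across the sampling days.

    Fold trajectories interpolate geometrically from 1x at the first
    day to the configured final fold, with multiplicative log-normal
    noise at non-baseline timepoints.
    """
    if rng is None:
        rng = config._rngs()[3]
    d0, d1 = config.days[0], config.days[-1]
    out = {}
    for gene, final_fold in config.expression_final_fold.items():
        if final_fold <= 0:
            raise ValueError(f"final fold for {gene!r} must be positive")
        base = float(rng.uniform(5.0, 50.0))
        values = []
        for day in config.days:
            s = (_logistic_fraction(day, d0, d1, 0.0, 1.0))
            fc = final_fold ** s
            noise = 1.0
            if config.expression_noise_sd > 0 and day != d0:
                noise = float(rng.lognormal(0.0, config.expression_noise_sd))
            values.append(base * fc * noise)
        out[gene] = ExpressionSeries(
            gene=gene,
            abundance=pd.Series(values, index=pd.Index(config.days, name="day")),
        )
    return out


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Full input bundle with planted ground truth, deterministic per seed."""
    rng_comm, rng_meta, rng_cycle, rng_expr = config._rngs()
    composition = simulate_community(config, rng_comm)
    (tax_nodes, counts, lengths, tax_hits, ko_hits,
     s2t, s2k) = simulate_metagenome(composition, config, rng_meta)
    cycle = simulate_cycle(config, rng_cycle)
    expression = simulate_expression(config, rng_expr)
    truth = {
        "composition": {s: {g: float(composition.loc[g, s])
                            for g in composition.index}
                        for s in composition.columns},
        "gene_placements": {g: list(v) for g, v in config.gene_placements.items()},
        "yields": {"y_gly": config.y_gly, "y_phb": config.y_phb,
                   "y_phv": config.y_phv},
        "expression_final_fold": dict(config.expression_final_fold),
        "dominant_genus": config.dominant_genus,
        "second_genus": config.second_genus,
    }
    return SyntheticDataset(
        config=config, taxonomy_nodes=tax_nodes, composition=composition,
        counts=counts, lengths=lengths, tax_hits=tax_hits, ko_hits=ko_hits,
        subject_to_taxon=s2t, subject_to_ko=s2k, cycle=cycle,
        expression=expression, truth=truth,
    )


def write_bundle(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write the complete input bundle as plain-text files plus truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "taxonomy": outdir / "taxonomy.tsv",
        "tax_hits": outdir / "hits_taxonomy.tsv",
        "ko_hits": outdir / "hits_ko.tsv",
        "subject_to_taxon": outdir / "subject_to_taxon.tsv",
        "subject_to_ko": outdir / "subject_to_ko.tsv",
        "counts": outdir / "counts.tsv",
        "lengths": outdir / "lengths.tsv",
        "cycle": outdir / "cycle.csv",
        "expression": outdir / "expression.tsv",
        "truth": outdir / "truth.json",
    }
    write_taxonomy(dataset.taxonomy_nodes, paths["taxonomy"])
    write_hit_table(dataset.tax_hits, paths["tax_hits"])
    write_hit_table(dataset.ko_hits, paths["ko_hits"])
    for key, mapping in (("subject_to_taxon", dataset.subject_to_taxon),
                         ("subject_to_ko", dataset.subject_to_ko)):
        with open(paths[key], "wt", encoding="utf-8") as fh:
            for subject, target in mapping.items():
                fh.write(f"{subject}\t{target}\n")
    dataset.counts.rename_axis("unigene_id").to_csv(paths["counts"], sep="\t")
    with open(paths["lengths"], "wt", encoding="utf-8") as fh:
        for uid, length in dataset.lengths.items():
            fh.write(f"{uid}\t{int(length)}\n")
    dataset.cycle.to_csv(paths["cycle"], index=False)
    with open(paths["expression"], "wt", encoding="utf-8") as fh:
        for gene, series in dataset.expression.items():
            for t, value in series.abundance.items():
                fh.write(f"{gene}\t{t}\t{value:.10g}\n")
    with open(paths["truth"], "wt", encoding="utf-8") as fh:
        json.dump(dataset.truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
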