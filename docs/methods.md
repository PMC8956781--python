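# Methods

## Scope and model

`gaoscope` reconstructs, from annotation-level inputs, the two analyses
that characterise a glycogen-accumulating-organism (GAO) enrichment
reactor:

1. **Gene-source attribution.** Which genera of the community carry the
   genes of the two candidate routes to propionyl-CoA — the
   ethylmalonyl-CoA (EMC) pathway (phbB, phaJ, ccr, ecm, mcd, mch, mcl)
   and the succinate–propionate pathway (MUT, MCEEepi, E2.1.3.1-5s) —
   and in what proportion.
2. **Cycle stoichiometry.** Whether a single anaerobic–aerobic cycle of
   the sequencing batch reactor exhibits glycogen-accumulating
   metabolism (GAM), read off six dimensionless yields.

The package never touches reads or assemblies: its inputs are the
products of an upstream annotation pipeline (12-column protein-alignment
hit tables, subject→taxon and subject→KO maps, a taxonomy table, a
unigene count matrix) plus reactor chemistry time series.

## Taxonomic assignment

Per unigene, hits against the taxonomy database are filtered in two
steps: an e-value cutoff (default 1e-5) and then a multiplicative
window — only hits with e-value ≤ 10× the best surviving e-value are
kept.  The assignment is the lowest common ancestor (LCA) of the
retained hits' taxa.  The cutoff is applied *before* the window; the
alternative order admits hits that fail the cutoff whenever the best
e-value is within a factor of ten of it, which contradicts the cutoff's
purpose.  Subjects absent from the map are dropped from the LCA input
(real reference subsets always have gaps) but counted in the log.

The taxonomy is a simplified 4-column TSV (id, parent, rank, name) with
the root as its own parent, rather than NCBI `nodes.dmp`/`names.dmp`;
this keeps test data self-contained.  Unranked nodes are transparent to
rank projection: they are traversed but never returned for a named-rank
query.  LCA correctness is checked against an independent brute-force
oracle (lineage-set intersection) on randomized trees.

## Functional assignment and abundance

The KO of a unigene is its best hit (maximum bitscore, ties broken by
lower e-value, then lexicographically smaller subject id) among hits
passing the same 1e-5 cutoff.  Relative abundance is length-normalised:
reads/length per unigene, renormalised to sum to one per sample.  The
upstream catalogue convention does not pin an exact formula; any
monotone alternative would permute nothing in the downstream
presence/absence calls, only rescale shares.

## Attribution and pathway completeness

A unigene attributes its KO to a genus iff it carries both a KO and a
taxon whose lineage contains a genus (co-location on one unigene is the
evidence).  Sub-genus assignments roll up; assignments above genus fall
into an explicit `unassigned` bucket so shares always total 100%.  A
KO's host genera are ranked by **mean share across samples** (ties:
total abundance, then id); the ranking statistic is a design choice —
per-sample bar charts with a single ranked legend are the figure style
this reproduces.  Share denominators are the KO's total abundance in
that sample, i.e. percentages are shares of a gene's total, not genome
fractions.

A pathway gene is *present* in a genus when the genus's share of that
gene's KO exceeds `min_share` (default 0, i.e. any nonzero share) in at
least one sample; completeness is the fraction of defined genes
present.  Gene symbols double as KO keys unless an explicit symbol→KO
map is supplied; no KO numbers are hard-coded.

## Expression tiers

Transcript fold change is the ratio to the first sampled timepoint
(config-overridable).  Tier boundaries are strict: >4-fold, >2-fold
(but ≤4), else down/flat.  Genes with zero baseline are reported as
not quantifiable — no pseudo-count, because an arbitrary offset would
manufacture tiers.  A gene's headline tier is its maximum over
timepoints.

## Cycle stoichiometry

All ratios are on a carbon-mol basis (mol-P for phosphorus), the
convention of the published GAO/PAO models, and the only basis under
which mass deltas in g/gSS reduce to dimensionless yields.  Monomer
constants are fixed in code: acetate C2H4O2 (60.05 g/mol, 2 C),
glucosyl C6H10O5 (162.14, 6 C), PHB monomer C4H6O2 (86.09, 4 C), PHV
monomer C5H8O2 (100.12, 5 C), P 31.0 g/mol.

Phase deltas are last-minus-first within a phase; the anaerobic window
is the full phase by default, with a `to-depletion` option ending at
the first zero-acetate sample (acetate is typically exhausted at
60 min of the 90-min phase).  Dissolved species (mg/L) are converted to
a per-gSS basis with the mixed-liquor suspended-solids concentration
(`--mlss`, default 3 g/L — a typical SBR biomass; the per-C-mol ratios
of intracellular polymers to VFA are insensitive to it because it
cancels, but it is required to place dissolved and intracellular
species on one basis).

Phenotype classification: GAM if P/VFA ≤ 0.10 and Gly/VFA ≥ 1.0; PAM
if P/VFA ≥ 0.30; otherwise mixed.  The thresholds sit in the gap of
the published spread — GAM-type enrichments report P/VFA 0.00–0.08,
PAO enrichments 0.62–0.73.  The carbon balance (PHA C formed over VFA
plus glycogen C consumed) is reported with a warning above 1; values
below 1 are expected from CO2 loss.

The bundled literature panel holds the seven published GAO/PAO model
rows used for comparison; the nearest row by Euclidean distance over
the six ratios (skipping unreported entries) is flagged.

## Synthetic data generator

The generator emulates the study conditions, not sequencing physics:

* **Community.** The dominant GAO genus follows a logistic trajectory
  from 2.6% to 6.9% across sampling days {1, 20, 39, 52, 75}; a second
  GAO goes 1.0% → 2.0%.  Both trajectories are planted exactly (the
  endpoints are hit to the float) so dominance ratios are recomputable;
  the remaining mass is split among background genera (a
  Thauera-dominated inoculum) with Dirichlet jitter.
* **Metagenome.** Each genus carries one unigene per planted pathway
  gene plus background unigenes (20 per genus by default, 8 genera).
  Read counts are multinomial with probability ∝ genus fraction ×
  within-genus weight × length, so length-normalised abundance recovers
  the planted composition; the default depth (200k reads) keeps the
  maximum per-genus profile error below 1%.  Taxonomy hits place the
  true genus at a log-uniform e-value in [1e-40, 1e-20]; decoy hits
  either corroborate (same genus, inside the ×10 window), miss the
  1e-5 cutoff, or are unmappable — every branch of the filter rule is
  exercised.  With probability `taxonomy_noise` a sibling-genus hit
  lands inside the window and drags the LCA to the family; the default
  is 0 (confidently annotated unigenes), making planted-truth recovery
  deterministic; the noise rate is a dial for robustness studies.
* **Cycle.** Anaerobic acetate declines linearly to zero at 60 min;
  glycogen falls and PHB/PHV rise in proportion to acetate C-mol
  consumed at the configured yields (defaults 1.32, 1.72, 0.37 C-mol
  per C-mol — the GAM operating point); phosphate is flat at 5 mg/L.
  Aerobically PHAs decay first-order (τ = 80 min) and glycogen
  recovers.  Measurement noise is *multiplicative* Gaussian (default
  sd 2%, the scale of GC/HPLC repeatability): analytes span four
  orders of magnitude across units, so additive noise with one sd
  would be meaningless, and multiplicative noise keeps true zeros at
  zero.  Negative noisy readings are clamped at zero and counted.
* **Expression.** Fold trajectories interpolate geometrically from 1×
  to planted final folds (ccr 6×, mcd 5.5×, mch 5×; ecm 3×, mcl 2.8×;
  phbB 1.3×, phaJ 0.9×), spanning each tier with margin, with
  log-normal noise off-baseline.

What the generator does **not** emulate: sequence content, assembly
chimerism, contig binning errors, database incompleteness beyond the
unmappable-subject rate, copy-number variation, and rRNA-depletion
artefacts.  Passing recovery tests therefore demonstrates correctness
of the attribution arithmetic and filter rules, not robustness to real
annotation error modes.

## Numerical choices

* Filter and ranking tie-breaks are total orders (bitscore, e-value,
  subject id; share, abundance, genus id), so outputs are
  order-independent and byte-reproducible.
* Ratios are rounded to 2 decimals in reports (full precision kept
  internally); `-0.0` is normalised to `0.0`.
* PHV/PHB on a zero-PHB cycle is NaN with a warning, never an
  exception.
* One seed drives four independent RNG streams (community, metagenome,
  cycle, expression) via seed-sequence spawning, so regenerating one
  stage does not perturb the others.

## Known limitations

* Gly/VFA and PHB/VFA cannot be recomputed from polymer deltas alone
  without the biomass concentration; when only deltas are available
  the package reports the ratios that are biomass-free (PHV/PHB, the
  PHAs additivity, P/VFA) and requires MLSS for the rest.
* Pathway completeness is presence/absence on annotation shares; it
  says nothing about flux or enzyme activity.
* The host ranking assumes the genus bucket absorbs all sub-genus
  structure; strain-level heterogeneity is invisible.
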