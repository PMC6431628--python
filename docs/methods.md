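# Methods

`aerotype` surveys annotated bacterial genomes — protein FASTA, gene
coordinates, assembly metadata — for O₂-reducing terminal oxidases, types
their operons by gene synteny, and sorts genomes into four aerobic-lifestyle
categories. This note records the model, the tunable parameters, and the
design choices that were genuinely open.

## Controlled vocabulary and category model

Terminal oxidases are held at two granularities. Subfamily labels
`{A1, A2, B, C_cbb3, bd_I, Cio, AOX}` are the unit of detection and of
oxygen-affinity assignment; the six recognised *types* collapse bd-I and Cio
into the bd superfamily (`six_type_of`). Two further labels never count as
O₂ reductases: `NOR` (nitric oxide reductase, an HCO relative catalysing a
different reaction) and `B_degenerate` (B-family-like sequences lacking the
catalytic tyrosine, whose O₂-reductase function is questioned).

Affinity tiers are a fixed total map: bd-I and C-family cbb₃ are high
affinity (nanomolar Km); the B family is intermediate (no Km has been
reported; no number is invented — `km_reference` returns an explicit
not-reported sentinel); A1, A2, Cio and AOX are low affinity (Km near or
above the Pasteur point, ~2 µM; curated examples: 4 µM for A1, 0.62 µM for
A2). The map and Km annotations ship as editable YAML
(`aerotype/data/ontology.yaml`).

Categories are a total function of the tier multiset: **I** no oxidases,
**II** all high, **IV** all low, **III** otherwise. Two refinements:

* Repertoires the underlying survey never observed still classify by the
  tier algebra but carry a `repertoire_not_observed` flag: category IV is
  canonically "A1 ± AOX", so e.g. `{Cio}` alone is IV-flagged; `{B}` alone
  (intermediate-only) is III-flagged.
* A genome whose only "oxidase" is AOX, on a background with ≥1 anaerobic
  trait and no complex III, is classified a strict anaerobe (category I with
  a `strict_anaerobe_contamination` override): a lone AOX gene on a fully
  anaerobic background is most plausibly contamination. The predicate's
  trait lists are configurable (`data/traits.yaml`).

## Quality gate

Assemblies enter classification only when completeness ≥ 90 %, tRNA count
≥ 16 and proteome > 1000 proteins (boundary semantics exactly as printed:
90 passes, 16 passes, 1000 fails). Completeness is consumed as metadata, not
estimated. Gate-failing genomes are still scanned — their detections are
reported — but the category is withheld and a single accepted bd subunit is
not promoted to an ambiguous bd call (that call is defined only for
≥90 %-complete genomes).

## Detection engine

Each protein is scored against every reference profile:

* **Similarity** — Smith–Waterman local alignment (Biopython's
  `PairwiseAligner`) under BLOSUM62 with affine gaps (first gap residue 12,
  each further residue 1). Identity = matches / aligned columns (internal
  gaps included). Significance is a Karlin–Altschul estimate
  E = K·m·n·e^(−λS) with ungapped BLOSUM62 constants (λ = 0.3176,
  K = 0.134); it is used for threshold semantics and monotonicity, not as an
  exact null.
* **Structure** — a Kyte–Doolittle hydropathy scan (window 19, threshold
  1.6, overlapping qualifying windows merged) counts transmembrane segments,
  which must fall in the profile's expected range; diagnostic residues are
  checked through the alignment coordinate map (columns outside the
  alignment are `unalignable`, never guessed).

**Acceptance** requires identity ≥ 25 % AND E ≤ 1e-10 AND TM count in range
AND required diagnostics present. A candidate meeting exactly one of the two
similarity criteria is kept as `ambiguous` for review; one meeting neither
is dropped. This both-required/either-ambiguous reading of the "25 % and/or
1e-10" rule reproduces a manual-curation funnel with a conservative
automatic core.

Diagnostic outcomes are graded per profile: HCO subunit I requires the three
CuB histidines and the catalytic tyrosine (a B-family hit lacking only the
tyrosine is relabelled `B_degenerate`; an A-family hit lacking it is
rejected); subunit II lacking the CuA ligand set is accepted as a
quinol-oxidizing (bo₃-like) variant; chaperone hits failing their residue
checks demote to ambiguous.

Four guards keep compositional noise out (all standard curation practice,
none tuned to a particular simulation seed):

1. a length-ratio prefilter (query/reference within [0.3, 3.3]);
2. a reference-coverage floor (aligned reference fraction ≥ 0.4);
3. a reporting ceiling — hits with E > 1e-3 are never recorded — plus the
   HSSP/Rost length correction on the identity criterion
   (480·L^(−0.32·(1+e^(−L/1000)))), so 25 % identity over a short
   compositional alignment cannot qualify;
4. best-hit reduction: within a competition group of homologous profiles
   (A1/A2/B subunit I, bd-I/Cio subunits, …) the highest-identity profile
   defines the call, demoted to ambiguous when the winning margin is below
   5 identity points; across groups a gene keeps only its single best
   accepted assignment (one gene, one protein). The nearest profile's
   verification verdict stands — a tyrosine-less A1 subunit is rejected, not
   rescued as degenerate B by the more permissive, more distant B profile.

bd-superfamily presence is genome-level: both CydA and CydB must be
accepted; exactly one accepted subunit in a gate-passing genome yields an
ambiguous (light-gray) bd call.

## Reference profiles

The shipped profile library is **synthetic**: deterministic seeded mock
proteins with planted hydrophobic TM stretches and planted diagnostic
residues (`profiles.py`; fixed internal seed, independent of run seeds).
Related profiles are derived from one another at fixed divergence (A2/B
subunit I from A1 at 40/50 %, Cio from bd-I at 40 %, NOR from CcoN at 45 %)
so that subfamily discrimination by nearest profile + margin is actually
exercised. Expected TM ranges are frozen from the references themselves
(tm_count ± 2), since no per-subunit counts are printed anywhere
authoritative. A curated library of real references loads from FASTA + YAML
sidecar (`load_library`) without code changes; the engine only consumes the
config. Consequences for interpretation: green tests establish the
*machinery* (thresholds, funnels, synteny, classification algebra), not the
biological fidelity of any shipped sequence.

## Synteny typing

Accepted oxidase/accessory/chaperone hits with coordinates are clustered
into maximal runs with intergenic gaps ≤ `max_gap` (default 500 bp — typical
bacterial operon spacing; the quantity is a knob, never printed). Strand is
recorded but not constrained. Each cluster with a catalytic subunit is
matched against an ordered-role signature table
(`data/signatures.yaml`, validated for ambiguity at load time), giving the
binomial (type, subtype) nomenclature: A1 subtypes a / a-III (COX3 doublet)
/ b (COX2–COX1–CtaB–CtaG) / b-Magnetospirillum (CtaB missing); A2 CyoCAB
(III–II–I order, SCO-rich) and a-I (Act fusion plus SCO); B ba3-a1 (B-type
subunit I with ≥1 SCO, no fixed accessory order assumed); bd-I, Cio, cbb₃.
Non-alphaproteobacterial layouts (delta, CyoBAC, chloroflexian) ship as
comparative context. Patterns are read in coordinate direction; only
minus-strand (majority-strand) clusters are matched against reversed
patterns — unconditional reversal would conflate CyoCAB with CyoBAC, which
are the same roles read in opposite directions. AOX and NOR have no subtype
nomenclature; their singleton clusters are silent rather than
"unclassified". Clusters mixing catalytic subunits of different families are
flagged chimeric.

## Chaperones and traits

Cu-chaperone families (SCO: CxxxC + His; CtaG_Cox11: two Cu-binding Cys;
Caa3_CtaG: His/Asp/Met ligand set, transmembrane) are assigned by the
detection engine; localization is `in_cluster` when the gene lies within
`max_gap` of an oxidase cluster span on the same replicon, else `isolated`.
Summary counts conserve totals by construction.

The trait panel (FeFe-hydrogenase, HydEFG maturation machinery, ASCT, malic
enzyme, fumarase, complexes I–III, quinone biosynthesis) uses configurable
subunit quorums: HydEFG needs ≥2 of HydE/F/G, complex I needs both NuoB and
NuoF; below-quorum evidence yields `ambiguous`. Co-occurrence tables are
plain counts — the source survey prints no significance tests, so none are
attached. Eukaryotic trait rows are out of scope; externally supplied
vectors can be merged into the matrix by the caller.

## Report

The trait matrix orders genomes by category then name; oxidase columns
render blue with intensity increasing as O₂ affinity decreases (high → light
`blue1`, intermediate → `blue2`, low → dark `blue3`; discrete codes, since
the tiers are discrete), anaerobic traits render black, absence is always
white, and every ambiguous call is light gray. The TSV is the authoritative
artifact; the optional matplotlib figure renders it. All orderings are
explicit and no timestamps are embedded, so re-runs are byte-identical.

## Synthetic genomes

The generator plants operons (template role orders mirroring the signature
table), chaperones (in-cluster or isolated), trait genes, shuffled decoys
(per-sequence Fisher–Yates permutations of references) and short padding
proteins (50–74 aa, deliberately below the detector's length-ratio floor) on
a single replicon; intergenic gaps inside operons default to 100 bp and
everything else is spaced ≫ `max_gap`. Planted genes are references mutated
to a requested divergence by seeded point substitutions that spare
diagnostic positions and substitute within the hydrophobic alphabet inside
TM segments, so divergence, diagnostics and TM counts are independently
controllable. Every genome carries a truth record (expected repertoire,
category, override, subtype labels, flags, trait states, chaperone
localizations); `verify` diffs a pipeline result against it.

Defaults state the modelled world: genomes are padded to 1010 proteins (so
the >1000 gate is genuinely exercised), completeness 98 %, 24 tRNAs, 10
decoys, planted divergence mostly 10–25 % (well inside detectable range,
with one 40 % genome probing the margin machinery and one 80 % case probing
rejection). The shipped 30-genome cohort covers all four categories, every
subtype, and the edge cases: single bd subunit (ambiguous call), Tyr-less B
(degenerate), CtaB-less A1-b (Magnetospirillum variant), AOX-only anaerobe
(override), CuA-less subunit II (quinol variant), shuffled cluster
(unclassified), below-quorum HydE, and a completeness-85 % gate failure.
What the generator does **not** emulate: real sequence evolution
(insertions/deletions, rate heterogeneity, domain shuffling), fragmented
assemblies, multiple replicons, or annotation errors — a clean cohort run
therefore validates the pipeline logic, not robustness to messy real
assemblies.

## Numerical and degenerate-input choices

* Alignment ties: the single highest-scoring traceback reported by the
  aligner defines identity; scores are tie-free and are what the DP oracle
  checks exactly.
* Zero-score local alignments return an empty result (identity 0, no map).
* Sequences shorter than the hydropathy window count 0 TM segments, with a
  warning.
* Profile ties in competition groups break by (higher identity, then
  lexicographic profile id).
* Unknown completeness fails the gate conservatively.
* FASTA entries without a coordinate row are scored but excluded from
  synteny; coordinate rows without FASTA entries warn.
* Per-genome RNG streams derive from (cohort seed, crc32(genome id) &
  0x7FFFFFFF); all derived seeds stay below 2³¹.

## Known limitations

* The synthetic reference library cannot validate family assignment of real
  proteins; swap in a curated library for production use.
* The E-value is calibrated for ungapped BLOSUM62 statistics but applied to
  gapped scores; it is monotone and threshold-consistent, not an exact null.
* Operon typing requires assembled, ordered coordinates; fragmented MAGs
  will under-call subtypes (clusters split across contig ends).
* Category II "likely loss" annotations require taxonomic context the
  pipeline does not have; they are accepted only as user-supplied notes.
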