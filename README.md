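# aerotype

Terminal-oxidase survey and aerobic-lifestyle classification for annotated
bacterial (meta)genome assemblies.

Microbes finish aerobic respiration with terminal oxidases — membrane
enzymes that reduce O₂ to water — and the *kind* of oxidase a genome carries
says a lot about the oxygen regime its owner lives in. Six O₂-reducing types
are recognised: the heme-copper oxidase (HCO) families A1 and A2 (low O₂
affinity, Km near the Pasteur point of ~2 µM), B (intermediate affinity) and
C/cbb₃ (high affinity, nanomolar Km), plus the bd-type quinol oxidases
(high-affinity bd-I and the low-affinity cyanide-insensitive Cio) and the
alternative oxidase AOX (lowest affinity). `aerotype` detects these enzymes,
their Cu-assembly chaperones (SCO, Caa3_CtaG, CtaG_Cox11) and a panel of
anaerobic-metabolism traits in protein-annotated genomes; types the oxidase
operons by gene synteny (the binomial "type + subtype" nomenclature, e.g.
*A1 subtype b* for the mitochondria-like COX2–COX1–CtaB–CtaG cluster); and
sorts each genome into one of four aerotype categories:

| category | repertoire |
|---|---|
| I | no O₂-reducing oxidases (strict anaerobe) |
| II | only high-affinity oxidases (bd-I, cbb₃) |
| III | a mixture of affinities (facultative/generalist) |
| IV | only low-affinity oxidases (A1 ± AOX) |

It is aimed at comparative genomicists working with MAG collections who want
a reproducible, scriptable version of this survey: quality gate
(completeness ≥ 90 %, ≥ 16 tRNAs, > 1000 proteins), dual-criterion homolog
detection (identity ≥ 25 % **and** E ≤ 1e-10, with diagnostic-residue and
hydropathy verification; candidates meeting only one criterion are kept as
reviewable *ambiguous* calls), and a presence/absence trait matrix whose
blue intensity increases as oxygen affinity decreases, with black anaerobic
traits, white absences and light-gray ambiguities.

Because no survey genome set is redistributable, the package ships a
fully synthetic benchmark: a seeded generator plants ground-truthed operons,
chaperones, traits and decoys in mock genomes (including the classic edge
cases — a single bd subunit, a tyrosine-less degenerate B oxidase, the
CtaB-less *Magnetospirillum* operon variant, an AOX gene stranded in an
otherwise strictly anaerobic genome). The shipped reference profiles are
synthetic stand-ins; point `load_library` at curated FASTA + YAML references
for production use.

## Worked example

```python
from aerotype.simulate import GenomeSpec, OperonSpec, ChaperoneSpec, generate
from aerotype.report import analyze_genome

spec = GenomeSpec(
    "demo_magnetovibrio_like", seed=7,
    operons=(OperonSpec("A2.CyoCAB", 15.0), OperonSpec("bd_I", 15.0)),
    chaperones=(ChaperoneSpec("SCO", "isolated"),),
    traits=("FeFe_hydrogenase", "HydEFG", "ASCT"),
)
bundle = generate(spec)                  # genome + ground-truth record
result = analyze_genome(bundle.record)   # gate -> detect -> synteny -> classify
print("category:", result.category_label)
print("repertoire:", sorted(result.repertoire))
print("subtypes:", list(result.subtypes))
print("chaperones:", sorted(f"{c.family}:{c.localization}" for c in result.chaperones))
print("traits present:", [t for t, s in result.trait_states.items() if s == "present"])
```

prints

```
category: III
repertoire: ['A2', 'bd_I']
subtypes: ['A2 subtype CyoCAB', 'bd_I subtype bd-I']
chaperones: ['SCO:in_cluster', 'SCO:in_cluster', 'SCO:isolated']
traits present: ['FeFe_hydrogenase', 'HydEFG', 'ASCT']
```

The genome carries a low-affinity A2 oxidase in the SCO-rich CyoCAB operon
arrangement plus a high-affinity bd-I oxidase — a mixed-affinity repertoire,
hence category III (a facultative-anaerobe profile reminiscent of the marine
magnetotactic Rhodospirillaceae). Two SCO chaperones sit inside the CyoCAB
cluster, the third planted copy is correctly reported as isolated elsewhere
in the genome.

The same pipeline runs from the shell on FASTA + GFF3 + metadata:

```bash
aerotype simulate --seed 1 --out genomes/          # synthetic cohort + truth
aerotype classify genomes/IV_A1b.faa genomes/IV_A1b.gff3 genomes/IV_A1b.meta.yaml
aerotype matrix genomes/ --out survey/ --figure    # cohort matrix TSV + PNG
aerotype run-all --seed 1 --out survey/            # simulate + run + verify
```

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates the 30-genome synthetic benchmark cohort from the given seed,
runs the complete pipeline on it (gate, detection, operon typing,
chaperone localization, trait panel, category assignment, trait matrix),
verifies every genome against its ground-truth record, writes the pipeline
artifacts (results/matrix TSVs, run manifest) next to the output file, and
writes the target manifest JSON to `--out`.
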