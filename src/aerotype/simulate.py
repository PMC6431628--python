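"""Synthetic annotated genomes with planted, ground-truthed content.

Because the original survey's genome list is not redistributable, every
pipeline stage is exercised on mock genomes built here: planted oxidase
operons (reference sequences mutated to a requested divergence via seeded
point substitutions that spare diagnostic residues and keep transmembrane
stretches hydrophobic), planted Cu chaperones (inside a cluster or isolated
elsewhere), planted anaerobic-trait genes, composition-preserving shuffled
decoys, and short padding proteins that bring the proteome above the
quality-gate threshold. Each genome ships with a :class:`TruthRecord`
stating the expected downstream verdicts, and :func:`verify` diffs a
pipeline result against it.

Generation is deterministic given (cohort seed, genome id); two runs of the
same spec are byte-identical.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from aerotype.genome_io import GeneFeature, GenomeRecord
from aerotype.ontology import OxidaseFamily, TraitContext, classify_repertoire
from aerotype.profiles import AA20, ReferenceProfile, default_library, get_profile, mutate_sequence
from aerotype.synteny import SubtypeSignature, _contains, load_signatures
from aerotype.traits import load_trait_config

# operon templates: key -> ordered (profile_id, synteny role). The catalytic
# subunits define the family contributed to the repertoire; chaperone
# members are ground-truth 'in_cluster' chaperones.
OPERON_TEMPLATES: dict[str, tuple[tuple[str, str], ...]] = {
    "A1.a":      (("A1.COX2", "COX2"), ("A1.COX1", "COX1"), ("A1.COX3", "COX3")),
    "A1.a-III":  (("A1.COX2", "COX2"), ("A1.COX1", "COX1"), ("A1.COX3", "COX3"), ("A1.COX3", "COX3")),
    "A1.b":      (("A1.COX2", "COX2"), ("A1.COX1", "COX1"), ("acc.CtaB", "CtaB"), ("CtaG_Cox11.Cox11", "CtaG")),
    "A2.CyoCAB": (("A2.COX3", "COX3"), ("A2.COX2", "COX2"), ("A2.COX1", "COX1"), ("SCO.SCO", "SCO"), ("SCO.SCO", "SCO")),
    "A2.a-I":    (("acc.ActB", "ActB"), ("acc.ActA", "ActA"), ("A2.COX1", "COX1"), ("A2.COX2", "COX2"), ("SCO.SCO", "SCO")),
    "B.ba3-a1":  (("B.COX1", "COX1"), ("B.COX2", "COX2"), ("SCO.SCO", "SCO")),
    "bd_I":      (("bd_I.CydA", "CydA"), ("bd_I.CydB", "CydB")),
    "Cio":       (("Cio.CydA", "CydA"), ("Cio.CydB", "CydB")),
    "C_cbb3":    (("C_cbb3.CcoN", "CcoN"), ("C_cbb3.CcoO", "CcoO"), ("C_cbb3.CcoP", "CcoP")),
    "AOX":       (("AOX.AOX", "AOX"),),
    "NOR":       (("NOR.NorB", "NorB"),),
}

# repertoire contribution of each template's catalytic subunit(s)
_TEMPLATE_FAMILY: dict[str, Optional[str]] = {
    "A1.a": "A1", "A1.a-III": "A1", "A1.b": "A1",
    "A2.CyoCAB": "A2", "A2.a-I": "A2", "B.ba3-a1": "B",
    "bd_I": "bd_I", "Cio": "Cio", "C_cbb3": "C_cbb3",
    "AOX": "AOX", "NOR": None,
}


@dataclass(frozen=True)
class OperonSpec:
    template: str
    divergence: float = 15.0            # % substitutions from the references
    strand: str = "+"
    gap_bp: int = 100                   # intergenic gap within the operon
    drop_roles: tuple[str, ...] = ()    # roles removed (first occurrence each)
    remove_diagnostics: tuple[tuple[str, str], ...] = ()  # (role, diagnostic name)
    shuffle: bool = False               # rotate gene order to break synteny

    def __post_init__(self) -> None:
        if self.template not in OPERON_TEMPLATES:
            raise ValueError(f"unknown operon template {self.template!r}")
        if not (0 <= self.divergence <= 80):
            raise ValueError("divergence must be in [0, 80] %")


@dataclass(frozen=True)
class ChaperoneSpec:
    family: str                         # SCO | Caa3_CtaG | CtaG_Cox11
    placement: str                      # in_cluster | isolated
    operon_index: int = 0               # host operon when in_cluster
    divergence: float = 10.0


@dataclass(frozen=True)
class GenomeSpec:
    genome_id: str
    seed: int
    operons: tuple[OperonSpec, ...] = ()
    chaperones: tuple[ChaperoneSpec, ...] = ()
    traits: tuple[str, ...] = ()        # trait names, or "subunit:<name>"
    trait_divergence: float = 15.0
    decoy_count: int = 10
    completeness: Optional[float] = 98.0
    trna_count: int = 24
    total_proteins: int = 1010          # padded with short mock proteins
    taxon_note: str = ""


@dataclass
class TruthRecord:
    genome_id: str
    genes: dict[str, str]               # gene_id -> planted label / decoy / padding
    expected_repertoire: list[str]
    expected_category: str              # I..IV or "withheld"
    expected_override: bool
    expected_subtypes: list[str]
    expected_flags: list[str]           # must all appear in result flags
    expected_traits: dict[str, str]
    expected_chaperones: list[str]      # "family:localization", sorted

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TruthRecord":
        return cls(**json.loads(text))


@dataclass
class GenomeBundle:
    spec: GenomeSpec
    record: GenomeRecord
    truth: TruthRecord


def _rng_for(spec: GenomeSpec) -> np.random.Generator:
    return np.random.default_rng([spec.seed, zlib.crc32(spec.genome_id.encode()) & 0x7FFFFFFF])


def _expected_subtype(roles: Sequence[str], family: Optional[str],
                      signatures: Sequence[SubtypeSignature], minus: bool = False) -> Optional[str]:
    """Binomial label the nomenclature assigns to a planted role order."""
    if family is None:
        return None
    fam = "B" if family == "B_degenerate" else family
    if fam not in {s.family for s in signatures}:
        return None
    ordered = tuple(reversed(roles)) if minus else tuple(roles)
    role_set = set(roles)
    for sig in sorted(signatures, key=lambda s: (-len(s.pattern), s.family, s.subtype)):
        if sig.family != fam:
            continue
        if not (sig.required <= role_set) or (sig.forbidden & role_set):
            continue
        if _contains(ordered, sig.pattern):
            return sig.binomial
    return None


def generate(spec: GenomeSpec) -> GenomeBundle:
    """Build one mock genome plus its ground-truth record."""
    rng = _rng_for(spec)
    signatures = load_signatures()
    trait_config = load_trait_config()

    features: list[GeneFeature] = []
    genes: dict[str, str] = {}
    cursor = 1001
    replicon = "chr1"
    counter = [0]

    def add_gene(seq: str, label: str, gap: int, strand: str = "+") -> str:
        nonlocal cursor
        counter[0] += 1
        gid = f"{spec.genome_id}_g{counter[0]:04d}"
        start = cursor + gap
        end = start + 3 * len(seq) + 2
        features.append(GeneFeature(gid, replicon, start, end, strand, seq))
        genes[gid] = label
        cursor = end
        return gid

    expected_repertoire: set[str] = set()
    expected_subtypes: list[str] = []
    expected_flags: list[str] = []
    expected_chaperones: list[str] = []

    # --- operons
    for op_idx, op in enumerate(spec.operons):
        layout = [
            (pid, role) for pid, role in OPERON_TEMPLATES[op.template]
        ]
        drops = list(op.drop_roles)
        kept = []
        for pid, role in layout:
            if role in drops:
                drops.remove(role)
                continue
            kept.append((pid, role))
        if drops:
            raise ValueError(f"{spec.genome_id}: cannot drop {drops} from {op.template}")

        # chaperones attached to this operon join its tail
        for ch in spec.chaperones:
            if ch.placement == "in_cluster" and ch.operon_index == op_idx:
                pid = {"SCO": "SCO.SCO", "CtaG_Cox11": "CtaG_Cox11.Cox11",
                       "Caa3_CtaG": "Caa3_CtaG.CtaG"}[ch.family]
                role = get_profile(pid).role
                kept.append((pid, role))

        if op.shuffle and len(kept) > 1:
            kept = kept[1:] + kept[:1]  # rotation breaks any canonical order

        order = list(reversed(kept)) if op.strand == "-" else kept

        removed: dict[tuple[str, str], list[str]] = {}
        for role, diag in op.remove_diagnostics:
            removed.setdefault((role, diag), [])

        seen_roles: list[str] = []
        truth_roles: list[str] = []
        family: Optional[str] = _TEMPLATE_FAMILY[op.template]
        degenerate = False
        quinol = False
        chaperone_members: list[str] = []
        for j, (pid, role) in enumerate(order):
            profile = get_profile(pid)
            protected = [d.ref_pos for d in profile.diagnostics]
            seq = mutate_sequence(profile.reference, op.divergence, rng,
                                  protected=protected, tm_segments=profile.tm_segments)
            # targeted diagnostic removal (e.g. catalytic Tyr -> Phe)
            for (r, diag_name), hit_list in removed.items():
                if r == role and not hit_list:
                    diag = next(d for d in profile.diagnostics if d.name == diag_name)
                    letters = list(seq)
                    current = letters[diag.ref_pos]
                    substitute = "F" if current == "Y" else ("S" if current == "C" else "A")
                    letters[diag.ref_pos] = substitute
                    seq = "".join(letters)
                    hit_list.append(role)
                    if diag.on_absent == "relabel_degenerate":
                        degenerate = True
                    elif diag.on_absent == "quinol_variant":
                        quinol = True
            gap = 5000 if j == 0 else op.gap_bp
            add_gene(seq, pid, gap, op.strand)
            truth_roles.append(role)
            if profile.kind == "chaperone":
                chaperone_members.append(profile.target)
            seen_roles.append(role)

        missing = [(r, d) for (r, d), hits_ in removed.items() if not hits_]
        if missing:
            raise ValueError(f"{spec.genome_id}: diagnostics {missing} not applicable to {op.template}")

        # ground-truth repertoire and flags for this operon
        if family in ("bd_I", "Cio"):
            n_cat = sum(1 for r in truth_roles if r in ("CydA", "CydB"))
            if n_cat == 2:
                expected_repertoire.add(family)
            elif n_cat == 1:
                expected_flags.append(f"single_subunit:{family}")
        elif family is not None:
            if degenerate:
                expected_flags.append("B_degenerate_present")
            else:
                expected_repertoire.add(family)
        if op.template == "NOR":
            expected_flags.append("NOR_present_excluded")
        if quinol:
            expected_flags.append(f"quinol_variant:{family}")

        fam_for_subtype = "B_degenerate" if degenerate else family
        label = _expected_subtype(truth_roles, fam_for_subtype, signatures, minus=op.strand == "-")
        if label:
            expected_subtypes.append(label)
        for fam_ch in chaperone_members:
            expected_chaperones.append(f"{fam_ch}:in_cluster")

    # --- isolated chaperones, far from any cluster
    for ch in spec.chaperones:
        if ch.placement != "isolated":
            continue
        pid = {"SCO": "SCO.SCO", "CtaG_Cox11": "CtaG_Cox11.Cox11",
               "Caa3_CtaG": "Caa3_CtaG.CtaG"}[ch.family]
        profile = get_profile(pid)
        seq = mutate_sequence(profile.reference, ch.divergence, rng,
                              protected=[d.ref_pos for d in profile.diagnostics],
                              tm_segments=profile.tm_segments)
        add_gene(seq, pid, 25000)
        expected_chaperones.append(f"{ch.family}:isolated")

    # --- trait genes
    expected_traits = {t: "absent" for t in trait_config.order}
    for entry in spec.traits:
        if entry.startswith("subunit:"):
            subunits = [entry.split(":", 1)[1]]
        else:
            if entry not in trait_config.subunits:
                raise ValueError(f"unknown trait {entry!r}")
            subunits = list(trait_config.subunits[entry])
        for sub in subunits:
            profile = get_profile(f"trait.{sub}")
            seq = mutate_sequence(profile.reference, spec.trait_divergence, rng,
                                  tm_segments=profile.tm_segments)
            add_gene(seq, profile.profile_id, 8000)
    # expected trait states from planted subunits + quorum rules
    planted_subunits = {g.split(".")[-1] for g in genes.values() if g.startswith("trait.")}
    for trait in trait_config.order:
        n = sum(1 for s in trait_config.subunits[trait] if s in planted_subunits)
        if n >= trait_config.quorum[trait]:
            expected_traits[trait] = "present"
        elif n > 0:
            expected_traits[trait] = "ambiguous"

    # --- decoys: composition-preserving shuffles of references
    lib = default_library()
    for i in range(spec.decoy_count):
        ref = lib[i % len(lib)].reference
        shuffled = "".join(np.array(list(ref))[rng.permutation(len(ref))])
        add_gene(shuffled, "decoy", 4000)

    # --- padding to the requested proteome size (short mock proteins,
    # below the detector's length-ratio floor for every reference)
    while len(features) < spec.total_proteins:
        k = int(rng.integers(50, 75))
        seq = "".join(rng.choice(list(AA20), size=k))
        add_gene(seq, "padding", 1500)

    record = GenomeRecord(
        genome_id=spec.genome_id,
        features=sorted(features, key=lambda f: (f.replicon, f.start, f.gene_id)),
        completeness=spec.completeness,
        trna_count=spec.trna_count,
        taxon_note=spec.taxon_note,
    )

    gate_ok = (
        spec.completeness is not None and spec.completeness >= 90
        and spec.trna_count >= 16 and record.protein_count > 1000
    )
    if not gate_ok:
        # a lone bd subunit is only an ambiguous call in gate-passing genomes
        expected_flags = [
            f.replace("single_subunit:", "single_subunit_low_completeness:")
            if f.startswith("single_subunit:") else f
            for f in expected_flags
        ]
    if gate_ok:
        context = TraitContext(
            anaerobic_traits_present=sum(
                1 for t in trait_config.anaerobic if expected_traits[t] == "present"
            ),
            aerobic_chain_present=any(
                expected_traits[t] == "present" for t in trait_config.aerobic_chain
            ),
        )
        category = classify_repertoire(
            {OxidaseFamily(f) for f in expected_repertoire}, context
        )
        expected_category = category.label
        expected_override = category.override is not None
        expected_flags.extend(category.flags)
    else:
        expected_category = "withheld"
        expected_override = False

    truth = TruthRecord(
        genome_id=spec.genome_id,
        genes=genes,
        expected_repertoire=sorted(expected_repertoire),
        expected_category=expected_category,
        expected_override=expected_override,
        expected_subtypes=sorted(expected_subtypes),
        expected_flags=sorted(set(expected_flags)),
        expected_traits=expected_traits,
        expected_chaperones=sorted(expected_chaperones),
    )
    return GenomeBundle(spec=spec, record=record, truth=truth)


def mutate_case(bundle: GenomeBundle, edit: dict) -> GenomeBundle:
    """Apply a named edge-case edit and regenerate genome + truth.

    Supported edits:
    ``{"op": "drop_subunit", "operon": i, "role": "CydB"}``,
    ``{"op": "remove_residue", "operon": i, "role": "COX1", "diagnostic": "catalytic_Tyr"}``,
    ``{"op": "shuffle_cluster", "operon": i}``,
    ``{"op": "set_completeness", "value": 85.0}``.
    """
    spec = bundle.spec
    kind = edit["op"]
    if kind == "set_completeness":
        new_spec = replace(spec, completeness=float(edit["value"]))
    elif kind in ("drop_subunit", "remove_residue", "shuffle_cluster"):
        idx = int(edit.get("operon", 0))
        if idx >= len(spec.operons):
            raise ValueError(f"no operon {idx} in {spec.genome_id}")
        op = spec.operons[idx]
        if kind == "drop_subunit":
            roles = [r for _, r in OPERON_TEMPLATES[op.template]]
            if edit["role"] not in roles:
                raise ValueError(f"role {edit['role']!r} not in template {op.template}")
            op = replace(op, drop_roles=op.drop_roles + (edit["role"],))
        elif kind == "remove_residue":
            op = replace(op, remove_diagnostics=op.remove_diagnostics + ((edit["role"], edit["diagnostic"]),))
        else:
            op = replace(op, shuffle=True)
        ops = list(spec.operons)
        ops[idx] = op
        new_spec = replace(spec, operons=tuple(ops))
    else:
        raise ValueError(f"unknown edit {kind!r}")
    return generate(new_spec)


def write_bundle(bundle: GenomeBundle, out_dir: Union[str, Path]) -> dict[str, Path]:
    """Write FASTA + GFF3 + metadata YAML + truth JSON for one genome."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rec = bundle.record
    paths = {
        "fasta": out_dir / f"{rec.genome_id}.faa",
        "gff": out_dir / f"{rec.genome_id}.gff3",
        "metadata": out_dir / f"{rec.genome_id}.meta.yaml",
        "truth": out_dir / f"{rec.genome_id}.truth.json",
    }
    SeqIO.write(
        [SeqRecord(Seq(f.product_seq), id=f.gene_id, description="") for f in rec.features],
        str(paths["fasta"]), "fasta",
    )
    with open(paths["gff"], "w") as fh:
        fh.write("##gff-version 3\n")
        for f in rec.features:
            fh.write(
                f"{f.replicon}\taerotype-sim\tCDS\t{f.start}\t{f.end}\t.\t{f.strand}\t0\tID={f.gene_id}\n"
            )
    with open(paths["metadata"], "w") as fh:
        yaml.safe_dump(
            {"genome_id": rec.genome_id, "completeness": rec.completeness,
             "trna_count": rec.trna_count, "taxon_note": rec.taxon_note},
            fh, sort_keys=True,
        )
    paths["truth"].write_text(bundle.truth.to_json())
    return paths


def verify(truth: TruthRecord, result) -> list[str]:
    """Diff a pipeline result against a truth record; empty = full recovery."""
    problems: list[str] = []
    if result.category_label != truth.expected_category:
        problems.append(f"category: {result.category_label} != {truth.expected_category}")
    has_override = bool(result.category and result.category.override)
    if has_override != truth.expected_override:
        problems.append(f"override: {has_override} != {truth.expected_override}")
    if sorted(result.repertoire) != truth.expected_repertoire:
        problems.append(f"repertoire: {sorted(result.repertoire)} != {truth.expected_repertoire}")
    if sorted(result.subtypes) != truth.expected_subtypes:
        problems.append(f"subtypes: {sorted(result.subtypes)} != {truth.expected_subtypes}")
    for trait, state in truth.expected_traits.items():
        got = result.trait_states.get(trait, "absent")
        if got != state:
            problems.append(f"trait {trait}: {got} != {state}")
    got_ch = sorted(f"{c.family}:{c.localization}" for c in result.chaperones)
    if got_ch != truth.expected_chaperones:
        problems.append(f"chaperones: {got_ch} != {truth.expected_chaperones}")
    missing = [f for f in truth.expected_flags if f not in result.flags]
    if missing:
        problems.append(f"missing flags: {missing} (got {list(result.flags)})")
    return problems


def default_cohort(seed: int, total_proteins: int = 1010) -> list[GenomeSpec]:
    """The shipped 30-genome cohort: all four categories, every operon
    subtype the nomenclature defines for alphaproteobacteria, and the edge
    cases (single bd subunit, tyrosine-less B, CtaB-less A1-b, AOX-only
    anaerobe, quinol variant, shuffled cluster, gate failure)."""
    s = int(seed)
    ops = lambda *a: tuple(a)  # noqa: E731

    specs = [
        # --- category I
        GenomeSpec("I_strict_anaerobe", s, traits=("FeFe_hydrogenase", "HydEFG", "ASCT", "fumarase"),
                   total_proteins=total_proteins),
        GenomeSpec("I_aox_contaminant", s, operons=ops(OperonSpec("AOX", 10.0)),
                   traits=("FeFe_hydrogenase", "HydEFG", "malic_enzyme"),
                   total_proteins=total_proteins, taxon_note="GWF2-like"),
        GenomeSpec("I_bare", s, traits=("ASCT", "malic_enzyme", "fumarase"),
                   decoy_count=12, total_proteins=total_proteins),
        GenomeSpec("I_nor_only", s, operons=ops(OperonSpec("NOR", 15.0)),
                   traits=("FeFe_hydrogenase", "fumarase"), total_proteins=total_proteins),
        # --- category II
        GenomeSpec("II_cbb3", s, operons=ops(OperonSpec("C_cbb3", 12.0)),
                   traits=("FeFe_hydrogenase", "HydEFG", "complex_II"),
                   total_proteins=total_proteins, taxon_note="Magnetococcus-like"),
        GenomeSpec("II_bdI", s, operons=ops(OperonSpec("bd_I", 15.0)),
                   traits=("ASCT", "fumarase"), total_proteins=total_proteins),
        GenomeSpec("II_bdI_cbb3", s, operons=ops(OperonSpec("bd_I", 20.0), OperonSpec("C_cbb3", 20.0)),
                   traits=("HydEFG", "malic_enzyme", "complex_I"), total_proteins=total_proteins),
        GenomeSpec("II_cbb3_div30", s, operons=ops(OperonSpec("C_cbb3", 30.0)),
                   traits=("FeFe_hydrogenase",), total_proteins=total_proteins),
        GenomeSpec("II_bdI_sco_isolated", s, operons=ops(OperonSpec("bd_I", 10.0)),
                   chaperones=(ChaperoneSpec("SCO", "isolated"),),
                   traits=("fumarase",), total_proteins=total_proteins),
        # --- category III
        GenomeSpec("III_A1b_cbb3", s, operons=ops(OperonSpec("A1.b", 15.0), OperonSpec("C_cbb3", 15.0)),
                   traits=("complex_I", "complex_II", "complex_III", "quinone_biosynthesis", "fumarase"),
                   total_proteins=total_proteins, taxon_note="facultative anaerobe"),
        GenomeSpec("III_A1a_bdI", s, operons=ops(OperonSpec("A1.a", 15.0), OperonSpec("bd_I", 15.0)),
                   chaperones=(ChaperoneSpec("Caa3_CtaG", "in_cluster", 0),),
                   traits=("complex_I", "complex_II", "complex_III"), total_proteins=total_proteins),
        GenomeSpec("III_mixed_tiers", s,
                   operons=ops(OperonSpec("A1.b", 18.0), OperonSpec("B.ba3-a1", 15.0), OperonSpec("C_cbb3", 15.0)),
                   traits=("complex_I", "complex_II", "complex_III", "malic_enzyme"),
                   total_proteins=total_proteins, taxon_note="Azospirillum-like"),
        GenomeSpec("III_A2CyoCAB_bdI", s, operons=ops(OperonSpec("A2.CyoCAB", 15.0), OperonSpec("bd_I", 15.0)),
                   traits=("FeFe_hydrogenase", "HydEFG", "ASCT"),
                   total_proteins=total_proteins, taxon_note="Magnetovibrio-like"),
        GenomeSpec("III_all_six", s,
                   operons=ops(OperonSpec("A1.b", 12.0), OperonSpec("A2.CyoCAB", 12.0),
                               OperonSpec("B.ba3-a1", 12.0), OperonSpec("bd_I", 12.0),
                               OperonSpec("Cio", 12.0), OperonSpec("C_cbb3", 12.0),
                               OperonSpec("AOX", 12.0), OperonSpec("NOR", 12.0)),
                   traits=("complex_I", "complex_II", "complex_III", "FeFe_hydrogenase",
                           "HydEFG", "ASCT", "malic_enzyme", "fumarase", "quinone_biosynthesis"),
                   total_proteins=total_proteins, taxon_note="Rhodospirillaceae-like"),
        GenomeSpec("III_minus_strand", s,
                   operons=ops(OperonSpec("A1.b", 15.0, strand="-"), OperonSpec("C_cbb3", 15.0)),
                   traits=("complex_I", "complex_II", "complex_III"), total_proteins=total_proteins),
        GenomeSpec("III_div40", s, operons=ops(OperonSpec("A1.b", 40.0), OperonSpec("bd_I", 35.0)),
                   traits=("complex_I", "complex_II", "complex_III"), total_proteins=total_proteins),
        # --- category IV
        GenomeSpec("IV_A1b", s, operons=ops(OperonSpec("A1.b", 15.0)),
                   traits=("complex_I", "complex_II", "complex_III"), total_proteins=total_proteins),
        GenomeSpec("IV_A1a_AOX", s, operons=ops(OperonSpec("A1.a", 15.0), OperonSpec("AOX", 15.0)),
                   traits=("complex_I", "complex_II", "complex_III", "quinone_biosynthesis"),
                   total_proteins=total_proteins),
        GenomeSpec("IV_A1aIII", s, operons=ops(OperonSpec("A1.a-III", 15.0)),
                   traits=("complex_I", "complex_II", "complex_III"), total_proteins=total_proteins),
        GenomeSpec("IV_A1aIII_cox11_isolated", s, operons=ops(OperonSpec("A1.a-III", 15.0)),
                   chaperones=(ChaperoneSpec("CtaG_Cox11", "isolated"),),
                   traits=("complex_I", "complex_II", "complex_III"), total_proteins=total_proteins),
        GenomeSpec("IV_A2aI", s, operons=ops(OperonSpec("A2.a-I", 15.0)),
                   traits=("complex_I", "complex_II", "complex_III"), total_proteins=total_proteins),
        GenomeSpec("IV_cio", s, operons=ops(OperonSpec("Cio", 15.0)),
                   traits=("complex_II",), total_proteins=total_proteins),
        GenomeSpec("IV_two_A1_operons", s,
                   operons=ops(OperonSpec("A1.a", 15.0), OperonSpec("A1.b", 25.0), OperonSpec("AOX", 15.0)),
                   traits=("complex_I", "complex_II", "complex_III"), total_proteins=total_proteins),
        # --- edge cases
        GenomeSpec("edge_bd_single_subunit", s,
                   operons=ops(OperonSpec("bd_I", 15.0, drop_roles=("CydB",)), OperonSpec("C_cbb3", 15.0)),
                   traits=("fumarase",), total_proteins=total_proteins),
        GenomeSpec("edge_B_degenerate", s,
                   operons=ops(OperonSpec("B.ba3-a1", 15.0, remove_diagnostics=(("COX1", "catalytic_Tyr"),)),
                               OperonSpec("A1.b", 15.0)),
                   traits=("complex_I", "complex_II", "complex_III"),
                   total_proteins=total_proteins, taxon_note="Magnetospirillum-like"),
        GenomeSpec("edge_ctab_less_A1b", s,
                   operons=ops(OperonSpec("A1.b", 15.0, drop_roles=("CtaB",)),),
                   traits=("complex_I", "complex_II", "complex_III"),
                   total_proteins=total_proteins, taxon_note="Magnetospirillum variant"),
        GenomeSpec("edge_quinol_variant", s,
                   operons=ops(OperonSpec("A1.a", 15.0, remove_diagnostics=(("COX2", "CuA_Cys1"),)),),
                   traits=("complex_I", "complex_II", "complex_III"),
                   total_proteins=total_proteins, taxon_note="bo3-like"),
        GenomeSpec("edge_shuffled_cluster", s,
                   operons=ops(OperonSpec("A1.a", 15.0, shuffle=True),),
                   traits=("complex_I", "complex_II", "complex_III"), total_proteins=total_proteins),
        GenomeSpec("edge_hydE_only", s, traits=("subunit:HydE", "FeFe_hydrogenase"),
                   total_proteins=total_proteins),
        GenomeSpec("edge_gate_fail", s, operons=ops(OperonSpec("A1.b", 15.0)),
                   traits=("complex_I",), completeness=85.0, total_proteins=total_proteins),
    ]
    assert len(specs) == 30
    return specs


def calibration_curve(profile_id: str, divergences: Sequence[float], seed: int) -> list[float]:
    """Percent identity of a mutated copy against its own reference, per
    requested divergence — the generator's own divergence/identity oracle."""
    from aerotype.detection import align_identity

    profile = get_profile(profile_id)
    rng = np.random.default_rng([seed, zlib.crc32(profile_id.encode()) & 0x7FFFFFFF])
    out = []
    for d in divergences:
        seq = mutate_sequence(profile.reference, d, rng,
                              protected=[x.ref_pos for x in profile.diagnostics],
                              tm_segments=profile.tm_segments)
        out.append(align_identity(seq, profile.reference).percent_identity)
    return out
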