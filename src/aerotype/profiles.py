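"""Reference profile library for homolog detection.

A :class:`ReferenceProfile` bundles a reference amino-acid sequence for one
subunit (e.g. the catalytic subunit I of an A1-type heme-copper oxidase),
the diagnostic residues that verify a hit (CuB-ligating histidines, the
catalytic tyrosine, CuA ligands, chaperone Cu-binding cysteines, ...), the
expected transmembrane-segment count, and a competition group that collects
mutually homologous profiles (a gene is assigned to the best profile of its
group, with a minimum identity margin).

The default library shipped here is SYNTHETIC: deterministic, seeded mock
sequences with planted hydrophobic transmembrane stretches and planted
diagnostic residues. They stand in for curated reference alignments (which
cannot be redistributed here) and are the same sequences the synthetic
genome generator mutates, so divergence between a planted gene and its
profile is exactly controllable. A user-curated library of real references
can be loaded from FASTA + YAML sidecar via :func:`load_library`.

Diagnostic ``on_absent`` policies:

* ``reject`` — the residue is required; its absence rejects the hit.
* ``relabel_degenerate`` — B-family subunit I lacking the catalytic
  tyrosine is relabelled a degenerate B oxidase (not an O2 reductase).
* ``quinol_variant`` — subunit II lacking the CuA ligand set is accepted
  and flagged as a quinol-oxidizing (bo3-like) variant.
* ``ambiguous`` — the hit is kept but demoted to ambiguous.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml
from Bio import SeqIO

# Kyte-Doolittle hydropathy scale.
KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}

HYDROPHOBIC = "ILVFAM"
LOOP_ALPHABET = "DEKRNQSTGPHYWA"
AA20 = "ACDEFGHIKLMNPQRSTVWY"

_LIBRARY_SALT = 7654321  # fixed: the reference library is part of the stated world


@dataclass(frozen=True)
class Diagnostic:
    """One diagnostic residue on the profile reference (0-based position)."""

    name: str
    ref_pos: int
    allowed: frozenset[str]
    on_absent: str  # reject | relabel_degenerate | quinol_variant | ambiguous


@dataclass(frozen=True)
class ReferenceProfile:
    profile_id: str
    kind: str        # oxidase | accessory | chaperone | trait
    target: str      # oxidase subfamily, chaperone family, or trait-subunit name
    role: str        # synteny role (COX1, CydA, SCO, CtaG, ...)
    reference_seqs: tuple[str, ...]
    diagnostics: tuple[Diagnostic, ...]
    expected_tm_range: tuple[int, int]
    tm_segments: tuple[tuple[int, int], ...]  # planted segments, generator use
    competition_group: str
    comparative: bool = False

    def __post_init__(self) -> None:
        if not self.reference_seqs:
            raise ValueError(f"{self.profile_id}: profile needs >= 1 reference sequence")
        n = len(self.reference_seqs[0])
        for d in self.diagnostics:
            if not (0 <= d.ref_pos < n):
                raise ValueError(f"{self.profile_id}: diagnostic {d.name} outside reference")

    @property
    def reference(self) -> str:
        return self.reference_seqs[0]


def _rng_for(profile_id: str) -> np.random.Generator:
    return np.random.default_rng([_LIBRARY_SALT, zlib.crc32(profile_id.encode())])


def _synth_sequence(
    rng: np.random.Generator,
    n_tm: int,
    loop_len: tuple[int, int] = (20, 32),
    tm_len: int = 21,
    min_len: int = 250,
) -> tuple[str, list[tuple[int, int]]]:
    """Mock membrane protein: hydrophilic loops alternating with TM stretches."""
    parts: list[str] = []
    segments: list[tuple[int, int]] = []
    pos = 0

    def loop() -> None:
        nonlocal pos
        k = int(rng.integers(*loop_len))
        parts.append("".join(rng.choice(list(LOOP_ALPHABET), size=k)))
        pos += k

    loop()
    for _ in range(n_tm):
        seg = "".join(rng.choice(list(HYDROPHOBIC), size=tm_len))
        segments.append((pos, pos + tm_len))
        parts.append(seg)
        pos += tm_len
        loop()
    seq = "".join(parts)
    while len(seq) < min_len:  # pad soluble proteins to a realistic size
        extra = "".join(rng.choice(list(LOOP_ALPHABET + "ACFILMVWY"), size=min_len - len(seq)))
        seq += extra
    return seq, segments


def _place_diagnostics(
    seq: str,
    segments: list[tuple[int, int]],
    spec: Sequence[tuple[str, str, str]],
    rng: np.random.Generator,
) -> tuple[str, tuple[Diagnostic, ...]]:
    """Plant diagnostic residues in loop regions, well separated."""
    in_tm = np.zeros(len(seq), dtype=bool)
    for s, e in segments:
        in_tm[s:e] = True
    # candidate loop positions away from sequence ends
    candidates = [i for i in range(15, len(seq) - 15) if not in_tm[i]]
    chosen: list[int] = []
    for i in candidates:
        if all(abs(i - j) >= 8 for j in chosen):
            chosen.append(i)
        if len(chosen) >= len(spec):
            break
    if len(chosen) < len(spec):
        raise ValueError("not enough loop positions for diagnostics")
    letters = list(seq)
    diags = []
    for (name, allowed, on_absent), pos in zip(spec, chosen):
        letters[pos] = allowed[0]
        diags.append(Diagnostic(name, pos, frozenset(allowed), on_absent))
    return "".join(letters), tuple(diags)


def _derive(parent: ReferenceProfile, divergence: float, rng: np.random.Generator) -> tuple[str, tuple[Diagnostic, ...]]:
    """A homologous reference: point substitutions away from the parent,
    sparing diagnostic positions and keeping TM stretches hydrophobic."""
    seq = mutate_sequence(
        parent.reference, divergence, rng,
        protected=[d.ref_pos for d in parent.diagnostics],
        tm_segments=parent.tm_segments,
    )
    return seq, parent.diagnostics


def mutate_sequence(
    seq: str,
    divergence_pct: float,
    rng: np.random.Generator,
    protected: Sequence[int] = (),
    tm_segments: Sequence[tuple[int, int]] = (),
) -> str:
    """Substitute ``divergence_pct`` % of positions with different residues.

    Protected (diagnostic) positions are never touched; positions inside TM
    segments are substituted within the hydrophobic alphabet so hydropathy is
    preserved, which keeps divergence and TM count independently tunable.
    """
    if not (0 <= divergence_pct <= 80):
        raise ValueError("divergence must be within [0, 80] %")
    letters = list(seq)
    in_tm = np.zeros(len(seq), dtype=bool)
    for s, e in tm_segments:
        in_tm[s:e] = True
    eligible = np.array([i for i in range(len(seq)) if i not in set(protected)])
    n_mut = int(round(divergence_pct / 100 * len(seq)))
    n_mut = min(n_mut, len(eligible))
    sites = rng.choice(eligible, size=n_mut, replace=False)
    for i in sites:
        pool = HYDROPHOBIC if in_tm[i] else AA20
        choices = [a for a in pool if a != letters[i]]
        letters[i] = str(rng.choice(choices))
    return "".join(letters)


def tm_range_of(seq: str, margin: int = 2) -> tuple[int, int]:
    from aerotype.detection import tm_count

    t = tm_count(seq)
    return (max(0, t - margin), t + margin)


_HCO1_DIAG = [
    ("CuB_His1", "H", "reject"),
    ("CuB_His2", "H", "reject"),
    ("CuB_His3", "H", "reject"),
    ("catalytic_Tyr", "Y", "reject"),
]
_HCO1_DIAG_B = _HCO1_DIAG[:3] + [("catalytic_Tyr", "Y", "relabel_degenerate")]
_HCO1_DIAG_NOR = _HCO1_DIAG[:3]  # NOR naturally lacks the catalytic tyrosine
_COX2_DIAG = [
    ("CuA_Cys1", "C", "quinol_variant"),
    ("CuA_Cys2", "C", "quinol_variant"),
    ("CuA_His", "H", "quinol_variant"),
    ("CuA_Met", "M", "quinol_variant"),
]
_SCO_DIAG = [("Cu_Cys1", "C", "ambiguous"), ("Cu_Cys2", "C", "ambiguous"), ("Cu_His", "H", "ambiguous")]
_COX11_DIAG = [("Cu_Cys1", "C", "ambiguous"), ("Cu_Cys2", "C", "ambiguous")]
_CAA3_CTAG_DIAG = [
    ("Cu_His1", "H", "ambiguous"),
    ("Cu_His2", "H", "ambiguous"),
    ("Cu_Asp", "D", "ambiguous"),
    ("Cu_Met", "M", "ambiguous"),
]
_AOX_DIAG = [("diiron_Glu1", "E", "reject"), ("diiron_Glu2", "E", "reject"), ("diiron_His", "H", "reject")]


def _build_root(
    profile_id: str, kind: str, target: str, role: str, n_tm: int,
    diag_spec: Sequence[tuple[str, str, str]], group: str, comparative: bool = False,
) -> ReferenceProfile:
    rng = _rng_for(profile_id)
    seq, segments = _synth_sequence(rng, n_tm)
    seq, diags = _place_diagnostics(seq, segments, diag_spec, rng)
    return ReferenceProfile(
        profile_id=profile_id, kind=kind, target=target, role=role,
        reference_seqs=(seq,), diagnostics=diags,
        expected_tm_range=(0, 0),  # patched after tm_count is importable
        tm_segments=tuple(segments), competition_group=group, comparative=comparative,
    )


def _build_derived(
    profile_id: str, parent: ReferenceProfile, divergence: float, *,
    target: str, role: Optional[str] = None, diagnostics: Optional[Sequence[tuple[str, str, str]]] = None,
) -> ReferenceProfile:
    rng = _rng_for(profile_id)
    seq, diags = _derive(parent, divergence, rng)
    if diagnostics is not None:
        diags = tuple(
            Diagnostic(name, d.ref_pos, frozenset(allowed), on_absent)
            for d, (name, allowed, on_absent) in zip(parent.diagnostics, diagnostics)
        )
    return ReferenceProfile(
        profile_id=profile_id, kind=parent.kind, target=target, role=role or parent.role,
        reference_seqs=(seq,), diagnostics=diags,
        expected_tm_range=(0, 0), tm_segments=parent.tm_segments,
        competition_group=parent.competition_group,
    )


@lru_cache(maxsize=1)
def default_library() -> tuple[ReferenceProfile, ...]:
    """The shipped synthetic reference library (deterministic, fixed seed)."""
    profiles: list[ReferenceProfile] = []

    # --- heme-copper oxidase catalytic subunits (subunit I), one competition
    # group: A1 is the root, A2/B are moderately diverged homologs, the
    # compact C-family CcoN and NOR are independent/distant relatives.
    a1_cox1 = _build_root("A1.COX1", "oxidase", "A1", "COX1", 12, _HCO1_DIAG, "HCO_COX1")
    a2_cox1 = _build_derived("A2.COX1", a1_cox1, 40.0, target="A2")
    b_cox1 = _build_derived("B.COX1", a1_cox1, 50.0, target="B", diagnostics=_HCO1_DIAG_B)
    ccon = _build_root("C_cbb3.CcoN", "oxidase", "C_cbb3", "CcoN", 12, _HCO1_DIAG, "HCO_COX1")
    norb = _build_derived("NOR.NorB", ccon, 45.0, target="NOR", role="NorB",
                          diagnostics=None)
    norb = ReferenceProfile(  # NOR keeps CuB histidines only
        profile_id=norb.profile_id, kind=norb.kind, target=norb.target, role=norb.role,
        reference_seqs=norb.reference_seqs,
        diagnostics=tuple(d for d in norb.diagnostics if d.name != "catalytic_Tyr"),
        expected_tm_range=norb.expected_tm_range, tm_segments=norb.tm_segments,
        competition_group=norb.competition_group,
    )
    profiles += [a1_cox1, a2_cox1, b_cox1, ccon, norb]

    # --- subunit II (CuA-carrying; loss of the ligand set marks a
    # quinol-oxidizing bo3-like variant) and subunit III
    a1_cox2 = _build_root("A1.COX2", "oxidase", "A1", "COX2", 2, _COX2_DIAG, "HCO_COX2")
    profiles += [
        a1_cox2,
        _build_derived("A2.COX2", a1_cox2, 40.0, target="A2"),
        _build_derived("B.COX2", a1_cox2, 50.0, target="B"),
    ]
    a1_cox3 = _build_root("A1.COX3", "oxidase", "A1", "COX3", 7, [], "HCO_COX3")
    profiles += [a1_cox3, _build_derived("A2.COX3", a1_cox3, 40.0, target="A2")]
    profiles += [
        _build_root("C_cbb3.CcoO", "oxidase", "C_cbb3", "CcoO", 1, [], "C_cbb3.CcoO"),
        _build_root("C_cbb3.CcoP", "oxidase", "C_cbb3", "CcoP", 2, [], "C_cbb3.CcoP"),
    ]

    # --- bd-type quinol oxidases: bd-I and the cyanide-insensitive Cio are
    # homologous subunit pairs, discriminated by nearest profile + margin.
    cyda = _build_root("bd_I.CydA", "oxidase", "bd_I", "CydA", 9, [], "BD_A")
    cydb = _build_root("bd_I.CydB", "oxidase", "bd_I", "CydB", 8, [], "BD_B")
    profiles += [
        cyda, cydb,
        _build_derived("Cio.CydA", cyda, 40.0, target="Cio"),
        _build_derived("Cio.CydB", cydb, 40.0, target="Cio"),
    ]

    # --- alternative oxidase: interfacial membrane protein, diiron carboxylate
    profiles += [_build_root("AOX.AOX", "oxidase", "AOX", "AOX", 0, _AOX_DIAG, "AOX.AOX")]

    # --- family-neutral operon accessories
    profiles += [
        _build_root("acc.CtaB", "accessory", "accessory", "CtaB", 7, [], "acc.CtaB"),
        _build_root("acc.ActA", "accessory", "accessory", "ActA", 1, [], "acc.ActA"),
        _build_root("acc.ActB", "accessory", "accessory", "ActB", 0, [], "acc.ActB"),
    ]

    # --- Cu assembly chaperones
    profiles += [
        _build_root("SCO.SCO", "chaperone", "SCO", "SCO", 1, _SCO_DIAG, "SCO.SCO"),
        _build_root("CtaG_Cox11.Cox11", "chaperone", "CtaG_Cox11", "CtaG", 1, _COX11_DIAG, "CtaG_Cox11.Cox11"),
        _build_root("Caa3_CtaG.CtaG", "chaperone", "Caa3_CtaG", "CtaG", 7, _CAA3_CTAG_DIAG, "Caa3_CtaG.CtaG"),
    ]

    # --- anaerobic / bioenergetic trait subunits (soluble unless noted)
    trait_subunits = [
        ("HydA", 0), ("HydE", 0), ("HydF", 0), ("HydG", 0),
        ("Asct", 0), ("MaeB", 0), ("FumB", 0),
        ("NuoB", 0), ("NuoF", 0), ("SdhA", 0), ("PetB", 8), ("UbiA", 9),
    ]
    for name, n_tm in trait_subunits:
        profiles.append(_build_root(f"trait.{name}", "trait", name, name, n_tm, [], f"trait.{name}"))

    # Freeze expected TM ranges from the shipped references themselves.
    out = []
    for p in profiles:
        lo, hi = tm_range_of(p.reference)
        out.append(ReferenceProfile(
            profile_id=p.profile_id, kind=p.kind, target=p.target, role=p.role,
            reference_seqs=p.reference_seqs, diagnostics=p.diagnostics,
            expected_tm_range=(lo, hi), tm_segments=p.tm_segments,
            competition_group=p.competition_group, comparative=p.comparative,
        ))
    return tuple(out)


def get_profile(profile_id: str) -> ReferenceProfile:
    for p in default_library():
        if p.profile_id == profile_id:
            return p
    raise KeyError(profile_id)


def load_library(fasta_path: Path, sidecar_path: Path) -> tuple[ReferenceProfile, ...]:
    """Load a user-curated library: FASTA references + YAML sidecar.

    The sidecar maps each FASTA id to kind/target/role/competition_group,
    diagnostic positions (1-based in the sidecar, converted here) and an
    expected TM-count range.
    """
    with open(sidecar_path) as fh:
        meta = yaml.safe_load(fh)
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    profiles = []
    for pid, m in meta["profiles"].items():
        if pid not in seqs:
            raise ValueError(f"sidecar profile {pid!r} missing from {fasta_path}")
        diags = tuple(
            Diagnostic(d["name"], int(d["position"]) - 1, frozenset(d["allowed"]), d["on_absent"])
            for d in m.get("diagnostics", [])
        )
        profiles.append(ReferenceProfile(
            profile_id=pid, kind=m["kind"], target=m["target"], role=m["role"],
            reference_seqs=(seqs[pid],), diagnostics=diags,
            expected_tm_range=tuple(m.get("expected_tm_range", (0, 99))),
            tm_segments=tuple(tuple(s) for s in m.get("tm_segments", [])),
            competition_group=m.get("competition_group", pid),
            comparative=bool(m.get("comparative", False)),
        ))
    return tuple(profiles)
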