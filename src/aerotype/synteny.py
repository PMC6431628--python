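"""Operon clustering and binomial synteny-subtype assignment.

Accepted detection hits are clustered into maximal runs of co-located genes
(consecutive intergenic gaps at most ``max_gap``, default 500 bp, regardless
of strand), then each cluster carrying at least one catalytic oxidase
subunit is matched against an ordered-role signature table to receive a
binomial (type, subtype) label — e.g. A1 subtype b for the mitochondria-like
COX2-COX1-CtaB-CtaG arrangement, or its Magnetospirillum variant when CtaB
is missing between COX1 and CtaG. Clusters matching no signature are
reported as 'unclassified' with their observed role string; clusters mixing
catalytic subunits of different families are flagged chimeric.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

import yaml

from aerotype.detection import DetectionHit
from aerotype.genome_io import GeneFeature, GenomeRecord

# roles that define the oxidase family of a cluster
CATALYTIC_ROLES = {"COX1", "COX2", "COX3", "CydA", "CydB", "CcoN", "CcoO", "CcoP", "AOX", "NorB"}


@dataclass(frozen=True)
class ClusterMember:
    gene_id: str
    role: str
    target: str
    strand: str
    start: int
    end: int


@dataclass(frozen=True)
class OperonCluster:
    replicon: str
    members: tuple[ClusterMember, ...]  # sorted by coordinate

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("empty cluster")
        starts = [m.start for m in self.members]
        if starts != sorted(starts):
            raise ValueError("cluster members must be coordinate-sorted")

    @property
    def span(self) -> tuple[int, int]:
        return (self.members[0].start, self.members[-1].end)

    @property
    def roles(self) -> tuple[str, ...]:
        return tuple(m.role for m in self.members)

    def family(self) -> Optional[str]:
        """Oxidase family of the cluster from its catalytic subunits.

        Degenerate-B members count as family B for synteny purposes.
        Returns None for clusters without catalytic subunits and the string
        'chimeric' when catalytic subunits disagree.
        """
        fams = set()
        for m in self.members:
            if m.role in CATALYTIC_ROLES:
                fams.add("B" if m.target == "B_degenerate" else m.target)
        if not fams:
            return None
        if len(fams) > 1:
            return "chimeric"
        return fams.pop()


@dataclass(frozen=True)
class SubtypeSignature:
    family: str
    subtype: str
    pattern: tuple[str, ...]
    required: frozenset[str] = frozenset()
    forbidden: frozenset[str] = frozenset()
    comparative: bool = False

    @property
    def binomial(self) -> str:
        return f"{self.family} subtype {self.subtype}"


def _contains(haystack: Sequence[str], needle: Sequence[str]) -> bool:
    n, m = len(haystack), len(needle)
    return any(tuple(haystack[i:i + m]) == tuple(needle) for i in range(n - m + 1))


def load_signatures(path=None) -> tuple[SubtypeSignature, ...]:
    """Load and validate the signature table (ships as package data).

    Validation fails fast when two signatures of the same family are
    mutually indistinguishable: identical patterns whose required/forbidden
    constraints cannot separate them.
    """
    if path is None:
        with resources.files("aerotype.data").joinpath("signatures.yaml").open() as fh:
            raw = yaml.safe_load(fh)
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    sigs = tuple(
        SubtypeSignature(
            family=s["family"], subtype=str(s["subtype"]),
            pattern=tuple(s["pattern"]),
            required=frozenset(s.get("required", [])),
            forbidden=frozenset(s.get("forbidden", [])),
            comparative=bool(s.get("comparative", False)),
        )
        for s in raw["signatures"]
    )
    for i, a in enumerate(sigs):
        for b in sigs[i + 1:]:
            if a.family != b.family or a.pattern != b.pattern:
                continue
            separable = (a.required ^ b.required) or (a.forbidden ^ b.forbidden)
            if not separable:
                raise ValueError(f"ambiguous signatures: {a.binomial} vs {b.binomial}")
    return sigs


def cluster(
    hits: Sequence[DetectionHit],
    genome: GenomeRecord,
    max_gap: int = 500,
    include_kinds: frozenset[str] = frozenset({"oxidase", "accessory", "chaperone"}),
) -> list[OperonCluster]:
    """Group accepted hits into operon-like runs.

    Consecutive hits on the same replicon whose intergenic distance is at
    most ``max_gap`` bp join one cluster; strand is recorded per member but
    not constrained. Hits without coordinates are excluded with a warning.
    """
    members: list[ClusterMember] = []
    for h in hits:
        if not h.accepted or h.kind not in include_kinds:
            continue
        feat = genome.feature(h.gene_id)
        if not feat.has_coordinates:
            warnings.warn(f"{h.gene_id}: accepted hit lacks coordinates; excluded from synteny")
            continue
        role = h.subunit_role
        members.append(ClusterMember(h.gene_id, role, h.target, feat.strand, feat.start, feat.end))

    members.sort(key=lambda m: (m.start, m.end, m.gene_id))
    by_replicon: dict[str, list[ClusterMember]] = {}
    repl_of = {f.gene_id: f.replicon for f in genome.features}
    for m in members:
        by_replicon.setdefault(repl_of[m.gene_id], []).append(m)

    clusters: list[OperonCluster] = []
    for replicon in sorted(by_replicon):
        run: list[ClusterMember] = []
        for m in by_replicon[replicon]:
            if run and (m.start - run[-1].end - 1) > max_gap:
                clusters.append(OperonCluster(replicon, tuple(run)))
                run = []
            run.append(m)
        if run:
            clusters.append(OperonCluster(replicon, tuple(run)))
    return clusters


@dataclass(frozen=True)
class SubtypeCall:
    binomial: Optional[str]      # "A1 subtype b" etc., None when unclassified
    family: Optional[str]
    subtype: Optional[str]
    comparative: bool
    diagnostic: str              # "", "unclassified:<roles>", "chimeric_cluster"


def assign_subtype(
    operon: OperonCluster,
    signatures: Sequence[SubtypeSignature],
) -> SubtypeCall:
    """Binomial synteny label for a cluster.

    Signatures are tried most-specific first (longest pattern). The role
    string is read in genome coordinate direction for plus-strand clusters
    and reversed for minus-strand (majority-strand) clusters, so that e.g.
    a CyoCAB operon on the minus strand is not mistaken for CyoBAC order.
    The family must agree, required roles must be present and forbidden
    roles absent. Families without any signature (AOX, NOR singletons)
    return an empty call rather than an 'unclassified' diagnostic.
    """
    fam = operon.family()
    if fam == "chimeric":
        return SubtypeCall(None, None, None, False, "chimeric_cluster")
    if fam is None:
        return SubtypeCall(None, None, None, False, f"unclassified:{','.join(operon.roles)}")
    sig_fam = "B" if fam == "B_degenerate" else fam
    if sig_fam not in {s.family for s in signatures}:
        return SubtypeCall(None, fam, None, False, "")

    n_minus = sum(1 for m in operon.members if m.strand == "-")
    minus = n_minus > len(operon.members) / 2
    roles = tuple(reversed(operon.roles)) if minus else operon.roles
    role_set = set(roles)
    ordered = sorted(signatures, key=lambda s: (-len(s.pattern), s.family, s.subtype))
    for sig in ordered:
        if sig.family != sig_fam:
            continue
        if not (sig.required <= role_set) or (sig.forbidden & role_set):
            continue
        if _contains(roles, sig.pattern):
            return SubtypeCall(sig.binomial, sig.family, sig.subtype, sig.comparative, "")
    return SubtypeCall(None, fam, None, False, f"unclassified:{','.join(roles)}")
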