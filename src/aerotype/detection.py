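"""Homolog detection for oxidase subunits, chaperones and trait proteins.

Detection mirrors a two-pronged survey protocol in a single reproducible
engine: (1) local sequence similarity (Smith-Waterman-style alignment under
BLOSUM62 with affine gaps, identity and a Karlin-Altschul E-value), and
(2) structural verification (Kyte-Doolittle hydropathy scan for the expected
transmembrane-segment count, plus diagnostic-residue checks through the
alignment coordinate map).

Acceptance requires BOTH similarity criteria (identity >= 25% AND E-value
<= 1e-10) plus the structural checks; a candidate meeting exactly one of the
two similarity criteria is retained as *ambiguous* for review, never
silently dropped. Competing assignments among homologous profiles (A1 vs A2
subunit I, bd-I vs Cio subunits) go to the best-identity profile, demoted to
ambiguous when the winning margin is below a configurable floor.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from aerotype.genome_io import GenomeRecord
from aerotype.profiles import KYTE_DOOLITTLE, Diagnostic, ReferenceProfile

_VALID_AA = set("ACDEFGHIKLMNPQRSTVWYXBZ")

# Karlin-Altschul calibration, standard ungapped BLOSUM62 values. The E-value
# is used for threshold semantics and monotonicity, not as an exact null.
LAMBDA = 0.3176
KAPPA = 0.134


def _aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.substitution_matrix = substitution_matrices.load("BLOSUM62")
    # affine gaps: first gap residue -12, each further residue -1
    a.open_gap_score = -12
    a.extend_gap_score = -1
    return a


_ALIGNER = _aligner()


@dataclass(frozen=True)
class AlignmentResult:
    """Local alignment of a query against a profile reference."""

    percent_identity: float
    score: float
    ref_to_query: dict[int, int]  # aligned (non-gap) columns, 0-based
    aligned_columns: int          # identities + mismatches + internal gaps
    ref_coverage: float           # aligned reference residues / reference length


def _check_seq(seq: str, name: str) -> str:
    if not seq:
        raise ValueError(f"{name}: empty sequence")
    seq = seq.upper()
    bad = set(seq) - _VALID_AA
    if bad:
        raise ValueError(f"{name}: non-amino-acid characters {sorted(bad)}")
    return seq


def align_identity(query: str, reference: str) -> AlignmentResult:
    """Best local alignment (BLOSUM62, gap open 11 / extend 1, i.e. a first
    gap residue costs 12) with percent identity over aligned columns.

    Identity = matches / (matches + mismatches + internal gap columns) * 100,
    computed on the single highest-scoring alignment reported by the
    deterministic dynamic-programming traceback.
    """
    query = _check_seq(query, "query")
    reference = _check_seq(reference, "reference")
    score = _ALIGNER.score(query, reference)
    if score <= 0:
        return AlignmentResult(0.0, 0.0, {}, 0, 0.0)
    aln = next(iter(_ALIGNER.align(query, reference)))
    counts = aln.counts()
    cols = counts.identities + counts.mismatches + counts.internal_gaps
    identity = 100.0 * counts.identities / cols if cols else 0.0
    ref_to_query: dict[int, int] = {}
    for (qs, qe), (rs, re_) in zip(aln.aligned[0], aln.aligned[1]):
        for off in range(qe - qs):
            ref_to_query[rs + off] = qs + off
    coverage = len(ref_to_query) / len(reference)
    return AlignmentResult(identity, float(score), ref_to_query, int(cols), coverage)


def significance(score: float, query_len: int, db_size: int,
                 lam: float = LAMBDA, kappa: float = KAPPA) -> float:
    """Karlin-Altschul extreme-value E-value: E = K * m * n * exp(-lambda*S).

    Monotone decreasing in the score and linear in the search-space size.
    """
    if query_len <= 0 or db_size <= 0:
        raise ValueError("query_len and db_size must be positive")
    return kappa * query_len * db_size * math.exp(-lam * score)


def tm_count(seq: str, window: int = 19, threshold: float = 1.6) -> int:
    """Number of predicted transmembrane segments by hydropathy scan.

    Windows of ``window`` residues whose mean Kyte-Doolittle hydropathy
    exceeds ``threshold`` are merged into maximal segments; the segment count
    is returned. Sequences shorter than the window yield 0 with a warning.
    """
    seq = _check_seq(seq, "sequence")
    if len(seq) < window:
        warnings.warn(f"sequence shorter than hydropathy window ({len(seq)} < {window})")
        return 0
    values = np.array([KYTE_DOOLITTLE.get(a, 0.0) for a in seq])
    means = np.convolve(values, np.ones(window) / window, mode="valid")
    above = means > threshold
    # count runs of consecutive qualifying windows
    return int(np.count_nonzero(above[1:] & ~above[:-1]) + (1 if above.size and above[0] else 0))


def check_diagnostics(alignment: AlignmentResult, profile: ReferenceProfile, query: str) -> dict[str, str]:
    """Verdict per diagnostic residue: present / absent / unalignable.

    A diagnostic reference column that falls outside the aligned region (or
    against a gap) is 'unalignable' — never guessed either way.
    """
    verdicts: dict[str, str] = {}
    for d in profile.diagnostics:
        qpos = alignment.ref_to_query.get(d.ref_pos)
        if qpos is None:
            verdicts[d.name] = "unalignable"
        else:
            verdicts[d.name] = "present" if query[qpos].upper() in d.allowed else "absent"
    return verdicts


@dataclass(frozen=True)
class DetectionThresholds:
    """Similarity and verification thresholds (defaults as surveyed)."""

    min_identity: float = 25.0   # percent
    max_evalue: float = 1e-10
    min_coverage: float = 0.4    # aligned fraction of the reference
    margin: float = 5.0          # identity points between competing profiles
    min_len_ratio: float = 0.3   # skip grossly length-mismatched pairs
    report_ceiling: float = 1e-3  # hits above this E-value are never recorded


def hssp_identity_threshold(columns: int) -> float:
    """Length-corrected homology threshold for percent identity (HSSP curve).

    A fixed identity cutoff is meaningless for short alignments; the curve
    480 * L^(-0.32 * (1 + exp(-L/1000))) gives the identity above which an
    alignment of L columns indicates homology. For L >~ 150 the curve drops
    below 25%, so the flat survey threshold dominates there.
    """
    if columns <= 0:
        return 100.0
    return min(100.0, 480.0 * columns ** (-0.32 * (1 + math.exp(-columns / 1000))))


@dataclass(frozen=True)
class DetectionHit:
    gene_id: str
    profile_id: str
    target: str        # oxidase subfamily / chaperone family / trait subunit
    kind: str
    subunit_role: str
    percent_identity: float
    evalue: float
    tm_count: int
    coverage: float
    residue_verdicts: dict[str, str]
    status: str        # accepted | ambiguous | rejected
    flags: tuple[str, ...] = ()

    @property
    def accepted(self) -> bool:
        return self.status == "accepted"


def _evaluate_candidate(
    gene_id: str,
    seq: str,
    tm: int,
    profile: ReferenceProfile,
    aln: AlignmentResult,
    evalue: float,
    thresholds: DetectionThresholds,
) -> Optional[DetectionHit]:
    id_ok = (
        aln.percent_identity >= thresholds.min_identity
        and aln.percent_identity >= hssp_identity_threshold(aln.aligned_columns)
    )
    ev_ok = evalue <= thresholds.max_evalue
    if not (id_ok or ev_ok):
        return None

    verdicts = check_diagnostics(aln, profile, seq)
    target = profile.target
    flags: list[str] = []
    status: str

    if id_ok and ev_ok:
        lo, hi = profile.expected_tm_range
        if not (lo <= tm <= hi):
            status = "rejected"
            flags.append("tm_out_of_range")
        else:
            status = "accepted"
            for d in profile.diagnostics:
                v = verdicts[d.name]
                if v == "present":
                    continue
                if v == "unalignable":
                    status = "ambiguous"
                    flags.append(f"unalignable:{d.name}")
                elif d.on_absent == "reject":
                    status = "rejected"
                    flags.append(f"missing:{d.name}")
                    break
                elif d.on_absent == "relabel_degenerate":
                    target = "B_degenerate"
                    flags.append("degenerate:missing_catalytic_Tyr")
                elif d.on_absent == "quinol_variant":
                    if "quinol_variant" not in flags:
                        flags.append("quinol_variant")
                elif d.on_absent == "ambiguous":
                    status = "ambiguous"
                    flags.append(f"missing:{d.name}")
    else:
        status = "ambiguous"
        flags.append("identity_only" if id_ok else "evalue_only")

    return DetectionHit(
        gene_id=gene_id, profile_id=profile.profile_id, target=target,
        kind=profile.kind, subunit_role=profile.role,
        percent_identity=round(aln.percent_identity, 2), evalue=evalue,
        tm_count=tm, coverage=round(aln.ref_coverage, 3),
        residue_verdicts=verdicts, status=status, flags=tuple(flags),
    )


def _reduce_competition(
    hits: list[DetectionHit], margin: float, group_of: dict[str, str]
) -> list[DetectionHit]:
    """One assignment per (gene, competition group): best identity wins;
    a winning margin below the floor demotes the call to ambiguous."""
    by_key: dict[tuple[str, str], list[DetectionHit]] = {}
    for h in hits:
        by_key.setdefault((h.gene_id, group_of[h.profile_id]), []).append(h)

    out: list[DetectionHit] = []
    for (_, _), group in by_key.items():
        # the nearest profile (highest identity) defines the call; its own
        # verification verdict stands even when a farther profile would have
        # accepted the gene (e.g. a tyrosine-less A1 subunit I must not be
        # rescued as degenerate B by the more permissive B profile)
        ranked = sorted(group, key=lambda h: (-h.percent_identity, h.profile_id))
        best = ranked[0]
        rivals = [h for h in ranked[1:] if h.status == "accepted"]
        if best.status == "accepted" and rivals:
            gap = best.percent_identity - rivals[0].percent_identity
            if gap < margin:
                best = replace(
                    best, status="ambiguous",
                    flags=best.flags + (f"family_margin<{margin}:{rivals[0].target}",),
                )
        out.append(best)
    return out


def detect(
    genome: GenomeRecord,
    library: Sequence[ReferenceProfile],
    thresholds: DetectionThresholds = DetectionThresholds(),
) -> list[DetectionHit]:
    """Score every protein of a genome against every reference profile.

    Deterministic given (genome, library, thresholds); the hit list is
    independent of input gene order. Only candidates meeting at least one
    similarity criterion at >= ``min_coverage`` reference coverage are
    reported; genes grossly shorter/longer than a reference are skipped.
    """
    if not library:
        raise ValueError("empty profile library")
    if not genome.features:
        return []
    db_size = sum(len(f.product_seq) for f in genome.features)

    hits: list[DetectionHit] = []
    tm_cache: dict[str, int] = {}
    for feat in genome.features:
        seq = feat.product_seq.upper()
        tm = None
        for profile in library:
            ref = profile.reference
            ratio = len(seq) / len(ref)
            if ratio < thresholds.min_len_ratio or ratio > 1.0 / thresholds.min_len_ratio:
                continue
            aln = align_identity(seq, ref)
            if aln.score <= 0 or aln.ref_coverage < thresholds.min_coverage:
                continue
            evalue = significance(aln.score, len(seq), db_size)
            if evalue > thresholds.report_ceiling:
                continue
            if aln.percent_identity < thresholds.min_identity and evalue > thresholds.max_evalue:
                continue
            if tm is None:
                tm = tm_cache.get(feat.gene_id)
                if tm is None:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        tm = tm_count(seq)
                    tm_cache[feat.gene_id] = tm
            hit = _evaluate_candidate(feat.gene_id, seq, tm, profile, aln, evalue, thresholds)
            if hit is not None:
                hits.append(hit)

    group_of = {p.profile_id: p.competition_group for p in library}
    reduced = _reduce_competition(hits, thresholds.margin, group_of)
    # one gene, one protein: a gene with accepted assignments keeps only its
    # best one (highest identity); lesser accepted/ambiguous/rejected matches
    # to other profiles — typically hydrophobic compositional cross-hits
    # between membrane proteins — are suppressed
    best: dict[str, DetectionHit] = {}
    for h in reduced:
        if not h.accepted:
            continue
        cur = best.get(h.gene_id)
        if cur is None or (-h.percent_identity, h.profile_id) < (-cur.percent_identity, cur.profile_id):
            best[h.gene_id] = h
    reduced = [h for h in reduced if (h.gene_id not in best) or (h is best[h.gene_id])]
    reduced.sort(key=lambda h: (h.gene_id, h.profile_id))
    return reduced
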