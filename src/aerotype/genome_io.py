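"""Genome input, quality gating and coordinate normalization.

A genome enters the pipeline as a protein FASTA plus gene coordinates
(GFF3 or a tab-separated gene sheet) plus assembly metadata (completeness %,
tRNA gene count). Coordinates are held 1-based inclusive (GFF3 convention).

The quality gate mirrors the survey's inclusion rule for (meta)genome
assemblies: completeness >= 90%, at least 16 tRNA genes, and more than 1000
encoded proteins. Each threshold is configurable but defaults to the printed
value; assemblies with unknown completeness fail the gate conservatively.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import gffutils
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_AA = set("ACDEFGHIKLMNPQRSTVWYXBZJUO*")


@dataclass(frozen=True)
class GeneFeature:
    """A protein-coding gene: coordinates plus translated product.

    ``start``/``end`` are 1-based inclusive nucleotide coordinates on
    ``replicon``. Features lacking coordinates (FASTA entry without an
    annotation row) carry ``replicon=None`` and are excluded from synteny.
    """

    gene_id: str
    replicon: Optional[str]
    start: Optional[int]
    end: Optional[int]
    strand: str  # '+' or '-'; '.' when unknown
    product_seq: str

    def __post_init__(self) -> None:
        if not self.product_seq:
            raise ValueError(f"{self.gene_id}: empty product sequence")
        if self.start is not None and self.end is not None and self.start > self.end:
            raise ValueError(f"{self.gene_id}: start {self.start} > end {self.end}")
        bad = set(self.product_seq.upper()) - VALID_AA
        if bad:
            raise ValueError(f"{self.gene_id}: non-amino-acid characters {sorted(bad)}")

    @property
    def has_coordinates(self) -> bool:
        return self.replicon is not None and self.start is not None


@dataclass
class GenomeRecord:
    """One genome: features plus the assembly metadata the gate consumes."""

    genome_id: str
    features: list[GeneFeature]
    completeness: Optional[float]  # percent, None = unknown
    trna_count: int
    taxon_note: str = ""

    def __post_init__(self) -> None:
        if self.completeness is not None and not (0 <= self.completeness <= 100):
            raise ValueError(f"completeness {self.completeness} outside [0, 100]")
        if self.trna_count < 0:
            raise ValueError("negative tRNA count")
        ids = [f.gene_id for f in self.features]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate gene ids: {dup}")

    @property
    def protein_count(self) -> int:
        return len(self.features)

    def feature(self, gene_id: str) -> GeneFeature:
        for f in self.features:
            if f.gene_id == gene_id:
                return f
        raise KeyError(gene_id)


GateReason = str  # one of: low_completeness, few_trnas, small_proteome


@dataclass(frozen=True)
class GateVerdict:
    passed: bool
    reasons: tuple[GateReason, ...]

    def __post_init__(self) -> None:
        if self.passed != (len(self.reasons) == 0):
            raise ValueError("passed must hold iff reasons is empty")


@dataclass(frozen=True)
class GateThresholds:
    """Inclusion thresholds; defaults are the printed survey values."""

    min_completeness: float = 90.0  # completeness >= 90 passes
    min_trna: int = 16              # at least 16 tRNA genes
    min_proteins: int = 1000        # strictly more than 1000 proteins


def quality_gate(record: GenomeRecord, thresholds: GateThresholds = GateThresholds()) -> GateVerdict:
    """Apply the assembly-quality gate.

    Boundary semantics follow the printed wording: completeness exactly at
    the threshold passes ("less than 90% excluded"), tRNA count exactly at
    the threshold passes ("at least 16"), protein count exactly at the
    threshold fails (">1000 proteins"). Unknown completeness fails.
    """
    reasons: list[GateReason] = []
    if record.completeness is None or record.completeness < thresholds.min_completeness:
        reasons.append("low_completeness")
    if record.trna_count < thresholds.min_trna:
        reasons.append("few_trnas")
    if record.protein_count <= thresholds.min_proteins:
        reasons.append("small_proteome")
    return GateVerdict(passed=not reasons, reasons=tuple(reasons))


# ---------------------------------------------------------------------------
# readers / writers


def _features_from_gff3(path: Path) -> dict[str, tuple[str, int, int, str]]:
    """gene_id -> (replicon, start, end, strand) from a GFF3 file."""
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="error", from_string=False,
    )
    out: dict[str, tuple[str, int, int, str]] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("CDS", "gene"):
            continue
        gid = feat.attributes.get("ID", [feat.id])[0]
        if gid in out:
            raise ValueError(f"duplicate gene_id {gid!r} in {path}")
        if feat.end < feat.start:
            raise ValueError(f"{path}: feature {gid} has end < start")
        out[gid] = (feat.seqid, feat.start, feat.end, feat.strand or ".")
    return out


_SHEET_COLUMNS = ["gene_id", "replicon", "start", "end", "strand"]


def _features_from_sheet(path: Path) -> dict[str, tuple[str, int, int, str]]:
    """Tab-separated gene sheet with columns gene_id, replicon, start, end, strand."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "replicon": str, "strand": str})
    missing = set(_SHEET_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: gene sheet missing columns {sorted(missing)}")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
        raise ValueError(f"duplicate gene_id {dup} in {path}")
    out = {}
    for row in df.itertuples(index=False):
        start, end = int(row.start), int(row.end)
        if end < start:
            raise ValueError(f"{path}: gene {row.gene_id} has end < start")
        out[str(row.gene_id)] = (str(row.replicon), start, end, str(row.strand))
    return out


def read_genome(
    fasta_path: Union[str, Path],
    features_path: Union[str, Path],
    metadata: Union[str, Path, dict],
) -> GenomeRecord:
    """Read one genome from protein FASTA + coordinates + metadata.

    ``features_path`` may be GFF3 (``.gff``/``.gff3``) or a TSV gene sheet.
    ``metadata`` is a dict or a YAML file with keys ``genome_id``,
    ``completeness`` (percent or null), ``trna_count`` and optionally
    ``taxon_note``. FASTA entries without a coordinate row are retained with
    unknown coordinates (a warning is emitted); they are scored by detection
    but never enter synteny clusters.
    """
    fasta_path, features_path = Path(fasta_path), Path(features_path)
    if not isinstance(metadata, dict):
        with open(metadata) as fh:
            metadata = yaml.safe_load(fh)

    if features_path.suffix.lower() in (".gff", ".gff3"):
        coords = _features_from_gff3(features_path)
    else:
        coords = _features_from_sheet(features_path)

    features: list[GeneFeature] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        gid = rec.id
        if gid in seen:
            raise ValueError(f"duplicate gene_id {gid!r} in {fasta_path}")
        seen.add(gid)
        seq = str(rec.seq).rstrip("*")
        if gid in coords:
            replicon, start, end, strand = coords[gid]
            features.append(GeneFeature(gid, replicon, start, end, strand, seq))
        else:
            warnings.warn(f"{fasta_path}: {gid} has no coordinate row; excluded from synteny")
            features.append(GeneFeature(gid, None, None, None, ".", seq))

    orphans = set(coords) - seen
    if orphans:
        warnings.warn(f"{features_path}: {len(orphans)} coordinate rows without FASTA entry")

    features.sort(key=lambda f: (f.replicon or "~", f.start or 0, f.gene_id))
    comp = metadata.get("completeness")
    return GenomeRecord(
        genome_id=str(metadata["genome_id"]),
        features=features,
        completeness=None if comp is None else float(comp),
        trna_count=int(metadata.get("trna_count", 0)),
        taxon_note=str(metadata.get("taxon_note", "")),
    )


def write_genome(record: GenomeRecord, out_dir: Union[str, Path]) -> dict[str, Path]:
    """Write a genome back to FASTA + gene sheet + metadata YAML.

    Round-trips losslessly through :func:`read_genome` for well-formed
    records (features with coordinates).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fasta = out_dir / f"{record.genome_id}.faa"
    sheet = out_dir / f"{record.genome_id}.genes.tsv"
    meta = out_dir / f"{record.genome_id}.meta.yaml"

    SeqIO.write(
        [SeqRecord(Seq(f.product_seq), id=f.gene_id, description="") for f in record.features],
        str(fasta), "fasta",
    )
    rows = [
        {"gene_id": f.gene_id, "replicon": f.replicon, "start": f.start,
         "end": f.end, "strand": f.strand}
        for f in record.features if f.has_coordinates
    ]
    pd.DataFrame(rows, columns=_SHEET_COLUMNS).to_csv(sheet, sep="\t", index=False)
    with open(meta, "w") as fh:
        yaml.safe_dump(
            {"genome_id": record.genome_id, "completeness": record.completeness,
             "trna_count": record.trna_count, "taxon_note": record.taxon_note},
            fh, sort_keys=True,
        )
    return {"fasta": fasta, "features": sheet, "metadata": meta}


def gate_log(records: Sequence[GenomeRecord], thresholds: GateThresholds = GateThresholds()) -> pd.DataFrame:
    """Gate verdicts for a cohort as a tidy frame (one row per genome)."""
    rows = []
    for rec in records:
        v = quality_gate(rec, thresholds)
        rows.append({
            "genome_id": rec.genome_id,
            "completeness": rec.completeness,
            "trna_count": rec.trna_count,
            "protein_count": rec.protein_count,
            "passed": v.passed,
            "reasons": ";".join(v.reasons),
        })
    return pd.DataFrame(rows)
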