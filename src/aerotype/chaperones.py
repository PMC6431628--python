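"""Cu-assembly chaperone classification and genomic localization.

Three chaperone families deliver copper to nascent oxidases: SCO proteins
(thioredoxin-fold, CxxxC + His Cu site, normally serving the CuA center of
subunit II), the periplasmic CtaG_Cox11 family (Cu bound by two conserved
cysteines; PF04442) and the transmembrane Caa3_CtaG family (His/Asp/Met
ligand set; PF09678). Family assignment happens in the detection engine
(best profile + diagnostic residues; a failed residue check demotes the call
to ambiguous). This module scores where each chaperone gene sits relative to
oxidase operon clusters: inside/near a cluster or isolated elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from aerotype.detection import DetectionHit
from aerotype.genome_io import GenomeRecord
from aerotype.synteny import OperonCluster

CHAPERONE_FAMILIES = ("SCO", "Caa3_CtaG", "CtaG_Cox11")


@dataclass(frozen=True)
class ChaperoneHit:
    gene_id: str
    family: str                   # SCO | Caa3_CtaG | CtaG_Cox11
    status: str                   # accepted | ambiguous
    localization: str             # in_cluster | isolated
    nearest_family: Optional[str]  # oxidase family of the hosting cluster
    nearest_binomial: Optional[str]


def classify_chaperones(hits: Sequence[DetectionHit]) -> list[DetectionHit]:
    """Chaperone-family calls among detection hits (accepted or ambiguous)."""
    return [h for h in hits if h.kind == "chaperone" and h.status in ("accepted", "ambiguous")]


def localize(
    chaperone_hits: Sequence[DetectionHit],
    clusters: Sequence[OperonCluster],
    genome: GenomeRecord,
    subtype_of: Optional[dict[int, str]] = None,
    max_gap: int = 500,
) -> list[ChaperoneHit]:
    """Localization per chaperone: in_cluster iff within ``max_gap`` bp of an
    oxidase cluster span on the same replicon, else isolated.

    ``subtype_of`` optionally maps cluster index -> binomial label for
    reporting. A genome without oxidase clusters localizes every chaperone
    as isolated.
    """
    repl_of = {f.gene_id: f.replicon for f in genome.features}
    oxidase_clusters = [
        (i, c) for i, c in enumerate(clusters)
        if c.family() not in (None, "chimeric")
    ]
    out: list[ChaperoneHit] = []
    for h in chaperone_hits:
        feat = genome.feature(h.gene_id)
        loc, fam, binom = "isolated", None, None
        if feat.has_coordinates:
            for i, c in oxidase_clusters:
                if repl_of[h.gene_id] != c.replicon:
                    continue
                lo, hi = c.span
                if feat.end >= lo - max_gap and feat.start <= hi + max_gap:
                    loc, fam = "in_cluster", c.family()
                    binom = subtype_of.get(i) if subtype_of else None
                    break
        out.append(ChaperoneHit(h.gene_id, h.target, h.status, loc, fam, binom))
    return out


def summarize(per_genome: dict[str, Sequence[ChaperoneHit]]) -> pd.DataFrame:
    """Cohort summary: counts by genome x family x localization x host oxidase.

    Totals are conserved: summing counts over localizations recovers the
    number of classified chaperones per genome and family.
    """
    rows = []
    for genome_id, chs in sorted(per_genome.items()):
        for ch in chs:
            rows.append({
                "genome_id": genome_id,
                "family": ch.family,
                "status": ch.status,
                "localization": ch.localization,
                "host_oxidase_family": ch.nearest_family or "",
            })
    if not rows:
        return pd.DataFrame(
            columns=["genome_id", "family", "status", "localization", "host_oxidase_family", "count"]
        )
    df = pd.DataFrame(rows)
    return (
        df.groupby(["genome_id", "family", "status", "localization", "host_oxidase_family"])
        .size().rename("count").reset_index()
    )
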