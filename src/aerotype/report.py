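"""Per-genome assembly of results and the trait-matrix report.

An :class:`AerotypeResult` collects, for one genome, the quality-gate
verdict, the O2-reductase repertoire (with operon subtype labels), the
lifestyle category, chaperone localizations, the anaerobic-trait vector and
every ambiguity flag. :func:`render_matrix` lays a cohort out as the
survey-style presence/absence matrix: oxidase columns colored in blue whose
intensity increases as oxygen affinity decreases (high-affinity lightest,
low-affinity darkest), anaerobic traits in black, absence always white, and
ambiguous calls — e.g. a single bd-oxidase subunit in a >=90%-complete
genome — in light gray.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from aerotype import ontology
from aerotype.chaperones import ChaperoneHit, classify_chaperones, localize
from aerotype.detection import DetectionHit, DetectionThresholds, detect
from aerotype.genome_io import GateThresholds, GateVerdict, GenomeRecord, quality_gate
from aerotype.ontology import (
    AffinityTier,
    CategoryLabel,
    OxidaseFamily,
    TraitContext,
    affinity_tier,
    classify_repertoire,
)
from aerotype.profiles import ReferenceProfile, default_library
from aerotype.synteny import OperonCluster, SubtypeCall, assign_subtype, cluster, load_signatures
from aerotype.traits import TraitConfig, detect_traits, load_trait_config

# column order of the matrix oxidase block
OXIDASE_ORDER = ("bd_I", "C_cbb3", "B", "A1", "A2", "Cio", "AOX")

# render codes: blue intensity increases as affinity decreases
_TIER_CODE = {
    AffinityTier.HIGH: "blue1",
    AffinityTier.INTERMEDIATE: "blue2",
    AffinityTier.LOW: "blue3",
}
_TIER_RGB = {"blue1": (0.75, 0.85, 1.0), "blue2": (0.45, 0.62, 0.95), "blue3": (0.10, 0.25, 0.80)}


@dataclass
class AerotypeResult:
    genome_id: str
    gate: GateVerdict
    repertoire: set[str]                 # O2-reductase subfamilies present
    oxidase_states: dict[str, str]       # subfamily -> present/ambiguous/absent
    category: Optional[CategoryLabel]    # None when the gate failed
    subtypes: tuple[str, ...]            # binomial operon labels
    chaperones: tuple[ChaperoneHit, ...]
    trait_states: dict[str, str]
    flags: tuple[str, ...]

    @property
    def category_label(self) -> str:
        if self.category is None:
            return "withheld"
        return self.category.label


def repertoire_from_hits(
    hits: Sequence[DetectionHit], gate_passed: bool
) -> tuple[set[str], dict[str, str], list[str]]:
    """O2-reductase repertoire and per-subfamily display state from hits.

    HCO families are called present on an accepted catalytic subunit I
    (COX1/CcoN). bd-superfamily oxidases need BOTH catalytic subunits
    accepted; a single accepted subunit in a gate-passing genome yields a
    genome-level ambiguous call (light gray). NOR and degenerate-B hits are
    recorded as flags but never enter the repertoire.
    """
    accepted_roles: dict[str, set[str]] = {}
    ambiguous_targets: set[str] = set()
    flags: list[str] = []
    for h in hits:
        if h.kind != "oxidase":
            continue
        if h.status == "accepted":
            accepted_roles.setdefault(h.target, set()).add(h.subunit_role)
            for f in h.flags:
                if f == "quinol_variant":
                    flags.append(f"quinol_variant:{h.target}")
        elif h.status == "ambiguous" and h.subunit_role in ("COX1", "CcoN", "CydA", "CydB", "AOX"):
            ambiguous_targets.add(h.target)

    present: set[str] = set()
    states: dict[str, str] = {}
    for sub in OXIDASE_ORDER:
        roles = accepted_roles.get(sub, set())
        if sub in ("bd_I", "Cio"):
            n_cat = len(roles & {"CydA", "CydB"})
            if n_cat == 2:
                states[sub] = "present"
            elif n_cat == 1 and gate_passed:
                states[sub] = "ambiguous"
                flags.append(f"single_subunit:{sub}")
            elif n_cat == 1:
                states[sub] = "absent"
                flags.append(f"single_subunit_low_completeness:{sub}")
            else:
                states[sub] = "ambiguous" if sub in ambiguous_targets else "absent"
        elif sub in ("A1", "A2", "B", "C_cbb3"):
            cat_role = "CcoN" if sub == "C_cbb3" else "COX1"
            if cat_role in roles:
                states[sub] = "present"
            else:
                states[sub] = "ambiguous" if sub in ambiguous_targets else "absent"
        else:  # AOX
            if "AOX" in roles:
                states[sub] = "present"
            else:
                states[sub] = "ambiguous" if sub in ambiguous_targets else "absent"
        if states[sub] == "present":
            present.add(sub)

    if accepted_roles.get("B_degenerate"):
        flags.append("B_degenerate_present")
    if accepted_roles.get("NOR"):
        flags.append("NOR_present_excluded")
    return present, states, flags


def assemble(
    genome: GenomeRecord,
    hits: Sequence[DetectionHit],
    clusters: Sequence[OperonCluster],
    subtype_calls: Sequence[SubtypeCall],
    chaperone_hits: Sequence[ChaperoneHit],
    trait_states: dict[str, str],
    trait_config: Optional[TraitConfig] = None,
    gate: Optional[GateVerdict] = None,
) -> AerotypeResult:
    """Combine all per-genome evidence into one result.

    The lifestyle category is withheld for gate-failing genomes; NOR and
    degenerate-B calls never reach the repertoire; every ambiguous call
    surfaces as a flag.
    """
    trait_config = trait_config or load_trait_config()
    gate = gate if gate is not None else quality_gate(genome)
    present, states, flags = repertoire_from_hits(hits, gate.passed)

    context = TraitContext(
        anaerobic_traits_present=sum(
            1 for t in trait_config.anaerobic if trait_states.get(t) == "present"
        ),
        aerobic_chain_present=any(
            trait_states.get(t) == "present" for t in trait_config.aerobic_chain
        ),
    )
    category: Optional[CategoryLabel] = None
    if gate.passed:
        category = classify_repertoire({OxidaseFamily(p) for p in present}, context)
        flags.extend(category.flags)
    else:
        flags.append("gate_failed:" + ";".join(gate.reasons))

    subtypes = []
    for call in subtype_calls:
        if call.binomial:
            subtypes.append(call.binomial)
        elif call.diagnostic:
            flags.append(call.diagnostic)
    for t, s in trait_states.items():
        if s == "ambiguous":
            flags.append(f"ambiguous_trait:{t}")
    for ch in chaperone_hits:
        if ch.status == "ambiguous":
            flags.append(f"ambiguous_chaperone:{ch.gene_id}")

    return AerotypeResult(
        genome_id=genome.genome_id,
        gate=gate,
        repertoire=present,
        oxidase_states=states,
        category=category,
        subtypes=tuple(sorted(subtypes)),
        chaperones=tuple(chaperone_hits),
        trait_states=trait_states,
        flags=tuple(dict.fromkeys(flags)),  # de-duplicated, order-stable
    )


def analyze_genome(
    genome: GenomeRecord,
    library: Optional[Sequence[ReferenceProfile]] = None,
    thresholds: DetectionThresholds = DetectionThresholds(),
    gate_thresholds: GateThresholds = GateThresholds(),
    max_gap: int = 500,
    trait_config: Optional[TraitConfig] = None,
) -> AerotypeResult:
    """Run the full per-genome pipeline: gate, detect, cluster, classify."""
    library = library if library is not None else default_library()
    trait_config = trait_config or load_trait_config()
    gate = quality_gate(genome, gate_thresholds)
    hits = detect(genome, library, thresholds)
    clusters = cluster(hits, genome, max_gap=max_gap)
    signatures = load_signatures()
    calls = [assign_subtype(c, signatures) for c in clusters]
    subtype_of = {i: c.binomial for i, c in enumerate(calls) if c.binomial}
    chap = localize(classify_chaperones(hits), clusters, genome, subtype_of, max_gap=max_gap)
    trait_states = detect_traits(hits, trait_config)
    return assemble(genome, hits, clusters, calls, chap, trait_states, trait_config, gate)


def run_pipeline(
    genomes: Sequence[GenomeRecord],
    out_dir: Optional[Path] = None,
    library: Optional[Sequence[ReferenceProfile]] = None,
    thresholds: DetectionThresholds = DetectionThresholds(),
    gate_thresholds: GateThresholds = GateThresholds(),
    max_gap: int = 500,
    seed: Optional[int] = None,
    figure: bool = False,
) -> list[AerotypeResult]:
    """Analyze a cohort; optionally write TSV/JSON artifacts to ``out_dir``.

    Outputs are byte-identical across re-runs on the same inputs: all
    orderings are explicit and no timestamps are embedded.
    """
    results = [
        analyze_genome(g, library, thresholds, gate_thresholds, max_gap) for g in genomes
    ]
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        results_frame(results).to_csv(out_dir / "results.tsv", sep="\t", index=False)
        matrix = render_matrix(results, out_dir / "matrix.tsv",
                               figure_path=(out_dir / "matrix.png") if figure else None)
        manifest = {
            "n_genomes": len(genomes),
            "thresholds": vars(thresholds),
            "gate_thresholds": vars(gate_thresholds),
            "max_gap": max_gap,
            "seed": seed,
            "oxidase_order": list(OXIDASE_ORDER),
        }
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return results


def results_frame(results: Sequence[AerotypeResult]) -> pd.DataFrame:
    rows = []
    for r in sorted(results, key=lambda r: r.genome_id):
        rows.append({
            "genome_id": r.genome_id,
            "gate_passed": r.gate.passed,
            "gate_reasons": ";".join(r.gate.reasons),
            "category": r.category_label,
            "override": r.category.override.value if (r.category and r.category.override) else "",
            "repertoire": ";".join(sorted(r.repertoire)),
            "subtypes": ";".join(r.subtypes),
            "flags": ";".join(r.flags),
        })
    return pd.DataFrame(rows)


def _cell(state: str, sub: Optional[str] = None, trait: bool = False) -> str:
    if state == "absent":
        return "absent|white"
    if state == "ambiguous":
        return "ambiguous|light_gray"
    if trait:
        return "present|black"
    code = _TIER_CODE[affinity_tier(OxidaseFamily(sub))]
    return f"present|{code}"


_CATEGORY_SORT = {"I": 0, "II": 1, "III": 2, "IV": 3, "withheld": 4}


def render_matrix(
    results: Sequence[AerotypeResult],
    tsv_path: Optional[Path] = None,
    figure_path: Optional[Path] = None,
) -> pd.DataFrame:
    """The cohort trait matrix: rows are genomes (ordered by category then
    name), columns the oxidase subfamilies then the traits; each cell holds
    ``state|render_code``. The TSV is the authoritative artifact; the
    optional figure is a rendering of it.
    """
    if not results:
        raise ValueError("no results to render")
    ordered = sorted(results, key=lambda r: (_CATEGORY_SORT[r.category_label], r.genome_id))
    trait_cols = list(ordered[0].trait_states.keys())
    rows = []
    for r in ordered:
        row = {"genome_id": r.genome_id, "category": r.category_label}
        for sub in OXIDASE_ORDER:
            row[sub] = _cell(r.oxidase_states.get(sub, "absent"), sub)
        for t in trait_cols:
            row[t] = _cell(r.trait_states.get(t, "absent"), trait=True)
        rows.append(row)
    df = pd.DataFrame(rows)
    if tsv_path is not None:
        df.to_csv(tsv_path, sep="\t", index=False)
    if figure_path is not None:
        _draw_matrix(df, trait_cols, Path(figure_path))
    return df


def read_matrix(tsv_path: Path) -> pd.DataFrame:
    """Round-trip reader for the matrix TSV."""
    return pd.read_csv(tsv_path, sep="\t", dtype=str)


_CODE_RGB = {
    "white": (1.0, 1.0, 1.0),
    "light_gray": (0.85, 0.85, 0.85),
    "black": (0.0, 0.0, 0.0),
    **_TIER_RGB,
}


def _draw_matrix(df: pd.DataFrame, trait_cols: list[str], path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Patch

    cols = list(OXIDASE_ORDER) + trait_cols
    img = [[_CODE_RGB[df.iloc[i][c].split("|")[1]] for c in cols] for i in range(len(df))]
    fig, ax = plt.subplots(figsize=(0.4 * len(cols) + 3, 0.3 * len(df) + 2))
    ax.imshow(img, aspect="auto")
    ax.set_xticks(range(len(cols)), cols, rotation=90, fontsize=7)
    ax.set_yticks(range(len(df)), [f"{r.genome_id} ({r.category})" for r in df.itertuples()], fontsize=7)
    legend = [
        Patch(facecolor=_CODE_RGB["blue1"], edgecolor="k", label="high-affinity oxidase"),
        Patch(facecolor=_CODE_RGB["blue2"], edgecolor="k", label="intermediate-affinity oxidase"),
        Patch(facecolor=_CODE_RGB["blue3"], edgecolor="k", label="low-affinity oxidase"),
        Patch(facecolor=_CODE_RGB["black"], edgecolor="k", label="anaerobic/bioenergetic trait"),
        Patch(facecolor=_CODE_RGB["light_gray"], edgecolor="k", label="ambiguous"),
        Patch(facecolor=_CODE_RGB["white"], edgecolor="k", label="absent"),
    ]
    ax.legend(handles=legend, bbox_to_anchor=(1.02, 1), loc="upper left", fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
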