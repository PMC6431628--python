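"""Anaerobic / bioenergetic trait panel.

Traits beyond the oxidases themselves — FeFe-hydrogenase and its HydEFG
maturation machinery, acetate:succinate CoA transferase (ASCT), malic
enzyme, fumarase, respiratory complexes I-III and quinone biosynthesis — are
detected with the same engine as the oxidases. Multi-subunit traits apply a
configurable subunit quorum: e.g. HydEFG is present with >= 2 of HydE/F/G
accepted, ambiguous with fewer-but-some evidence, absent otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Optional, Sequence

import pandas as pd
import yaml

from aerotype.detection import DetectionHit


@dataclass(frozen=True)
class TraitConfig:
    order: tuple[str, ...]                       # render order, fixed
    subunits: dict[str, tuple[str, ...]]
    quorum: dict[str, int]
    anaerobic: tuple[str, ...]
    aerobic_chain: tuple[str, ...]


def load_trait_config(path=None) -> TraitConfig:
    if path is None:
        with resources.files("aerotype.data").joinpath("traits.yaml").open() as fh:
            raw = yaml.safe_load(fh)
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    order = tuple(raw["traits"].keys())
    return TraitConfig(
        order=order,
        subunits={t: tuple(v["subunits"]) for t, v in raw["traits"].items()},
        quorum={t: int(v["quorum"]) for t, v in raw["traits"].items()},
        anaerobic=tuple(raw.get("anaerobic", [])),
        aerobic_chain=tuple(raw.get("aerobic_chain", [])),
    )


def detect_traits(
    hits: Sequence[DetectionHit],
    config: Optional[TraitConfig] = None,
) -> dict[str, str]:
    """Trait-state vector from a genome's detection hits.

    Returns one state per configured trait, in configuration order:
    'present' (subunit quorum met by accepted hits), 'ambiguous' (some
    accepted/ambiguous evidence below quorum) or 'absent'.
    """
    config = config or load_trait_config()
    accepted: dict[str, set[str]] = {}
    ambiguous: dict[str, set[str]] = {}
    for h in hits:
        if h.kind != "trait":
            continue
        if h.status == "accepted":
            accepted.setdefault(h.target, set()).add(h.gene_id)
        elif h.status == "ambiguous":
            ambiguous.setdefault(h.target, set()).add(h.gene_id)

    states: dict[str, str] = {}
    for trait in config.order:
        subs = config.subunits[trait]
        n_acc = sum(1 for s in subs if accepted.get(s))
        n_amb = sum(1 for s in subs if ambiguous.get(s))
        if n_acc >= config.quorum[trait]:
            states[trait] = "present"
        elif n_acc + n_amb > 0:
            states[trait] = "ambiguous"
        else:
            states[trait] = "absent"
    return states


def cooccurrence(
    trait_states: dict[str, dict[str, str]],
    repertoires: dict[str, set[str]],
) -> pd.DataFrame:
    """Contingency counts of trait presence against oxidase-type presence.

    One row per (trait, oxidase subfamily): counts of genomes with both,
    trait only, oxidase only, and neither. No significance testing is
    attached — counts only.
    """
    genomes = sorted(trait_states)
    if len(genomes) < 2:
        warnings.warn("co-occurrence over fewer than 2 genomes is degenerate")
    traits = sorted({t for v in trait_states.values() for t in v})
    oxidases = sorted({o for v in repertoires.values() for o in v})
    rows = []
    for trait in traits:
        for ox in oxidases:
            both = t_only = o_only = neither = 0
            for g in genomes:
                has_t = trait_states[g].get(trait) == "present"
                has_o = ox in repertoires.get(g, set())
                if has_t and has_o:
                    both += 1
                elif has_t:
                    t_only += 1
                elif has_o:
                    o_only += 1
                else:
                    neither += 1
            rows.append({
                "trait": trait, "oxidase": ox, "both": both,
                "trait_only": t_only, "oxidase_only": o_only, "neither": neither,
            })
    return pd.DataFrame(rows)
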