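"""Controlled vocabularies: oxidase families, affinity tiers, lifestyle categories.

Terminal oxidases are grouped at two granularities. The family level
{A, B, C, bd, AOX, NOR} counts the six recognised O2-reductase types (NOR is
carried for bookkeeping but excluded from repertoires because it reduces NO,
not O2). The subfamily level splits A into A1/A2 and bd into bd-I/Cio, which
is the granularity at which oxygen affinity is assigned:

* high affinity (Km in the nanomolar range): bd-I, C-family cbb3
* intermediate affinity: B family (no Km reported; inferred between C and A)
* low affinity (Km near or above the Pasteur point, ~2 uM): A1, A2, Cio, AOX

A genome's O2-reductase repertoire maps onto one of four lifestyle
categories: (I) no oxidases, (II) only high-affinity oxidases, (III) a
mixture of affinities, (IV) only low-affinity oxidases. A genome whose sole
"oxidase" is an AOX gene in an otherwise fully anaerobic trait context is
treated as a strict anaerobe (category I) with a contamination override,
since a lone AOX on an anaerobic background is most plausibly contaminant.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Optional

import yaml


class OxidaseFamily(str, enum.Enum):
    """Subfamily-level labels for terminal oxidases and relatives."""

    A1 = "A1"
    A2 = "A2"
    B = "B"
    C_CBB3 = "C_cbb3"
    BD_I = "bd_I"
    CIO = "Cio"
    AOX = "AOX"
    NOR = "NOR"
    B_DEGENERATE = "B_degenerate"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class AffinityTier(str, enum.Enum):
    HIGH = "high"
    INTERMEDIATE = "intermediate"
    LOW = "low"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class Override(str, enum.Enum):
    STRICT_ANAEROBE_CONTAMINATION = "strict_anaerobe_contamination"


@dataclass(frozen=True)
class CategoryLabel:
    """One of the four base lifestyle categories, with optional override.

    The only defined override is the strict-anaerobe contamination call,
    attachable to category I only.
    """

    label: str  # "I" | "II" | "III" | "IV"
    override: Optional[Override] = None
    flags: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.label not in ("I", "II", "III", "IV"):
            raise ValueError(f"unknown category label {self.label!r}")
        if self.override is not None and self.label != "I":
            raise ValueError("override is only attachable to category I")


@dataclass(frozen=True)
class KmAnnotation:
    """Curated Km-for-O2 annotation; value is None when not reported."""

    value: Optional[float]
    unit: str
    note: str

    @property
    def reported(self) -> bool:
        return self.value is not None


def _load_vocab() -> dict:
    with resources.files("aerotype.data").joinpath("ontology.yaml").open() as fh:
        return yaml.safe_load(fh)


_VOCAB = _load_vocab()

FAMILY_OF: dict[OxidaseFamily, str] = {
    OxidaseFamily(k): v["family"] for k, v in _VOCAB["subfamilies"].items()
}
COUNTS_AS_O2_REDUCTASE: dict[OxidaseFamily, bool] = {
    OxidaseFamily(k): v["counts_as_o2_reductase"] for k, v in _VOCAB["subfamilies"].items()
}
O2_REDUCTASES: frozenset[OxidaseFamily] = frozenset(
    k for k, v in COUNTS_AS_O2_REDUCTASE.items() if v
)
_TIERS: dict[OxidaseFamily, AffinityTier] = {
    OxidaseFamily(k): AffinityTier(v) for k, v in _VOCAB["affinity_tiers"].items()
}
_KM: dict[OxidaseFamily, KmAnnotation] = {
    OxidaseFamily(k): KmAnnotation(v["value"], v["unit"], v["note"])
    for k, v in _VOCAB["km_annotations"].items()
}

# The six recognised O2-reducing oxidase types: A1 and A2 counted apart,
# bd-I and Cio collapsed into the bd superfamily, NOR excluded.
SIX_FAMILIES: tuple[str, ...] = ("A1", "A2", "B", "C", "bd", "AOX")

_SIX_TYPE = {
    OxidaseFamily.A1: "A1", OxidaseFamily.A2: "A2", OxidaseFamily.B: "B",
    OxidaseFamily.C_CBB3: "C", OxidaseFamily.BD_I: "bd", OxidaseFamily.CIO: "bd",
    OxidaseFamily.AOX: "AOX",
}


def family_of(subfamily: OxidaseFamily) -> str:
    """Family-level label ({A, B, C, bd, AOX, NOR}) for a subfamily."""
    return FAMILY_OF[subfamily]


def six_type_of(subfamily: OxidaseFamily) -> str:
    """One of the six recognised O2-reductase types for a subfamily."""
    subfamily = OxidaseFamily(subfamily)
    if subfamily not in _SIX_TYPE:
        raise ValueError(f"{subfamily.value} is not an O2-reducing oxidase type")
    return _SIX_TYPE[subfamily]


def affinity_tier(subfamily: OxidaseFamily) -> AffinityTier:
    """Oxygen-affinity tier of an O2-reductase subfamily.

    Raises
    ------
    ValueError
        For NOR and degenerate-B labels, whose O2-reductase activity is
        respectively absent and questioned: no tier is defined for them.
    """
    subfamily = OxidaseFamily(subfamily)
    if not COUNTS_AS_O2_REDUCTASE[subfamily]:
        raise ValueError(f"tier undefined for non-O2-reductase {subfamily.value}")
    return _TIERS[subfamily]


def km_reference(subfamily: OxidaseFamily) -> KmAnnotation:
    """Curated Km-for-O2 annotation for reporting; never a fabricated number."""
    subfamily = OxidaseFamily(subfamily)
    if not COUNTS_AS_O2_REDUCTASE[subfamily]:
        raise ValueError(f"Km annotation undefined for non-O2-reductase {subfamily.value}")
    return _KM[subfamily]


@dataclass(frozen=True)
class TraitContext:
    """Trait evidence consulted by the strict-anaerobe override.

    ``anaerobic_traits_present`` is the number of anaerobic-metabolism traits
    detected as present; ``aerobic_chain_present`` is True when any gene of
    the aerobic respiratory chain beyond the oxidases themselves (complex III
    or oxidase-associated assembly genes) is present.
    """

    anaerobic_traits_present: int = 0
    aerobic_chain_present: bool = False

    @property
    def fully_anaerobic(self) -> bool:
        return self.anaerobic_traits_present >= 1 and not self.aerobic_chain_present


# Repertoires the survey's category definitions describe explicitly:
# IV is defined as "only low-affinity oxidases of the A1 family, with or
# without AOX"; III as a mixture of tiers. Anything else that still lands on
# those labels (e.g. {Cio} alone, {B} alone) is classified by tier algebra
# and flagged as not observed in the survey.
FLAG_NOT_OBSERVED = "repertoire_not_observed"
FLAG_OVERRIDE = "strict_anaerobe_override"


def classify_repertoire(
    present: Iterable[OxidaseFamily],
    trait_context: Optional[TraitContext] = None,
) -> CategoryLabel:
    """Sort an O2-reductase repertoire into one of the four categories.

    The function is total over subsets of the seven O2-reductase subfamilies:
    I iff empty; II iff all present oxidases are high affinity; IV iff all
    are low affinity; III otherwise. When the repertoire is exactly {AOX}
    and the trait context is fully anaerobic, the genome is classified as a
    strict anaerobe (category I) with the contamination override.

    Parameters
    ----------
    present : iterable of OxidaseFamily
        O2-reductase subfamilies detected in the genome. NOR and degenerate-B
        must be stripped upstream.
    trait_context : TraitContext, optional
        Anaerobic-trait evidence; only consulted for the {AOX} override.
    """
    pres = frozenset(OxidaseFamily(p) for p in present)
    bad = pres - O2_REDUCTASES
    if bad:
        raise ValueError(f"repertoire contains non-O2-reductase labels: {sorted(b.value for b in bad)}")

    if not pres:
        return CategoryLabel("I")

    if pres == {OxidaseFamily.AOX} and trait_context is not None and trait_context.fully_anaerobic:
        return CategoryLabel(
            "I", override=Override.STRICT_ANAEROBE_CONTAMINATION, flags=(FLAG_OVERRIDE,)
        )

    tiers = {_TIERS[p] for p in pres}
    if tiers == {AffinityTier.HIGH}:
        return CategoryLabel("II")
    if tiers == {AffinityTier.LOW}:
        observed = OxidaseFamily.A1 in pres and pres <= {OxidaseFamily.A1, OxidaseFamily.AOX}
        flags = () if observed else (FLAG_NOT_OBSERVED,)
        return CategoryLabel("IV", flags=flags)
    # Mixture of tiers, or intermediate-only ({B} alone was never observed
    # but must still classify; by the tier algebra it is neither all-high
    # nor all-low, hence III).
    flags = (FLAG_NOT_OBSERVED,) if tiers == {AffinityTier.INTERMEDIATE} else ()
    return CategoryLabel("III", flags=flags)
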