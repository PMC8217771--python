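"""Peptide-evidence acceptance, extract-presence partition and SMP categories.

Shell matrix proteins (SMPs) are accepted when supported by more than one
distinct peptide in total across extracts (the two-peptide rule). Accepted
proteins are partitioned by which of the four extracts (ASM/AIM, each after
two or three bleachings) they appear in, and assigned to one of three
categories:

* ``conserved_domain`` — carries at least one catalogued functional domain,
  sub-categorized (polysaccharide affinity > enzyme > protease inhibitor);
* ``lcr_containing`` — no catalogued domain but at least one low-complexity
  region;
* ``uncharacterized`` — neither.

BMSP-likeness (Blue Mussel Shell Protein architecture) is flagged for
proteins whose N-terminal catalogued domains are more than one VWA domain in
tandem immediately followed by at least one chitin-binding domain.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .lcr import LCRegion
from .model import (
    CANONICAL_EXTRACTS,
    DomainHit,
    EvidenceTable,
    ProteinRecord,
    ShellomeError,
)

CATEGORY_CONSERVED = "conserved_domain"
CATEGORY_LCR = "lcr_containing"
CATEGORY_UNCHARACTERIZED = "uncharacterized"

SUB_POLYSACCHARIDE = "polysaccharide_affinity"
SUB_ENZYME = "enzyme"
SUB_PROTEASE_INHIBITOR = "protease_inhibitor"
SUB_NONE = "none"

#: precedence when a protein carries domains of several sub-categories
SUBCATEGORY_PRECEDENCE = (SUB_POLYSACCHARIDE, SUB_ENZYME, SUB_PROTEASE_INHIBITOR)

#: accession -> sub-category; user-extensible configuration
DEFAULT_CATALOG: dict[str, str] = {
    # chitin-binding, lectin folds, TSP-1, VWA: polysaccharide / ECM affinity
    "PF01607": SUB_POLYSACCHARIDE,   # chitin binding domain
    "IPR002557": SUB_POLYSACCHARIDE, # chitin binding domain
    "PF03067": SUB_POLYSACCHARIDE,   # chitin-binding, domain 3
    "SSF49899": SUB_POLYSACCHARIDE,  # concanavalin A-like lectin/glucanase
    "PF00090": SUB_POLYSACCHARIDE,   # thrombospondin type-1 repeat
    "PF00092": SUB_POLYSACCHARIDE,   # von Willebrand factor type A
    "SSF53300": SUB_POLYSACCHARIDE,  # VWA-like superfamily
    "SSF56436": SUB_POLYSACCHARIDE,  # C-type lectin fold
    "PF00150": SUB_ENZYME,           # glycoside hydrolase family 5
    "PF00264": SUB_ENZYME,           # tyrosinase copper-binding domain
    "PF00014": SUB_PROTEASE_INHIBITOR,  # Kunitz trypsin-inhibitor domain
    "IPR002350": SUB_PROTEASE_INHIBITOR,  # Kazal domain
}

VWA_ACCESSIONS = frozenset({"PF00092", "SSF53300"})
CHBD_ACCESSIONS = frozenset({"PF01607", "IPR002557", "PF03067"})

PRESENCE_COMMON_TO_FOUR = "common_to_four"
PRESENCE_IN_THREE = "in_three"
PRESENCE_ASM_SPECIFIC = "ASM_specific"
PRESENCE_AIM_SPECIFIC = "AIM_specific"
PRESENCE_OTHER = "other"

PRESENCE_CLASSES = (
    PRESENCE_COMMON_TO_FOUR, PRESENCE_IN_THREE,
    PRESENCE_ASM_SPECIFIC, PRESENCE_AIM_SPECIFIC, PRESENCE_OTHER,
)


@dataclass(frozen=True)
class SMPClassification:
    protein_id: str
    category: str
    subcategory: str
    bmsp_like: bool
    lcr_labels_single: tuple[str, ...]
    lcr_labels_pair: tuple[str, ...]
    presence: frozenset[str] = frozenset()
    presence_class: str = PRESENCE_OTHER


def apply_peptide_rule(evidence: EvidenceTable, min_peptides: int = 2) -> set[str]:
    """Protein ids supported by at least ``min_peptides`` distinct peptides.

    Counts are totalled over all extracts ("more than one peptide" = >= 2).
    """
    totals: dict[str, int] = {}
    for (pid, _), count in evidence.entries.items():
        totals[pid] = totals.get(pid, 0) + count
    return {pid for pid, total in totals.items() if total >= min_peptides}


def _extract_group(extract_id: str) -> str:
    return extract_id.split("_", 1)[0]


def presence_class(
    presence: frozenset[str] | set[str],
    extract_ids: Sequence[str] = CANONICAL_EXTRACTS,
) -> str:
    """Assign one presence class, in precedence order, mutually exclusively."""
    known = set(extract_ids)
    unknown = set(presence) - known
    if unknown:
        raise ShellomeError(f"unknown extract id(s): {sorted(unknown)}")
    groups = {_extract_group(e) for e in extract_ids}
    if groups != {"ASM", "AIM"} or len(extract_ids) != 4:
        raise ShellomeError("presence partition requires the four canonical "
                            "extracts (two ASM, two AIM)")
    present = set(presence)
    if present == known:
        return PRESENCE_COMMON_TO_FOUR
    if len(present) == 3:
        return PRESENCE_IN_THREE
    if present and all(_extract_group(e) == "ASM" for e in present):
        return PRESENCE_ASM_SPECIFIC
    if present and all(_extract_group(e) == "AIM" for e in present):
        return PRESENCE_AIM_SPECIFIC
    return PRESENCE_OTHER


def presence_partition(
    presences: Mapping[str, frozenset[str] | set[str]],
    extract_ids: Sequence[str] = CANONICAL_EXTRACTS,
) -> dict[str, int]:
    """Counts per presence class over accepted proteins (disjoint, exhaustive)."""
    counts = Counter(presence_class(p, extract_ids) for p in presences.values())
    return {cls: counts.get(cls, 0) for cls in PRESENCE_CLASSES}


def detect_bmsp_architecture(
    domains: Sequence[DomainHit],
    catalog: Mapping[str, str] = DEFAULT_CATALOG,
) -> tuple[int, int, bool]:
    """(n_vwa, n_chbd_following, bmsp_like) for one protein's domains.

    bmsp_like requires, among the catalogued domains in N->C order, a leading
    block of >= 2 VWA domains immediately followed by >= 1 chitin-binding
    domain (no other catalogued domain type in between).
    """
    ordered = sorted(domains, key=lambda d: (d.start, d.end, d.accession))
    kinds: list[str] = []
    for d in ordered:
        if d.accession in VWA_ACCESSIONS:
            kinds.append("VWA")
        elif d.accession in CHBD_ACCESSIONS:
            kinds.append("ChBD")
        elif d.accession in catalog:
            kinds.append("other")
    n_vwa = 0
    for k in kinds:
        if k == "VWA":
            n_vwa += 1
        else:
            break
    n_chbd = 0
    for k in kinds[n_vwa:]:
        if k == "ChBD":
            n_chbd += 1
        else:
            break
    bmsp_like = n_vwa >= 2 and n_chbd >= 1
    return n_vwa, n_chbd, bmsp_like


def classify_protein(
    protein: ProteinRecord,
    domains: Sequence[DomainHit],
    lcrs: Sequence[LCRegion],
    catalog: Mapping[str, str] = DEFAULT_CATALOG,
    presence: frozenset[str] | set[str] | None = None,
    extract_ids: Sequence[str] = CANONICAL_EXTRACTS,
) -> SMPClassification:
    """Assign the three-way category, sub-category and BMSP flag."""
    subcats = {catalog[d.accession] for d in domains if d.accession in catalog}
    if subcats:
        category = CATEGORY_CONSERVED
        subcategory = next(s for s in SUBCATEGORY_PRECEDENCE if s in subcats)
    elif lcrs:
        category = CATEGORY_LCR
        subcategory = SUB_NONE
    else:
        category = CATEGORY_UNCHARACTERIZED
        subcategory = SUB_NONE

    singles = tuple(sorted({r.label for r in lcrs if r.kind == "single"}))
    pairs = tuple(sorted({r.label for r in lcrs if r.kind == "pair"}))
    _, _, bmsp = detect_bmsp_architecture(domains, catalog)

    pres = frozenset(presence) if presence is not None else frozenset()
    pclass = presence_class(pres, extract_ids) if presence is not None else PRESENCE_OTHER
    return SMPClassification(
        protein_id=protein.id, category=category, subcategory=subcategory,
        bmsp_like=bmsp, lcr_labels_single=singles, lcr_labels_pair=pairs,
        presence=pres, presence_class=pclass,
    )


def category_counts(classifications: Iterable[SMPClassification]) -> dict[str, int]:
    counts = Counter(c.category for c in classifications)
    return {cat: counts.get(cat, 0) for cat in
            (CATEGORY_CONSERVED, CATEGORY_LCR, CATEGORY_UNCHARACTERIZED)}
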