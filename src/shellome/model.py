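"""Domain types shared across the package.

All sequence and table coordinates are 1-based and inclusive on both ends,
matching the convention of protein domain-annotation tables. Sequences are
strings over the 20 standard one-letter amino-acid codes plus ``X`` for an
unknown residue; ``X`` participates in window denominators and lengths but is
never an enriched residue and carries no charge.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
ALLOWED_AA = frozenset(STANDARD_AA) | {"X"}

#: canonical shell-matrix extract identifiers: acid-soluble (ASM) and
#: acid-insoluble (AIM) fractions, each after two or three bleaching steps.
CANONICAL_EXTRACTS = ("ASM_2bl", "ASM_3bl", "AIM_2bl", "AIM_3bl")


class ShellomeError(ValueError):
    """Base class for validation errors raised by this package."""


@dataclass(frozen=True)
class ProteinRecord:
    """A single identified protein sequence."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ShellomeError("protein id must be non-empty")
        if len(self.sequence) < 1:
            raise ShellomeError(f"{self.id}: sequence must have length >= 1")
        for pos, aa in enumerate(self.sequence, start=1):
            if aa not in ALLOWED_AA:
                raise ShellomeError(
                    f"{self.id}: illegal character {aa!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class DomainHit:
    """One domain annotation on a protein (InterProScan-style)."""

    protein_id: str
    source: str
    accession: str
    name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.accession:
            raise ShellomeError(f"{self.protein_id}: domain accession must be non-empty")
        if not (1 <= self.start <= self.end):
            raise ShellomeError(
                f"{self.protein_id}/{self.accession}: invalid coordinates "
                f"start={self.start} end={self.end} (need 1 <= start <= end)"
            )


@dataclass(frozen=True)
class FeatureFlags:
    """Signal-peptide and transmembrane predictor outcomes for one protein."""

    protein_id: str
    signal_peptide: bool
    tm_count: int

    def __post_init__(self) -> None:
        if self.tm_count < 0:
            raise ShellomeError(f"{self.protein_id}: tm_count must be >= 0")


@dataclass(frozen=True)
class PhosphoSite:
    position: int  # 1-based
    residue: str  # S, T or Y
    probability: float

    def __post_init__(self) -> None:
        if self.residue not in ("S", "T", "Y"):
            raise ShellomeError(f"phospho residue must be S/T/Y, got {self.residue!r}")
        if not (0.0 <= self.probability <= 1.0):
            raise ShellomeError(
                f"phospho probability {self.probability} at position "
                f"{self.position} outside [0, 1]"
            )


@dataclass(frozen=True)
class PhosphoTrack:
    """Per-residue phosphorylation probabilities for one protein."""

    protein_id: str
    sites: tuple[PhosphoSite, ...]

    def __post_init__(self) -> None:
        positions = [s.position for s in self.sites]
        if any(b <= a for a, b in zip(positions, positions[1:])):
            raise ShellomeError(
                f"{self.protein_id}: phospho positions must be strictly increasing"
            )

    def cross_check(self, record: ProteinRecord) -> None:
        """Verify every site's residue matches the sequence."""
        for s in self.sites:
            if s.position > len(record.sequence):
                raise ShellomeError(
                    f"{self.protein_id}: phospho position {s.position} beyond "
                    f"sequence length {len(record.sequence)}"
                )
            actual = record.sequence[s.position - 1]
            if actual != s.residue:
                raise ShellomeError(
                    f"{self.protein_id}: phospho site at {s.position} states "
                    f"{s.residue} but sequence has {actual}"
                )


@dataclass(frozen=True)
class EvidenceTable:
    """Distinct-peptide counts per (protein, extract).

    ``extract_ids`` is the ordered set of extracts the experiment defines;
    entries referring to extracts outside it are preserved but flagged by the
    reader.
    """

    entries: Mapping[tuple[str, str], int]
    extract_ids: tuple[str, ...] = CANONICAL_EXTRACTS

    def __post_init__(self) -> None:
        if not self.extract_ids:
            raise ShellomeError("extract_ids must be non-empty")
        for (pid, ext), count in self.entries.items():
            if count < 0:
                raise ShellomeError(f"({pid}, {ext}): negative peptide count {count}")

    def protein_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for pid, _ in self.entries:
            seen.setdefault(pid, None)
        return list(seen)

    def total_peptides(self, protein_id: str) -> int:
        return sum(c for (pid, _), c in self.entries.items() if pid == protein_id)

    def presence(self, protein_id: str) -> frozenset[str]:
        """Extracts in which the protein has at least one peptide."""
        return frozenset(
            ext for (pid, ext), c in self.entries.items()
            if pid == protein_id and c >= 1
        )


def unique_ids(records: Iterable[ProteinRecord]) -> dict[str, ProteinRecord]:
    """Index records by id, rejecting duplicates."""
    index: dict[str, ProteinRecord] = {}
    for rec in records:
        if rec.id in index:
            raise ShellomeError(f"duplicate protein id: {rec.id}")
        index[rec.id] = rec
    return index
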