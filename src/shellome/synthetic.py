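"""Synthetic input generator with known ground truth.

Emulates the statistical structure of a shell-proteome study's inputs so every
pipeline stage is testable without the deposited raw data: protein sequences
drawn residue-wise from background frequencies with planted single- and
two-residue-biased LCR stretches and acidic C-terminal poly-Asp tails;
planted domain annotations; four-extract peptide-count tables; per-residue
phospho-probability tracks concentrated on S/T; and lectin plates with
replicate noise and a background well.

In *clean* mode (default) the background is guaranteed LCR-free: background
segments exclude the focal residues of that protein's plants, and any segment
containing even one flagged composition window is regenerated, so planted
features are recovered exactly and the false-positive rate is zero by
construction. ``clean=False`` disables both safeguards for realistic
backgrounds. Everything is deterministic under the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .ella import LectinPlate
from .lcr import LCRParams, flag_windows_pair, flag_windows_single
from .model import (
    CANONICAL_EXTRACTS,
    DomainHit,
    EvidenceTable,
    PhosphoSite,
    PhosphoTrack,
    ProteinRecord,
    ShellomeError,
    STANDARD_AA,
)

#: the 21 biotinylated lectins of a three-kit screening panel
DEFAULT_LECTINS = (
    "ConA", "DBA", "PNA", "RCA", "SBA", "UEA I", "WGA",
    "GSL I", "LCA", "PHA-E", "PHA-L", "PSA", "SJA", "sWGA",
    "DSL", "ECL", "GSL II", "Jacalin", "LEL", "STL", "VVA",
)

#: evidence templates over (ASM_2bl, ASM_3bl, AIM_2bl, AIM_3bl)
EVIDENCE_TEMPLATES: dict[str, tuple[int, int, int, int]] = {
    "common_to_four": (1, 1, 1, 1),
    "in_three": (2, 1, 1, 0),
    "ASM_specific": (2, 1, 0, 0),
    "AIM_specific": (0, 0, 2, 1),
    "rejected": (1, 0, 0, 0),
}


@dataclass(frozen=True)
class PlantedLCR:
    kind: str  # "single" or "pair"
    residues: str  # 1 or 2 letters
    length: int
    purity: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("single", "pair"):
            raise ShellomeError(f"unknown plant kind {self.kind!r}")
        if len(self.residues) != (1 if self.kind == "single" else 2):
            raise ShellomeError(f"{self.kind} plant needs "
                                f"{1 if self.kind == 'single' else 2} residue(s)")
        if not (0.0 < self.purity <= 1.0):
            raise ShellomeError("purity must be in (0, 1]")
        if self.length <= 0:
            raise ShellomeError("plant length must be positive")


@dataclass(frozen=True)
class PlantedSpan:
    kind: str
    residues: str
    start: int  # 1-based inclusive
    end: int
    purity: float

    @property
    def exact(self) -> bool:
        """Spans planted with purity 1 are literal and support exact assertions."""
        return self.purity >= 1.0


@dataclass(frozen=True)
class ProteinTruth:
    protein_id: str
    lcr_spans: tuple[PlantedSpan, ...]
    polyd_tail: tuple[int, int] | None
    domains: tuple[DomainHit, ...]


@dataclass(frozen=True)
class SynthSpec:
    n_proteins: int = 30
    length_range: tuple[int, int] = (120, 260)
    background_freqs: Mapping[str, float] | None = None
    planted_lcrs: tuple[PlantedLCR, ...] = ()
    planted_polyd_tail: int | None = None
    planted_domains: tuple[tuple[str, int], ...] = ()  # (accession, approx start)
    phospho_rate_in_lcr: float = 0.8
    phospho_rate_outside: float = 0.05
    plate_true: Mapping[str, float] | None = None
    plate_background: float = 0.1
    plate_noise_sd: float = 0.02
    plate_replicates: int = 3
    clean: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.background_freqs is not None:
            total = sum(self.background_freqs.values())
            if abs(total - 1.0) > 1e-9:
                raise ShellomeError(f"background_freqs sum to {total}, not 1")
        lo, hi = self.length_range
        if not (0 < lo <= hi):
            raise ShellomeError("invalid length_range")
        for rate in (self.phospho_rate_in_lcr, self.phospho_rate_outside):
            if not (0.0 <= rate <= 1.0):
                raise ShellomeError("phospho rates must lie in [0, 1]")


_MAX_REJECTION_TRIES = 10_000


def _background_distribution(
    spec: SynthSpec, focal: set[str]
) -> tuple[list[str], np.ndarray]:
    """Background alphabet and probabilities; focal residues excluded in clean mode."""
    if spec.background_freqs is not None:
        items = dict(spec.background_freqs)
    else:
        items = {aa: 1.0 for aa in STANDARD_AA}
    if spec.clean:
        items = {aa: p for aa, p in items.items() if aa not in focal}
    if not items:
        raise ShellomeError("background alphabet is empty after excluding focal residues")
    letters = sorted(items)
    probs = np.array([items[aa] for aa in letters], dtype=float)
    return letters, probs / probs.sum()


def _segment_is_clean(segment: str, params: LCRParams) -> bool:
    """No composition window flagged under either criterion."""
    if len(segment) < params.window_len:
        return True
    return not flag_windows_single(segment, params) and not flag_windows_pair(segment, params)


def _draw_background(
    rng: np.random.Generator, n: int, letters: list[str], probs: np.ndarray,
    clean: bool, params: LCRParams,
) -> str:
    for _ in range(_MAX_REJECTION_TRIES):
        seg = "".join(rng.choice(letters, size=n, p=probs)) if n else ""
        if not clean or _segment_is_clean(seg, params):
            return seg
    raise ShellomeError(
        f"could not draw a clean background segment of length {n}; "
        "background frequencies are too biased"
    )


def _plant_sequence(
    rng: np.random.Generator, plant: PlantedLCR,
    letters: list[str], probs: np.ndarray,
) -> str:
    if plant.kind == "single":
        pure = plant.residues * plant.length
    else:
        a, b = sorted(plant.residues)
        pure = ((a + b) * plant.length)[: plant.length]
    if plant.purity >= 1.0:
        return pure
    chars = list(pure)
    for i in range(len(chars)):
        if rng.random() > plant.purity:
            chars[i] = str(rng.choice(letters, p=probs))
    return "".join(chars)


def gen_protein_set(
    spec: SynthSpec, params: LCRParams = LCRParams()
) -> tuple[list[ProteinRecord], dict[str, ProteinTruth]]:
    """Generate proteins with planted features and their ground-truth table."""
    rng = np.random.default_rng(spec.seed)
    focal = set("".join(p.residues for p in spec.planted_lcrs))
    if spec.planted_polyd_tail:
        focal.add("D")
    letters, probs = _background_distribution(spec, focal)

    gap_min = params.window_len
    plant_total = sum(p.length for p in spec.planted_lcrs)
    tail_len = spec.planted_polyd_tail or 0
    required = plant_total + tail_len + gap_min * (len(spec.planted_lcrs) + 1)
    lo, hi = spec.length_range
    if required > hi:
        raise ShellomeError(
            f"planted features need {required} residues but proteins are at most {hi} long"
        )

    records: list[ProteinRecord] = []
    truths: dict[str, ProteinTruth] = {}
    for idx in range(spec.n_proteins):
        pid = f"syn_{idx + 1:04d}"
        length = int(rng.integers(max(lo, required), hi + 1))
        n_gaps = len(spec.planted_lcrs) + 1
        slack = length - plant_total - tail_len - gap_min * n_gaps
        extra = rng.multinomial(slack, np.ones(n_gaps) / n_gaps) if slack > 0 else np.zeros(n_gaps, dtype=int)
        gap_lens = [gap_min + int(e) for e in extra]

        parts: list[str] = []
        spans: list[PlantedSpan] = []
        pos = 0
        for plant, gap in zip(spec.planted_lcrs, gap_lens[:-1]):
            seg = _draw_background(rng, gap, letters, probs, spec.clean, params)
            parts.append(seg)
            pos += gap
            planted = _plant_sequence(rng, plant, letters, probs)
            parts.append(planted)
            spans.append(PlantedSpan(plant.kind, "".join(sorted(plant.residues)),
                                     pos + 1, pos + plant.length, plant.purity))
            pos += plant.length
        parts.append(_draw_background(rng, gap_lens[-1], letters, probs, spec.clean, params))
        pos += gap_lens[-1]

        polyd: tuple[int, int] | None = None
        if tail_len:
            parts.append("D" * tail_len)
            polyd = (pos + 1, pos + tail_len)
            pos += tail_len

        sequence = "".join(parts)
        domains = []
        for accession, approx in spec.planted_domains:
            start = min(max(1, approx), len(sequence))
            end = min(start + 59, len(sequence))
            domains.append(DomainHit(pid, "synthetic", accession,
                                     f"planted {accession}", start, end))
        records.append(ProteinRecord(pid, sequence, "synthetic protein"))
        truths[pid] = ProteinTruth(pid, tuple(spans), polyd, tuple(domains))
    return records, truths


def gen_evidence(
    patterns: Mapping[str, str | Sequence[int]],
    extract_ids: Sequence[str] = CANONICAL_EXTRACTS,
) -> EvidenceTable:
    """Evidence table from per-protein count tuples or named templates."""
    entries: dict[tuple[str, str], int] = {}
    for pid, pattern in patterns.items():
        counts = EVIDENCE_TEMPLATES[pattern] if isinstance(pattern, str) else tuple(pattern)
        if len(counts) != len(extract_ids):
            raise ShellomeError(f"{pid}: pattern length {len(counts)} != "
                                f"{len(extract_ids)} extracts")
        for ext, count in zip(extract_ids, counts):
            if count:
                entries[(pid, ext)] = int(count)
    return EvidenceTable(entries=entries, extract_ids=tuple(extract_ids))


def _likely_prob(rng: np.random.Generator) -> float:
    # Beta(8, 2) rescaled to (0.5, 1]: always above the 0.5 threshold
    return 0.5 + 0.5 * float(rng.beta(8, 2))


def _unlikely_prob(rng: np.random.Generator) -> float:
    # Beta(2, 8) rescaled to [0, 0.5): never above the threshold
    return 0.5 * float(rng.beta(2, 8))


def gen_phospho(
    spec: SynthSpec,
    records: Sequence[ProteinRecord],
    truths: Mapping[str, ProteinTruth],
) -> list[PhosphoTrack]:
    """Phospho-probability tracks over S/T positions.

    Inside planted LCR spans a site is likely (probability drawn above 0.5)
    at rate ``phospho_rate_in_lcr``; elsewhere at ``phospho_rate_outside``.
    """
    rng = np.random.default_rng(spec.seed + 1)
    tracks: list[PhosphoTrack] = []
    for rec in records:
        spans = truths[rec.id].lcr_spans if rec.id in truths else ()
        in_lcr = set()
        for span in spans:
            in_lcr.update(range(span.start, span.end + 1))
        sites: list[PhosphoSite] = []
        for pos, aa in enumerate(rec.sequence, start=1):
            if aa not in ("S", "T"):
                continue
            rate = spec.phospho_rate_in_lcr if pos in in_lcr else spec.phospho_rate_outside
            prob = _likely_prob(rng) if rng.random() < rate else _unlikely_prob(rng)
            sites.append(PhosphoSite(pos, aa, prob))
        tracks.append(PhosphoTrack(rec.id, tuple(sites)))
    return tracks


def gen_plate(spec: SynthSpec) -> LectinPlate:
    """Lectin plate: reading = background + true signal + Gaussian noise."""
    rng = np.random.default_rng(spec.seed + 2)
    if spec.plate_true is not None:
        true = dict(spec.plate_true)
    else:
        # default emulates a galactose/chitin-reactive matrix: jacalin strongest,
        # DSL next, a mid tier of chitin/mannose binders, the rest near background
        true = {lectin: 0.05 for lectin in DEFAULT_LECTINS}
        true.update({"Jacalin": 1.40, "DSL": 1.05, "LEL": 0.55, "STL": 0.50,
                     "PSA": 0.40, "DBA": 0.30, "ConA": 0.30, "SBA": 0.28,
                     "PHA-L": 0.27, "ECL": 0.26, "GSL I": 0.26})
    n = spec.plate_replicates
    absorbance = {
        lectin: tuple(
            max(0.0, spec.plate_background + signal + rng.normal(0.0, spec.plate_noise_sd))
            for _ in range(n)
        )
        for lectin, signal in true.items()
    }
    background = tuple(
        max(0.0, spec.plate_background + rng.normal(0.0, spec.plate_noise_sd))
        for _ in range(n)
    )
    return LectinPlate(lectins=tuple(true), absorbance=absorbance, background=background)
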