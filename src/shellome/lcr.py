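"""Low-complexity region (LCR) detection by windowed amino-acid composition.

Two criteria are applied over a sliding window of ``window_len`` residues
(default 10), each window lying fully inside the sequence:

(i)  *single*: one amino acid fills >= 50% of the window, and the resulting
     stretch spans more than 14 successive residues (>= 15);
(ii) *pair*: the most abundant amino acid fills >= 40% of the window and a
     second amino acid >= 20%, with the stretch spanning more than 19
     successive residues (>= 20).

Fraction thresholds are applied as integer counts via ceiling (>= 5, >= 4,
>= 2 of a 10-window), avoiding floating-point comparisons. For each enriched
residue (or unordered residue pair) the positions covered by its flagged
windows are unioned; each maximal run of consecutive covered positions is
trimmed at both ends to the nearest focal residue — a region cannot begin or
end on a residue it is not enriched in — and kept if it still meets the
minimum stretch length. Single and pair regions are reported independently
(no suppression of one by the other). ``X`` counts in the window denominator
but can never be an enriched residue.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable

from .model import ProteinRecord, ShellomeError, STANDARD_AA


@dataclass(frozen=True)
class LCRParams:
    """Window and stretch thresholds for the two LCR criteria."""

    window_len: int = 10
    single_min_frac: float = 0.50
    single_min_run: int = 15
    pair_first_min_frac: float = 0.40
    pair_second_min_frac: float = 0.20
    pair_min_run: int = 20

    def __post_init__(self) -> None:
        for frac in (self.single_min_frac, self.pair_first_min_frac,
                     self.pair_second_min_frac):
            if not (0.0 < frac <= 1.0):
                raise ShellomeError(f"fraction threshold {frac} outside (0, 1]")
        if self.window_len < 2:
            raise ShellomeError("window_len must be >= 2")
        if self.single_min_run < self.window_len or self.pair_min_run < self.window_len:
            raise ShellomeError("run minima must be >= window_len")

    @property
    def single_min_count(self) -> int:
        return math.ceil(self.single_min_frac * self.window_len)

    @property
    def pair_first_min_count(self) -> int:
        return math.ceil(self.pair_first_min_frac * self.window_len)

    @property
    def pair_second_min_count(self) -> int:
        return math.ceil(self.pair_second_min_frac * self.window_len)


@dataclass(frozen=True)
class LCRegion:
    """A detected low-complexity span (1-based, inclusive)."""

    protein_id: str
    start: int
    end: int
    kind: str  # "single" or "pair"
    residues: str  # 1 letter, or 2 letters stored alphabetically
    label: str  # e.g. "T-rich", "GS-rich"

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def positions(self) -> range:
        return range(self.start, self.end + 1)


@dataclass(frozen=True)
class HomopolymerRun:
    """A maximal run of one residue (e.g. poly-Asp)."""

    protein_id: str
    residue: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def make_label(residues: str) -> str:
    return f"{''.join(sorted(residues))}-rich"


def _window_counts(sequence: str, window_len: int):
    """Yield (1-based start, Counter) for every full window, O(n) updates."""
    n = len(sequence)
    if n < window_len:
        return
    counts = Counter(sequence[:window_len])
    yield 1, counts
    for start in range(2, n - window_len + 2):
        counts = counts.copy()
        out_aa = sequence[start - 2]
        counts[out_aa] -= 1
        if counts[out_aa] == 0:
            del counts[out_aa]
        counts[sequence[start + window_len - 2]] += 1
        yield start, counts


def flag_windows_single(
    sequence: str, params: LCRParams = LCRParams()
) -> dict[str, set[int]]:
    """Window starts where a single residue meets the >= 50% criterion."""
    flagged: dict[str, set[int]] = {}
    for start, counts in _window_counts(sequence, params.window_len):
        for aa, c in counts.items():
            if aa in STANDARD_AA and c >= params.single_min_count:
                flagged.setdefault(aa, set()).add(start)
    return flagged


def flag_windows_pair(
    sequence: str, params: LCRParams = LCRParams()
) -> dict[str, set[int]]:
    """Window starts flagged for unordered residue pairs (keys alphabetized).

    A window is flagged for pair XY when X attains the window's maximum count
    with count >= ceil(0.4 w) and Y is any other residue with count
    >= ceil(0.2 w); ties produce multiple pairs.
    """
    flagged: dict[str, set[int]] = {}
    for start, counts in _window_counts(sequence, params.window_len):
        std = {aa: c for aa, c in counts.items() if aa in STANDARD_AA}
        if not std:
            continue
        max_count = max(std.values())
        if max_count < params.pair_first_min_count:
            continue
        firsts = [aa for aa, c in std.items() if c == max_count]
        for x in firsts:
            for y, c in std.items():
                if y != x and c >= params.pair_second_min_count:
                    key = "".join(sorted((x, y)))
                    flagged.setdefault(key, set()).add(start)
    return flagged


def _covered_runs(starts: set[int], window_len: int) -> list[tuple[int, int]]:
    """Maximal runs of consecutive positions covered by >= 1 flagged window."""
    covered: set[int] = set()
    for s in starts:
        covered.update(range(s, s + window_len))
    runs: list[tuple[int, int]] = []
    for pos in sorted(covered):
        if runs and pos == runs[-1][1] + 1:
            runs[-1] = (runs[-1][0], pos)
        else:
            runs.append((pos, pos))
    return runs


def _trim_to_focal(sequence: str, start: int, end: int, residues: str) -> tuple[int, int] | None:
    """Shrink a run so it begins and ends on an enriched residue."""
    focal = set(residues)
    while start <= end and sequence[start - 1] not in focal:
        start += 1
    while end >= start and sequence[end - 1] not in focal:
        end -= 1
    if start > end:
        return None
    return start, end


def detect_lcrs(
    protein: ProteinRecord, params: LCRParams = LCRParams()
) -> list[LCRegion]:
    """All single- and pair-criterion LCRs of a protein, sorted by position."""
    seq = protein.sequence
    regions: set[tuple[int, str, str]] = set()
    out: list[LCRegion] = []

    def emit(residues: str, kind: str, min_run: int, starts: set[int]) -> None:
        for run_start, run_end in _covered_runs(starts, params.window_len):
            trimmed = _trim_to_focal(seq, run_start, run_end, residues)
            if trimmed is None:
                continue
            t_start, t_end = trimmed
            if t_end - t_start + 1 < min_run:
                continue
            key = (t_start, kind, residues)
            if key in regions:
                continue
            regions.add(key)
            out.append(LCRegion(
                protein_id=protein.id, start=t_start, end=t_end,
                kind=kind, residues=residues, label=make_label(residues),
            ))

    for aa, starts in flag_windows_single(seq, params).items():
        emit(aa, "single", params.single_min_run, starts)
    for pair, starts in flag_windows_pair(seq, params).items():
        emit(pair, "pair", params.pair_min_run, starts)

    out.sort(key=lambda r: (r.start, r.kind, r.residues))
    return out


def find_homopolymer_runs(
    protein: ProteinRecord, residue: str, min_len: int = 2
) -> list[HomopolymerRun]:
    """Maximal runs of ``residue`` with length >= ``min_len``, in order."""
    if min_len < 2:
        raise ShellomeError("min_len must be >= 2")
    runs: list[HomopolymerRun] = []
    seq = protein.sequence
    i = 0
    n = len(seq)
    while i < n:
        if seq[i] == residue:
            j = i
            while j + 1 < n and seq[j + 1] == residue:
                j += 1
            if j - i + 1 >= min_len:
                runs.append(HomopolymerRun(protein.id, residue, i + 1, j + 1))
            i = j + 1
        else:
            i += 1
    return runs


def lcrs_for_records(
    records: Iterable[ProteinRecord], params: LCRParams = LCRParams()
) -> dict[str, list[LCRegion]]:
    return {rec.id: detect_lcrs(rec, params) for rec in records}
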