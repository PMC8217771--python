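"""Thresholding of phosphorylation probabilities and overlap with LCRs.

A site is a *likely* phosphorylation site when its predicted probability is
strictly greater than the threshold (default 0.5). The overlay counts how
many likely sites fall inside at least one low-complexity region; overlapping
regions are merged to a position set first, so no site is double-counted,
while per-region densities are still reported for each original region.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .lcr import LCRegion
from .model import PhosphoTrack, ShellomeError

PHOSPHO_THRESHOLD = 0.5


@dataclass(frozen=True)
class PhosphoSummary:
    protein_id: str
    likely_sites: tuple[int, ...]
    n_likely: int
    n_in_lcr: int
    frac_in_lcr: float
    undefined_base: bool  # True when n_likely == 0 and frac is reported as 0
    per_region_density: Mapping[LCRegion, float]


def likely_sites(track: PhosphoTrack, threshold: float = PHOSPHO_THRESHOLD) -> list[int]:
    """Positions with probability strictly greater than the threshold."""
    return [s.position for s in track.sites if s.probability > threshold]


def overlay_lcr(
    protein_id: str,
    positions: Sequence[int],
    regions: Sequence[LCRegion],
    protein_length: int | None = None,
) -> PhosphoSummary:
    """Overlap of likely phospho sites with LCRs for one protein."""
    if protein_length is not None:
        bad = [p for p in positions if not (1 <= p <= protein_length)]
        if bad:
            raise ShellomeError(
                f"{protein_id}: phospho position(s) {bad} outside 1..{protein_length}"
            )
    covered: set[int] = set()
    for region in regions:
        covered.update(region.positions())
    pos_set = set(positions)
    n_likely = len(pos_set)
    n_in = len(pos_set & covered)
    undefined = n_likely == 0
    frac = 0.0 if undefined else n_in / n_likely
    density = {
        region: len(pos_set & set(region.positions())) / region.length
        for region in regions
    }
    return PhosphoSummary(
        protein_id=protein_id,
        likely_sites=tuple(sorted(pos_set)),
        n_likely=n_likely,
        n_in_lcr=n_in,
        frac_in_lcr=frac,
        undefined_base=undefined,
        per_region_density=density,
    )


def overlay_track(
    track: PhosphoTrack,
    regions: Sequence[LCRegion],
    threshold: float = PHOSPHO_THRESHOLD,
    protein_length: int | None = None,
) -> PhosphoSummary:
    return overlay_lcr(track.protein_id, likely_sites(track, threshold),
                       regions, protein_length)
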