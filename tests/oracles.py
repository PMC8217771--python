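"""Independent brute-force re-implementations used only as test oracles.

Everything here recomputes results from first principles (full recounts per
window, boolean position arrays, regular expressions) without sharing code
with the package's sliding-window implementation.
"""

from __future__ import annotations

import math
import re

from shellome.lcr import LCRParams
from shellome.model import STANDARD_AA


def naive_flag_single(seq: str, params: LCRParams) -> dict[str, set[int]]:
    w = params.window_len
    need = math.ceil(params.single_min_frac * w)
    flagged: dict[str, set[int]] = {}
    for start in range(1, len(seq) - w + 2):
        window = seq[start - 1 : start - 1 + w]
        for aa in set(window):
            if aa in STANDARD_AA and window.count(aa) >= need:
                flagged.setdefault(aa, set()).add(start)
    return flagged


def naive_flag_pair(seq: str, params: LCRParams) -> dict[str, set[int]]:
    w = params.window_len
    need1 = math.ceil(params.pair_first_min_frac * w)
    need2 = math.ceil(params.pair_second_min_frac * w)
    flagged: dict[str, set[int]] = {}
    for start in range(1, len(seq) - w + 2):
        window = seq[start - 1 : start - 1 + w]
        counts = {aa: window.count(aa) for aa in set(window) if aa in STANDARD_AA}
        if not counts:
            continue
        top = max(counts.values())
        if top < need1:
            continue
        for x, cx in counts.items():
            if cx != top:
                continue
            for y, cy in counts.items():
                if y != x and cy >= need2:
                    flagged.setdefault("".join(sorted((x, y))), set()).add(start)
    return flagged


def naive_regions(seq: str, params: LCRParams) -> list[tuple[str, str, int, int]]:
    """(kind, residues, start, end) tuples re-derived from per-window recounts."""
    out: list[tuple[str, str, int, int]] = []
    jobs = [("single", naive_flag_single(seq, params), params.single_min_run),
            ("pair", naive_flag_pair(seq, params), params.pair_min_run)]
    for kind, flags, min_run in jobs:
        for residues, starts in flags.items():
            covered = [False] * (len(seq) + 1)  # 1-based
            for s in starts:
                for pos in range(s, s + params.window_len):
                    covered[pos] = True
            pos = 1
            while pos <= len(seq):
                if not covered[pos]:
                    pos += 1
                    continue
                end = pos
                while end + 1 <= len(seq) and covered[end + 1]:
                    end += 1
                # trim ends to the enriched residue(s)
                a, b = pos, end
                while a <= b and seq[a - 1] not in residues:
                    a += 1
                while b >= a and seq[b - 1] not in residues:
                    b -= 1
                if a <= b and b - a + 1 >= min_run:
                    out.append((kind, residues, a, b))
                pos = end + 1
    return sorted(set(out), key=lambda t: (t[2], t[0], t[1]))


def regex_homopolymer_runs(seq: str, residue: str, min_len: int) -> list[tuple[int, int]]:
    return [(m.start() + 1, m.end())
            for m in re.finditer(f"{re.escape(residue)}{{{min_len},}}", seq)]
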