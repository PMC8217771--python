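from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # tests/oracles.py

from shellome.model import ProteinRecord


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20210608)


def random_sequences(
    rng: np.random.Generator, n: int, length_range: tuple[int, int],
    letters: str = "TGSAPDKRMNC",
    weights: tuple[float, ...] | None = None,
) -> list[str]:
    """Random sequences over a biased, LCR-prone alphabet."""
    if weights is None:
        # heavy on four letters so composition windows actually fire
        heavy = {"T": 0.18, "G": 0.18, "S": 0.14, "A": 0.14}
        rest = (1.0 - sum(heavy.values())) / (len(letters) - len(heavy))
        weights = tuple(heavy.get(aa, rest) for aa in letters)
    probs = np.array(weights) / np.sum(weights)
    lo, hi = length_range
    seqs = []
    for _ in range(n):
        length = int(rng.integers(lo, hi + 1))
        seqs.append("".join(rng.choice(list(letters), size=length, p=probs)))
    return seqs


def record(seq: str, pid: str = "p") -> ProteinRecord:
    return ProteinRecord(pid, seq)
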