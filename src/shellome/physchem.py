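"""Composition, molecular weight, theoretical pI and acidity classification.

The net charge of a protein at a given pH is modelled with the
Henderson–Hasselbalch equation over its ionizable groups:

    Q(pH) = sum_b n_b / (1 + 10^(pH - pKa_b)) - sum_a n_a / (1 + 10^(pKa_a - pH))

with basic groups b in {N-terminus, His, Lys, Arg} and acidic groups a in
{C-terminus, Asp, Glu, Cys, Tyr}. Q is strictly decreasing in pH, so the
theoretical isoelectric point is the unique zero crossing, found by bisection
on [0, 14].

pKa sets are named configuration data:

* ``IPC_protein`` / ``IPC_peptide`` — transcribed from Kozlowski (2016),
  "IPC — Isoelectric Point Calculator", Biology Direct 11:55.
* ``EMBOSS`` — the pKa data shipped with the EMBOSS ``iep`` tool.

Average residue masses are the standard average isotopic masses (Expasy);
molecular weight = sum of residue masses + one water. ``X`` residues carry no
charge and contribute a configurable average residue mass.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping

from .model import ProteinRecord, ShellomeError, STANDARD_AA


@dataclass(frozen=True)
class PKaSet:
    name: str
    n_term: float
    c_term: float
    side_chains: Mapping[str, float]  # keys subset of D E C Y H K R

    def __post_init__(self) -> None:
        values = [self.n_term, self.c_term, *self.side_chains.values()]
        if any(not (0.0 < v < 14.0) for v in values):
            raise ShellomeError(f"{self.name}: pKa values must lie in (0, 14)")


PKA_SETS: dict[str, PKaSet] = {
    "IPC_protein": PKaSet(
        name="IPC_protein", n_term=9.094, c_term=2.869,
        side_chains={"C": 7.555, "D": 3.872, "E": 4.412, "H": 5.637,
                     "K": 9.052, "R": 11.84, "Y": 10.85},
    ),
    "IPC_peptide": PKaSet(
        name="IPC_peptide", n_term=9.564, c_term=2.383,
        side_chains={"C": 8.297, "D": 3.887, "E": 4.317, "H": 6.018,
                     "K": 10.517, "R": 12.503, "Y": 10.071},
    ),
    "EMBOSS": PKaSet(
        name="EMBOSS", n_term=8.6, c_term=3.6,
        side_chains={"C": 8.5, "D": 3.9, "E": 4.1, "H": 6.5,
                     "K": 10.8, "R": 12.5, "Y": 10.1},
    ),
}

DEFAULT_PKA = "IPC_protein"

#: average residue (monomer minus water) masses, Da
AVERAGE_RESIDUE_MASS: dict[str, float] = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "V": 99.1326, "W": 186.2132, "Y": 163.1760,
}
WATER_MASS = 18.01524
#: default mass of an unknown residue: mean over the 20 standard residues
UNKNOWN_RESIDUE_MASS = sum(AVERAGE_RESIDUE_MASS.values()) / 20.0

BASIC_SIDE_CHAINS = ("H", "K", "R")
ACIDIC_SIDE_CHAINS = ("D", "E", "C", "Y")

PI_ACIDIC_CUTOFF = 3.5
DE_FRACTION_CUTOFF = 0.20


@dataclass(frozen=True)
class PhyschemProfile:
    protein_id: str
    length: int
    molecular_weight: float
    pI: float
    aa_fractions: Mapping[str, float]
    asp_glu_fraction: float
    is_acidic: bool


def composition(protein: ProteinRecord) -> dict[str, float]:
    """Fraction of each observed residue over the full sequence length."""
    n = len(protein.sequence)
    counts = Counter(protein.sequence)
    return {aa: c / n for aa, c in sorted(counts.items())}


def asp_glu_fraction(protein: ProteinRecord) -> float:
    seq = protein.sequence
    return (seq.count("D") + seq.count("E")) / len(seq)


def molecular_weight(
    protein: ProteinRecord, unknown_mass: float = UNKNOWN_RESIDUE_MASS
) -> float:
    total = WATER_MASS
    for aa in protein.sequence:
        total += AVERAGE_RESIDUE_MASS.get(aa, unknown_mass)
    return total


def net_charge(protein: ProteinRecord, pH: float, pka: PKaSet | str = DEFAULT_PKA) -> float:
    """Net charge (elementary charges) at the given pH."""
    if isinstance(pka, str):
        pka = PKA_SETS[pka]
    if not (0.0 <= pH <= 14.0):
        raise ShellomeError(f"pH {pH} outside [0, 14]")
    counts = Counter(protein.sequence)
    q = 1.0 / (1.0 + 10.0 ** (pH - pka.n_term))
    q -= 1.0 / (1.0 + 10.0 ** (pka.c_term - pH))
    for aa in BASIC_SIDE_CHAINS:
        if counts[aa]:
            q += counts[aa] / (1.0 + 10.0 ** (pH - pka.side_chains[aa]))
    for aa in ACIDIC_SIDE_CHAINS:
        if counts[aa]:
            q -= counts[aa] / (1.0 + 10.0 ** (pka.side_chains[aa] - pH))
    return q


def isoelectric_point(
    protein: ProteinRecord, pka: PKaSet | str = DEFAULT_PKA, tol: float = 1e-4
) -> float:
    """pH where the net charge crosses zero (bisection on [0, 14]).

    The free termini guarantee one positive and one negative group, so Q(0) > 0
    and Q(14) < 0 and the crossing exists and is unique (Q strictly decreasing).
    Full precision is returned; round to 2 decimals for reporting.
    """
    if isinstance(pka, str):
        pka = PKA_SETS[pka]
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(protein, mid, pka) > 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def classify_acidic(
    pI: float,
    de_fraction: float,
    pi_cut: float = PI_ACIDIC_CUTOFF,
    de_cut: float = DE_FRACTION_CUTOFF,
) -> bool:
    """Acidic-protein verdict: pI strictly below 3.5 AND Asp+Glu strictly above 20%."""
    return pI < pi_cut and de_fraction > de_cut


def profile(
    protein: ProteinRecord, pka: PKaSet | str = DEFAULT_PKA
) -> PhyschemProfile:
    pi = isoelectric_point(protein, pka)
    de = asp_glu_fraction(protein)
    return PhyschemProfile(
        protein_id=protein.id,
        length=len(protein.sequence),
        molecular_weight=molecular_weight(protein),
        pI=pi,
        aa_fractions=composition(protein),
        asp_glu_fraction=de,
        is_acidic=classify_acidic(pi, de),
    )
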