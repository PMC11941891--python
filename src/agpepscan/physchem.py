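"""Physicochemical profiling of screened peptides.

Molecular weight (average isotopic masses), Henderson-Hasselbalch net
charge and isoelectric point, the Guruprasad instability index, and
amino-acid counts. All constant tables are bundled as plain-text data
(see ``agpepscan/data``); unknown residues (X) contribute zero to every
computation.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from ._tables import WATER_MASS, diwv, pka_set, residue_masses

POSITIVE_GROUPS = ("K", "R", "H")
NEGATIVE_GROUPS = ("D", "E", "C", "Y")


@dataclass
class PhyschemProfile:
    """Per-candidate physicochemical summary (raw values; reports round)."""

    mw_kda: float
    pi: float
    instability: float
    aa_counts: dict[str, int] = field(default_factory=dict)


def molecular_weight(seq: str) -> float:
    """Peptide average molecular weight in Da.

    Sum of average residue masses plus one water (18.0153 Da).
    """
    if not seq:
        raise ValueError("empty sequence")
    masses = residue_masses()
    return sum(masses.get(c, 0.0) for c in seq) + WATER_MASS


def net_charge(seq: str, pH: float, pka: str = "expasy") -> float:
    """Net charge at a given pH by the Henderson-Hasselbalch equation.

    The N-terminus and K/R/H side chains contribute ``n / (1 + 10^(pH -
    pKa))`` each; the C-terminus and D/E/C/Y side chains contribute
    ``-n / (1 + 10^(pKa - pH))``. ``pka`` selects the bundled pKa set
    ("expasy", the Bjellqvist convention, or "emboss").
    """
    if not (0 <= pH <= 14):
        raise ValueError("pH must be in [0, 14]")
    if not seq:
        raise ValueError("empty sequence")
    pk = pka_set(pka)
    counts = Counter(seq)
    charge = 1.0 / (1.0 + 10 ** (pH - pk["Nterm"]))
    charge -= 1.0 / (1.0 + 10 ** (pk["Cterm"] - pH))
    for aa in POSITIVE_GROUPS:
        charge += counts[aa] / (1.0 + 10 ** (pH - pk[aa]))
    for aa in NEGATIVE_GROUPS:
        charge -= counts[aa] / (1.0 + 10 ** (pk[aa] - pH))
    return charge


def isoelectric_point(
    seq: str, pka: str = "expasy", tol: float = 1e-4, max_iter: int = 100
) -> float:
    """pH at which the net charge is zero, by bisection on [0, 14].

    Net charge is strictly decreasing in pH, so the root is unique;
    bisection stops at |charge| < ``tol`` or after ``max_iter`` halvings.
    """
    lo, hi = 0.0, 14.0
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        c = net_charge(seq, mid, pka)
        if abs(c) < tol:
            return mid
        if c > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def instability_index(seq: str) -> float:
    """Guruprasad instability index: (10/L) * sum of dipeptide weights.

    Values above 40 predict an unstable protein in vitro. Pairs involving
    X contribute zero. Requires length >= 2.
    """
    if len(seq) < 2:
        raise ValueError("instability index needs length >= 2")
    table = diwv()
    total = 0.0
    for i in range(len(seq) - 1):
        total += table.get(seq[i], {}).get(seq[i + 1], 0.0)
    return 10.0 * total / len(seq)


def profile(seq: str, pka: str = "expasy") -> PhyschemProfile:
    """Full physicochemical profile of one sequence."""
    return PhyschemProfile(
        mw_kda=molecular_weight(seq) / 1000.0,
        pi=isoelectric_point(seq, pka),
        instability=instability_index(seq),
        aa_counts=dict(Counter(seq)),
    )
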