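"""CDS variant application, translation and protein physicochemistry.

Applies a single-nucleotide substitution to a coding sequence, translates
it (with explicit selenocysteine recoding — U is inserted only at codon
positions the caller names, never inferred from context), and computes the
ProtParam-style report: average molecular weight, theoretical isoelectric
point, Guruprasad instability index, Kyte-Doolittle GRAVY, and charged-
residue counts. The motivating application is a missense variant in exon 7
of ovine PIK3R1 (C1146T; 1146 = 3 x 382, i.e. the third base of codon 382)
reported to replace a glutamate with selenocysteine: the E→U edit raises
MW by 150.0379 − 129.1155 = +20.92 Da, drops the Asp+Glu count by one, and
moves pI and GRAVY upward.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from Bio.Data.CodonTable import unambiguous_dna_by_name
from Bio.SeqUtils.ProtParamData import DIWV

from .protparam_data import (
    AVG_RESIDUE_MASS,
    KYTE_DOOLITTLE,
    PKA_NEGATIVE,
    PKA_POSITIVE,
    VALID_RESIDUES,
    WATER_MW,
)

_CODON_TABLE = unambiguous_dna_by_name["Standard"]

__all__ = [
    "CdsVariant",
    "PhysChemReport",
    "apply_variant",
    "translate",
    "molecular_weight",
    "theoretical_pi",
    "net_charge",
    "instability_index",
    "gravy",
    "charged_counts",
    "physchem_report",
]


@dataclass(frozen=True)
class CdsVariant:
    """A single-base substitution at a 1-based position within the CDS."""

    position: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("position is 1-based and must be >= 1")
        for base in (self.ref, self.alt):
            if base not in "ACGT":
                raise ValueError(f"invalid nucleotide {base!r}")


@dataclass(frozen=True)
class PhysChemReport:
    """ProtParam-style physicochemical summary of one protein sequence."""

    length: int
    mw: float
    pi: float
    n_neg: int
    n_pos: int
    instability: float
    unstable: bool
    gravy: float

    def as_dict(self) -> dict:
        return {
            "length": self.length,
            "molecular_weight": round(self.mw, 2),
            "theoretical_pi": round(self.pi, 2),
            "negatively_charged_residues": self.n_neg,
            "positively_charged_residues": self.n_pos,
            "instability_index": round(self.instability, 2),
            "classified_unstable": self.unstable,
            "gravy": round(self.gravy, 3),
        }


def _check_protein(seq: str) -> str:
    seq = seq.upper()
    if not seq:
        raise ValueError("empty protein sequence")
    bad = set(seq) - VALID_RESIDUES
    if bad:
        raise ValueError(f"unknown residue(s): {sorted(bad)}")
    return seq


def apply_variant(cds: str, variant: CdsVariant) -> str:
    """Apply a single-base substitution; the stated reference base must match."""
    cds = cds.upper()
    if variant.position > len(cds):
        raise ValueError(
            f"position {variant.position} beyond CDS length {len(cds)}"
        )
    observed = cds[variant.position - 1]
    if observed != variant.ref:
        raise ValueError(
            f"reference mismatch at position {variant.position}: "
            f"expected {variant.ref}, observed {observed}"
        )
    i = variant.position - 1
    return cds[:i] + variant.alt + cds[i + 1 :]


def translate(cds: str, sec_positions: Sequence[int] | None = None) -> str:
    """Translate a CDS with the standard genetic code.

    ``sec_positions`` lists 1-based codon indices decoded as selenocysteine
    (U); recoding is always explicit. A single trailing stop codon is
    dropped; an internal stop outside ``sec_positions`` raises with the
    offending codon index.
    """
    cds = cds.upper().replace("U", "T")
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    sec = set(sec_positions or ())
    n_codons = len(cds) // 3
    residues = []
    for i in range(n_codons):
        codon = cds[3 * i : 3 * i + 3]
        codon_index = i + 1
        if codon_index in sec:
            residues.append("U")
            continue
        if codon in _CODON_TABLE.stop_codons:
            if codon_index == n_codons:
                break
            raise ValueError(f"premature stop codon {codon} at codon {codon_index}")
        try:
            residues.append(_CODON_TABLE.forward_table[codon])
        except KeyError as exc:
            raise ValueError(f"unrecognized codon {codon!r} at codon {codon_index}") from exc
    return "".join(residues)


def molecular_weight(protein: str) -> float:
    """Average molecular weight in Daltons: sum of residue masses plus one water."""
    protein = _check_protein(protein)
    return sum(AVG_RESIDUE_MASS[r] for r in protein) + WATER_MW


def net_charge(protein: str, ph: float, pka: Mapping[str, Mapping[str, float]] | None = None) -> float:
    """Henderson-Hasselbalch net charge at a given pH.

    Ionizable groups: the two termini plus D, E, C, Y (acidic) and H, K, R
    (basic). Residues absent from the pKa tables (notably U) contribute
    nothing.
    """
    protein = _check_protein(protein)
    pos = dict(PKA_POSITIVE if pka is None else pka["positive"])
    neg = dict(PKA_NEGATIVE if pka is None else pka["negative"])
    charge = 1.0 / (1.0 + 10.0 ** (ph - pos["Nterm"]))
    charge -= 1.0 / (1.0 + 10.0 ** (neg["Cterm"] - ph))
    for r in protein:
        if r in pos:
            charge += 1.0 / (1.0 + 10.0 ** (ph - pos[r]))
        elif r in neg:
            charge -= 1.0 / (1.0 + 10.0 ** (neg[r] - ph))
    return charge


def theoretical_pi(
    protein: str,
    pka: Mapping[str, Mapping[str, float]] | None = None,
    precision: float = 0.001,
) -> float:
    """Isoelectric point: the pH where the net charge crosses zero.

    Net charge is strictly decreasing in pH, so bisection on [0, 14]
    converges; the root is returned to ``precision`` (default 0.001,
    comfortably inside the 0.01 the report prints).
    """
    lo, hi = 0.0, 14.0
    while hi - lo > precision:
        mid = 0.5 * (lo + hi)
        if net_charge(protein, mid, pka) > 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def instability_index(protein: str) -> float:
    """Guruprasad instability index: (10/L) x sum of published dipeptide
    weights over consecutive residue pairs; > 40 predicts an unstable
    protein. Pairs involving selenocysteine contribute zero (the published
    20x20 table has no U row)."""
    protein = _check_protein(protein)
    if len(protein) < 2:
        raise ValueError("instability index needs length >= 2")
    total = 0.0
    for a, b in zip(protein, protein[1:]):
        total += DIWV.get(a, {}).get(b, 0.0)
    return 10.0 / len(protein) * total


def gravy(protein: str, u_value: float = KYTE_DOOLITTLE["C"]) -> float:
    """Grand average of hydropathicity: mean Kyte-Doolittle value per residue.

    Selenocysteine takes ``u_value`` (default: cysteine's 2.5)."""
    protein = _check_protein(protein)
    table = dict(KYTE_DOOLITTLE)
    table["U"] = u_value
    return sum(table[r] for r in protein) / len(protein)


def charged_counts(protein: str) -> tuple[int, int]:
    """(negatively, positively) charged residue counts: Asp+Glu and Arg+Lys."""
    protein = _check_protein(protein)
    n_neg = protein.count("D") + protein.count("E")
    n_pos = protein.count("R") + protein.count("K")
    return n_neg, n_pos


def physchem_report(protein: str) -> PhysChemReport:
    """Full physicochemical report for one sequence."""
    protein = _check_protein(protein)
    n_neg, n_pos = charged_counts(protein)
    ii = instability_index(protein)
    return PhysChemReport(
        length=len(protein),
        mw=molecular_weight(protein),
        pi=theoretical_pi(protein),
        n_neg=n_neg,
        n_pos=n_pos,
        instability=ii,
        unstable=ii > 40.0,
        gravy=gravy(protein),
    )
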