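"""Sequence-level bookkeeping: one-letter extraction, charge census at pH 7.4,
and the neutralizing-counterion count used in system preparation.

The module also carries the mature human SP-B peptide sequence (the 79-residue
chain obtained by trimming the preprotein). Its composition is the canonical
reference for the census functions: 7 cysteines with the three saposin
disulfides 8-77, 11-71 and 35-46, nine Arg/Lys, two Asp/Glu, net charge +7 at
physiological pH.
"""

from __future__ import annotations

from dataclasses import dataclass

from .structure import Topology

__all__ = [
    "ChargeSummary",
    "extract_sequence",
    "count_charged_residues",
    "neutralizing_ion_count",
    "SPB_MATURE_SEQUENCE",
    "THREE_TO_ONE",
]

#: Mature human surfactant protein B (79 residues).
SPB_MATURE_SEQUENCE = "FPIPLPYCWLCRALIKRIQAMIPKGALAVAVAQVCRVVPLVAGGICQCLAERYSVILLDTLLGRMLPQLVCRLVLRCSM"

THREE_TO_ONE: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    # common alternate protonation-state names map to their parent residue
    "HID": "H", "HIE": "H", "HIP": "H", "CYX": "C", "CYM": "C",
    "ASH": "D", "GLH": "E", "LYN": "K",
}

_POSITIVE = set("RK")
_NEGATIVE = set("DE")


@dataclass(frozen=True)
class ChargeSummary:
    """Charged-residue census of a peptide at pH 7.4."""

    n_positive: int
    n_negative: int
    net_charge: int


def extract_sequence(topology: Topology) -> str:
    """One-letter sequence of the protein residues, 'X' for nonstandard codes."""
    residues = topology.protein_residues()
    if not residues:
        raise ValueError("topology contains no protein residues")
    return "".join(THREE_TO_ONE.get(name.upper(), "X") for _, name in residues)


def count_charged_residues(sequence: str, include_termini: bool = True) -> ChargeSummary:
    """Count charged residues at pH 7.4.

    Arg and Lys count positive, Asp and Glu negative; His is treated as
    neutral at pH 7.4. With ``include_termini`` the free N-terminus (+1) and
    C-terminus (-1) are added to the net charge; for a free peptide they
    cancel. Unknown letters contribute no charge.
    """
    if not sequence:
        raise ValueError("sequence must be non-empty")
    seq = sequence.upper()
    n_pos = sum(c in _POSITIVE for c in seq)
    n_neg = sum(c in _NEGATIVE for c in seq)
    terminal = (1 - 1) if include_termini else 0
    return ChargeSummary(n_pos, n_neg, n_pos - n_neg + terminal)


def neutralizing_ion_count(summary: ChargeSummary) -> tuple[str, int]:
    """Counterion species and count that neutralize the peptide's net charge.

    Returns ``("anion", n)`` for a positive net charge, ``("cation", n)`` for
    a negative one and ``("none", 0)`` for a neutral peptide.
    """
    q = summary.net_charge
    if q > 0:
        return ("anion", q)
    if q < 0:
        return ("cation", -q)
    return ("none", 0)
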