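"""Small sequence helpers shared across modules.

Only primitives that are pure plumbing live here (complementation, IUPAC
matching, codon translation); everything biological sits in the domain
modules.
"""

from __future__ import annotations

from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

DNA = "ACGT"

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: IUPAC nucleotide codes -> the set of concrete bases each matches.
IUPAC = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"), "R": frozenset("AG"), "Y": frozenset("CT"),
    "S": frozenset("CG"), "W": frozenset("AT"), "K": frozenset("GT"),
    "M": frozenset("AC"), "B": frozenset("CGT"), "D": frozenset("AGT"),
    "H": frozenset("ACT"), "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

STOP_CODONS = frozenset(standard_dna_table.stop_codons)  # TAA, TAG, TGA

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (case-preserving, N-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


def complement(base: str) -> str:
    return base.translate(_COMPLEMENT)


def matches_iupac(seq: str, pattern: str) -> bool:
    """True iff ``seq`` matches the equal-length IUPAC ``pattern``."""
    if len(seq) != len(pattern):
        return False
    try:
        return all(b in IUPAC[p] for b, p in zip(seq.upper(), pattern.upper()))
    except KeyError as exc:
        raise ValueError(f"invalid IUPAC code in pattern {pattern!r}: {exc}") from exc


def validate_iupac_pattern(pattern: str) -> str:
    pattern = pattern.upper()
    bad = [c for c in pattern if c not in IUPAC]
    if bad:
        raise ValueError(f"invalid IUPAC code(s) {bad} in pattern {pattern!r}")
    return pattern


def translate_codon(codon: str) -> str:
    """One-letter amino acid for a codon, '*' for a stop."""
    codon = codon.upper()
    if codon in STOP_CODONS:
        return "*"
    return standard_dna_table.forward_table[codon]


def translate_cds(seq: str) -> str:
    return str(Seq(seq).translate())
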