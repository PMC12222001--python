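"""Invertebrate mitochondrial genetic code (NCBI translation table 5) helpers.

Everything downstream (codon usage, NG86 site counting, dataset translation,
the simulator) translates through this module so the table-5 idiosyncrasies
(ATA=Met, AGA/AGG=Ser, TGA=Trp; stops TAA/TAG only) are applied in exactly
one place.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

from Bio.Data import CodonTable

NUCLEOTIDES = "ACGT"
PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")

_TABLE5 = CodonTable.unambiguous_dna_by_id[5]

#: codon -> one-letter amino acid, sense codons only
CODON_TO_AA: dict[str, str] = dict(_TABLE5.forward_table)
STOP_CODONS: frozenset[str] = frozenset(_TABLE5.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(
    sorted(c for c in ("".join(p) for p in itertools.product(NUCLEOTIDES, repeat=3))
           if c not in STOP_CODONS)
)

#: amino acid -> synonymous family (table 5: Ser has 8 members, Leu 6)
FAMILY: dict[str, tuple[str, ...]] = {}
for _codon in SENSE_CODONS:
    FAMILY.setdefault(CODON_TO_AA[_codon], ())
FAMILY = {aa: tuple(c for c in SENSE_CODONS if CODON_TO_AA[c] == aa) for aa in FAMILY}

AA_THREE_LETTER = {
    "A": "Ala", "C": "Cys", "D": "Asp", "E": "Glu", "F": "Phe", "G": "Gly",
    "H": "His", "I": "Ile", "K": "Lys", "L": "Leu", "M": "Met", "N": "Asn",
    "P": "Pro", "Q": "Gln", "R": "Arg", "S": "Ser", "T": "Thr", "V": "Val",
    "W": "Trp", "Y": "Tyr",
}

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVNacgtryswkmbdhvn",
    "TGCAYRSWMKVHDBNtgcayrswmkvhdbn",
)


def reverse_complement(seq: str) -> str:
    """Reverse complement preserving IUPAC ambiguity codes."""
    return seq.translate(_COMPLEMENT)[::-1]


def is_transition(a: str, b: str) -> bool:
    """A<->G or C<->T substitutions."""
    return (a in PURINES and b in PURINES) or (a in PYRIMIDINES and b in PYRIMIDINES)


def is_unambiguous(seq: str) -> bool:
    return all(c in NUCLEOTIDES for c in seq)


def translate_codon(codon: str) -> str:
    """Codon -> one-letter AA under table 5; '-' for gap codons, '*' for stops,
    'X' for anything ambiguous or partially gapped."""
    codon = codon.upper()
    if codon == "---":
        return "-"
    if codon in STOP_CODONS:
        return "*"
    return CODON_TO_AA.get(codon, "X")


@lru_cache(maxsize=None)
def single_base_neighbours(codon: str) -> tuple[str, ...]:
    """The 9 codons reachable by one substitution (stops included)."""
    out = []
    for pos in range(3):
        for base in NUCLEOTIDES:
            if base != codon[pos]:
                out.append(codon[:pos] + base + codon[pos + 1:])
    return tuple(out)
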