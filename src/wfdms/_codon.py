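"""Genetic-code constants shared across the package.

The amino-acid alphabet is fixed (20 canonical residues plus the stop
symbol ``*``) so that matrices and output tables have a deterministic
order. Codons are ordered lexicographically over the DNA alphabet
``ACGT``, matching the column order of dms_tools-style codon-count
tables.
"""

from __future__ import annotations

from itertools import product

from Bio.Data.CodonTable import standard_dna_table

#: Fixed amino-acid ordering used for all output tables and matrix indices.
AA_ALPHABET: str = "ACDEFGHIKLMNPQRSTVWY*"

#: All 64 DNA codons in lexicographic {A,C,G,T} order.
CODONS: tuple[str, ...] = tuple("".join(c) for c in product("ACGT", repeat=3))

#: Codon -> one-letter amino acid (stop codons map to "*").
CODON_TO_AA: dict[str, str] = {
    codon: standard_dna_table.forward_table.get(codon, "*") for codon in CODONS
}

#: One-letter amino acid -> first codon (lexicographic) encoding it.
CANONICAL_CODON: dict[str, str] = {}
for _codon in CODONS:  # CODONS is sorted, so first hit wins
    CANONICAL_CODON.setdefault(CODON_TO_AA[_codon], _codon)

#: Three-letter -> one-letter amino-acid codes (HGVS uses either).
THREE_TO_ONE: dict[str, str] = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
    "Ter": "*",
}

ONE_TO_THREE: dict[str, str] = {v: k for k, v in THREE_TO_ONE.items()}
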