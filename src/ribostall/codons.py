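"""Codon alphabet shared by every module.

The analysis frame is the 61 amino-acid-encoding ("sense") codons of the
standard nuclear code; stop codons never carry A-site assignments and are
excluded from occupancy, composition and content denominators throughout.
"""

from __future__ import annotations

from itertools import product

from Bio.Data import CodonTable

BASES = "ACGT"

STOP_CODONS: frozenset[str] = frozenset({"TAA", "TAG", "TGA"})

ALL_CODONS: tuple[str, ...] = tuple("".join(p) for p in product(BASES, repeat=3))

#: The 61 sense codons, lexicographically sorted — the canonical row order of
#: every occupancy table this package writes.
SENSE_CODONS: tuple[str, ...] = tuple(c for c in ALL_CODONS if c not in STOP_CODONS)

_TABLE = CodonTable.unambiguous_dna_by_id[1]

#: codon -> one-letter amino acid, sense codons only.
CODON_TO_AA: dict[str, str] = {c: _TABLE.forward_table[c] for c in SENSE_CODONS}

START_CODON = "ATG"


def is_sense(codon: str) -> bool:
    return codon in CODON_TO_AA
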