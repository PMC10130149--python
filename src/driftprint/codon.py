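"""Standard genetic code helpers shared by site counting and variant classification.

The codon→amino-acid map is built once from Biopython's standard DNA codon
table so every consumer in the package uses the same code. Stop codons are
represented by ``*``.
"""

from __future__ import annotations

from functools import lru_cache

from Bio.Data import CodonTable

BASES = "ACGT"

_TABLE = CodonTable.unambiguous_dna_by_name["Standard"]

#: codon (upper-case DNA) -> one-letter amino acid, '*' for stop
GENETIC_CODE: dict[str, str] = dict(_TABLE.forward_table)
for _stop in _TABLE.stop_codons:
    GENETIC_CODE[_stop] = "*"

STOP_CODONS = frozenset(_TABLE.stop_codons)
START_CODON = "ATG"

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def complement(base: str) -> str:
    return base.translate(_COMPLEMENT)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate_codon(codon: str) -> str:
    """Translate one codon; returns '*' for stop, 'X' for ambiguous codons."""
    return GENETIC_CODE.get(codon.upper(), "X")


@lru_cache(maxsize=None)
def synonymous_fraction(codon: str) -> tuple[float, float]:
    """Nei–Gojobori site contributions (syn_sites, nonsyn_sites) of one codon.

    Each of the three positions contributes ``f/3`` synonymous sites, where
    ``f`` is the number of the three possible single-base changes at that
    position that preserve the amino acid. Changes to a stop codon count as
    nonsynonymous. Stop codons contribute nothing (excluded upstream).
    """
    codon = codon.upper()
    aa = translate_codon(codon)
    if aa in ("*", "X"):
        return (0.0, 0.0)
    syn = 0.0
    for i in range(3):
        f = 0
        for b in BASES:
            if b == codon[i]:
                continue
            alt = codon[:i] + b + codon[i + 1 :]
            if translate_codon(alt) == aa:
                f += 1
        syn += f / 3.0
    return (syn, 3.0 - syn)
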