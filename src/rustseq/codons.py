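"""Genetic-code tables and codon bookkeeping shared across the package.

The 61 sense codons are kept in a fixed lexicographic order; every array
indexed "per codon" in this package follows :data:`SENSE_CODONS`.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"

GENETIC_CODE: dict[str, str] = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

STOP_CODONS = ("TAA", "TAG", "TGA")

ALL_CODONS: tuple[str, ...] = tuple(sorted(GENETIC_CODE))

SENSE_CODONS: tuple[str, ...] = tuple(
    c for c in ALL_CODONS if GENETIC_CODE[c] != "*"
)

AMINO_ACIDS: tuple[str, ...] = tuple(sorted(set(GENETIC_CODE.values()) - {"*"}))

SENSE_INDEX: dict[str, int] = {c: i for i, c in enumerate(SENSE_CODONS)}
AA_INDEX: dict[str, int] = {a: i for i, a in enumerate(AMINO_ACIDS)}

# Human codon usage, frequency per thousand codons (GenBank-derived
# averages commonly used for H. sapiens).  Used to order simulated dwell
# times by codon rarity and to sample realistic synthetic coding sequences.
HUMAN_CODON_USAGE: dict[str, float] = {
    "TTT": 17.6, "TTC": 20.3, "TTA": 7.7, "TTG": 12.9,
    "CTT": 13.2, "CTC": 19.6, "CTA": 7.2, "CTG": 39.6,
    "ATT": 16.0, "ATC": 20.8, "ATA": 7.5, "ATG": 22.0,
    "GTT": 11.0, "GTC": 14.5, "GTA": 7.1, "GTG": 28.1,
    "TCT": 15.2, "TCC": 17.7, "TCA": 12.2, "TCG": 4.4,
    "CCT": 17.5, "CCC": 19.8, "CCA": 16.9, "CCG": 6.9,
    "ACT": 13.1, "ACC": 18.9, "ACA": 15.1, "ACG": 6.1,
    "GCT": 18.4, "GCC": 27.7, "GCA": 15.8, "GCG": 7.4,
    "TAT": 12.2, "TAC": 15.3,
    "CAT": 10.9, "CAC": 15.1, "CAA": 12.3, "CAG": 34.2,
    "AAT": 17.0, "AAC": 19.1, "AAA": 24.4, "AAG": 31.9,
    "GAT": 21.8, "GAC": 25.1, "GAA": 29.0, "GAG": 39.6,
    "TGT": 10.6, "TGC": 12.6, "TGG": 13.2,
    "CGT": 4.5, "CGC": 10.4, "CGA": 6.2, "CGG": 11.4,
    "AGT": 12.1, "AGC": 19.5, "AGA": 12.2, "AGG": 12.0,
    "GGT": 10.8, "GGC": 22.2, "GGA": 16.5, "GGG": 16.5,
}


def codons_of(sequence: str, start: int, end: int) -> list[str]:
    """Split ``sequence[start:end]`` into consecutive codons."""
    cds = sequence[start:end].upper()
    return [cds[i : i + 3] for i in range(0, len(cds), 3)]


def encode_codons(codon_list: list[str]) -> np.ndarray:
    """Map codons to sense-codon indices; stops and ambiguous codons -> -1."""
    return np.array([SENSE_INDEX.get(c, -1) for c in codon_list], dtype=np.int64)


def translate(codon_list: list[str]) -> str:
    """Translate codons to one-letter amino acids; unknown/stop -> ``*``/``X``."""
    out = []
    for c in codon_list:
        aa = GENETIC_CODE.get(c, "X")
        out.append(aa)
    return "".join(out)
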