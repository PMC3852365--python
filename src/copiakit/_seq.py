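"""Low-level nucleotide and peptide utilities shared across the package.

Sequences are plain Python strings (upper-case A/C/G/T plus IUPAC ambiguity
codes where noted); hot loops work on uint8 code arrays (A=0, C=1, G=2, T=3,
anything else 4).
"""
from __future__ import annotations

import numpy as np

DNA = "ACGT"

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(DNA):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)

_COMP = str.maketrans(
    "ACGTRYKMSWBVDHNacgtrykmswbvdhn",
    "TGCAYRMKSWVBHDNtgcayrmkswvbhdn",
)

IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

_BASES_BY_CODON = [a + b + c for a in DNA for b in DNA for c in DNA]
NONSTOP_CODONS = [c for c in _BASES_BY_CODON if c not in STOP_CODONS]

_CODON_AA = {
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

# deterministic aa -> codon choice (first codon in lexical order)
AA_TO_CODON: dict[str, str] = {}
for _codon in _BASES_BY_CODON:
    _aa = _CODON_AA[_codon]
    if _aa != "*" and _aa not in AA_TO_CODON:
        AA_TO_CODON[_aa] = _codon


def encode(seq: str) -> np.ndarray:
    """Map a sequence string onto uint8 codes (A=0 C=1 G=2 T=3, other=4)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return _DECODE[np.minimum(codes, 4)].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def random_dna(n: int, rng: np.random.Generator) -> str:
    return decode(rng.integers(0, 4, size=n, dtype=np.uint8))


def translate(nt: str) -> str:
    """Translate the + strand, frame 0; stops rendered as '*'."""
    n = len(nt) // 3 * 3
    return "".join(_CODON_AA.get(nt[i:i + 3].upper(), "X") for i in range(0, n, 3))


def encode_peptide(aa: str) -> str:
    """Deterministic reverse translation (one fixed codon per residue)."""
    return "".join(AA_TO_CODON[c] for c in aa)


def random_codons(n: int, rng: np.random.Generator) -> list[str]:
    idx = rng.integers(0, len(NONSTOP_CODONS), size=n)
    return [NONSTOP_CODONS[i] for i in idx]


def kmer_hashes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Rolling k-mer hashes (base-4) and a validity mask (no ambiguous base).

    Returns (hashes, valid) of length ``len(codes) - k + 1``.
    """
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    h = np.zeros(n, dtype=np.int64)
    good = codes < 4
    valid = np.ones(n, dtype=bool)
    for j in range(k):
        h = (h << 2) | codes[j:j + n]
        valid &= good[j:j + n]
    return h, valid
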