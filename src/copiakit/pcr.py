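"""IUPAC-degenerate primer handling and in-silico PCR.

Degenerate positions match their IUPAC code set at zero cost; substitutions
outside the code set count toward ``max_mismatch``.  Amplification pairs a
forward-primer site with an inward-facing reverse-primer site on the
opposite strand and keeps products inside ``product_range``.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import product as _iterproduct

import numpy as np

from ._seq import IUPAC, encode, revcomp

_COMP_CODE = {"A": "T", "C": "G", "G": "C", "T": "A", "R": "Y", "Y": "R", "S": "S",
              "W": "W", "K": "M", "M": "K", "B": "V", "V": "B", "D": "H", "H": "D", "N": "N"}


class PrimerFormatError(ValueError):
    pass


@dataclass(frozen=True)
class PrimerSet:
    name: str
    forward: str
    reverse: str
    max_mismatch: int = 1
    product_range: tuple[int, int] = (100, 1500)

    def __post_init__(self):
        for p in (self.forward, self.reverse):
            _validate(p)
        if self.product_range[0] < len(self.forward) + len(self.reverse):
            raise ValueError("product_range.min must cover both primers")


@dataclass(frozen=True)
class Amplicon:
    contig: str
    start: int
    end: int
    strand: str
    sequence: str
    primer_set: str
    mismatches: int = 0

    def __len__(self) -> int:
        return self.end - self.start


def _validate(primer: str) -> None:
    for i, ch in enumerate(primer.upper()):
        if ch not in IUPAC:
            raise PrimerFormatError(f"invalid IUPAC character {ch!r} at position {i}")


def degeneracy(primer: str) -> int:
    """Number of concrete sequences the degenerate primer represents."""
    _validate(primer)
    n = 1
    for ch in primer.upper():
        n *= len(IUPAC[ch])
    return n


def expand_degenerate(primer: str, cap: int = 65536) -> list[str]:
    """Enumerate all concrete expansions (raises above ``cap``; see degeneracy)."""
    n = degeneracy(primer)
    if n > cap:
        raise ValueError(f"degeneracy {n} exceeds cap {cap}; use degeneracy() instead")
    pools = [sorted(IUPAC[ch]) for ch in primer.upper()]
    return ["".join(t) for t in _iterproduct(*pools)]


def _pattern_table(primer: str) -> np.ndarray:
    """(k, 5) boolean table: table[j, code] == base allowed at position j."""
    k = len(primer)
    table = np.zeros((k, 5), dtype=bool)
    for j, ch in enumerate(primer.upper()):
        for b in IUPAC[ch]:
            table[j, "ACGT".index(b)] = True
    return table


def _scan(codes: np.ndarray, primer: str, max_mismatch: int) -> tuple[np.ndarray, np.ndarray]:
    """Positions and mismatch counts where ``primer`` matches the + strand."""
    k = len(primer)
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    table = _pattern_table(primer)
    mm = np.zeros(n, dtype=np.int16)
    for j in range(k):
        mm += ~table[j][codes[j:j + n]]
    pos = np.flatnonzero(mm <= max_mismatch)
    return pos, mm[pos].astype(np.int64)


def find_primer_sites(genome, primer: str, max_mismatch: int = 1) -> list[tuple[str, int, str, int]]:
    """All (contig, position, strand, mismatches) sites of a degenerate primer.

    '+' means the primer sequence matches ``contig[pos:pos+k]``; '-' means
    its reverse complement does (the primer anneals to the + strand).
    """
    _validate(primer)
    if max_mismatch > 3:
        raise ValueError("max_mismatch must be <= 3")
    contigs = genome.contigs if hasattr(genome, "contigs") else genome
    if isinstance(contigs, str):
        contigs = {"seq": contigs}
    rc = primer.upper().translate(str.maketrans(_COMP_CODE))[::-1]
    out = []
    for name, seq in contigs.items():
        codes = encode(seq)
        for strand, pat in (("+", primer.upper()), ("-", rc)):
            pos, mm = _scan(codes, pat, max_mismatch)
            out.extend((name, int(p), strand, int(m)) for p, m in zip(pos, mm))
    out.sort(key=lambda t: (t[0], t[1], t[2]))
    return out


def amplify(genome, primer_set: PrimerSet) -> list[Amplicon]:
    """Predict PCR products of a primer set over a genome.

    A product needs a forward-primer site and a reverse-primer site facing
    inward on opposite strands, with total length inside ``product_range``.
    Identical intervals are collapsed; output is coordinate-sorted.
    """
    contigs = genome.contigs if hasattr(genome, "contigs") else genome
    if isinstance(contigs, str):
        contigs = {"seq": contigs}
    fwd_sites = find_primer_sites(genome, primer_set.forward, primer_set.max_mismatch)
    rev_sites = find_primer_sites(genome, primer_set.reverse, primer_set.max_mismatch)
    lo, hi = primer_set.product_range
    kf, kr = len(primer_set.forward), len(primer_set.reverse)
    seen: dict[tuple, Amplicon] = {}
    # (left primer on + strand, right primer on - strand) in both role orders
    for left_sites, right_sites, klen_r, strand in (
            (fwd_sites, rev_sites, kr, "+"),   # product read 5'->3' from forward primer
            (rev_sites, fwd_sites, kf, "-")):
        rights = {}
        for c, p, s, m in right_sites:
            if s == "-":
                rights.setdefault(c, []).append((p, m))
        for c in rights:
            rights[c].sort()
        for c, p, s, m in left_sites:
            if s != "+":
                continue
            for rp, rm in rights.get(c, ()):
                end = rp + klen_r
                length = end - p
                if length < lo:
                    continue
                if length > hi:
                    break
                key = (c, p, end)
                slice_ = contigs[c][p:end]
                amp = Amplicon(contig=c, start=p, end=end, strand=strand,
                               sequence=slice_ if strand == "+" else revcomp(slice_),
                               primer_set=primer_set.name, mismatches=m + rm)
                if key not in seen or amp.mismatches < seen[key].mismatches:
                    seen[key] = amp
    return sorted(seen.values(), key=lambda a: (a.contig, a.start, a.end))
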