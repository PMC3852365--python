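"""Seeded ungapped local-alignment search with Karlin-Altschul E-values.

A word-indexed seed-and-extend engine used for copy-number estimation,
consensus building and flank analysis.  Seeds are exact ``word_size``-mers;
each seed diagonal is scored with +match/-mismatch and the optimal local
segment through the seed is taken in closed form from prefix sums, which is
exact for substitution-level homology.  E-values follow the Karlin-Altschul
formula E = K*m*n*exp(-lambda*S) with the published constants for the
+1/-2 scoring pair.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._seq import encode, kmer_hashes, revcomp


@dataclass
class SearchParams:
    word_size: int = 11
    match: int = 1
    mismatch: int = -2
    gap_open: int = -5       # reserved; the default engine is ungapped
    gap_extend: int = -2
    max_evalue: float = 1e-20
    karlin_lambda: float = 1.28
    karlin_k: float = 0.46

    def __post_init__(self):
        if self.word_size < 7:
            raise ValueError("word_size must be >= 7")
        if not (self.match > 0 > self.mismatch):
            raise ValueError("need match > 0 > mismatch")

    def evalue(self, score: int, m: int, n: int) -> float:
        return self.karlin_k * m * n * math.exp(-self.karlin_lambda * score)


@dataclass
class Hit:
    query_start: int
    query_end: int
    contig: str
    subject_start: int
    subject_end: int
    strand: str
    identity: float
    score: int
    evalue: float

    @property
    def length(self) -> int:
        return self.query_end - self.query_start


def _contigs(database) -> dict[str, str]:
    contigs = database.contigs if hasattr(database, "contigs") else database
    if isinstance(contigs, str):
        contigs = {"seq": contigs}
    return contigs


def search(query: str, database, params: SearchParams | None = None) -> list[Hit]:
    """All qualifying local alignments of ``query`` against ``database``.

    Both strands are searched; hit coordinates are on the subject + strand
    and ``query_*`` on the query as given.  Hits are sorted by score
    descending.  Every alignment with >=90% identity over >=100 bp that
    contains an exact word is guaranteed to be reported.
    """
    params = params or SearchParams()
    contigs = _contigs(database)
    k = params.word_size
    if len(query) < k:
        raise ValueError("query shorter than word_size")
    total_n = sum(len(s) for s in contigs.values())
    if total_n == 0:
        return []
    hits: list[Hit] = []
    for strand in ("+", "-"):
        q = query if strand == "+" else revcomp(query)
        qc = encode(q)
        qh, qv = kmer_hashes(qc, k)
        index: dict[int, list[int]] = {}
        for i in np.flatnonzero(qv):
            index.setdefault(int(qh[i]), []).append(int(i))
        q_keys = np.fromiter(index.keys(), dtype=np.int64, count=len(index))
        for cname, cseq in contigs.items():
            sc = encode(cseq)
            sh, sv = kmer_hashes(sc, k)
            if sh.size == 0:
                continue
            cand = np.flatnonzero(np.isin(sh, q_keys) & sv)
            # group seeds per diagonal, keep one representative each
            diag_seen: dict[int, tuple[int, int]] = {}
            for spos in cand:
                for qpos in index[int(sh[spos])]:
                    d = int(spos) - qpos
                    if d not in diag_seen:
                        diag_seen[d] = (qpos, int(spos))
            for d, (qpos, spos) in diag_seen.items():
                hit = _extend_diagonal(qc, sc, d, params, total_n)
                if hit is None:
                    continue
                qs, qe, ss, se, score, ident, ev = hit
                if strand == "-":
                    qs, qe = len(q) - qe, len(q) - qs
                hits.append(Hit(qs, qe, cname, ss, se, strand, ident, score, ev))
    # collapse duplicates (same subject span & strand reached from several diagonals)
    best: dict[tuple, Hit] = {}
    for h in hits:
        key = (h.contig, h.subject_start, h.subject_end, h.strand)
        if key not in best or h.score > best[key].score:
            best[key] = h
    out = sorted(best.values(), key=lambda h: (-h.score, h.contig, h.subject_start))
    return out


def _extend_diagonal(qc: np.ndarray, sc: np.ndarray, d: int, params: SearchParams,
                     total_n: int):
    """Optimal local segment on one diagonal (max-sum subarray, closed form)."""
    q_lo = max(0, -d)
    q_hi = min(qc.size, sc.size - d)
    if q_hi - q_lo < params.word_size:
        return None
    qs = qc[q_lo:q_hi]
    ss = sc[q_lo + d:q_hi + d]
    v = np.where((qs == ss) & (qs < 4), params.match, params.mismatch).astype(np.int64)
    pref = np.concatenate(([0], np.cumsum(v)))
    run_min = np.minimum.accumulate(pref[:-1])
    gains = pref[1:] - run_min
    j = int(np.argmax(gains))
    score = int(gains[j])
    if score <= 0:
        return None
    i = int(np.argmin(pref[:j + 1]))
    length = j + 1 - i
    matches = (score + -params.mismatch * length) // (params.match - params.mismatch)
    ident = matches / length
    ev = params.evalue(score, qc.size, total_n)
    if ev > params.max_evalue:
        return None
    return (q_lo + i, q_lo + j + 1, q_lo + d + i, q_lo + d + j + 1, score, ident, ev)


def collapse_loci(hits: list[Hit]) -> list[Hit]:
    """One best hit per cluster of subject-overlapping hits (locus).

    The representative keeps its own alignment coordinates; the cluster
    extent only controls grouping.
    """
    out: list[Hit] = []
    cur_contig, cur_end = None, -1
    for h in sorted(hits, key=lambda h: (h.contig, h.subject_start)):
        if out and h.contig == cur_contig and h.subject_start < cur_end:
            cur_end = max(cur_end, h.subject_end)
            if h.score > out[-1].score:
                out[-1] = h
        else:
            out.append(h)
            cur_contig, cur_end = h.contig, h.subject_end
    return out


def count_hits(query: str, database, params: SearchParams | None = None) -> int:
    """Number of distinct subject loci with a qualifying hit (copy-number proxy)."""
    return len(collapse_loci(search(query, database, params)))


def tabular(hits: list[Hit], query_name: str = "query") -> str:
    """12-column tabular report (query, subject, %id, len, spans, score, evalue)."""
    lines = []
    for h in hits:
        qs, qe = h.query_start + 1, h.query_end
        if h.strand == "+":
            ss, se = h.subject_start + 1, h.subject_end
        else:
            ss, se = h.subject_end, h.subject_start + 1
        lines.append("\t".join(map(str, (
            query_name, h.contig, f"{100 * h.identity:.2f}", h.length, 0, 0,
            qs, qe, ss, se, f"{h.evalue:.2e}", h.score))))
    return "\n".join(lines) + ("\n" if lines else "")
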