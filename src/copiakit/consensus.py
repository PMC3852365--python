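"""Iterative family-consensus building from an RT seed.

Starting from a family's RT consensus, genomic member loci are collected by
homology search, their windows extended stepwise on both sides, stacked
column-wise (the divergence model is substitution-only, so members align to
the consensus without gaps), and re-summarized as a majority consensus.  A
side is finished when column agreement collapses — member flanks are
unrelated host sequence, so agreement falls from near 1 inside the element
to the random-background level outside; the element edge is taken as the
change point of the agreement profile.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seq import encode, decode, revcomp
from .search import Hit, SearchParams, collapse_loci, search


class InsufficientCopyError(RuntimeError):
    """Fewer members than required to deduce a consensus (low-copy family)."""


@dataclass
class ConsensusState:
    family: str
    consensus: str
    members: list[tuple[str, int, int, str]]   # contig, start, end, strand
    left_done: bool = False
    right_done: bool = False
    round: int = 0
    log: list[dict] = field(default_factory=list)


def seed_consensus(clone_nts: list[str], min_coverage: float = 0.5) -> str:
    """Column-wise majority consensus of clone nucleotide sequences.

    Clones are stacked by an anchored ungapped offset against the longest
    clone; ties go to the alphabetically first base.  Columns covered by
    fewer than ``min_coverage`` of the clones are not reported.
    """
    from .classify import _star_align

    if not clone_nts:
        raise ValueError("no clones")
    if len(clone_nts) == 1:
        return clone_nts[0]
    rows = _star_align(clone_nts)
    arr = np.array([list(r) for r in rows])
    keep = (arr != "-").mean(axis=0) >= min_coverage
    out = []
    for col in arr.T[keep]:
        bases = col[col != "-"]
        vals, counts = np.unique(bases, return_counts=True)
        out.append(sorted(vals[counts == counts.max()])[0])
    return "".join(out)


def _member_window(contig_seq: str, hit: Hit, cons_len: int,
                   left_pad: int, right_pad: int) -> str:
    """Member bases over consensus columns [-left_pad, cons_len + right_pad).

    The hit fixes the offset mapping consensus column -> subject position;
    out-of-contig columns are returned as N.  Minus-strand members are
    reverse-complemented into consensus orientation.
    """
    if hit.strand == "+":
        # subject position of consensus column c: s_start + (c - q_start)
        origin = hit.subject_start - hit.query_start
        lo = origin - left_pad
        hi = origin + cons_len + right_pad
        chunk = contig_seq[max(0, lo):max(0, hi)]
        return "N" * max(0, -lo) + chunk + "N" * max(0, hi - len(contig_seq))
    # minus strand: consensus column c maps leftward on the subject
    origin = hit.subject_end + hit.query_start            # exclusive
    lo = origin - cons_len - right_pad
    hi = origin + left_pad
    chunk = contig_seq[max(0, lo):max(0, hi)]
    padded = "N" * max(0, -lo) + chunk + "N" * max(0, hi - len(contig_seq))
    return revcomp(padded)


def _agreement(rows: list[str]) -> tuple[np.ndarray, str]:
    """Per-column majority consensus and agreement fraction.

    Split columns (two bases with equal top counts) are resolved toward the
    member that agrees best with the provisional consensus overall, so one
    clean member outvotes an equal number of diverged ones.
    """
    arr = np.vstack([encode(r) for r in rows])
    counts = np.zeros((4, arr.shape[1]), dtype=np.int32)
    for b in range(4):
        counts[b] = (arr == b).sum(axis=0)
    cover = counts.sum(axis=0)
    top = counts.max(axis=0)
    maj = counts.argmax(axis=0)
    tied = (counts == top).sum(axis=0) > 1
    if tied.any() and arr.shape[0] > 1:
        quality = (arr == maj).mean(axis=1)           # member identity to draft
        order = np.argsort(-quality)
        for c in np.flatnonzero(tied):
            tied_bases = set(np.flatnonzero(counts[:, c] == top[c]))
            for m in order:
                if arr[m, c] in tied_bases:
                    maj[c] = arr[m, c]
                    break
    agree = np.where(cover > 0, top / np.maximum(cover, 1), 0.0)
    cons = decode(maj.astype(np.uint8))
    return agree, cons


def _boundary(agree: np.ndarray, start: int, direction: int, tau: float,
              window: int = 20) -> int | None:
    """Change point where agreement collapses, scanning from ``start`` outward.

    Coarse stage: first position whose forward-looking window mean drops
    below ``tau``.  Refine stage: within +-window of it, the cut maximizing
    the cumulative (agreement - tau) of the inside part.  Returns the
    boundary as an exclusive column index (direction +1) or inclusive start
    (direction -1); None when agreement never collapses within the array
    (the element edge lies beyond the current extension).
    """
    n = agree.size
    idx = start
    coarse = None
    while 0 <= idx < n:
        if direction > 0:
            seg = agree[idx:idx + window]
        else:
            seg = agree[max(0, idx - window + 1):idx + 1]
        if seg.size < window:
            break
        if seg.mean() < tau:
            coarse = idx
            break
        idx += direction
    if coarse is None:
        return None
    lo = max(0, coarse - window)
    hi = min(n, coarse + window)
    if direction > 0:
        gains = np.concatenate(([0.0], np.cumsum(agree[lo:hi] - tau)))
        return lo + int(np.argmax(gains))
    gains = np.concatenate(([0.0], np.cumsum(agree[lo:hi][::-1] - tau)))
    return hi - int(np.argmax(gains))


def iterative_extend(seed: str, genome, family: str = "",
                     params: SearchParams | None = None,
                     extend_step: int = 500, boundary_agreement: float = 0.6,
                     max_rounds: int = 40, min_members: int = 3) -> ConsensusState:
    """Extend an RT seed to the full element consensus.

    Each round: collect member loci by search, widen member windows by
    ``extend_step`` on unfinished sides, recompute the majority consensus,
    and stop a side at the first agreement collapse (host flanks diverge at
    the element edge).  Members whose alignment drops below the search
    threshold are dropped in later rounds; fewer than ``min_members``
    members raises InsufficientCopyError (the low-copy-family condition).
    """
    params = params or SearchParams()
    contigs = genome.contigs if hasattr(genome, "contigs") else genome
    if isinstance(contigs, str):
        contigs = {"seq": contigs}
    consensus = seed
    left_done = right_done = False
    state_log: list[dict] = []
    members: list[tuple[str, int, int, str]] = []
    for rnd in range(1, max_rounds + 1):
        hits = collapse_loci(search(consensus, contigs, params))
        # LTR-containing consensi hit the member's other LTR too; such
        # partial (and truncated-copy) alignments are dropped as members
        hits = [h for h in hits if h.query_end - h.query_start >= 0.5 * len(consensus)]
        if len(hits) < min_members:
            raise InsufficientCopyError(
                f"{family or 'family'}: only {len(hits)} member loci; "
                f"cannot deduce a consensus (need >= {min_members})")
        left_pad = 0 if left_done else extend_step
        right_pad = 0 if right_done else extend_step
        rows = [_member_window(contigs[h.contig], h, len(consensus), left_pad, right_pad)
                for h in hits]
        agree, cons = _agreement(rows)
        lb = 0 if left_done else None
        rb = agree.size if right_done else None
        if not left_done:
            lb = _boundary(agree, left_pad, -1, boundary_agreement)
            if lb is None:
                lb = 0
            else:
                left_done = True
        if not right_done:
            rb = _boundary(agree, left_pad + len(consensus) - 1, +1, boundary_agreement)
            if rb is None:
                rb = agree.size
            else:
                right_done = True
        consensus = cons[lb:rb]
        members = [(h.contig, h.subject_start, h.subject_end, h.strand) for h in hits]
        state_log.append({"round": rnd, "members": len(hits), "consensus_len": len(consensus),
                          "left_done": left_done, "right_done": right_done})
        if left_done and right_done:
            break
    return ConsensusState(family=family, consensus=consensus, members=members,
                          left_done=left_done, right_done=right_done,
                          round=len(state_log), log=state_log)
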