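"""Structural annotation of full-length copia-type elements.

Given a consensus sequence or a genomic copy (normalized to + orientation),
locate the LTR pair, primer binding site (PBS), polypurine tract (PPT), the
GAG-POL ORF with its domain order, the target site duplication (TSD), and a
restriction map; optionally place the RT core on a reference lineage tree.

Coordinates are 0-based half-open throughout.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seq import encode, translate
from . import motifs

Span = tuple[int, int]

PURINES = frozenset("AG")

RESTRICTION_SITES = {"EcoRI": "GAATTC", "BamHI": "GGATCC"}


class LtrNotFoundError(ValueError):
    """No qualifying pair of terminal direct repeats."""


@dataclass
class AnnotParams:
    """Thresholds for structural annotation (units: bp unless noted)."""

    trna_core: str = motifs.TRNA_CORE
    pbs_window: int = 30          # searched after the 5' LTR
    pbs_max_mismatch: int = 1
    ppt_window: int = 50          # searched before the 3' LTR
    ppt_min_len: int = 9
    ppt_purine_frac: float = 0.8
    min_ltr: int = 100
    min_ltr_identity: float = 0.85
    ltr_anchor: int = 25          # LTR ends must lie this close to the sequence ends
    tsd_range: tuple[int, int] = (4, 6)
    min_gagpol_aa: int = 900      # below this the ORF is flagged degenerate
    rt_core_len: int = motifs.RT_CORE_LEN


@dataclass
class OrfAnnotation:
    span: Span
    aa_len: int
    domains: list[str]
    copia_order: bool
    degenerate: bool
    peptide: str = field(repr=False, default="")


@dataclass
class ElementAnnotation:
    """Structural read-out of one element copy or consensus."""

    ltr5: Span
    ltr3: Span
    ltr_identity: float
    pbs: Span | None = None
    pbs_spacer: int | None = None
    ppt: Span | None = None
    ppt_purine_frac: float | None = None
    orf: OrfAnnotation | None = None
    tsd: str | None = None

    @property
    def total_len(self) -> int:
        return self.ltr3[1] - self.ltr5[0]

    @property
    def ltr_len(self) -> int:
        return self.ltr5[1] - self.ltr5[0]


def detect_ltr_pair(seq: str, params: AnnotParams | None = None) -> tuple[Span, Span, float]:
    """Find the highest-scoring pair of terminal direct repeats.

    One repeat must start within ``ltr_anchor`` bp of the sequence start and
    the other end within ``ltr_anchor`` bp of the sequence end; both repeats
    have the same length (substitution-only model), length >= ``min_ltr`` and
    identity >= ``min_ltr_identity``.  Scoring is +1 per match, -1 per
    mismatch; ties prefer longer repeats, then the smaller start offset.
    """
    params = params or AnnotParams()
    T = len(seq)
    if T < 2 * params.min_ltr + 100:
        raise LtrNotFoundError(f"sequence of {T} bp too short for an LTR pair")
    s = encode(seq)
    anchor = params.ltr_anchor
    min_l = params.min_ltr
    max_l = T // 2 - 10
    a_vec = np.arange(anchor + 1)                 # 5' LTR start offsets
    e_vec = np.arange(T - anchor, T + 1)          # 3' LTR end positions
    best = None  # (score, length, -a, a, D)
    d_lo = max(min_l, T - 2 * anchor - max_l)
    d_hi = T - min_l
    for D in range(d_lo, d_hi + 1):               # D = distance between LTR starts
        m = T - D
        if m < min_l:
            continue
        eq = s[:m] == s[D:]
        pref = np.concatenate(([0], np.cumsum(np.where(eq, 1, -1))))
        lengths = e_vec[None, :] - D - a_vec[:, None]
        ends = a_vec[:, None] + lengths
        valid = (lengths >= min_l) & (lengths <= max_l) & (ends <= m)
        valid &= lengths <= D  # the two repeats must not overlap
        if not valid.any():
            continue
        sc = np.where(valid, pref[np.where(valid, ends, 0)] - pref[a_vec][:, None], -(1 << 30))
        matches = (sc + lengths) // 2
        ident_ok = valid & (matches * 1.0 >= params.min_ltr_identity * lengths)
        if not ident_ok.any():
            continue
        sc = np.where(ident_ok, sc, -(1 << 30))
        flat = np.argmax(sc)
        ai, ei = np.unravel_index(flat, sc.shape)
        cand = (int(sc[ai, ei]), int(lengths[ai, ei]), -int(a_vec[ai]), int(a_vec[ai]), D)
        if best is None or cand > best:
            best = cand
    if best is None:
        raise LtrNotFoundError("no terminal direct repeat pair meets the length/identity thresholds")
    score, length, _, a, D = best
    ident = ((score + length) // 2) / length
    return (a, a + length), (a + D, a + D + length), float(ident)


def detect_pbs(seq: str, ltr5: Span, params: AnnotParams | None = None) -> tuple[Span, int] | None:
    """Locate the tRNA-core complement just downstream of the 5' LTR.

    Returns ``(span, spacer_len)`` where spacer_len is the gap between the
    LTR end and the core start, or None when no placement has at most
    ``pbs_max_mismatch`` substitutions inside ``pbs_window``.
    """
    params = params or AnnotParams()
    core = params.trna_core
    k = len(core)
    start = ltr5[1]
    best: tuple[int, int] | None = None  # (mismatches, offset)
    for off in range(params.pbs_window + 1):
        window = seq[start + off:start + off + k]
        if len(window) < k:
            break
        mm = sum(a != b for a, b in zip(window, core))
        if mm <= params.pbs_max_mismatch and (best is None or mm < best[0]):
            best = (mm, off)
            if mm == 0:
                break
    if best is None:
        return None
    off = best[1]
    return (start + off, start + off + k), off


def detect_ppt(seq: str, ltr3: Span, params: AnnotParams | None = None) -> tuple[Span, float] | None:
    """Best purine-rich window ending within ``ppt_window`` bp of the 3' LTR.

    Ranking: highest purine fraction, then longest, then leftmost; windows
    shorter than ``ppt_min_len`` or below ``ppt_purine_frac`` never qualify.
    """
    params = params or AnnotParams()
    lo = max(0, ltr3[0] - params.ppt_window)
    region = seq[lo:ltr3[0]]
    n = len(region)
    if n < params.ppt_min_len:
        return None
    is_pur = np.array([b in PURINES for b in region])
    cum = np.concatenate(([0], np.cumsum(is_pur)))
    best = None  # (frac, length, -start, start, end)
    for i in range(n - params.ppt_min_len + 1):
        for j in range(i + params.ppt_min_len, n + 1):
            frac = (cum[j] - cum[i]) / (j - i)
            if frac < params.ppt_purine_frac:
                continue
            cand = (frac, j - i, -i, i, j)
            if best is None or cand > best:
                best = cand
    if best is None:
        return None
    frac, _, _, i, j = best
    return (lo + i, lo + j), float(frac)


def find_gag_pol(seq: str, interior: Span, params: AnnotParams | None = None) -> OrfAnnotation:
    """Longest + strand ORF starting inside ``interior``; domain order report.

    The ORF may run past the interior (the printed Jc8 layout has the POL
    tail inside the right LTR).  Domains are located by sentinel peptides;
    ``copia_order`` is True when integrase precedes the RT core.  An ORF
    shorter than ``min_gagpol_aa`` is flagged degenerate, not an error.
    """
    params = params or AnnotParams()
    best: tuple[int, int, int] | None = None  # (aa_len, -start, start)
    n = len(seq)
    for frame in range(3):
        codons = [seq[i:i + 3] for i in range(frame, n - 2, 3)]
        stop_idx = [i for i, c in enumerate(codons) if c in {"TAA", "TAG", "TGA"}]
        bounds = [-1] + stop_idx + [len(codons)]
        for b0, b1 in zip(bounds[:-1], bounds[1:]):
            # stop-free codon run (b0, b1); find first ATG inside the interior
            for ci in range(b0 + 1, b1):
                pos = frame + 3 * ci
                if pos < interior[0]:
                    continue
                if pos >= interior[1]:
                    break
                if codons[ci] == "ATG":
                    aa_len = b1 - ci
                    cand = (aa_len, -pos, pos)
                    if best is None or cand > best:
                        best = cand
                    break
    if best is None:
        return OrfAnnotation((0, 0), 0, [], False, True)
    aa_len, _, start = best
    end = min(start + 3 * aa_len + 3, n)  # includes the stop codon when present
    pep = translate(seq[start:start + 3 * aa_len])
    sentinels = [
        ("GAG", motifs.GAG_SENTINEL),
        ("PR", motifs.PROT_SENTINEL),
        ("INT", motifs.INT_SENTINEL),
        ("RT", motifs.RT_SENTINEL),
        ("RH", motifs.RH_SENTINEL),
    ]
    found = [(pep.find(m), name) for name, m in sentinels if pep.find(m) >= 0]
    domains = [name for _, name in sorted(found)]
    copia_order = "INT" in domains and "RT" in domains and domains.index("INT") < domains.index("RT")
    return OrfAnnotation((start, end), aa_len, domains, copia_order,
                         aa_len < params.min_gagpol_aa, pep)


def detect_tsd(genome_seq: str, span: Span, params: AnnotParams | None = None) -> str | None:
    """Longest exact duplication flanking ``span`` within ``tsd_range``."""
    params = params or AnnotParams()
    lo, hi = params.tsd_range
    start, end = span
    for length in range(hi, lo - 1, -1):
        if start - length < 0 or end + length > len(genome_seq):
            continue
        left = genome_seq[start - length:start]
        if left == genome_seq[end:end + length]:
            return left
    return None


def restriction_map(seq: str, enzymes: dict[str, str] | None = None) -> dict[str, dict]:
    """Exact restriction sites and the fragment lengths they induce.

    Fragment boundaries are placed at site starts; per enzyme, fragment
    lengths always partition ``len(seq)``.
    """
    enzymes = enzymes or RESTRICTION_SITES
    out: dict[str, dict] = {}
    for name, site in enzymes.items():
        sites = []
        pos = seq.find(site)
        while pos >= 0:
            sites.append(pos)
            pos = seq.find(site, pos + 1)
        bounds = [0] + sites + [len(seq)]
        fragments = [b - a for a, b in zip(bounds[:-1], bounds[1:]) if b > a]
        if not fragments:
            fragments = [len(seq)]
        out[name] = {"sites": sites, "fragments": fragments}
    return out


def annotate_element(seq: str, params: AnnotParams | None = None,
                     genome_seq: str | None = None, span: Span | None = None) -> ElementAnnotation:
    """Full structural annotation of one + oriented element sequence.

    ``genome_seq``/``span`` give the genomic context for TSD detection when
    the sequence was extracted from a genome.
    """
    params = params or AnnotParams()
    ltr5, ltr3, ident = detect_ltr_pair(seq, params)
    ann = ElementAnnotation(ltr5=ltr5, ltr3=ltr3, ltr_identity=ident)
    pbs = detect_pbs(seq, ltr5, params)
    if pbs is not None:
        ann.pbs, ann.pbs_spacer = pbs
    ppt = detect_ppt(seq, ltr3, params)
    if ppt is not None:
        ann.ppt, ann.ppt_purine_frac = ppt
    ann.orf = find_gag_pol(seq, (ltr5[1], ltr3[0]), params)
    if genome_seq is not None and span is not None:
        ann.tsd = detect_tsd(genome_seq, span, params)
    return ann


def rt_core_peptide(orf: OrfAnnotation, params: AnnotParams | None = None) -> str | None:
    """The ~220-aa conserved RT region of a GAG-POL peptide, anchored on TAFLHG."""
    params = params or AnnotParams()
    pos = orf.peptide.find("TAFLHG")
    if pos < 0:
        return None
    return orf.peptide[pos:pos + params.rt_core_len]


def assign_lineage(rt_core: str, references: dict[str, tuple[str, str]],
                   outgroup: str, bootstrap_n: int = 100,
                   seed: int = 0, min_support: int = 50) -> tuple[str, int]:
    """Place an RT core peptide on a reference tree and report its lineage.

    ``references`` maps reference label -> (lineage, peptide).  For each
    bootstrap replicate an NJ tree of query + references + outgroup is built
    from resampled alignment columns; the replicate votes for a lineage when
    the smallest query-containing clade (rooted at the outgroup) holds
    references of exactly one lineage.  Returns ``(lineage, support)`` with
    lineage "unassigned" below ``min_support`` (out of 100).
    """
    from .classify import neighbor_joining, p_distance_matrix, _star_align

    labels = ["query"] + list(references) + ["outgroup"]
    peps = [rt_core] + [p for _, p in references.values()] + [outgroup]
    rows = _star_align(peps)
    width = len(rows[0])
    rng = np.random.default_rng(seed)
    votes: dict[str, int] = {}
    ref_idx = {label: i + 1 for i, label in enumerate(references)}
    for _ in range(bootstrap_n):
        cols = rng.integers(0, width, size=width)
        sampled = ["".join(r[c] for c in cols) for r in rows]
        dm = p_distance_matrix(sampled)
        tree = neighbor_joining(dm, labels)
        lin = _query_lineage(tree, references)
        if lin is None:
            continue
        # saturated queries sit anywhere by noise: only vote when the query
        # is meaningfully closer to its clade than to the outgroup
        nearest = min(dm[0, ref_idx[r]] for r, (l, _) in references.items() if l == lin)
        if nearest < 0.9 * dm[0, len(labels) - 1]:
            votes[lin] = votes.get(lin, 0) + 1
    if not votes:
        return "unassigned", 0
    lineage, count = max(votes.items(), key=lambda kv: kv[1])
    support = round(100 * count / bootstrap_n)
    if support < min_support:
        return "unassigned", support
    return lineage, support


def _query_lineage(tree, references: dict[str, tuple[str, str]]) -> str | None:
    """Lineage of the smallest clade containing the query, outgroup-rooted."""
    rooted = tree.rooted_at("outgroup")
    node = rooted.find("query")
    while node is not None:
        tips = set(node.tip_names())
        refs = tips & set(references)
        if refs:
            lineages = {references[r][0] for r in refs}
            if len(lineages) == 1 and "outgroup" not in tips:
                return lineages.pop()
            return None
        node = node.parent
    return None
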