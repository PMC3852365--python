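"""Ground-truth genome simulator for copia-type LTR retrotransposon studies.

Builds full-length family template elements from structural parameters
(total length, LTR length, GAG-POL size, printed PBS/PPT strings), implants
diverged copies with target site duplications into a random background
genome, plants genes in flanking regions at a per-family rate, and derives
accession panels that share or lack individual insertions (the pre-insertion
"empty site" allele keeps exactly one copy of the TSD motif).

The background is i.i.d. uniform A/C/G/T and divergence is substitution-only
by default, which keeps every truth coordinate exact.  All randomness flows
through explicit seeds; the same seed reproduces byte-identical genomes.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._seq import encode, decode, revcomp, random_dna, random_codons, translate, STOP_CODONS
from . import motifs
from .annotate import ElementAnnotation, OrfAnnotation

GEOMETRY_SLACK = 300  # bp by which GAG-POL may run into the 3' LTR (untranslated leader/trailer)


class GeometryError(ValueError):
    """Family parameters cannot be realized as an element layout."""


class PlacementError(RuntimeError):
    """Could not place a feature without overlap after bounded retries."""


def _mismatches(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


@dataclass(frozen=True)
class FamilySpec:
    """Structural parameters of one retrotransposon family.

    ``pbs``/``ppt`` follow the printed convention: lower-case letters are
    spacer or variable positions, upper-case the conserved core.
    """

    name: str
    lineage: str
    total_len: int
    ltr_len: int
    gagpol_len: int          # amino acids, stop excluded
    pbs: str
    ppt: str
    target_copies: int = 10
    flank_gene_prob: float = 0.5

    def __post_init__(self):
        if self.total_len <= 2 * self.ltr_len:
            raise GeometryError(
                f"{self.name}: total_len ({self.total_len}) must exceed "
                f"2*ltr_len ({2 * self.ltr_len}); no internal region")
        if 3 * self.gagpol_len + 2 * self.ltr_len > self.total_len + GEOMETRY_SLACK:
            raise GeometryError(
                f"{self.name}: 3*gagpol_len + 2*ltr_len = "
                f"{3 * self.gagpol_len + 2 * self.ltr_len} exceeds total_len + "
                f"{GEOMETRY_SLACK} = {self.total_len + GEOMETRY_SLACK}")
        core = motifs.TRNA_CORE
        up = self.pbs.upper()
        if not any(_mismatches(up[i:i + len(core)], core) <= 1
                   for i in range(max(1, len(up) - len(core) + 1))):
            raise ValueError(f"{self.name}: pbs {self.pbs!r} lacks the tRNA core {core}")
        if not 0.0 <= self.flank_gene_prob <= 1.0:
            raise ValueError("flank_gene_prob must be a probability")

    @property
    def pbs_spacer(self) -> int:
        """Leading lower-case (spacer) length of the printed PBS string."""
        n = 0
        for ch in self.pbs:
            if ch.islower():
                n += 1
            else:
                break
        return n


@dataclass
class ElementCopy:
    family: str
    contig: str
    start: int
    end: int
    strand: str
    tsd: str
    pct_divergence: float = 0.0
    truncated_5p: int = 0
    truncated_3p: int = 0
    ltr_identical: bool = True


@dataclass
class Gene:
    contig: str
    start: int
    end: int
    strand: str
    id: str


@dataclass
class AnnotatedGenome:
    contigs: dict[str, str]
    elements: list[ElementCopy] = field(default_factory=list)
    genes: list[Gene] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def element_seq(self, idx: int) -> str:
        """Sequence of element ``idx`` normalized to + orientation."""
        el = self.elements[idx]
        s = self.contigs[el.contig][el.start:el.end]
        return s if el.strand == "+" else revcomp(s)


@dataclass
class FamilyTemplate:
    spec: FamilySpec
    sequence: str
    annotation: ElementAnnotation


@dataclass
class AccessionPanel:
    accessions: dict[str, AnnotatedGenome]
    insertion_presence: "object"  # pandas DataFrame, accession x locus -> bool


def random_genome(size: int, seed: int, n_contigs: int = 1, prefix: str = "contig") -> AnnotatedGenome:
    """Uniform-composition background genome with no features."""
    rng = np.random.default_rng(seed)
    per = size // n_contigs
    contigs = {f"{prefix}{i + 1}": random_dna(per, rng) for i in range(n_contigs)}
    return AnnotatedGenome(contigs=contigs, provenance={"background_size": size, "seed": seed})


# ---------------------------------------------------------------------------
# template construction


def _write_codons(codons: list[str], at: int, block: str) -> None:
    for i in range(len(block) // 3):
        codons[at + i] = block[3 * i:3 * (i + 1)]


def _build_orf_codons(spec: FamilySpec, rng: np.random.Generator,
                      rt_ancestor: list[str] | None, rt_keep: float) -> list[str]:
    aa = spec.gagpol_len
    codons = random_codons(aa, rng)
    codons[0] = "ATG"
    if rt_ancestor is not None:
        for k in range(motifs.RT_CORE_LEN):
            ci = motifs.RT_CORE_AT + k
            if ci in motifs.RT_FIXED_CODONS:
                continue
            if rng.random() < rt_keep:
                codons[ci] = rt_ancestor[k]
    _write_codons(codons, motifs.GAG_AT, motifs.GAG_CODONS)
    _write_codons(codons, motifs.PROT_AT, motifs.PROT_CODONS)
    _write_codons(codons, motifs.INT_AT, motifs.INT_CODONS)
    _write_codons(codons, motifs.RT_CORE_AT, motifs.RT_F_SITE)
    _write_codons(codons, motifs.RT_V_AT, motifs.RT_V_SITE)
    _write_codons(codons, motifs.RT_YVDD_AT, motifs.RT_YVDD_SITE)
    _write_codons(codons, motifs.RH_AT, motifs.RH_CODONS)
    return codons


def build_family_template(spec: FamilySpec, seed: int,
                          rt_ancestor: list[str] | None = None,
                          rt_keep: float = 0.5) -> FamilyTemplate:
    """Construct the canonical element sequence of a family plus its truth.

    Layout (5'->3'): LTR | PBS | leader | GAG-POL ORF | trailer | PPT | LTR,
    with identical LTR copies.  When the ORF cannot fit before the PPT it is
    allowed to run over the PPT and into the 3' LTR (within the geometry
    slack); the PPT is then embedded in purine codons and the 5' LTR is
    synced to the final 3' LTR bytes so the pair stays identical.

    ``rt_ancestor`` (220 codons) seeds the RT core so families built from
    the same ancestor form a lineage; each non-anchor core codon is kept
    with probability ``rt_keep``.
    """
    if spec.gagpol_len < motifs.MIN_GAGPOL_AA:
        raise GeometryError(f"{spec.name}: gagpol_len {spec.gagpol_len} < "
                            f"{motifs.MIN_GAGPOL_AA} cannot hold the domain layout")
    rng = np.random.default_rng(seed)
    L, T = spec.ltr_len, spec.total_len
    pbs, ppt = spec.pbs.upper(), spec.ppt.upper()
    p, r = len(pbs), len(ppt)
    orf_nt = 3 * spec.gagpol_len + 3
    pad = (T - L - r) - (L + p) - orf_nt
    if pad >= 3:
        leader = max(3, pad // 3)
    else:
        leader = max(0, pad)
    orf_start = L + p + leader
    orf_end = orf_start + orf_nt
    if orf_end > T:
        raise GeometryError(
            f"{spec.name}: ltr_len + len(pbs) + 3*gagpol_len + 3 = {orf_end} "
            f"exceeds total_len = {T}; the ORF cannot fit")

    body = bytearray(random_dna(T, rng), "ascii")

    def put(pos: int, s: str) -> None:
        body[pos:pos + len(s)] = s.encode("ascii")

    ltr = "TG" + random_dna(L - 4, rng) + "CA"
    put(0, ltr)
    put(T - L, ltr)
    put(L, pbs)
    if leader >= 3:
        put(orf_start - 3, "TAA")       # blocks upstream in-frame ORF extension
    elif leader:
        put(L + p, "C" * leader)
    orf_seq = "".join(_build_orf_codons(spec, rng, rt_ancestor, rt_keep)) + "TAA"
    put(orf_start, orf_seq)
    ppt_start = T - L - r
    put(ppt_start, ppt)
    # pyrimidine guards so the placed PPT is the only qualifying purine window
    for pos in range(ppt_start - 3, ppt_start):
        body[pos:pos + 1] = b"C"
    for pos in range(max(orf_start, ppt_start - 58), ppt_start - 3):
        if (pos - ppt_start) % 4 == 0 and not orf_end - 3 <= pos < orf_end:
            body[pos:pos + 1] = b"C"
    if ppt_start < orf_end:
        _fix_stops(body, orf_start, orf_end, (ppt_start, T - L))
    body[0:L] = body[T - L:T]           # sync the pair if the ORF tail ran in
    seq = body.decode("ascii")

    orf_pep = translate(seq[orf_start:orf_start + 3 * spec.gagpol_len])
    assert "*" not in orf_pep and len(seq) == T
    spacer = spec.pbs_spacer
    core_len = len(motifs.TRNA_CORE)
    truth = ElementAnnotation(
        ltr5=(0, L), ltr3=(T - L, T), ltr_identity=1.0,
        pbs=(L + spacer, L + spacer + core_len), pbs_spacer=spacer,
        ppt=(ppt_start, T - L), ppt_purine_frac=None,
        orf=OrfAnnotation((orf_start, orf_end), spec.gagpol_len,
                          ["GAG", "PR", "INT", "RT", "RH"], True, False, orf_pep),
    )
    return FamilyTemplate(spec=spec, sequence=seq, annotation=truth)


def _fix_stops(body: bytearray, orf_start: int, orf_end: int, window: tuple[int, int]) -> None:
    """Repair stop codons created by embedding a fixed string inside the ORF.

    Any codon overlapping ``window`` that became a stop gets one of its
    outside-window bases set to C (no stop codon contains C).
    """
    first = orf_start + 3 * ((window[0] - orf_start) // 3)
    for cpos in range(max(orf_start, first - 3), min(orf_end - 3, window[1] + 3), 3):
        codon = body[cpos:cpos + 3].decode("ascii")
        if codon in STOP_CODONS:
            for k in range(3):
                if not (window[0] <= cpos + k < window[1]):
                    body[cpos + k:cpos + k + 1] = b"C"
                    break
            else:  # pragma: no cover - purine windows cannot spell a stop
                raise AssertionError("stop codon fully inside purine window")


# ---------------------------------------------------------------------------
# implantation


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = encode(seq)
    mask = rng.random(arr.size) < rate
    shift = rng.integers(1, 4, size=int(mask.sum()), dtype=np.uint8)
    arr = arr.copy()
    arr[mask] = (arr[mask] + shift) % 4
    return decode(arr)


def _shift_features(genome: AnnotatedGenome, contig: str, at: int, by: int) -> None:
    for el in genome.elements:
        if el.contig == contig and el.start >= at:
            el.start += by
            el.end += by
    for g in genome.genes:
        if g.contig == contig and g.start >= at:
            g.start += by
            g.end += by


def _too_close(genome: AnnotatedGenome, contig: str, pos: int, gap: int) -> bool:
    for el in genome.elements:
        if el.contig == contig and el.start - gap < pos < el.end + gap:
            return True
    for g in genome.genes:
        if g.contig == contig and g.start - gap < pos < g.end + gap:
            return True
    return False


def implant_copies(genome: AnnotatedGenome, template: FamilyTemplate, n: int,
                   divergence: float = 0.0, tsd_len_range: tuple[int, int] = (4, 6),
                   truncation_prob: float = 0.0, seed: int = 0,
                   min_gap: int = 200, max_tries: int = 1000) -> AnnotatedGenome:
    """Insert ``n`` diverged copies of a family template with TSDs.

    Each copy receives i.i.d. substitutions at ``divergence`` (the two LTRs
    mutate independently), a TSD of uniform length within ``tsd_len_range``
    duplicated from the host sequence at the insertion point, and optional
    5'/3' truncation.  Existing features shift right as insertions accrue;
    truth records are appended in place.
    """
    if not 0.0 <= divergence <= 0.3:
        raise ValueError("divergence must lie in [0, 0.3]")
    rng = np.random.default_rng(seed)
    spec = template.spec
    L, T = spec.ltr_len, spec.total_len
    names = list(genome.contigs)
    weights = np.array([len(genome.contigs[c]) for c in names], dtype=float)
    weights /= weights.sum()
    for _ in range(n):
        seq = template.sequence
        trunc5 = trunc3 = 0
        if truncation_prob and rng.random() < truncation_prob:
            amount = int(rng.integers(50, max(51, T // 3)))
            if rng.random() < 0.5:
                trunc5 = amount
                seq = seq[amount:]
            else:
                trunc3 = amount
                seq = seq[:len(seq) - amount]
        seq = _mutate(seq, divergence, rng)
        if trunc5 or trunc3:
            ltr_identical = False
        else:
            ltr_identical = seq[:L] == seq[T - L:]
        placed = False
        for _try in range(max_tries):
            contig = names[rng.choice(len(names), p=weights)]
            cs = genome.contigs[contig]
            tsd_len = int(rng.integers(tsd_len_range[0], tsd_len_range[1] + 1))
            if len(cs) <= tsd_len + 2 * min_gap:
                continue
            pos = int(rng.integers(min_gap, len(cs) - tsd_len - min_gap))
            if _too_close(genome, contig, pos, min_gap):
                continue
            tsd = cs[pos:pos + tsd_len]
            strand = "+" if rng.random() < 0.5 else "-"
            ins = seq if strand == "+" else revcomp(seq)
            genome.contigs[contig] = cs[:pos + tsd_len] + ins + cs[pos:pos + tsd_len] + cs[pos + tsd_len:]
            _shift_features(genome, contig, pos + tsd_len, len(ins) + tsd_len)
            genome.elements.append(ElementCopy(
                family=spec.name, contig=contig, start=pos + tsd_len,
                end=pos + tsd_len + len(ins), strand=strand, tsd=tsd,
                pct_divergence=divergence, truncated_5p=trunc5, truncated_3p=trunc3,
                ltr_identical=ltr_identical))
            placed = True
            break
        if not placed:
            raise PlacementError(f"could not place copy of {spec.name} after {max_tries} tries")
    genome.provenance.setdefault("implants", []).append(
        {"family": spec.name, "n": n, "divergence": divergence, "seed": seed})
    return genome


def plant_genes(genome: AnnotatedGenome, probs: dict[str, float],
                seed: int = 0, gene_len_range: tuple[int, int] = (500, 2000),
                window: int = 5000, exclusion: int = 6000,
                max_tries: int = 500) -> AnnotatedGenome:
    """Plant gene intervals next to element copies at per-family rates.

    With probability ``probs[family]`` a copy gets a gene whose nearest edge
    is uniform in [0, ``window``); copies drawn gene-free end up with no
    gene within ``exclusion`` bp (genes placed for other copies must keep
    that distance too).
    """
    rng = np.random.default_rng(seed)
    draws = [rng.random() < probs.get(el.family, 0.5) for el in genome.elements]
    gene_free = [el for el, d in zip(genome.elements, draws) if not d]

    def clear_of_gene_free(contig: str, lo: int, hi: int) -> bool:
        return not any(el.contig == contig and el.start - exclusion < hi and lo < el.end + exclusion
                       for el in gene_free)

    def overlaps(contig: str, lo: int, hi: int) -> bool:
        return any(f.contig == contig and f.start < hi and lo < f.end
                   for f in (*genome.elements, *genome.genes))

    gid = len(genome.genes)
    for el, draw in zip(list(genome.elements), draws):
        if not draw:
            continue
        cs = genome.contigs[el.contig]
        for _try in range(max_tries):
            dist = int(rng.integers(0, window))
            glen = int(rng.integers(gene_len_range[0], gene_len_range[1] + 1))
            if rng.random() < 0.5:
                lo, hi = el.start - dist - glen, el.start - dist
            else:
                lo, hi = el.end + dist, el.end + dist + glen
            if lo < 0 or hi > len(cs):
                continue
            if overlaps(el.contig, lo, hi):
                continue
            if not clear_of_gene_free(el.contig, lo, hi):
                continue
            gid += 1
            genome.genes.append(Gene(el.contig, lo, hi, "+" if rng.random() < 0.5 else "-",
                                     f"gene{gid}"))
            break
        else:
            raise PlacementError(f"could not place a flanking gene near {el.family} copy")
    genome.provenance["gene_probs"] = dict(probs)
    return genome


# ---------------------------------------------------------------------------
# accession panels


def simulate_accessions(reference: AnnotatedGenome, presence,
                        background_snp_rate: float = 0.0, seed: int = 0) -> AccessionPanel:
    """Derive accession genomes sharing or lacking individual insertions.

    ``presence`` is a pandas DataFrame (accession x element-index -> bool).
    Absent cells carry the pre-insertion allele: the element plus one TSD
    copy is excised, leaving a single TSD motif at the empty site.
    """
    import pandas as pd

    presence = pd.DataFrame(presence)
    n_el = len(reference.elements)
    for locus in presence.columns:
        if not (isinstance(locus, (int, np.integer)) and 0 <= locus < n_el):
            raise LookupError(f"locus {locus!r} is not an element index of the reference")
    rng = np.random.default_rng(seed)
    accessions: dict[str, AnnotatedGenome] = {}
    for acc in presence.index:
        contigs = dict(reference.contigs)
        elements = [replace(el) for el in reference.elements]
        genes = [replace(g) for g in reference.genes]
        absent = sorted((int(l) for l in presence.columns if not presence.loc[acc, l]),
                        key=lambda i: reference.elements[i].start, reverse=True)
        dropped = set(absent)
        for idx in absent:
            el = reference.elements[idx]
            cut_lo, cut_hi = el.start, el.end + len(el.tsd)
            cs = contigs[el.contig]
            contigs[el.contig] = cs[:cut_lo] + cs[cut_hi:]
            shift = cut_hi - cut_lo
            for other in elements:
                if other.contig == el.contig and other.start >= cut_hi:
                    other.start -= shift
                    other.end -= shift
            genes = [g for g in genes if not (g.contig == el.contig and g.start < cut_hi and g.end > cut_lo)]
            for g in genes:
                if g.contig == el.contig and g.start >= cut_hi:
                    g.start -= shift
                    g.end -= shift
        elements = [e for i, e in enumerate(elements) if i not in dropped]
        if background_snp_rate > 0:
            contigs = {k: _mutate(v, background_snp_rate, rng) for k, v in contigs.items()}
        accessions[str(acc)] = AnnotatedGenome(
            contigs=contigs, elements=elements, genes=genes,
            provenance={"derived_from": "reference", "accession": str(acc),
                        "background_snp_rate": background_snp_rate, "seed": seed})
    return AccessionPanel(accessions=accessions, insertion_presence=presence)
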