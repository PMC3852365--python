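"""Retrotransposon-based insertion polymorphism (RBIP) marker design and
in-silico genotyping.

An RBIP assay scores one insertion locus with three primer pairs: left
flank x left LTR and right LTR x right flank amplify only the occupied
allele (each junction product spans the element edge and the TSD), while
flank x flank amplifies only the pre-insertion empty allele (in the
occupied genome the flank-to-flank distance exceeds the PCR product range).
Calls are haploid: occupied needs both junction products and no empty
product; empty needs the flank product only; anything else is ambiguous
(both product classes present is reported as "both").
"""
from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from ._seq import revcomp
from .annotate import AnnotParams, ElementAnnotation, detect_tsd
from .pcr import PrimerSet, amplify
from .search import SearchParams
from .synthetic import AccessionPanel, AnnotatedGenome


class NoMarkerError(RuntimeError):
    """No unique primer placement exists for the locus (repetitive flank)."""


@dataclass
class RbipMarker:
    locus: str
    family: str
    contig: str
    element_span: tuple[int, int]
    tsd: str
    flkl: str
    flkr: str
    ltrl: str
    ltrr: str
    occupied_left: int     # expected product sizes, bp
    occupied_right: int
    empty: int

    def primer_sets(self, max_product: int = 1500) -> dict[str, PrimerSet]:
        return {
            "occupied_left": PrimerSet("FLKLxLTRL", self.flkl, self.ltrl, 0, (50, max_product)),
            "occupied_right": PrimerSet("LTRRxFLKR", self.ltrr, self.flkr, 0, (50, max_product)),
            "empty": PrimerSet("FLKLxFLKR", self.flkl, self.flkr, 0, (50, max_product)),
        }


@dataclass
class GenotypeCall:
    accession: str
    locus: str
    call: str                       # occupied / empty / ambiguous / both
    products: dict[str, list[int]] = field(default_factory=dict)


def find_recent_insertions(genome: AnnotatedGenome,
                           annotations: dict[int, ElementAnnotation] | None = None,
                           params: AnnotParams | None = None) -> list[int]:
    """Indices of candidate marker copies: identical LTRs, full length, TSD.

    When per-copy annotations are given, LTR identity comes from them;
    otherwise the simulator's truth flags are used.  The TSD must be
    detectable in the genome in either case.
    """
    params = params or AnnotParams()
    out = []
    for idx, el in enumerate(genome.elements):
        if el.truncated_5p or el.truncated_3p:
            continue
        if annotations is not None and idx in annotations:
            if annotations[idx].ltr_identity < 1.0:
                continue
        elif not el.ltr_identical:
            continue
        if detect_tsd(genome.contigs[el.contig], (el.start, el.end), params) is None:
            continue
        out.append(idx)
    return out


def _unique_in_genome(primer: str, genome: AnnotatedGenome) -> bool:
    total = 0
    for seq in genome.contigs.values():
        total += seq.count(primer) + seq.count(revcomp(primer))
        if total > 1:
            return False
    return total == 1


def design_marker(genome: AnnotatedGenome, copy_index: int,
                  primer_len: int = 20, product_range: tuple[int, int] = (100, 400),
                  ltr_depth: int = 60, min_flank: int = 300,
                  search_params: SearchParams | None = None,
                  max_shift: int = 60) -> RbipMarker:
    """Design the three-primer RBIP assay for one recent insertion.

    Junction primers sit ``ltr_depth`` bp inside each LTR end; flank primers
    are placed as far from the TSD as the product-length bound allows and
    shifted inward until every primer is unique genome-wide.  Repetitive
    flanks (copy-number class above "low") are rejected.
    """
    el = genome.elements[copy_index]
    seq = genome.contigs[el.contig]
    tsd = detect_tsd(seq, (el.start, el.end)) or el.tsd
    if el.start < min_flank or el.end + min_flank > len(seq):
        raise NoMarkerError("insufficient flanking sequence")
    from .context import classify_flank_copy_number

    for side in ("5p", "3p"):
        res = classify_flank_copy_number(genome, el, side, search_params=search_params)
        if res is None or res[1] != "low":
            raise NoMarkerError(f"{side} flank is repetitive (bin {res and res[1]}); "
                                "marker design needs single-copy flanks")
    ltrl = revcomp(seq[el.start + ltr_depth - primer_len:el.start + ltr_depth])
    ltrr = seq[el.end - ltr_depth:el.end - ltr_depth + primer_len]
    lo, hi = product_range

    flkl = flkl_start = None
    for shift in range(0, max_shift, 5):
        start = el.start + ltr_depth - hi + shift
        cand = seq[start:start + primer_len]
        if _unique_in_genome(cand, genome):
            flkl, flkl_start = cand, start
            break
    flkr = flkr_end = None
    for shift in range(0, max_shift, 5):
        end = el.end - ltr_depth + hi - shift
        cand = revcomp(seq[end - primer_len:end])
        if _unique_in_genome(cand, genome):
            flkr, flkr_end = cand, end
            break
    if flkl is None or flkr is None:
        raise NoMarkerError("no unique flank primer placement")
    occupied_left = el.start + ltr_depth - flkl_start
    occupied_right = flkr_end - (el.end - ltr_depth)
    if occupied_left < lo or occupied_right < lo:
        raise NoMarkerError("junction products fall below the product range")
    empty = (flkr_end - flkl_start) - (el.end - el.start) - len(tsd)
    return RbipMarker(locus=f"{el.family}-{copy_index}", family=el.family,
                      contig=el.contig, element_span=(el.start, el.end), tsd=tsd,
                      flkl=flkl, flkr=flkr, ltrl=ltrl, ltrr=ltrr,
                      occupied_left=occupied_left, occupied_right=occupied_right,
                      empty=empty)


def genotype(panel: AccessionPanel, marker: RbipMarker,
             max_product: int = 1500) -> pd.DataFrame:
    """Genotype every accession of a panel at one RBIP marker locus.

    Returns a DataFrame indexed by accession with the call and the product
    sizes seen per primer set.
    """
    sets = marker.primer_sets(max_product)
    calls: list[GenotypeCall] = []
    for acc, genome in panel.accessions.items():
        products = {name: [len(a) for a in amplify(genome, ps)]
                    for name, ps in sets.items()}
        occ = bool(products["occupied_left"]) and bool(products["occupied_right"])
        emp = bool(products["empty"])
        if occ and not emp:
            call = "occupied"
        elif emp and not occ and not products["occupied_left"] and not products["occupied_right"]:
            call = "empty"
        elif occ and emp:
            call = "both"
        else:
            call = "ambiguous"
        calls.append(GenotypeCall(acc, marker.locus, call, products))
    return pd.DataFrame([{"accession": c.accession, "locus": c.locus, "call": c.call,
                          **{f"n_{k}": len(v) for k, v in c.products.items()}}
                         for c in calls]).set_index("accession")
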