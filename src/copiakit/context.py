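"""Genomic neighborhood profiling of element copies.

For each copy, the 500 bp flank on each side is searched against the whole
genome to class its copy number (low 1-10, moderate 11-100, high >100; the
flank's self-hit counts, so the count is at least 1), and gene presence is
scored within a 5 kb window.  Both flanks of a copy are profiled as separate
flank observations.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .search import SearchParams, count_hits
from .synthetic import AnnotatedGenome, ElementCopy

BINS = (("low", 1, 10), ("moderate", 11, 100), ("high", 101, None))


@dataclass
class ContextParams:
    flank_len: int = 500
    gene_window: int = 5000
    min_flanks_per_family: int = 20
    marker_gene_frac: float = 0.6


@dataclass
class ContextProfile:
    copy_index: int
    family: str
    side: str                    # "5p" or "3p"
    flank_hit_count: int | None
    bin: str | None
    gene_within_window: bool
    nearest_gene_distance: float


def bin_label(count: int) -> str:
    for name, lo, hi in BINS:
        if count >= lo and (hi is None or count <= hi):
            return name
    raise ValueError(f"count {count} outside all bins")


def classify_flank_copy_number(genome: AnnotatedGenome, copy: ElementCopy, side: str,
                               params: ContextParams | None = None,
                               search_params: SearchParams | None = None) -> tuple[int, str] | None:
    """Hit-locus count of one 500 bp flank against the whole genome, binned.

    Returns None (with a warning) when the flank is truncated by the contig
    edge.
    """
    params = params or ContextParams()
    seq = genome.contigs[copy.contig]
    if side == "5p":
        lo, hi = copy.start - params.flank_len, copy.start
    elif side == "3p":
        lo, hi = copy.end, copy.end + params.flank_len
    else:
        raise ValueError("side must be '5p' or '3p'")
    if lo < 0 or hi > len(seq):
        warnings.warn(f"{copy.family} copy flank {side} truncated by contig edge; skipped")
        return None
    count = count_hits(seq[lo:hi], genome, search_params)
    return count, bin_label(count)


def gene_in_flank(copy: ElementCopy, genes, params: ContextParams | None = None) -> tuple[bool, float]:
    """Whether any gene lies within ``gene_window`` of the copy, plus distance.

    Distance is edge-to-edge (0 when overlapping); presence requires
    distance strictly below the window.
    """
    params = params or ContextParams()
    best = float("inf")
    for g in genes:
        if g.contig != copy.contig:
            continue
        gap = max(0, g.start - copy.end, copy.start - g.end)
        best = min(best, gap)
    return best < params.gene_window, best


def profile_copies(genome: AnnotatedGenome, params: ContextParams | None = None,
                   search_params: SearchParams | None = None) -> list[ContextProfile]:
    """Per-flank context profiles for every element copy."""
    params = params or ContextParams()
    out = []
    for idx, copy in enumerate(genome.elements):
        has_gene, dist = gene_in_flank(copy, genome.genes, params)
        for side in ("5p", "3p"):
            res = classify_flank_copy_number(genome, copy, side, params, search_params)
            count, label = res if res is not None else (None, None)
            out.append(ContextProfile(idx, copy.family, side, count, label, has_gene, dist))
    return out


def family_context_report(profiles: list[ContextProfile],
                          params: ContextParams | None = None) -> pd.DataFrame:
    """Per-family flank copy-number fractions and gene proximity.

    Families with fewer than ``min_flanks_per_family`` flank observations
    are excluded with a warning; a family is flagged as a marker candidate
    when more than ``marker_gene_frac`` of its flanks have a gene within
    the window.
    """
    params = params or ContextParams()
    rows = []
    df = pd.DataFrame([vars(p) for p in profiles])
    if df.empty:
        return pd.DataFrame(columns=["family", "n_flanks", "frac_low", "frac_moderate",
                                     "frac_high", "frac_gene_5kb", "marker_candidate"])
    for family, grp in df.groupby("family", sort=True):
        grp = grp[grp["bin"].notna()]
        n = len(grp)
        if n < params.min_flanks_per_family:
            warnings.warn(f"{family}: only {n} flanks (< {params.min_flanks_per_family}); "
                          "excluded from the report")
            continue
        frac_gene = grp["gene_within_window"].mean()
        rows.append({
            "family": family,
            "n_flanks": n,
            "frac_low": (grp["bin"] == "low").mean(),
            "frac_moderate": (grp["bin"] == "moderate").mean(),
            "frac_high": (grp["bin"] == "high").mean(),
            "frac_gene_5kb": frac_gene,
            "marker_candidate": bool(frac_gene > params.marker_gene_frac),
        })
    return pd.DataFrame(rows)
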