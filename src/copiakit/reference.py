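"""Reference inputs: family structural table, degenerate RT primers, RBIP fixtures.

The nine-family structural table (lineage, total length, LTR length, GAG-POL
size, PBS, PPT) and the F/V/H degenerate reverse-transcriptase primer sets
are the literature-reported inputs this pipeline consumes.  Per-family copy
numbers were not reported directly; ``target_copies`` carries the reported
homology-search hit counts as proxies where available and mid-range
placeholders elsewhere.
``flank_gene_prob`` encodes the reported gene-rich (>60%) and gene-poor
(<40%) flanking classes.
"""
from __future__ import annotations

import numpy as np

from ._seq import random_codons, translate
from . import motifs
from .pcr import PrimerSet
from .synthetic import FamilySpec, FamilyTemplate, build_family_template

FAMILY_TABLE: list[FamilySpec] = [
    FamilySpec("Jc1", "I", 5398, 510, 1339, "agTGGTATCAGAGCC", "AGGGGGAGAtt", 161, 0.65),
    FamilySpec("Jc2", "I", 5493, 697, 1326, "acTGGTATCAGAGCC", "GGGAGGGGGAGAAt", 60, 0.65),
    FamilySpec("Jc3", "I", 5387, 523, 1314, "agTGGTATCAGAGCC", "AGGGGGAGAtt", 45, 0.65),
    FamilySpec("Jc4", "I", 5254, 440, 1299, "acTGGTATCAGAGCC", "AAGtGGGAGAt", 30, 0.5),
    FamilySpec("Jc5", "II", 6217, 474, 1370, "tgTGGTATCAGAGCC", "AAGTGGGAGAt", 166, 0.35),
    FamilySpec("Jc6", "II", 7712, 959, 1428, "atTGGTATCAGAGCC", "AAGtAGAGAAtGGA", 90, 0.5),
    FamilySpec("Jc7", "II", 6652, 447, 1358, "agTGGTATCAGAGCC", "AAGtGGGAGAt", 55, 0.65),
    FamilySpec("Jc8", "III", 4984, 210, 1528, "TGGTATCAGAGCt", "GAGGGGGAG", 7, 0.5),
    FamilySpec("Jc9", "III", 5018, 161, 1398, "TGGTATCAGAGCC", "GAGGGGGAG", 128, 0.65),
]

FAMILIES: dict[str, FamilySpec] = {s.name: s for s in FAMILY_TABLE}

# degenerate primer sets targeting conserved copia RT peptides
PRIMER_SETS: dict[str, PrimerSet] = {
    "F": PrimerSet("F", "ACNGCNTTYYTNCAYGG", "ARCATRTCRTCNACRTA"),
    "V": PrimerSet("V", "CARATGGAYGTNAARAC", "CATRTCRTCNACRTA"),
    "H": PrimerSet("H", "GAYGTNAARACNGNTTYYT", "AYRTRTCNACRTANARNA"),
}

# JC7-1 RBIP primers (format fixtures; the published flanks are not printed,
# so the 242/182 bp products cannot be recomputed from them)
JC7_1_PRIMERS = {
    "FLKL": "CAAAGCACACGAGGATTCAG",
    "FLKR": "CAGGTCCAAATCTCCTCGTG",
    "LTRL": "GAAAATTAAATCCAACATGT",
    "LTRR": "GAGATTAATTCTTAACAGAA",
}
JC7_1_EXPECTED_PRODUCTS = {"occupied_left": 242, "occupied_right": 182}

# the twelve accessions genotyped with the JC7-1 marker; two lack the insertion
PANEL_ACCESSIONS = [
    "Philippines", "China", "Thailand", "Indonesia", "Uganda", "Tanzania",
    "Ethiopia", "India", "Vietnam", "Guatemala 2", "Mexico 2b", "Guatemala 1",
]
PANEL_ABSENT = ["Mexico 2b", "Guatemala 1"]

CLONE_LINES = ["Philippines", "China", "Thailand", "Indonesia", "Uganda"]


def lineage_ancestors(seed: int) -> dict[str, list[str]]:
    """Per-lineage ancestral RT-core codons (220 codons each)."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xA2CE57]))
    return {lin: random_codons(motifs.RT_CORE_LEN, rng) for lin in ("I", "II", "III")}


def build_reference_templates(seed: int, families: list[FamilySpec] | None = None,
                              rt_keep: float = 0.5) -> dict[str, FamilyTemplate]:
    """Templates for the standard family table with lineage-structured RT cores."""
    families = families or FAMILY_TABLE
    ancestors = lineage_ancestors(seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x7E3B1A]))
    out = {}
    for spec in families:
        sub = int(rng.integers(0, 2**31 - 1))
        out[spec.name] = build_family_template(spec, sub, rt_ancestor=ancestors[spec.lineage],
                                               rt_keep=rt_keep)
    return out


def lineage_reference_peptides(seed: int) -> tuple[dict[str, tuple[str, str]], str]:
    """(references, outgroup) for lineage assignment of RT core peptides.

    Each lineage ancestor is rendered with the same sentinel anchors the
    family templates carry; the outgroup is an unrelated random core.
    """
    refs = {}
    for lin, codons in lineage_ancestors(seed).items():
        codons = list(codons)
        _overlay_sentinels(codons)
        refs[f"ref_{lin}"] = (lin, translate("".join(codons)))
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x0C70D0]))
    out_codons = random_codons(motifs.RT_CORE_LEN, rng)
    _overlay_sentinels(out_codons)
    return refs, translate("".join(out_codons))


def _overlay_sentinels(codons: list[str]) -> None:
    for at, site in ((0, motifs.RT_F_SITE),
                     (motifs.RT_V_AT - motifs.RT_CORE_AT, motifs.RT_V_SITE),
                     (motifs.RT_YVDD_AT - motifs.RT_CORE_AT, motifs.RT_YVDD_SITE)):
        for i in range(len(site) // 3):
            codons[at + i] = site[3 * i:3 * (i + 1)]
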