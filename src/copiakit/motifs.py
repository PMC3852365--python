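"""Sentinel domain motifs and GAG-POL layout constants for synthetic elements.

A synthetic copia-type element carries a single GAG-POL open reading frame in
which short fixed peptide anchors mark the canonical domains (GAG, protease,
integrase, reverse transcriptase, RNase H) in copia order: integrase comes
before RT.  The three RT anchors are real conserved RT peptides — TAFLHG,
QMDVKT and YVDDML — and their codon spellings are chosen to be exact binding
sites for the F and V degenerate primer sets, so in-silico PCR on a synthetic
element amplifies the same ~300 bp RT fragment the primers target in a real
genome.  Everything between anchors is random codon filler; anchors aside, RT
cores are drawn from a per-lineage ancestor so families inside a lineage stay
more alike than families across lineages.
"""
from __future__ import annotations

from ._seq import encode_peptide, translate

# tRNA-Met 3' core complementary to the primer binding site
TRNA_CORE = "TGGTATCAGAGC"

# --- fixed codon spellings of the RT anchors -------------------------------
# TAFLHG: exact expansion of the F forward primer ACNGCNTTYYTNCAYGG
RT_F_SITE = "ACTGCATTCTTGCATGGA"          # 6 codons, peptide TAFLHG
# QMDVKTGSF: contains exact expansions of the V forward primer
# CARATGGAYGTNAARAC (offset 0) and the H forward primer (offset 6)
RT_V_SITE = "CAAATGGACGTAAAAACTGGTTCTTTC"  # 9 codons, peptide QMDVKTGSF
# YVDDML: reverse-complement holds exact expansions of the F and V reverse
# primers (ARCATRTCRTCNACRTA / CATRTCRTCNACRTA)
RT_YVDD_SITE = "TACGTAGACGATATGCTC"        # 6 codons, peptide YVDDML

# sentinel peptides used for domain-order checks
GAG_SENTINEL = "RQGSKEAV"
PROT_SENTINEL = "LLDSGASH"
INT_SENTINEL = "GKHHCCRA"
RT_SENTINEL = "QMDVKT"
RH_SENTINEL = "TDASRLGH"

GAG_CODONS = encode_peptide(GAG_SENTINEL)
PROT_CODONS = encode_peptide(PROT_SENTINEL)
INT_CODONS = encode_peptide(INT_SENTINEL)
RH_CODONS = encode_peptide(RH_SENTINEL)

# --- codon offsets inside the GAG-POL ORF ----------------------------------
# positions hold for every family (smallest printed ORF is 1299 aa)
GAG_AT = 10
PROT_AT = 280
INT_AT = 560
RT_CORE_AT = 820          # TAFLHG anchor = RT core start
RT_V_AT = 840             # QMDVKT anchor
RT_YVDD_AT = 914          # YVDDML anchor
RT_CORE_LEN = 220         # codons; the "ca. 220 aa" conserved RT region
RH_AT = 1060

MIN_GAGPOL_AA = 1075 + len(RH_SENTINEL)

# fixed codon positions inside the RT core that must not be mutated when
# deriving a family core from its lineage ancestor
_FIXED = set()
for _at, _site in ((RT_CORE_AT, RT_F_SITE), (RT_V_AT, RT_V_SITE), (RT_YVDD_AT, RT_YVDD_SITE)):
    _FIXED.update(range(_at, _at + len(_site) // 3))
RT_FIXED_CODONS = frozenset(_FIXED)

assert translate(RT_F_SITE) == "TAFLHG"
assert translate(RT_V_SITE) == "QMDVKTGSF"
assert translate(RT_YVDD_SITE) == "YVDDML"
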