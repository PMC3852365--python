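# Methods

## Synthetic elements and genomes

A family template is laid out 5'→3' as `LTR | PBS | leader | GAG-POL ORF |
trailer | PPT | LTR` with byte-identical LTR copies.  The PBS and PPT are
written exactly as their reference strings (upper-cased); the leading
lower-case letters of the PBS string define the spacer between the 5' LTR
and the tRNA-Met core `TGGTATCAGAGC`, which is how the lineage signature
(2 nt spacer in lineages I/II, 0 in III) enters the sequence.  The ORF is
`3*gagpol_len + 3` nt (ATG ... stop) of random non-stop codons carrying
fixed sentinel peptides for GAG, protease, integrase, the RT core and
RNase H at fixed codon offsets; the layout needs at least 1,083 codons,
comfortably below the smallest real family (1,299 aa).  The three RT
anchors — TAFLHG, QMDVKTGSF and YVDDML — are spelled with codons that are
exact binding sites for the F and V degenerate primer sets, so in-silico
PCR amplifies a 299 bp (F) or 237 bp (V) RT fragment from every template,
mirroring the ~300 bp fragments the primers target in a real genome.

When the ORF cannot fit between PBS and PPT (one lineage III family:
3·1528 + 2·210 > 4984), it is allowed to run over the PPT and into the
3' LTR within a 300 bp slack.  The PPT is then embedded inside the ORF
(purine codons cannot spell a stop; boundary codons get a C at a free
position, since no stop codon contains C), and the 5' LTR is synced to the
final 3' LTR bytes so the pair stays identical.  Two guards keep the placed
PPT the unique qualifying purine window of the 3' search region: the three
bases immediately upstream are forced to pyrimidines, and every fourth base
across the upstream window is a pyrimidine, capping competing windows below
the 0.8 purine-fraction threshold.

Backgrounds are i.i.d. uniform A/C/G/T (GC 0.5): a neutral substrate that
makes implanted homology unambiguous.  Divergence is substitution-only by
default so truth coordinates stay exact; each copy is mutated i.i.d. (the
two LTRs independently), inserted at a position clear of existing features,
and flanked by a host-derived TSD of 4–6 bp (default 5 bp drawn uniformly).
Insertion duplicates the host bases at the cut site, so genome length grows
by exactly element + TSD per copy, and the "empty site" allele of an
accession lacking the insertion is recovered by excising element + one TSD
copy.  Genes (0.5–2 kb) are planted with their nearest edge uniform within
5 kb of a copy at the family's gene probability; copies drawn gene-free are
guaranteed no gene within 6 kb.

What the simulator does *not* emulate: realistic base composition or
isochores, nested insertions, solo-LTR formation by recombination, indel
divergence (available behind a flag conceptually but off by default), and
real inter-family sequence relationships — family RT cores are drawn from a
per-lineage ancestor with 50% per-codon replacement, which produces clean
p-distance separation (intra-family ≈ 0.05 at 2% nucleotide divergence,
intra-lineage ≈ 0.6, inter-lineage ≈ 0.85) rather than the continuum of
real *copia* diversity.  Passing tests therefore demonstrate correctness of
the machinery under substitution-level divergence and unambiguous homology,
not performance on degenerate, nested or recombined repeat landscapes.

## In-silico PCR

Degenerate positions match their IUPAC set at zero cost; up to
`max_mismatch` (default 1) substitutions outside the set are tolerated,
standing in for wet-PCR tolerance without modeling thermodynamics.
Products pair a forward site with an inward-facing reverse site on the
opposite strand within 100–1,500 bp.  Degeneracies multiply per position
(the F forward primer expands to 512 seventeen-mers).

## Clone translation and classification

Amplicons at 2% divergence frequently carry substitution-induced nonsense
codons, and occasionally a genuine frameshift.  Translation is a dynamic
program chaining non-stop codons with steps of 3 nt (same frame) or 2/4 nt
(one frameshift event, penalty 4 codons, at most 2 events — spontaneous
frameshifts are rare point mutations, not free frame hopping), and reading
through at most 2 in-frame stops as `X` (penalty 3 codons each).  Both
strands are tried.  A clone is kept only if its peptide is *identifiable as
RT*: a conserved RT anchor must match with at most a quarter of its
positions substituted; if the DP's best reading fails this, the six
straight-frame read-through translations are tried, and a clone with no
identifiable reading is dropped (in practice ~2% of clones).  The anchor
check is what prevents a rare amplicon whose shifted frame happens to be
stop-free from founding a spurious family.

Clones are stacked by an anchored ungapped star alignment (exact for the
indel-free generator), trimmed to the longest column run covered by ≥95%
of clones (≈79 aa when F- and V-primed clones are mixed), and compared by
peptide p-distance with pairwise gap deletion — on a ~75-aa block,
model-corrected distances are unstable, so the uncorrected proportion is
used.  Neighbor joining follows Saitou–Nei exactly: Q-criterion
minimization with lowest-index tie-breaking, rate-corrected branch lengths,
negatives clamped to zero with the deficit moved to the sister edge; on an
additive matrix it reproduces the generating tree exactly, which the tests
verify against both tree construction and an independent NJ implementation.
Families are single-linkage clusters at p-distance 0.40 (the tree figure
equivalent of cutting by eye), labelled by descending clone count.  The
accession-by-family table is tested with Pearson's chi-square (no
continuity correction); expected-zero cells raise an error advising
pooling.

## Homology search

A word-indexed (11-mer) seed-and-extend engine scores diagonals at +1/−2
and takes the optimal local segment through each seed in closed form from
prefix sums — exact for substitution-level homology, which is the
generator's model; gapped refinement is intentionally absent.  E-values
follow Karlin–Altschul with the standard constants for this scoring pair
(λ = 1.28, K = 0.46), thresholded at 1e−20.  "Copy number" is the count of
subject-overlap-collapsed hit loci.  Tests compare hit sets against a full
quadratic Smith–Waterman enumeration on 20 kb instances.

## Iterative consensus extension

Each round searches the current consensus against the genome, keeps member
loci whose alignment covers ≥50% of the query (dropping truncated copies
and the phantom locus created when an LTR-containing consensus hits a
member's *other* LTR), widens member windows by 500 bp on unfinished
sides, and recomputes a column majority.  Ties between equally supported
bases go to the member most identical to the draft consensus, so one clean
member outvotes an equal number of diverged ones.  A side finishes where
column agreement collapses: a coarse scan flags the first 20-column window
whose mean agreement drops below 0.6 (inside the element agreement is ~1 at
low divergence; over unrelated host flanks it falls to the ~0.4 random
level), then a changepoint refinement places the boundary at the argmax of
the cumulative (agreement − 0.6).  At zero divergence this recovers the
implanted template byte-exactly; at 5% divergence with 8 members the
boundaries land within ±10 bp.  Fewer than 3 member loci is an explicit
low-copy-family error, and the procedure is idempotent on its own output.

## Structural annotation

LTR pairs are found by scanning alignment diagonals with both repeats
anchored within 25 bp of the sequence ends (scored +1/−1, ties to longer
then leftmost; length ≥ 100 bp, identity ≥ 0.85), vectorized so only
O(T²/4) base comparisons are needed instead of full self-comparison.  The
PBS is the tRNA core within 30 bp after the 5' LTR at ≤1 mismatch (spacer =
offset); the PPT is the best window of ≥9 bp ending within 50 bp of the
3' LTR ranked by purine fraction, then length, then leftmost position, with
a 0.8 fraction floor.  The GAG-POL ORF is the longest ATG-initiated
stop-free + strand ORF starting in the interior (it may end inside the
3' LTR), with sentinel-motif domain order and a *copia*-order flag
(integrase before RT).  TSDs are the longest exact 4–6 bp duplication
flanking a genomic copy.  Restriction maps report exact site positions with
fragment boundaries at site starts, so fragments always partition the
length.  Lineage assignment builds bootstrap NJ trees of the query RT core
against labelled reference cores plus an outgroup; a replicate votes for
the lineage of the smallest outgroup-rooted clade containing the query and
references of exactly one lineage, and only when the query is meaningfully
closer to that clade than to the outgroup (ratio < 0.9) — without the
margin, saturated random queries get placed somewhere by noise.  Support
≥ 50/100 assigns; otherwise "unassigned".

## Context and RBIP

Both 500 bp flanks of every copy are profiled as separate observations
(doubling n per copy); the flank's self-hit counts, so the low class starts
at 1.  Families need ≥20 flank observations to be reported; a family is a
marker candidate when >60% of flanks have a gene within 5 kb.  RBIP design
requires single-copy ("low") flanks on both sides, places junction primers
60 bp inside each LTR end and flank primers as far from the TSD as the
400 bp product bound allows, shifting inward until each flank primer is
unique genome-wide.  Both junction products span their LTR/flank boundary
and contain the full TSD.  Genotyping is haploid: occupied = both junction
products and no flank–flank product (in an occupied genome the flank–flank
distance exceeds the PCR size limit, so the two product classes are
mutually exclusive); empty = the flank–flank product only; both classes
present is flagged "both"; anything else is ambiguous (e.g. a SNP under a
primer 3' end).

## Problem sizes and defaults

The default pipeline run simulates 0.8 Mb with three 2%-diverged copies per
family plus one zero-divergence marker-family insertion, samples 60 clones
from the F+V amplicon pools across five source lines, and genotypes a
12-accession panel; the structural-recovery measurement implants
zero-divergence elements into a 2 Mb background.  These sizes keep a full
run under a minute while leaving every recovery quantity identifiable.
Known limitations: consensus boundaries from only three diverged members
wobble by a few bp (which can absorb the PBS spacer of short-LTR families);
the search engine does not model indels; primer design assumes haploid,
homozygous accessions.
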