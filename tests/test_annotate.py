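"""Structural annotation: LTR pair, PBS, PPT, GAG-POL, TSD, digests, lineage."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from copiakit._seq import random_dna
from copiakit.annotate import (AnnotParams, LtrNotFoundError, annotate_element,
                               assign_lineage, detect_ltr_pair, detect_pbs,
                               detect_ppt, detect_tsd, find_gag_pol,
                               restriction_map, rt_core_peptide)
from copiakit.reference import FAMILY_TABLE, lineage_reference_peptides


class TestLtrPair:
    def test_jc1_template_exact_ltr(self, jc1):
        ltr5, ltr3, ident = detect_ltr_pair(jc1.sequence)
        assert ltr5 == (0, 510) and ltr3 == (5398 - 510, 5398)
        assert ident == 1.0

    def test_random_sequence_has_no_pair(self, rng):
        with pytest.raises(LtrNotFoundError):
            detect_ltr_pair(random_dna(4000, rng))

    def test_three_substitutions_lower_identity_arithmetically(self, jc1):
        seq = list(jc1.sequence)
        L, T = 510, 5398
        for off in (50, 200, 400):          # inside the 3' LTR
            pos = T - L + off
            seq[pos] = "A" if seq[pos] != "A" else "C"
        ltr5, ltr3, ident = detect_ltr_pair("".join(seq))
        assert (ltr5, ltr3) == ((0, L), (T - L, T))
        assert ident == pytest.approx((L - 3) / L)


class TestPbs:
    def test_two_nt_spacer(self, jc1):
        span, spacer = detect_pbs(jc1.sequence, (0, 510))
        assert spacer == 2
        assert jc1.sequence[span[0]:span[1]] == "TGGTATCAGAGC"

    def test_zero_spacer_in_lineage_iii(self, templates):
        tpl = templates["Jc8"]
        span, spacer = detect_pbs(tpl.sequence, (0, 210))
        assert spacer == 0

    def test_two_mismatches_is_absent(self, rng):
        ltr = random_dna(200, rng)
        seq = ltr + "ag" + "TGGTATCAGAGC".replace("TG", "CA", 1) + random_dna(400, rng)
        assert detect_pbs(seq.upper(), (0, 200)) is None


class TestPpt:
    def _with_tail(self, rng, tail):
        # pyrimidine spacers isolate the window under test
        return random_dna(300, rng) + "CCC" + tail + "CC"

    def test_pure_purine_run(self, rng):
        seq = self._with_tail(rng, "AGGGGGAGA")
        ltr3 = (len(seq) - 2, len(seq) + 200)
        span, frac = detect_ppt(seq, ltr3)
        assert frac == 1.0
        assert seq[span[0]:span[1]] == "AGGGGGAGA"

    def test_pyrimidine_region_is_absent(self, rng):
        seq = random_dna(200, rng) + "CTCTCTCTCTCTCTCTCT" * 3
        # restrict the search window to the poly-CT tail
        params = AnnotParams(ppt_window=50)
        assert detect_ppt("C" * 250 + "CTCTCTCTCT" * 5, (300, 400), params) is None

    def test_hand_counted_best_window(self):
        # AAGTGGGAGAT: best-ranked window is AAGTGGGAGA, 9 purines / 10 = 0.9
        seq = "C" * 50 + "AAGTGGGAGAT" + "C" * 0
        span, frac = detect_ppt(seq + "X" * 0, (len(seq), len(seq) + 100))
        assert frac == pytest.approx(0.9)
        assert seq[span[0]:span[1]] == "AAGTGGGAGA"


class TestGagPol:
    def test_jc1_orf_and_domain_order(self, jc1):
        orf = find_gag_pol(jc1.sequence, (510, 5398 - 510))
        assert orf.aa_len == 1339
        assert orf.domains == ["GAG", "PR", "INT", "RT", "RH"]
        assert orf.copia_order and not orf.degenerate

    @pytest.mark.parametrize("name", [s.name for s in FAMILY_TABLE])
    def test_all_families_within_printed_aa_range(self, templates, name):
        tpl = templates[name]
        L = tpl.spec.ltr_len
        orf = find_gag_pol(tpl.sequence, (L, tpl.spec.total_len - L))
        assert orf.aa_len == tpl.spec.gagpol_len
        assert 1299 <= orf.aa_len <= 1528

    def test_excised_rt_motif_breaks_order_check(self, jc1):
        seq = jc1.sequence.replace("CAAATGGACGTAAAAACT", "CAAATGCATGTACATACT")
        orf = find_gag_pol(seq, (510, 5398 - 510))
        assert "RT" not in orf.domains or not orf.copia_order


class TestTsd:
    def test_planted_duplication_recovered(self, rng):
        left = random_dna(50, rng)
        right = random_dna(50, rng)
        genome = left + "GACGT" + "X" * 0 + random_dna(300, rng) + "GACGT" + right
        span = (55, len(genome) - 55)
        assert detect_tsd(genome, span) == "GACGT"

    def test_unrelated_flanks_give_none(self, rng):
        genome = random_dna(1000, rng)
        assert detect_tsd(genome, (400, 600)) is None

    def test_simulation_truth_recovered_for_all_zero_divergence_copies(self, genome5):
        for el in genome5.elements:
            got = detect_tsd(genome5.contigs[el.contig], (el.start, el.end))
            assert got == el.tsd


class TestRestriction:
    def test_no_sites_single_fragment(self, rng):
        seq = random_dna(500, rng).replace("GAATTC", "GAATTA")
        rm = restriction_map(seq, {"EcoRI": "GAATTC"})
        assert rm["EcoRI"]["fragments"] == [len(seq)]

    def test_two_sites_three_fragments(self):
        seq = "C" * 100 + "GGATCC" + "C" * 194 + "GGATCC" + "C" * 94
        rm = restriction_map(seq, {"BamHI": "GGATCC"})
        assert rm["BamHI"]["sites"] == [100, 300]
        assert rm["BamHI"]["fragments"] == [100, 200, 100]

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=1, max_size=400))
    def test_fragments_always_partition_length(self, seq):
        for enz in restriction_map(seq).values():
            assert sum(enz["fragments"]) == len(seq)


class TestRoundTrip:
    @pytest.mark.parametrize("name", [s.name for s in FAMILY_TABLE])
    def test_zero_divergence_template_annotates_to_spec(self, templates, name):
        tpl = templates[name]
        ann = annotate_element(tpl.sequence)
        truth = tpl.annotation
        assert (ann.ltr5, ann.ltr3) == (truth.ltr5, truth.ltr3)
        assert ann.orf.span[0] == truth.orf.span[0]
        assert ann.orf.aa_len == tpl.spec.gagpol_len
        assert ann.pbs_spacer == tpl.spec.pbs_spacer
        # detected PPT window lies inside the placed tract
        assert truth.ppt[0] <= ann.ppt[0] and ann.ppt[1] <= truth.ppt[1]

    def test_lineage_structural_concordance(self, templates):
        for spec in FAMILY_TABLE:
            ann = annotate_element(templates[spec.name].sequence)
            expected = 0 if spec.lineage == "III" else 2
            assert ann.pbs_spacer == expected, spec.name

    def test_annotation_from_genomic_copy_includes_tsd(self, genome5):
        el = genome5.elements[0]
        ann = annotate_element(genome5.element_seq(0),
                               genome_seq=genome5.contigs[el.contig],
                               span=(el.start, el.end))
        assert ann.total_len == 5398 and ann.tsd == el.tsd


class TestLineage:
    def test_reference_itself_gets_full_support(self):
        refs, outgroup = lineage_reference_peptides(11)
        label, (lineage, pep) = next(iter(refs.items()))
        got, support = assign_lineage(pep, refs, outgroup, bootstrap_n=50, seed=1)
        assert got == lineage and support == 100

    def test_random_peptide_unassigned(self, rng):
        refs, outgroup = lineage_reference_peptides(11)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        pep = "".join(np.array(list(aas))[rng.integers(0, 20, 220)])
        got, support = assign_lineage(pep, refs, outgroup, bootstrap_n=50, seed=2)
        assert got == "unassigned"

    def test_three_lineages_recovered_from_family_cores(self, templates):
        refs, outgroup = lineage_reference_peptides(11)
        for spec in FAMILY_TABLE:
            tpl = templates[spec.name]
            L = tpl.spec.ltr_len
            orf = find_gag_pol(tpl.sequence, (L, tpl.spec.total_len - L))
            core = rt_core_peptide(orf)
            got, support = assign_lineage(core, refs, outgroup, bootstrap_n=50, seed=3)
            assert got == spec.lineage, spec.name
            assert support >= 50
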