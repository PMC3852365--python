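"""Generator invariants: template geometry, implantation, genes, accessions."""
import numpy as np
import pandas as pd
import pytest

from copiakit.reference import FAMILIES, FAMILY_TABLE
from copiakit.synthetic import (FamilySpec, GeometryError, build_family_template,
                                implant_copies, plant_genes, random_genome,
                                simulate_accessions)


class TestFamilyTemplate:
    def test_jc1_dimensions_and_identical_ltrs(self, jc1):
        spec = jc1.spec
        assert len(jc1.sequence) == 5398
        assert jc1.sequence[:spec.ltr_len] == jc1.sequence[-spec.ltr_len:]

    @pytest.mark.parametrize("name", [s.name for s in FAMILY_TABLE])
    def test_every_family_builds_to_spec(self, templates, name):
        tpl = templates[name]
        spec = tpl.spec
        assert len(tpl.sequence) == spec.total_len
        assert tpl.sequence[:spec.ltr_len] == tpl.sequence[-spec.ltr_len:]
        ann = tpl.annotation
        assert ann.orf.aa_len == spec.gagpol_len
        assert ann.pbs_spacer == spec.pbs_spacer

    def test_same_seed_reproduces_sequence(self):
        spec = FAMILIES["Jc1"]
        a = build_family_template(spec, 42)
        b = build_family_template(spec, 42)
        assert a.sequence == b.sequence

    def test_no_internal_region_is_a_geometry_error(self):
        with pytest.raises(GeometryError, match="internal region"):
            FamilySpec("bad", "I", 2000, 1000, 1300, "agTGGTATCAGAGCC", "AGGGGGAGA")

    def test_orf_ltr_overflow_is_a_geometry_error(self):
        with pytest.raises(GeometryError, match="gagpol_len"):
            FamilySpec("bad", "I", 4000, 500, 1300, "agTGGTATCAGAGCC", "AGGGGGAGA")

    def test_pbs_must_contain_trna_core(self):
        with pytest.raises(ValueError, match="tRNA core"):
            FamilySpec("bad", "I", 6000, 500, 1300, "agAAAAAAAAAAAAA", "AGGGGGAGA")


class TestImplant:
    def test_zero_divergence_copies_have_identical_ltrs(self, genome5):
        assert len(genome5.elements) == 5
        assert all(e.ltr_identical for e in genome5.elements)

    def test_tsd_flanks_every_copy(self, genome5):
        for el in genome5.elements:
            seq = genome5.contigs[el.contig]
            t = len(el.tsd)
            assert seq[el.start - t:el.start] == el.tsd
            assert seq[el.end:el.end + t] == el.tsd

    def test_length_conservation(self, jc1):
        g = random_genome(50_000, seed=3)
        background = len(g.contigs["contig1"])
        implant_copies(g, jc1, 3, divergence=0.0, seed=5)
        expected = background + sum((e.end - e.start) + len(e.tsd) for e in g.elements)
        assert len(g.contigs["contig1"]) == expected

    def test_substitution_count_matches_binomial(self, jc1):
        rate, L = 0.05, jc1.spec.total_len
        g = random_genome(80_000, seed=6)
        implant_copies(g, jc1, 4, divergence=rate, seed=8)
        sd = np.sqrt(L * rate * (1 - rate))
        for idx in range(4):
            copy = g.element_seq(idx)
            subs = sum(a != b for a, b in zip(copy, jc1.sequence))
            assert abs(subs - L * rate) <= 3 * sd

    def test_fixed_tsd_length(self, jc1):
        g = random_genome(60_000, seed=9)
        implant_copies(g, jc1, 3, divergence=0.0, tsd_len_range=(5, 5), seed=10)
        assert all(len(e.tsd) == 5 for e in g.elements)

    def test_same_seed_bit_identical_outputs(self, jc1, tmp_path):
        from copiakit.fileio import write_fasta, write_truth_gff3

        paths = []
        for run in ("a", "b"):
            g = random_genome(40_000, seed=12)
            implant_copies(g, jc1, 2, divergence=0.02, seed=13)
            write_fasta(g.contigs, tmp_path / f"{run}.fa")
            write_truth_gff3(g, tmp_path / f"{run}.gff3")
            paths.append(run)
        assert (tmp_path / "a.fa").read_bytes() == (tmp_path / "b.fa").read_bytes()
        assert (tmp_path / "a.gff3").read_bytes() == (tmp_path / "b.gff3").read_bytes()


class TestGenes:
    def test_prob_one_every_copy_has_gene_within_5kb(self, jc1):
        from copiakit.context import gene_in_flank

        g = random_genome(400_000, seed=14)
        implant_copies(g, jc1, 20, divergence=0.0, seed=15)
        plant_genes(g, {"Jc1": 1.0}, seed=16)
        assert all(gene_in_flank(el, g.genes)[0] for el in g.elements)

    def test_prob_zero_nearest_gene_beyond_6kb(self, jc1):
        from copiakit.context import gene_in_flank

        g = random_genome(200_000, seed=17)
        implant_copies(g, jc1, 8, divergence=0.0, seed=18)
        plant_genes(g, {"Jc1": 0.0}, seed=19)
        assert all(gene_in_flank(el, g.genes)[1] >= 6000 for el in g.elements)

    def test_intermediate_prob_recovered_within_binomial_error(self, jc1):
        from copiakit.context import gene_in_flank

        p, n = 0.65, 100
        g = random_genome(2_500_000, seed=20)
        implant_copies(g, jc1, n, divergence=0.0, seed=21, min_gap=12_000)
        plant_genes(g, {"Jc1": p}, seed=22)
        frac = np.mean([gene_in_flank(el, g.genes)[0] for el in g.elements])
        assert abs(frac - p) <= 3 * np.sqrt(p * (1 - p) / n)


@pytest.fixture(scope="module")
def ref(jc1):
    g = random_genome(60_000, seed=23)
    implant_copies(g, jc1, 2, divergence=0.0, seed=24)
    return g


class TestAccessions:
    def test_two_absent_accessions_carry_empty_allele(self, ref):
        presence = pd.DataFrame(True, index=[f"acc{i}" for i in range(12)], columns=[0])
        presence.iloc[[3, 7], 0] = False
        panel = simulate_accessions(ref, presence, seed=25)
        ref_len = len(ref.contigs["contig1"])
        short = [a for a, g in panel.accessions.items()
                 if len(g.contigs["contig1"]) < ref_len]
        assert sorted(short) == ["acc3", "acc7"]

    def test_absent_allele_length_identity(self, ref):
        presence = pd.DataFrame([[False]], index=["a"], columns=[0])
        panel = simulate_accessions(ref, presence, seed=26)
        el = ref.elements[0]
        expected = len(ref.contigs["contig1"]) - (el.end - el.start) - len(el.tsd)
        assert len(panel.accessions["a"].contigs["contig1"]) == expected

    def test_empty_site_keeps_single_tsd_copy(self, ref):
        presence = pd.DataFrame([[False]], index=["a"], columns=[0])
        panel = simulate_accessions(ref, presence, seed=27)
        el = ref.elements[0]
        t = len(el.tsd)
        acc_seq = panel.accessions["a"].contigs["contig1"]
        assert acc_seq[el.start - t:el.start] == el.tsd
        # the duplicated copy went with the element (this seed's flank differs)
        assert acc_seq[el.start:el.start + t] != el.tsd

    def test_all_present_equal_lengths(self, ref):
        presence = pd.DataFrame(True, index=["a", "b"], columns=[0, 1])
        panel = simulate_accessions(ref, presence, seed=28)
        lens = {len(g.contigs["contig1"]) for g in panel.accessions.values()}
        assert lens == {len(ref.contigs["contig1"])}

    def test_unknown_locus_is_lookup_error(self, ref):
        presence = pd.DataFrame([[True]], index=["a"], columns=[99])
        with pytest.raises(LookupError):
            simulate_accessions(ref, presence, seed=29)
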