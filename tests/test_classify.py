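"""Clone translation, core trimming, distances, NJ, family cutting, chi-square."""
import numpy as np
import pytest

from copiakit._seq import random_codons
from copiakit.classify import (RTClone, Tree, cut_families, family_distribution_test,
                               neighbor_joining, p_distance_matrix,
                               translate_with_frameshift_recovery, trim_to_core)


def random_tree(n, rng):
    """Random unrooted binary tree with positive branch lengths."""
    t = Tree()
    avail = [t.new_node(f"t{i}") for i in range(n)]
    while len(avail) > 3:
        i, j = sorted(rng.choice(len(avail), 2, replace=False))
        u = t.new_node()
        t.link(avail[i], u, float(rng.uniform(0.05, 1.0)))
        t.link(avail[j], u, float(rng.uniform(0.05, 1.0)))
        avail = [a for k, a in enumerate(avail) if k not in (i, j)] + [u]
    center = t.new_node()
    for a in avail:
        t.link(a, center, float(rng.uniform(0.05, 1.0)))
    return t


class TestTranslation:
    def test_clean_orf_translates_in_frame(self, rng):
        orf = "ATG" + "".join(random_codons(100, rng))
        pep, events = translate_with_frameshift_recovery(orf)
        assert events == 0 and len(pep) == 101 and pep[0] == "M"

    def test_single_deletion_recovered_with_one_event(self, rng):
        # build an ORF whose off-frame readings are stop-rich, so after the
        # deletion only the frameshift path can recover the full peptide
        from copiakit._seq import translate

        while True:
            orf = "ATG" + "".join(random_codons(100, rng))
            if all(max(len(run) for run in translate(orf[f:]).split("*")) < 15
                   for f in (1, 2)):
                break
        pep0, _ = translate_with_frameshift_recovery(orf)
        pep1, events = translate_with_frameshift_recovery(orf[:150] + orf[151:])
        assert events == 1
        assert sum(a != b for a, b in zip(pep0, pep1)) <= 2

    def test_nonsense_codon_read_through_as_x(self, rng):
        orf = "ATG" + "".join(random_codons(100, rng))
        mutated = orf[:150] + "TAA" + orf[153:]
        pep, events = translate_with_frameshift_recovery(mutated)
        assert events == 0 and pep.count("X") == 1 and len(pep) == 101

    def test_stop_dense_sequence_dropped(self):
        assert translate_with_frameshift_recovery(("TAACTAACTAAC" * 26)[:300]) is None

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            translate_with_frameshift_recovery("ATGATG")


def _clones(peps):
    return [RTClone(f"c{i}", "acc", "F", "", aa) for i, aa in enumerate(peps)]


class TestTrim:
    def test_identical_peptides_keep_full_length(self, rng):
        pep = "".join(np.array(list("ACDEFGHIKLMNPQRSTVWY"))[rng.integers(0, 20, 90)])
        block = trim_to_core(_clones([pep] * 10))
        assert block.length == 90

    def test_staggered_ends_trim_to_intersection(self, rng):
        pep = "".join(np.array(list("ACDEFGHIKLMNPQRSTVWY"))[rng.integers(0, 20, 100)])
        clones = _clones([pep, pep[10:], pep[:90], pep[10:95]])
        block = trim_to_core(clones, coverage=1.0)
        assert block.length == 80    # columns covered by all: residues 10..90

    def test_fewer_than_three_clones_is_an_error(self):
        with pytest.raises(ValueError):
            trim_to_core(_clones(["AAAA", "AAAA"]))


class TestPDistance:
    def test_identical_rows_are_zero(self):
        D = p_distance_matrix(["ACDE", "ACDE"])
        assert D[0, 1] == 0.0

    def test_one_difference_in_four_is_quarter(self):
        D = p_distance_matrix(["ACDE", "ACDF"])
        assert D[0, 1] == pytest.approx(0.25)

    def test_hand_computed_toy_matrix(self):
        # AC-E vs ACDE: 3 shared columns, 0 diffs; ACDE vs GCDE: 1/4; AC-E vs GCDE: 1/3
        rows = ["AC-E", "ACDE", "GCDE"]
        D = p_distance_matrix(rows)
        assert D[0, 1] == pytest.approx(0.0)
        assert D[1, 2] == pytest.approx(0.25)
        assert D[0, 2] == pytest.approx(1 / 3)


class TestNeighborJoining:
    def test_additive_matrices_recover_topology_and_lengths(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            n = int(rng.integers(5, 9))
            truth = random_tree(n, rng)
            labels = [f"t{i}" for i in range(n)]
            D = truth.distance_matrix(labels)
            nj = neighbor_joining(D, labels)
            assert nj.splits() == truth.splits()
            assert np.allclose(nj.distance_matrix(labels), D, atol=1e-9)

    def test_three_taxa_analytic_branch_lengths(self):
        D = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0.0]])
        tree = neighbor_joining(D, ["a", "b", "c"])
        # la = (dab+dac-dbc)/2 = 1, lb = 2, lc = 3
        got = tree.distance_matrix(["a", "b", "c"])
        assert np.allclose(got, D)

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            neighbor_joining(np.array([[0, 1, 2], [9, 0, 1], [2, 1, 0.0]]))

    def test_matches_dendropy_on_random_distances(self):
        dendropy = pytest.importorskip("dendropy")
        rng = np.random.default_rng(3)
        n = 8
        labels = [f"t{i}" for i in range(n)]
        truth = random_tree(n, rng)
        D = truth.distance_matrix(labels)
        csv = "," + ",".join(labels) + "\n" + "\n".join(
            labels[i] + "," + ",".join(str(D[i, j]) for j in range(n)) for i in range(n))
        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            src=__import__("io").StringIO(csv))
        ref = pdm.nj_tree()
        ref_splits = set()
        tns = ref.taxon_namespace
        ref.encode_bipartitions()
        all_tips = frozenset(t.label for t in tns)
        for edge in ref.preorder_edge_iter():
            if edge.bipartition:
                side = frozenset(t.label for t in edge.bipartition.leafset_taxa(tns))
                if 1 < len(side) < n - 1:
                    ref_splits.add(min(side, all_tips - side, key=lambda s: (len(s), sorted(s))))
        assert neighbor_joining(D, labels).splits() == ref_splits


class TestFamilies:
    def test_two_separated_clusters_cut_into_two(self):
        D = np.full((6, 6), 0.8)
        D[:3, :3] = 0.05
        D[3:, 3:] = 0.05
        np.fill_diagonal(D, 0)
        asg = cut_families(D, [f"c{i}" for i in range(6)], 0.40)
        assert asg.n_families == 2

    def test_cut_of_one_merges_everything(self):
        rng = np.random.default_rng(1)
        D = rng.uniform(0.1, 0.9, (5, 5))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0)
        asg = cut_families(D, [f"c{i}" for i in range(5)], 0.999)
        assert asg.n_families == 1

    def test_family_count_non_increasing_in_cut(self):
        rng = np.random.default_rng(2)
        D = rng.uniform(0.05, 0.95, (12, 12))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0)
        ids = [f"c{i}" for i in range(12)]
        counts = [cut_families(D, ids, t).n_families for t in (0.1, 0.3, 0.5, 0.7, 0.9)]
        assert counts == sorted(counts, reverse=True)

    def test_labels_ordered_by_clone_count(self):
        D = np.full((5, 5), 0.9)
        D[:2, :2] = 0.01
        D[2:, 2:] = 0.01
        np.fill_diagonal(D, 0)
        asg = cut_families(D, [f"c{i}" for i in range(5)], 0.4)
        # the 3-clone cluster gets the first label
        assert [asg.families[f"c{i}"] for i in range(5)] == ["Jc2", "Jc2", "Jc1", "Jc1", "Jc1"]


class TestChiSquare:
    def test_homogeneous_table_gives_zero(self):
        chi2, df, p = family_distribution_test([[10, 10], [10, 10]])
        assert chi2 == 0.0 and p == pytest.approx(1.0)

    def test_closed_form_2x2(self):
        chi2, df, p = family_distribution_test([[30, 10], [10, 30]])
        assert chi2 == pytest.approx(20.0) and df == 1

    def test_df_formula_on_5x10(self, rng):
        table = rng.integers(5, 30, (5, 10))
        _, df, _ = family_distribution_test(table)
        assert df == 36

    def test_zero_expected_cell_advises_pooling(self):
        with pytest.raises(ValueError, match="pool"):
            family_distribution_test([[5, 0], [7, 0]])

    def test_type_one_error_calibrated(self):
        # clones drawn evenly across accessions: ~5% rejections at alpha=0.05
        rng = np.random.default_rng(7)
        probs = np.array([0.3, 0.25, 0.2, 0.15, 0.1])
        rejections = 0
        n_rep = 200
        for _ in range(n_rep):
            table = np.array([rng.multinomial(30, probs) for _ in range(4)])
            if (table.sum(axis=0) == 0).any():
                continue
            _, _, p = family_distribution_test(table[:, table.sum(axis=0) > 0])
            rejections += p < 0.05
        assert rejections / n_rep <= 0.09
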