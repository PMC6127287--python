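"""Pairwise identity, distance models, NJ trees, resolution scoring."""

import io
import math

import numpy as np
import pytest
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj as skbio_nj

from primerscope.discrimination import (compare_resolution, distance_matrix,
                                        indistinguishable_fraction,
                                        neighbor_joining, newick_to_tree,
                                        pairwise_identity,
                                        pairwise_identity_matrix,
                                        tree_to_newick)
from primerscope.fixtures import generate_insert_panel
from primerscope.seqio import SequenceRecord


class TestPairwiseIdentity:
    @pytest.mark.parametrize("a,b,expected", [
        ("ACGT", "ACGT", 1.0),
        ("AAAA", "AAAT", 0.75),
        ("ACGTACGT", "ACGT", 1.0),  # terminal gaps excluded from denominator
    ])
    def test_examples(self, a, b, expected):
        assert pairwise_identity(a, b) == pytest.approx(expected)

    def test_symmetry(self):
        rng = np.random.default_rng(11)
        bases = np.array(list("ACGT"))
        for _ in range(20):
            a = "".join(rng.choice(bases, size=rng.integers(5, 40)))
            b = "".join(rng.choice(bases, size=rng.integers(5, 40)))
            assert pairwise_identity(a, b) == pytest.approx(pairwise_identity(b, a))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pairwise_identity("", "ACGT")


class TestDistanceMatrix:
    def _records(self, seqs):
        return [SequenceRecord(f"s{i}", s) for i, s in enumerate(seqs)]

    def test_identical_sequences_zero(self):
        dm = distance_matrix(self._records(["ACGTACGT"] * 3))
        assert np.allclose(dm.data, 0.0)

    def test_jc69_zero_at_p_zero(self):
        dm = distance_matrix(self._records(["ACGTACGT"] * 3), model="jc69")
        assert np.allclose(dm.data, 0.0)

    def test_jc69_closed_form_at_p_01(self):
        base = "ACGT" * 25
        mutated = list(base)
        for i in range(0, 100, 10):  # 10 substitutions = p 0.1
            mutated[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[mutated[i]]
        dm = distance_matrix(self._records([base, "".join(mutated), base]), model="jc69")
        assert dm[0, 1] == pytest.approx(-0.75 * math.log(1 - 0.4 / 3), abs=1e-5)
        assert dm[0, 1] == pytest.approx(0.10732, abs=1e-4)

    def test_k2p_transitions_only_closed_form(self):
        base = "ACGT" * 25
        mutated = list(base)
        for i in range(0, 100, 10):  # transitions: A<->G, C<->T
            mutated[i] = {"A": "G", "C": "T", "G": "A", "T": "C"}[mutated[i]]
        dm = distance_matrix(self._records([base, "".join(mutated), base]), model="k2p")
        # P=0.1, Q=0: d = -0.5 ln(1-2P) - 0.25 ln(1)
        assert dm[0, 1] == pytest.approx(-0.5 * math.log(0.8), abs=1e-5)

    def test_saturated_distance_capped_with_warning(self):
        records = self._records(["AAAAAAAA", "TTTTTTTT", "AAAAAAAA"])
        with pytest.warns(UserWarning, match="saturated"):
            dm = distance_matrix(records, model="jc69", max_distance=5.0)
        assert dm[0, 1] == 5.0

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError):
            distance_matrix(self._records(["ACGT"]))


class TestIndistinguishableFraction:
    def test_two_identical_of_three(self):
        records = [SequenceRecord("a", "ACGTACGTACGTACGTACGT"),
                   SequenceRecord("b", "ACGTACGTACGTACGTACGT"),
                   SequenceRecord("c", "TGCATGCATGCATGCATGCA")]
        _, M = pairwise_identity_matrix(records)
        assert indistinguishable_fraction(M, 0.98) == pytest.approx(1 / 3)

    def test_all_below_threshold(self):
        M = np.eye(4) + 0.5 * (1 - np.eye(4))
        assert indistinguishable_fraction(M, 0.98) == 0.0

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(5)
        vals = rng.uniform(0.5, 1.0, size=(10, 10))
        M = (vals + vals.T) / 2
        np.fill_diagonal(M, 1.0)
        fracs = [indistinguishable_fraction(M, t) for t in (0.6, 0.7, 0.8, 0.9, 0.99)]
        assert fracs == sorted(fracs, reverse=True)

    def test_accepts_p_distance_matrix(self):
        dm = DistanceMatrix([[0, 0.01, 0.3], [0.01, 0, 0.3], [0.3, 0.3, 0]],
                            ids=list("abc"))
        assert indistinguishable_fraction(dm, 0.98) == pytest.approx(1 / 3)

    def test_distinct_species_denominator(self):
        records = [SequenceRecord("a1", "ACGTACGTACGTACGTACGT"),
                   SequenceRecord("a2", "ACGTACGTACGTACGTACGT"),
                   SequenceRecord("b1", "TGCATGCATGCATGCATGCA")]
        labels, M = pairwise_identity_matrix(records)
        species = {"a1": "A", "a2": "A", "b1": "B"}
        # the identical pair is conspecific, so it drops from both counts
        assert indistinguishable_fraction(M, 0.98, labels, species) == 0.0

    def test_engineered_panel_exact(self):
        panel = generate_insert_panel(n=20, n_close_pairs=2, length=200, seed=3)
        _, M = pairwise_identity_matrix(panel)
        assert indistinguishable_fraction(M, 0.98) == pytest.approx(2 / 190)

    def test_single_sequence_rejected(self):
        with pytest.raises(ValueError):
            indistinguishable_fraction(np.eye(1), 0.98)


def _random_tree(rng, n_leaves):
    nodes = [TreeNode(name=f"t{i}") for i in range(n_leaves)]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = TreeNode()
        for k in (i, j):
            child = nodes[k]
            child.length = float(rng.uniform(0.1, 1.0))
            parent.append(child)
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)] + [parent]
    root = TreeNode()
    for child in nodes:
        child.length = float(rng.uniform(0.1, 1.0))
        root.append(child)
    return root


def _path_distance_matrix(tree, ids):
    tips = {t.name: t for t in tree.tips()}
    n = len(ids)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = tips[ids[i]].distance(tips[ids[j]])
    return DistanceMatrix(D, ids=ids)


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix([[0, 3, 4], [3, 0, 5], [4, 5, 0]], ids=list("abc"))
        tree = neighbor_joining(dm)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["a"] == pytest.approx(1.0)
        assert lengths["b"] == pytest.approx(2.0)
        assert lengths["c"] == pytest.approx(3.0)

    def test_additive_matrix_recovered(self):
        rng = np.random.default_rng(23)
        ref = _random_tree(rng, 5)
        ids = sorted(t.name for t in ref.tips())
        dm = _path_distance_matrix(ref, ids)
        tree = neighbor_joining(dm)
        assert tree.compare_rfd(ref) == 0.0
        for a in ids:
            for b in ids:
                if a != b:
                    assert tree.find(a).distance(tree.find(b)) == pytest.approx(dm[a, b])

    def test_permutation_invariance(self):
        rng = np.random.default_rng(31)
        ref = _random_tree(rng, 7)
        ids = sorted(t.name for t in ref.tips())
        dm = _path_distance_matrix(ref, ids)
        shuffled = list(ids)
        rng.shuffle(shuffled)
        dm2 = dm.filter(shuffled)
        assert neighbor_joining(dm).compare_rfd(neighbor_joining(dm2)) == 0.0

    def test_agrees_with_library_nj(self):
        rng = np.random.default_rng(47)
        ref = _random_tree(rng, 8)
        ids = sorted(t.name for t in ref.tips())
        dm = _path_distance_matrix(ref, ids)
        ours = neighbor_joining(dm)
        theirs = skbio_nj(dm)
        assert ours.compare_rfd(theirs) == 0.0

    def test_negative_branch_clamped(self):
        # triangle-inequality violation forces a negative closed-form length
        dm = DistanceMatrix([[0, 1, 1], [1, 0, 3], [1, 3, 0]], ids=list("abc"))
        with pytest.warns(UserWarning, match="clamped"):
            tree = neighbor_joining(dm)
        assert all((t.length or 0) >= 0 for t in tree.traverse())

    def test_too_few_labels_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix([[0, 1], [1, 0]], ids=list("ab")))

    def test_newick_round_trip(self):
        rng = np.random.default_rng(3)
        ref = _random_tree(rng, 6)
        ids = sorted(t.name for t in ref.tips())
        tree = neighbor_joining(_path_distance_matrix(ref, ids))
        back = newick_to_tree(tree_to_newick(tree))
        assert back.compare_rfd(tree) == 0.0
        for name in ids:
            for other in ids:
                if name != other:
                    assert back.find(name).distance(back.find(other)) == pytest.approx(
                        tree.find(name).distance(tree.find(other)), abs=1e-9)


class TestCompareResolution:
    def test_identical_sets_equal_fractions(self):
        records = generate_insert_panel(n=10, n_close_pairs=1, length=120, seed=9)
        report = compare_resolution(records, records, 0.98)
        assert report.fraction_full == report.fraction_insert
        assert report.detail.empty

    def test_conserved_flanks_inflate_full_length_identity(self):
        rng = np.random.default_rng(13)
        bases = np.array(list("ACGT"))
        flank5 = "".join(rng.choice(bases, size=400))
        flank3 = "".join(rng.choice(bases, size=400))
        full, inserts = [], []
        for i in range(6):
            core = "".join(rng.choice(bases, size=40))
            inserts.append(SequenceRecord(f"s{i}", core))
            full.append(SequenceRecord(f"s{i}", flank5 + core + flank3))
        report = compare_resolution(full, inserts, 0.9)
        assert report.fraction_insert <= report.fraction_full
        assert report.fraction_full == 1.0  # 840 of 880 columns shared

    def test_label_mismatch_rejected(self):
        a = [SequenceRecord("x", "ACGTACGT")]
        b = [SequenceRecord("y", "ACGTACGT")]
        with pytest.raises(ValueError):
            compare_resolution(a, b, 0.98)
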