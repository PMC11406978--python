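"""Alignment-free distances, neighbor joining and sub-type purity."""

import itertools

import numpy as np
import pytest
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj as skbio_nj

from bfuscan.neighborhood import extract_neighborhood
from bfuscan.phylo import concat_abc, kmer_distance, nj_tree, subtype_purity

from test_neighborhood import genome_with_roles


class TestConcat:
    def test_concat_order_fixed_regardless_of_gene_order(self):
        ann, anchor = genome_with_roles(["C", "A", "B"])
        ann.proteins["g1"] = "CCCCC"  # role C
        ann.proteins["g3"] = "BBBBB"[:5].replace("B", "W")  # role B
        cluster = extract_neighborhood(ann, anchor)
        seq = concat_abc(cluster, ann.proteins)
        assert seq == ann.proteins["g2"] + "WWWWW" + "CCCCC"

    def test_concat_length_is_sum(self):
        ann, anchor = genome_with_roles(["A", "B", "C"])
        ann.proteins["g2"] = "M" * 600
        ann.proteins["g3"] = "L" * 150
        cluster = extract_neighborhood(ann, anchor)
        assert len(concat_abc(cluster, ann.proteins)) == len(ann.proteins["g1"]) + 750

    def test_missing_subunit_raises(self):
        ann, anchor = genome_with_roles(["A", "B"])
        with pytest.raises(ValueError, match="missing subunit C"):
            concat_abc(extract_neighborhood(ann, anchor), ann.proteins)


class TestKmerDistance:
    def test_identical_sequences_distance_zero(self):
        dm = kmer_distance({"a": "MKVLYRED", "b": "MKVLYRED"})
        assert dm["a", "b"] == 0.0

    def test_disjoint_kmer_sets_distance_one(self):
        dm = kmer_distance({"a": "AAAAA", "b": "WWWWW"})
        assert dm["a", "b"] == 1.0

    def test_hand_enumerated_overlap(self):
        # ARCDE -> {ARCD, RCDE}; RCDEF -> {RCDE, CDEF}; shared 1 of 3
        dm = kmer_distance({"a": "ARCDE", "b": "RCDEF"})
        assert dm["a", "b"] == pytest.approx(1 - 1 / 3)

    def test_too_short_sequence_raises(self):
        with pytest.raises(ValueError, match="shorter than k"):
            kmer_distance({"a": "MK"}, k=4)

    def test_empirical_triangle_inequality(self):
        rng = np.random.default_rng(5)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        seqs = {f"s{i}": "".join(rng.choice(aas, size=40)) for i in range(9)}
        dm = kmer_distance(seqs)
        ids = list(seqs)
        for a, b, c in itertools.combinations(ids, 3):
            assert dm[a, c] <= dm[a, b] + dm[b, c] + 1e-12


def random_additive_tree(n, rng):
    """A random binary tree with positive branch lengths, as a TreeNode."""
    names = [f"t{i}" for i in range(n)]
    nodes = [TreeNode(name=nm, length=float(rng.uniform(0.1, 1.0))) for nm in names]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[j], nodes[i]
        parent = TreeNode(length=float(rng.uniform(0.1, 1.0)), children=[nodes[i], nodes[j]])
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [parent]
    root = TreeNode(children=nodes)
    return root


class TestNeighborJoining:
    @pytest.mark.parametrize("n", [4, 5, 6, 8])
    def test_recovers_additive_tree_exactly(self, n):
        rng = np.random.default_rng(n)
        true_tree = random_additive_tree(n, rng)
        dm = true_tree.tip_tip_distances()
        est = nj_tree(DistanceMatrix(dm.data, ids=dm.ids))
        assert est.compare_rfd(true_tree) == 0
        est_dm = est.tip_tip_distances()
        for a, b in itertools.combinations(dm.ids, 2):
            assert est_dm[a, b] == pytest.approx(dm[a, b], abs=1e-5)

    def test_three_taxa_closed_form(self):
        dm = DistanceMatrix([[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]],
                            ids=["a", "b", "c"])
        tree = nj_tree(dm)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == {
            "a": pytest.approx(0.1),
            "b": pytest.approx(0.2),
            "c": pytest.approx(0.4),
        }

    def test_fewer_than_three_taxa_rejected(self):
        dm = DistanceMatrix([[0, 1], [1, 0]], ids=["a", "b"])
        with pytest.raises(ValueError, match="at least 3"):
            nj_tree(dm)

    def test_degenerate_equal_distances_deterministic(self):
        mat = np.ones((5, 5)) - np.eye(5)
        dm = DistanceMatrix(mat, ids=list("abcde"))
        assert str(nj_tree(dm)) == str(nj_tree(dm))

    def test_negative_branch_lengths_clamped(self):
        # a non-additive matrix that drives a branch estimate negative
        dm = DistanceMatrix(
            [[0, 0.1, 0.6, 0.6], [0.1, 0, 0.6, 0.6],
             [0.6, 0.6, 0, 0.05], [0.6, 0.6, 0.05, 0]],
            ids=list("abcd"),
        )
        tree = nj_tree(dm)
        for node in tree.traverse(include_self=False):
            assert node.length >= 0

    def test_topology_agrees_with_reference_nj(self):
        rng = np.random.default_rng(17)
        pts = rng.normal(size=(7, 3))
        mat = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        np.fill_diagonal(mat, 0)
        ids = [f"t{i}" for i in range(7)]
        dm = DistanceMatrix(mat, ids=ids)
        assert nj_tree(dm).compare_rfd(skbio_nj(dm)) == 0


class TestSubtypePurity:
    def test_perfect_separation_all_pure(self):
        tree = TreeNode.read(["((a:1,b:1):1,(c:1,d:1):1,(e:1,f:1):1);"])
        labels = {"a": "I", "b": "I", "c": "II", "d": "II", "e": "III", "f": "III"}
        report = subtype_purity(tree, labels)
        assert report.mean_purity == 1.0
        assert report.per_subtype["monophyletic"].all()

    def test_intruder_leaf_lowers_purity(self):
        # x (sub-type II) sits inside the III clade {c,d,e}; purities
        # hand-computed over all bipartitions of the 6-leaf tree
        tree = TreeNode.read(["((a:1,b:1):1,((c:1,x:1):1,(d:1,e:1):1):1);"])
        labels = {"a": "II", "b": "II", "x": "II", "c": "III", "d": "III", "e": "III"}
        report = subtype_purity(tree, labels)
        by = {r["subtype"]: r["purity"] for _, r in report.per_subtype.iterrows()}
        # III {c,d,e}: smallest containing side is {c,x,d,e} -> 3/4;
        # II {a,b,x}: smallest containing side is {a,b,c,x} (the complement
        # of the {d,e} edge) -> 3/4
        assert by["III"] == pytest.approx(3 / 4)
        assert by["II"] == pytest.approx(3 / 4)
        assert report.mean_purity == pytest.approx(3 / 4)

    def test_single_subtype_is_pure(self):
        tree = TreeNode.read(["((a:1,b:1):1,c:1,d:1);"])
        report = subtype_purity(tree, {n: "IV" for n in "abcd"})
        assert report.mean_purity == 1.0

    def test_unlabeled_leaf_raises(self):
        tree = TreeNode.read(["((a:1,b:1):1,c:1,d:1);"])
        with pytest.raises(KeyError, match="unlabeled"):
            subtype_purity(tree, {"a": "I", "b": "I", "c": "I"})

    def test_generator_defaults_give_pure_subtypes(self, default_run):
        _, _, summary = default_run
        assert summary.mean_purity == 1.0
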