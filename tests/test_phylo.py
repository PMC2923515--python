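"""MSA, distances, neighbor joining, bootstrap, partition, assignment."""

import math

import numpy as np
import pytest

from ferlinkit.benchmarks import random_tree, tree_distance_matrix
from ferlinkit.phylo import (
    DistanceMatrix,
    PhyloError,
    Tree,
    TreeNode,
    assign_fragment,
    bootstrap,
    correct_distance,
    nj_tree,
    partition_types,
    progressive_msa,
)


class TestMSA:
    def test_identical_sequences_align_gap_free(self):
        msa = progressive_msa([("a", "MKVLM"), ("b", "MKVLM"), ("c", "MKVLM")])
        assert all("-" not in row for _, row in msa)

    def test_two_sequences_reduce_to_pairwise_global(self):
        from ferlinkit.align import global_align

        a, b = "MKVLACDEFGHIK", "MKVLAEFGHIK"
        msa = progressive_msa([("x", a), ("y", b)])
        res = global_align(a, b)
        assert msa[0][1] == res.aligned_a
        assert msa[1][1] == res.aligned_b

    def test_planted_insertion_confined_to_one_gap_block(self):
        base = "MKVLACDEFGHIKWERTYIPASDFGHKLCV"
        ins = base[:12] + "WWW" + base[12:]
        msa = progressive_msa([("a", base), ("b", base), ("c", ins), ("d", base)])
        rows = dict(msa)
        assert rows["c"].replace("-", "") == ins
        for lab in "abd":
            assert rows[lab].replace("-", "") == base
            assert rows[lab].count("-") == 3
            gap_at = rows[lab].index("---")
            assert "-" not in rows[lab][:gap_at] + rows[lab][gap_at + 3 :]

    def test_gap_removal_recovers_inputs(self, diverged_family):
        seqs = [(p.id, p.sequence) for p in diverged_family[:4]]
        msa = progressive_msa(seqs)
        for (lab, orig), (lab2, row) in zip(seqs, msa):
            assert lab == lab2
            assert row.replace("-", "") == orig

    def test_single_sequence_rejected(self):
        with pytest.raises(PhyloError):
            progressive_msa([("a", "MKVL")])


class TestDistances:
    def test_correction_zero_at_zero(self):
        assert correct_distance(0.0) == 0.0

    def test_correction_monotone(self):
        ps = np.linspace(0, 0.79, 40)
        ds = [correct_distance(p) for p in ps]
        assert all(b > a for a, b in zip(ds, ds[1:]))

    def test_gap_columns_excluded_pairwise(self):
        aln = [("a", "MKVL--"), ("b", "MKVLAC"), ("c", "MKWLAC")]
        dm = DistanceMatrix.from_alignment(aln)
        i, j = dm.labels.index("a"), dm.labels.index("c")
        # a-c share 4 columns, one mismatch
        assert dm.d[i, j] == pytest.approx(correct_distance(0.25))

    def test_saturated_pairs_flagged(self):
        aln = [("a", "MKVLMKVL"), ("b", "WYWYWYWY")]
        dm = DistanceMatrix.from_alignment(aln)
        assert ("a", "b") in dm.saturated

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(PhyloError):
            DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))


class TestNJ:
    def test_three_leaves_closed_form(self):
        dm = DistanceMatrix(
            ["A", "B", "C"], np.array([[0, 4, 6], [4, 0, 8], [6, 8, 0]], float)
        )
        tree = nj_tree(dm)
        lengths = {}

        def walk(node):
            if node.is_leaf:
                lengths[node.name] = node.length
            for c in node.children:
                walk(c)

        walk(tree.root)
        assert lengths == {"A": 1.0, "B": 3.0, "C": 5.0}

    @pytest.mark.parametrize("seed", range(8))
    def test_additive_matrix_recovers_topology(self, seed):
        rng = np.random.default_rng(seed)
        true = random_tree(int(rng.integers(5, 11)), rng)
        est = nj_tree(tree_distance_matrix(true))
        assert est.bipartitions() == true.bipartitions()

    def test_matches_independent_nj_implementation(self):
        skbio = pytest.importorskip("skbio")
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj as sk_nj

        rng = np.random.default_rng(11)
        for _ in range(5):
            true = random_tree(7, rng)
            dm = tree_distance_matrix(true)
            mine = nj_tree(dm).bipartitions()
            sk_tree = sk_nj(SkDM(dm.d, ids=dm.labels))
            ref = min(dm.labels)
            theirs = set()
            for node in sk_tree.non_tips():
                side = frozenset(t.name for t in node.tips())
                if ref in side:
                    side = frozenset(set(dm.labels) - side)
                if 1 < len(side) < len(dm.labels) - 1:
                    theirs.add(side)
            assert mine == theirs

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(2)
        true = random_tree(7, rng)
        dm = tree_distance_matrix(true)
        base = nj_tree(dm).bipartitions()
        perm = rng.permutation(len(dm.labels))
        dm2 = DistanceMatrix(
            [dm.labels[i] for i in perm], dm.d[np.ix_(perm, perm)]
        )
        assert nj_tree(dm2).bipartitions() == base

    def test_uniform_scaling_invariance(self):
        rng = np.random.default_rng(3)
        true = random_tree(6, rng)
        dm = tree_distance_matrix(true)
        scaled = DistanceMatrix(dm.labels, dm.d * 7.5)
        assert nj_tree(scaled).bipartitions() == nj_tree(dm).bipartitions()

    def test_too_few_labels_rejected(self):
        with pytest.raises(PhyloError):
            nj_tree(DistanceMatrix(["a", "b"], np.zeros((2, 2))))


@pytest.fixture(scope="module")
def family_alignment(diverged_family):
    return progressive_msa([(p.id, p.sequence) for p in diverged_family])


class TestBootstrap:
    def test_supports_bounded_and_on_internal_edges(self, family_alignment):
        tree = bootstrap(family_alignment, n_replicates=30, seed=1)
        supports = [
            n.support
            for n in tree._walk(tree.root)
            if n.support is not None
        ]
        assert supports
        assert all(0 <= s <= 100 for s in supports)
        n_leaves = len(tree.leaf_labels)
        for bp in tree.bipartitions():
            assert 1 < len(bp) < n_leaves - 1

    def test_single_replicate_supports_binary(self, family_alignment):
        tree = bootstrap(family_alignment, n_replicates=1, seed=5)
        supports = {
            n.support for n in tree._walk(tree.root) if n.support is not None
        }
        assert supports <= {0.0, 100.0}

    def test_fixed_seed_reproducible(self, family_alignment):
        one = bootstrap(family_alignment, n_replicates=20, seed=9)
        two = bootstrap(family_alignment, n_replicates=20, seed=9)
        assert one.newick(with_support=True) == two.newick(with_support=True)

    def test_bad_replicate_count_rejected(self, family_alignment):
        with pytest.raises(PhyloError):
            bootstrap(family_alignment, n_replicates=0)


def _two_clade_tree():
    left = [TreeNode(name=f"T1_{i}", length=0.1) for i in range(3)]
    right = [TreeNode(name=f"T2_{i}", length=0.1) for i in range(3)]
    a = TreeNode(length=1.0)
    a.children = left
    b = TreeNode(length=1.0)
    b.children = right
    root = TreeNode()
    root.children = [a, b]
    return Tree(root)


class TestPartition:
    def test_clean_two_clade_partition(self):
        tree = _two_clade_tree()
        labels = {f"T1_{i}": 1 for i in range(3)} | {f"T2_{i}": 2 for i in range(3)}
        rep = partition_types(tree, labels)
        assert rep["clean"] and rep["outliers"] == []

    def test_grafted_leaf_reported_as_outlier(self):
        tree = _two_clade_tree()
        # graft a Type 2 leaf inside the Type 1 clade
        intruder = TreeNode(name="T2_x", length=2.0)
        tree.root.children[0].children.append(intruder)
        labels = (
            {f"T1_{i}": 1 for i in range(3)}
            | {f"T2_{i}": 2 for i in range(3)}
            | {"T2_x": 2}
        )
        rep = partition_types(tree, labels)
        assert not rep["clean"]
        assert rep["outliers"] == ["T2_x"]

    def test_single_type_trivially_partitioned(self):
        tree = _two_clade_tree()
        labels = {leaf: 1 for leaf in tree.leaf_labels}
        rep = partition_types(tree, labels)
        assert rep["clean"] and rep["outliers"] == []

    def test_unlabeled_leaf_rejected(self):
        tree = _two_clade_tree()
        with pytest.raises(PhyloError):
            partition_types(tree, {"T1_0": 1})


class TestAssignment:
    REFS = [
        ("P1", "MKVLACDEFGHIKWERTYIPASDFGHKLMKVLACDEFGHIK"),
        ("P2", "MKVLACWWFGHIKAARTYIPASDFGHKLMKVWWCDEFGHIK"),
        ("P3", "MKQQACDEFGHIKWERTYIPCCDFGHKLMKVLACDCCGHIK"),
    ]

    def test_exact_copy_assigned_with_positive_margin(self):
        result = assign_fragment(self.REFS[1][1], self.REFS)
        assert result["label"] == "P2"
        assert result["margin"] > 0
        assert not result["ambiguous"]

    def test_equidistant_fragment_flagged_ambiguous(self):
        refs = [("P1", "MKVLACDEFGHIK"), ("P2", "MKVLACDEFGHIK")]
        result = assign_fragment("MKVLACDEFGHIK", refs)
        assert result["ambiguous"]

    def test_single_label_reference_set_rejected(self):
        with pytest.raises(PhyloError):
            assign_fragment("MKVL", [("P1", "MKVLACDEF"), ("P1", "MKVLACDEW")])

    def test_unalignable_fragment_rejected(self):
        refs = [("P1", "W" * 40), ("P2", "Y" * 40)]
        with pytest.raises(PhyloError):
            assign_fragment("MKVLMKVLMKVLGGGG", refs)
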