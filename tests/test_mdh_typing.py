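"""MDH typing: p-distance, neighbor joining against additive-matrix and
scikit-bio oracles, and the outgroup clade rule."""

import math

import numpy as np
import pytest

from pgpt_profiler.formats import PhyloTree, TreeNode
from pgpt_profiler.mdh_typing import (
    AlignedSeqSet,
    DistanceMatrix,
    MDHType,
    Role,
    nj_tree,
    p_distance,
    type_all,
    type_query,
)
from pgpt_profiler.synthetic import (
    mutate_sequence,
    random_protein,
    simulate_mdh_reference_set,
)
from .conftest import random_additive_matrix


def seq_set(pairs, roles=None):
    labels = [p[0] for p in pairs]
    seqs = [p[1] for p in pairs]
    roles = roles or {l: Role.QUERY for l in labels}
    return AlignedSeqSet(labels=labels, sequences=seqs, roles=roles)


class TestPDistance:
    def test_identical_sequences(self):
        dm = p_distance(seq_set([("a", "AAAA"), ("b", "AAAA")]))
        assert dm.matrix[0, 1] == 0.0

    def test_half_mismatches(self):
        dm = p_distance(seq_set([("a", "AAAA"), ("b", "AATT")]))
        assert dm.matrix[0, 1] == 0.5

    def test_pairwise_deletion_of_gaps(self):
        dm = p_distance(seq_set([("a", "AA-A"), ("b", "AACA")]))
        assert dm.matrix[0, 1] == 0.0  # 0 mismatches over 3 compared columns

    def test_all_gap_pair_rejected_naming_pair(self):
        with pytest.raises(ValueError, match="a.*b"):
            p_distance(seq_set([("a", "--AA"), ("b", "AA--")]))

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="unequal"):
            seq_set([("a", "AAA"), ("b", "AAAA")])

    def test_poisson_correction(self):
        dm = p_distance(seq_set([("a", "AAAA"), ("b", "AATT")]), poisson_correct=True)
        assert math.isclose(dm.matrix[0, 1], -math.log(0.5))


class TestNeighborJoining:
    def test_three_taxa_solves_three_point_equations(self):
        labels = ["A", "B", "C"]
        D = np.array([[0.0, 0.3, 0.5], [0.3, 0.0, 0.6], [0.5, 0.6, 0.0]])
        tree = nj_tree(DistanceMatrix(labels, D))
        pl = tree.path_lengths()
        assert math.isclose(pl[("A", "B")], 0.3, abs_tol=1e-12)
        assert math.isclose(pl[("A", "C")], 0.5, abs_tol=1e-12)
        assert math.isclose(pl[("B", "C")], 0.6, abs_tol=1e-12)

    def test_zero_distance_pair_joined_first(self):
        labels = ["A", "B", "C", "D"]
        D = np.array(
            [
                [0.0, 0.0, 0.5, 0.6],
                [0.0, 0.0, 0.5, 0.6],
                [0.5, 0.5, 0.0, 0.3],
                [0.6, 0.6, 0.3, 0.0],
            ]
        )
        tree = nj_tree(DistanceMatrix(labels, D))
        # A and B must be siblings: their path length is 0
        assert tree.path_lengths()[("A", "B")] == 0.0

    def test_asymmetric_matrix_rejected(self):
        D = np.array([[0.0, 0.1, 0.2], [0.3, 0.0, 0.2], [0.2, 0.2, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(["a", "b", "c"], D)

    def test_additive_matrix_recovered_exactly(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            n = int(rng.integers(4, 13))
            labels, D = random_additive_matrix(n, rng)
            tree = nj_tree(DistanceMatrix(labels, D))
            pl = tree.path_lengths()
            for i in range(n):
                for j in range(i + 1, n):
                    assert abs(pl[(labels[i], labels[j])] - D[i, j]) < 1e-9

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(23)
        labels, D = random_additive_matrix(8, rng)
        tree = nj_tree(DistanceMatrix(labels, D))
        ref = tree.path_lengths()
        perm = rng.permutation(8)
        labels_p = [labels[i] for i in perm]
        D_p = D[np.ix_(perm, perm)]
        tree_p = nj_tree(DistanceMatrix(labels_p, D_p))
        pl = tree_p.path_lengths()
        assert set(pl) == set(ref)
        for key in ref:
            assert math.isclose(pl[key], ref[key], abs_tol=1e-9)

    def test_agrees_with_skbio(self):
        skbio = pytest.importorskip("skbio")
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(31)
        labels, D = random_additive_matrix(7, rng)
        D = (D + D.T) / 2  # exact symmetry for skbio's validator
        ours = nj_tree(DistanceMatrix(labels, D)).path_lengths()
        sk_tree = skbio_nj(SkbioDM(D, ids=labels))
        for i in range(7):
            for j in range(i + 1, 7):
                a, b = labels[i], labels[j]
                sk_d = sk_tree.find(a).distance(sk_tree.find(b))
                assert math.isclose(ours[(min(a, b), max(a, b))], sk_d, abs_tol=1e-6)


def build_tree(newick_like):
    """Tiny helper building fixed 5-leaf trees for clade-rule tests."""
    return newick_like


class TestTypeQuery:
    @staticmethod
    def five_leaf_tree(query_sister_to, xox=("x1", "x2"), mxa=("m1",), out=("og",)):
        """Unrooted tree: ((q, S), rest...) where S = query's sister leaf."""
        leaves = {}
        for name in (*xox, *mxa, *out, "q"):
            leaves[name] = TreeNode(label=name, length=0.1)
        sister = leaves[query_sister_to]
        pair = TreeNode(length=0.1, children=[leaves["q"], sister])
        rest = [v for k, v in leaves.items() if k not in ("q", query_sister_to)]
        root = TreeNode(children=[pair, *rest])
        return PhyloTree(root=root)

    ROLES = {
        "q": Role.QUERY,
        "x1": Role.REF_XOXF,
        "x2": Role.REF_XOXF,
        "m1": Role.REF_MXAF,
        "og": Role.OUTGROUP,
    }

    def test_query_in_xoxf_clade(self):
        tree = self.five_leaf_tree("x1")
        assert type_query(tree, self.ROLES).call is MDHType.XOXF

    def test_query_in_mxaf_clade(self):
        tree = self.five_leaf_tree("m1")
        assert type_query(tree, self.ROLES).call is MDHType.MXAF

    def test_query_sister_to_outgroup_undetermined(self):
        tree = self.five_leaf_tree("og")
        assert type_query(tree, self.ROLES).call is MDHType.UNDETERMINED

    def test_mixed_smallest_clade_undetermined(self):
        # query joins a cherry containing one xoxF and one mxaF ref
        leaves = {n: TreeNode(label=n, length=0.1) for n in ("q", "x1", "m1", "x2", "og")}
        mixed = TreeNode(length=0.1, children=[leaves["x1"], leaves["m1"]])
        with_query = TreeNode(length=0.1, children=[leaves["q"], mixed])
        root = TreeNode(children=[with_query, leaves["x2"], leaves["og"]])
        roles = dict(self.ROLES)
        assert type_query(PhyloTree(root=root), roles).call is MDHType.UNDETERMINED

    def test_missing_outgroup_rejected(self):
        tree = self.five_leaf_tree("x1")
        roles = {k: (Role.REF_XOXF if v is Role.OUTGROUP else v) for k, v in self.ROLES.items()}
        with pytest.raises(ValueError, match="outgroup"):
            type_query(tree, roles)


class TestTypeAll:
    def test_no_queries(self):
        refs, outs = simulate_mdh_reference_set(seed=2)
        typed = {l: (s, Role.REF_XOXF if t == "xoxF" else Role.REF_MXAF) for l, (s, t) in refs.items()}
        assert type_all({}, typed, outs) == []

    def test_query_identical_to_reference_called_its_type(self):
        refs, outs = simulate_mdh_reference_set(seed=2)
        typed = {l: (s, Role.REF_XOXF if t == "xoxF" else Role.REF_MXAF) for l, (s, t) in refs.items()}
        xox_seq = next(s for l, (s, t) in refs.items() if t == "xoxF")
        mxa_seq = next(s for l, (s, t) in refs.items() if t == "mxaF")
        calls = type_all({"qx": xox_seq, "qm": mxa_seq}, typed, outs)
        by_label = {c.query: c.call for c in calls}
        assert by_label == {"qx": MDHType.XOXF, "qm": MDHType.MXAF}

    def test_noisy_copies_of_xoxf_called_xoxf(self):
        rng = np.random.default_rng(6)
        refs, outs = simulate_mdh_reference_set(seed=2)
        typed = {l: (s, Role.REF_XOXF if t == "xoxF" else Role.REF_MXAF) for l, (s, t) in refs.items()}
        xox_seqs = [s for l, (s, t) in refs.items() if t == "xoxF"]
        queries = {f"q{i}": mutate_sequence(xox_seqs[i % len(xox_seqs)], 0.1, rng) for i in range(3)}
        calls = type_all(queries, typed, outs)
        assert all(c.call is MDHType.XOXF for c in calls)

    def test_random_queries_undetermined(self):
        rng = np.random.default_rng(8)
        refs, outs = simulate_mdh_reference_set(seed=2)
        typed = {l: (s, Role.REF_XOXF if t == "xoxF" else Role.REF_MXAF) for l, (s, t) in refs.items()}
        aln_len = len(outs["outgroup1"])
        queries = {f"q{i}": random_protein(rng, aln_len) for i in range(10)}
        calls = type_all(queries, typed, outs)
        undet = sum(c.call is MDHType.UNDETERMINED for c in calls)
        assert undet > len(calls) / 2
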