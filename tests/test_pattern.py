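import dendropy
import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import linkage as scipy_linkage
from scipy.spatial.distance import squareform

from plastdeg.association import AssociationMatrix, GroupScheme
from plastdeg.pattern import (
    DistanceMatrix,
    compare_partition,
    cosine_distance_matrix,
    cut_tree,
    dendrogram_to_newick,
    hierarchical_cluster,
    nmds_embed,
)


def binary_matrix(arr, genera=None, plastics=None):
    arr = np.asarray(arr)
    genera = genera or [f"G{i}" for i in range(arr.shape[0])]
    plastics = plastics or [f"P{j}" for j in range(arr.shape[1])]
    return AssociationMatrix(pd.DataFrame(arr, index=genera, columns=plastics))


from oracles import naive_agglomerate, naive_cosine, pair_count_ari


def random_distance(rng, n):
    D = rng.random((n, n))
    D = (D + D.T) / 2
    np.fill_diagonal(D, 0.0)
    return D


TWO_PAIR = DistanceMatrix(
    ("A", "B", "C", "D"),
    np.array(
        [
            [0.0, 0.1, 0.9, 0.9],
            [0.1, 0.0, 0.9, 0.9],
            [0.9, 0.9, 0.0, 0.1],
            [0.9, 0.9, 0.1, 0.0],
        ]
    ),
)


class TestCosine:
    def test_identical_columns_distance_zero(self):
        m = binary_matrix([[1, 1], [0, 0], [1, 1]])
        d = cosine_distance_matrix(m)
        assert d.values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_columns_distance_one(self):
        m = binary_matrix([[1, 0], [0, 1]])
        d = cosine_distance_matrix(m)
        assert d.values[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_half_overlap(self):
        # u=(1,1,0,0), v=(1,0,1,0): dot=1, norms sqrt(2) each -> d=0.5
        d = cosine_distance_matrix(binary_matrix([[1, 1], [1, 0], [0, 1], [0, 0]]))
        assert d.values[0, 1] == pytest.approx(0.5, abs=1e-12)

    def test_matches_naive_oracle_on_random_binary_matrices(self):
        rng = np.random.default_rng(101)
        for _ in range(20):
            shape = (rng.integers(2, 12), rng.integers(2, 12))
            X = rng.integers(0, 2, size=shape)
            X[0, :] = 1  # no all-zero column
            d = cosine_distance_matrix(binary_matrix(X))
            assert np.abs(d.values - naive_cosine(X.astype(float))).max() <= 1e-12

    def test_all_zero_column_named_in_error(self):
        m = binary_matrix([[1, 0], [1, 0]], plastics=["PE", "PHB"])
        with pytest.raises(ValueError, match="PHB"):
            cosine_distance_matrix(m)


class TestHierarchicalCluster:
    def test_two_labels_single_merge_at_distance(self):
        d = DistanceMatrix(("A", "B"), np.array([[0.0, 0.3], [0.3, 0.0]]))
        dendro = hierarchical_cluster(d)
        assert dendro.merges == ((0, 1, 0.3, 2),)

    def test_well_separated_pairs_merge_first(self):
        dendro = hierarchical_cluster(TWO_PAIR)
        first_two = {frozenset(m[:2]) for m in dendro.merges[:2]}
        assert first_two == {frozenset({0, 1}), frozenset({2, 3})}

    @pytest.mark.parametrize("method", ["average", "complete", "single"])
    def test_matches_naive_agglomeration(self, method):
        rng = np.random.default_rng(202)
        for _ in range(15):
            n = int(rng.integers(3, 8))
            labels = tuple(f"L{i}" for i in range(n))
            D = random_distance(rng, n)
            dendro = hierarchical_cluster(DistanceMatrix(labels, D), method)
            expected = naive_agglomerate(labels, D.tolist(), method)
            for got, exp in zip(dendro.merges, expected):
                assert got[:2] == exp[:2]
                assert got[2] == pytest.approx(exp[2], abs=1e-12)
                assert got[3] == exp[3]

    def test_average_heights_match_scipy_on_tie_free_matrices(self):
        rng = np.random.default_rng(303)
        for _ in range(10):
            n = int(rng.integers(4, 10))
            D = random_distance(rng, n)
            dendro = hierarchical_cluster(
                DistanceMatrix(tuple(f"L{i}" for i in range(n)), D)
            )
            Z = scipy_linkage(squareform(D), method="average")
            assert np.allclose(sorted(dendro.heights), sorted(Z[:, 2]))

    def test_heights_non_decreasing(self):
        rng = np.random.default_rng(404)
        for _ in range(10):
            D = random_distance(rng, 8)
            h = hierarchical_cluster(
                DistanceMatrix(tuple(f"L{i}" for i in range(8)), D)
            ).heights
            assert all(a <= b + 1e-12 for a, b in zip(h, h[1:]))

    def test_invariant_to_genus_row_permutation(self):
        rng = np.random.default_rng(505)
        X = rng.integers(0, 2, size=(10, 6))
        X[0, :] = 1
        m = binary_matrix(X)
        perm = rng.permutation(10)
        m_perm = AssociationMatrix(m.data.iloc[perm])
        d1 = hierarchical_cluster(cosine_distance_matrix(m))
        d2 = hierarchical_cluster(cosine_distance_matrix(m_perm))
        assert d1.merges == d2.merges

    def test_fewer_than_two_labels_rejected(self):
        with pytest.raises(ValueError):
            hierarchical_cluster(DistanceMatrix(("A",), np.zeros((1, 1))))


class TestCutTree:
    def test_k_one_single_cluster(self):
        part = cut_tree(hierarchical_cluster(TWO_PAIR), k=1)
        assert set(part.values()) == {0}

    def test_k_equals_leaf_count_gives_singletons(self):
        part = cut_tree(hierarchical_cluster(TWO_PAIR), k=4)
        assert sorted(part.values()) == [0, 1, 2, 3]

    def test_k_two_recovers_planted_pairs(self):
        part = cut_tree(hierarchical_cluster(TWO_PAIR), k=2)
        assert part["A"] == part["B"] != part["C"] == part["D"]

    def test_k_out_of_range(self):
        dendro = hierarchical_cluster(TWO_PAIR)
        for k in (0, 5):
            with pytest.raises(ValueError):
                cut_tree(dendro, k)


class TestNewick:
    def test_two_leaf_shape(self):
        d = DistanceMatrix(("A", "B"), np.array([[0.0, 0.4], [0.4, 0.0]]))
        nwk = dendrogram_to_newick(hierarchical_cluster(d))
        assert nwk == "(A:0.2,B:0.2);"

    def test_round_trip_topology(self):
        dendro = hierarchical_cluster(TWO_PAIR)
        tree = dendropy.Tree.get(data=dendrogram_to_newick(dendro), schema="newick")
        leaf_sets = {
            frozenset(l.taxon.label for l in node.leaf_iter())
            for node in tree.preorder_node_iter()
            if not node.is_leaf()
        }
        assert frozenset({"A", "B"}) in leaf_sets
        assert frozenset({"C", "D"}) in leaf_sets

    def test_bipartitions_match_two_cluster_cut(self):
        dendro = hierarchical_cluster(TWO_PAIR)
        part = cut_tree(dendro, 2)
        tree = dendropy.Tree.get(data=dendrogram_to_newick(dendro), schema="newick")
        root_children = [
            frozenset(l.taxon.label for l in child.leaf_iter())
            for child in tree.seed_node.child_nodes()
        ]
        clusters = {}
        for label, cid in part.items():
            clusters.setdefault(cid, set()).add(label)
        assert {frozenset(c) for c in clusters.values()} == set(root_children)


class TestNMDS:
    def test_equilateral_three_points_embed_exactly(self):
        d = DistanceMatrix(
            ("A", "B", "C"),
            np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float),
        )
        emb = nmds_embed(d, seed=0)
        assert emb.stress <= 1e-6

    def test_same_seed_bit_identical(self):
        e1 = nmds_embed(TWO_PAIR, seed=7)
        e2 = nmds_embed(TWO_PAIR, seed=7)
        assert np.array_equal(e1.coordinates, e2.coordinates)
        assert e1.stress == e2.stress

    def test_two_cluster_toy_separates(self):
        emb = nmds_embed(TWO_PAIR, seed=1)
        c1 = emb.coordinates[:2].mean(axis=0)
        c2 = emb.coordinates[2:].mean(axis=0)
        sep = np.linalg.norm(c1 - c2)
        spread = max(
            np.linalg.norm(emb.coordinates[0] - emb.coordinates[1]),
            np.linalg.norm(emb.coordinates[2] - emb.coordinates[3]),
        )
        assert sep > spread

    def test_fewer_than_three_labels_rejected(self):
        d = DistanceMatrix(("A", "B"), np.array([[0.0, 1.0], [1.0, 0.0]]))
        with pytest.raises(ValueError):
            nmds_embed(d)


class TestComparePartition:
    SCHEME = GroupScheme(
        {"P1": "CC", "P2": "CC", "P3": "CC", "P4": "CX", "P5": "CX", "P6": "CX"}
    )

    def test_identical_partition_scores_one(self):
        part = {"P1": 0, "P2": 0, "P3": 0, "P4": 1, "P5": 1, "P6": 1}
        assert compare_partition(part, self.SCHEME) == pytest.approx(1.0)

    def test_single_cluster_scores_zero(self):
        part = {p: 0 for p in self.SCHEME.membership}
        assert compare_partition(part, self.SCHEME) == pytest.approx(0.0)

    def test_one_misassigned_matches_pair_count_oracle(self):
        part = {"P1": 0, "P2": 0, "P3": 1, "P4": 1, "P5": 1, "P6": 1}
        labels = sorted(part)
        expected = pair_count_ari(
            [self.SCHEME.group_of(p) for p in labels], [part[p] for p in labels]
        )
        assert compare_partition(part, self.SCHEME) == pytest.approx(expected)

    def test_unmapped_label_rejected(self):
        with pytest.raises(ValueError, match="PTFE"):
            compare_partition({"PTFE": 0, "P1": 1}, self.SCHEME)
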