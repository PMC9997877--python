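import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.cluster.hierarchy import cophenet, linkage as scipy_linkage
from scipy.spatial.distance import pdist, squareform

from dftclust import (
    DistanceMatrix,
    FeatureVector,
    LINKAGE_METHODS,
    cut_at_height,
    cut_tree,
    euclidean_distances,
    linkage,
    to_newick,
)
from oracles import brute_force_linkage


def three_leaf_matrix():
    d = np.array([[0.0, 1.0, 4.0], [1.0, 0.0, 5.0], [4.0, 5.0, 0.0]])
    return DistanceMatrix(ids=["leaf1", "leaf2", "leaf3"], d=d)


def random_distance_matrix(rng, n, integer=False):
    if integer:
        raw = rng.integers(1, 6, size=(n, n)).astype(float)
    else:
        raw = rng.random((n, n)) * 10
    d = np.triu(raw, 1)
    return d + d.T


class TestEuclideanDistances:
    def test_identical_vectors_zero(self):
        f = [FeatureVector("a", np.ones(4)), FeatureVector("b", np.ones(4))]
        assert euclidean_distances(f).d[0, 1] == 0.0

    def test_3_4_5(self):
        f = [FeatureVector("a", np.array([0.0, 0.0])),
             FeatureVector("b", np.array([3.0, 4.0]))]
        assert euclidean_distances(f).d[0, 1] == pytest.approx(5.0)

    def test_dimension_mismatch(self):
        f = [FeatureVector("a", np.ones(3)), FeatureVector("b", np.ones(4))]
        with pytest.raises(ValueError):
            euclidean_distances(f)

    @given(st.integers(0, 1000))
    @settings(derandomize=True, max_examples=20, deadline=None)
    def test_metric_properties(self, seed):
        rng = np.random.default_rng(seed)
        f = [FeatureVector(f"v{i}", rng.normal(size=6)) for i in range(6)]
        D = euclidean_distances(f).d
        assert np.allclose(D, D.T)
        for i in range(6):
            for j in range(6):
                for k in range(6):
                    assert D[i, j] <= D[i, k] + D[k, j] + 1e-9


class TestLinkage:
    @pytest.mark.parametrize(
        "method,heights",
        [
            ("single", [1.0, 4.0]),
            ("complete", [1.0, 5.0]),
            ("average", [1.0, 4.5]),
            ("median", [1.0, np.sqrt(0.5 * 16 + 0.5 * 25 - 0.25 * 1)]),
        ],
    )
    def test_three_leaf_heights(self, method, heights):
        tree = linkage(three_leaf_matrix(), method)
        assert [m.height for m in tree.merges] == pytest.approx(heights)
        assert (tree.merges[0].left, tree.merges[0].right) == (0, 1)

    @pytest.mark.parametrize("method", LINKAGE_METHODS)
    def test_two_leaves_merge_at_their_distance(self, method):
        D = DistanceMatrix(ids=["a", "b"], d=np.array([[0.0, 2.5], [2.5, 0.0]]))
        tree = linkage(D, method)
        assert len(tree.merges) == 1
        assert tree.merges[0].height == pytest.approx(2.5)

    def test_aliases(self):
        D = three_leaf_matrix()
        assert linkage(D, "UPGMA").merges == linkage(D, "average").merges
        assert linkage(D, "wpgmc").merges == linkage(D, "median").merges

    def test_unknown_method(self):
        with pytest.raises(ValueError):
            linkage(three_leaf_matrix(), "ward")

    @pytest.mark.parametrize("method", LINKAGE_METHODS)
    def test_agrees_with_bruteforce_oracle(self, method):
        """Running LW updates equal from-scratch recomputation, ties included."""
        rng = np.random.default_rng(1234)
        for trial in range(30):
            n = int(rng.integers(3, 13))
            d = random_distance_matrix(rng, n, integer=trial % 2 == 0)
            D = DistanceMatrix(ids=[f"s{i}" for i in range(n)], d=d)
            got = [(m.left, m.right, m.height, m.size) for m in linkage(D, method).merges]
            exp = brute_force_linkage(d, method)
            assert [(l, r, s) for l, r, _, s in got] == [
                (l, r, s) for l, r, _, s in exp
            ]
            np.testing.assert_allclose(
                [h for _, _, h, _ in got], [h for _, _, h, _ in exp], atol=1e-10
            )

    @pytest.mark.parametrize("method", LINKAGE_METHODS)
    def test_agrees_with_scipy_on_euclidean_points(self, method):
        """Independent library cross-check via cophenetic distances."""
        rng = np.random.default_rng(99)
        X = rng.normal(size=(15, 5))
        cond = pdist(X)
        D = DistanceMatrix(ids=[f"p{i}" for i in range(15)], d=squareform(cond))
        Z_ours = linkage(D, method).to_scipy_linkage()
        Z_ref = scipy_linkage(cond, method=method)
        np.testing.assert_allclose(
            cophenet(Z_ours), cophenet(Z_ref), rtol=1e-8, atol=1e-10
        )

    @pytest.mark.parametrize("method", ["single", "complete", "average"])
    def test_monotone_heights(self, method):
        rng = np.random.default_rng(3)
        d = random_distance_matrix(rng, 10)
        tree = linkage(DistanceMatrix(ids=[f"s{i}" for i in range(10)], d=d), method)
        h = [m.height for m in tree.merges]
        assert all(a <= b + 1e-12 for a, b in zip(h, h[1:]))

    def test_single_linkage_components_property(self):
        """Cutting a single-linkage tree at h gives components of the d<=h graph."""
        rng = np.random.default_rng(8)
        d = random_distance_matrix(rng, 12)
        D = DistanceMatrix(ids=[f"s{i}" for i in range(12)], d=d)
        tree = linkage(D, "single")
        h = np.median([m.height for m in tree.merges])
        lab = cut_at_height(tree, h)
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(12))
        for i in range(12):
            for j in range(i + 1, 12):
                if d[i, j] <= h:
                    g.add_edge(i, j)
        comps = {i: ci for ci, comp in enumerate(nx.connected_components(g)) for i in comp}
        same_ours = lab.labels[:, None] == lab.labels[None, :]
        comp_vec = np.array([comps[i] for i in range(12)])
        assert np.array_equal(same_ours, comp_vec[:, None] == comp_vec[None, :])


class TestCutTree:
    def setup_method(self):
        self.tree = linkage(three_leaf_matrix(), "single")

    def test_k_equals_n_singletons(self):
        assert cut_tree(self.tree, 3).labels.tolist() == [0, 1, 2]

    def test_k_one_single_cluster(self):
        assert cut_tree(self.tree, 1).labels.tolist() == [0, 0, 0]

    def test_k_two_pairs_first_two_leaves(self):
        assert cut_tree(self.tree, 2).labels.tolist() == [0, 0, 1]

    @pytest.mark.parametrize("k", [0, 4])
    def test_k_out_of_range(self, k):
        with pytest.raises(ValueError):
            cut_tree(self.tree, k)

    def test_partition_is_exhaustive_and_exclusive(self):
        rng = np.random.default_rng(17)
        d = random_distance_matrix(rng, 11)
        tree = linkage(DistanceMatrix(ids=[f"s{i}" for i in range(11)], d=d), "average")
        for k in range(1, 12):
            lab = cut_tree(tree, k)
            assert len(lab.labels) == 11
            assert lab.k == k


class TestNewick:
    def test_two_leaf_tree(self):
        D = DistanceMatrix(ids=["a", "b"], d=np.array([[0.0, 2.0], [2.0, 0.0]]))
        assert to_newick(linkage(D, "single")) == "(a:2,b:2);"

    def test_three_leaf_topology(self):
        nwk = to_newick(linkage(three_leaf_matrix(), "single"))
        # leaves 1 and 2 merge first: ((leaf1,leaf2),leaf3) topology
        assert nwk == "(leaf3:4,(leaf1:1,leaf2:1):3);"

    def test_roundtrip_through_dendropy(self):
        import dendropy

        rng = np.random.default_rng(23)
        d = random_distance_matrix(rng, 9)
        ids = [f"g{i}" for i in range(9)]
        tree = linkage(DistanceMatrix(ids=ids, d=d), "average")
        nwk = to_newick(tree)
        parsed = dendropy.Tree.get(data=nwk, schema="newick")
        assert sorted(t.label for t in parsed.taxon_namespace) == sorted(ids)
        # ultrametric: every leaf sits at the root height
        root_h = tree.merges[-1].height
        depths = {
            leaf.taxon.label: leaf.distance_from_root()
            for leaf in parsed.leaf_node_iter()
        }
        assert all(abs(v - root_h) < 1e-6 for v in depths.values())

    def test_metacharacter_labels_quoted(self):
        D = DistanceMatrix(
            ids=["ge ne(1)", "b:c"], d=np.array([[0.0, 1.0], [1.0, 0.0]])
        )
        nwk = to_newick(linkage(D, "single"))
        assert "'ge ne(1)':1" in nwk and "'b:c':1" in nwk

    def test_median_inversion_clamped_with_warning(self):
        # geometry chosen to force a centroid-method height inversion
        d = squareform(pdist(np.array([[0.0, 0.0], [1.0, 0.0], [0.5, 0.86]])))
        D = DistanceMatrix(ids=["a", "b", "c"], d=d)
        tree = linkage(D, "median")
        if tree.merges[1].height < tree.merges[0].height:
            with pytest.warns(UserWarning, match="clamped"):
                nwk = to_newick(tree)
            assert ":-" not in nwk
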