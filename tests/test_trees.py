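import numpy as np
import pytest

from radscape.errors import ConfigurationError, DegenerateInputError
from radscape.trees import ConstraintTree, Tree, nj_tree, rescaled_rf, study_constraint


def random_binary_tree(names, rng):
    """Random unrooted binary tree with positive branch lengths."""
    adjacency = {0: [], 1: [], 2: [], 3: []}
    leaf_names = {0: names[0], 1: names[1], 2: names[2]}

    def connect(a, b, w):
        adjacency.setdefault(a, []).append((b, w))
        adjacency.setdefault(b, []).append((a, w))

    lengths = lambda: float(rng.uniform(0.5, 3.0))
    connect(3, 0, lengths())
    connect(3, 1, lengths())
    connect(3, 2, lengths())
    next_id = 4
    for name in names[3:]:
        edges = [
            (u, v) for u, nbrs in adjacency.items() for v, _ in nbrs if u < v
        ]
        u, v = edges[rng.integers(len(edges))]
        w_uv = dict(adjacency[u])[v]
        adjacency[u] = [(x, w) for x, w in adjacency[u] if x != v]
        adjacency[v] = [(x, w) for x, w in adjacency[v] if x != u]
        mid, leaf = next_id, next_id + 1
        next_id += 2
        split = float(rng.uniform(0.2, 0.8)) * w_uv
        connect(u, mid, split)
        connect(mid, v, w_uv - split)
        connect(mid, leaf, lengths())
        leaf_names[leaf] = name
    return Tree(adjacency, leaf_names)


def networkx_splits(tree: Tree):
    """Independent split enumeration through networkx edge removal."""
    import networkx as nx

    g = nx.Graph()
    for u, nbrs in tree.adjacency.items():
        for v, _ in nbrs:
            g.add_edge(u, v)
    anchor = min(tree.leaves)
    n = len(tree.leaves)
    splits = set()
    for u, v in list(g.edges()):
        h = g.copy()
        h.remove_edge(u, v)
        comp = next(c for c in __import__("networkx").connected_components(h) if v in c)
        side = {tree.leaf_names[x] for x in comp if x in tree.leaf_names}
        if len(side) < 2 or len(side) > n - 2:
            continue
        if anchor in side:
            side = set(tree.leaves) - side
        splits.add(frozenset(side))
    return splits


class TestNeighborJoining:
    @pytest.mark.parametrize("n_taxa", [4, 5, 6, 7, 8])
    def test_additive_matrix_recovers_generating_tree(self, n_taxa, rng):
        names = [f"t{i}" for i in range(n_taxa)]
        for rep in range(5):
            true = random_binary_tree(names, rng)
            D = true.distance_matrix(names)
            est = nj_tree(D, names)
            assert est.splits() == true.splits()
            np.testing.assert_allclose(est.distance_matrix(names), D, atol=1e-9)

    def test_three_taxon_star(self):
        D = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
        t = nj_tree(D, ["a", "b", "c"])
        assert t.splits() == set()
        assert t.branch_length("a", "b") == pytest.approx(3.0)
        # forced lengths: l_a = (3+4-5)/2 = 1
        center = t.adjacency[0][0][0]
        assert dict(t.adjacency[center])[0] == pytest.approx(1.0)

    def test_taxon_order_invariance(self, rng):
        names = [f"t{i}" for i in range(7)]
        true = random_binary_tree(names, rng)
        D = true.distance_matrix(names)
        t1 = nj_tree(D, names)
        perm = rng.permutation(7)
        D2 = D[np.ix_(perm, perm)]
        t2 = nj_tree(D2, [names[i] for i in perm])
        assert t1.splits() == t2.splits()

    def test_matches_scikit_bio_on_noisy_matrices(self, rng):
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj

        names = [f"t{i}" for i in range(6)]
        for rep in range(5):
            true = random_binary_tree(names, rng)
            D = true.distance_matrix(names)
            noise = rng.uniform(0.98, 1.02, size=D.shape)
            D = D * (noise + noise.T) / 2
            np.fill_diagonal(D, 0.0)
            mine = nj_tree(D, names)
            other = skbio_nj(DistanceMatrix(D, names))
            other_splits = set()
            anchor = min(names)
            for node in other.non_tips():
                side = {t.name for t in node.tips()}
                if 2 <= len(side) <= len(names) - 2:
                    if anchor in side:
                        side = set(names) - side
                    other_splits.add(frozenset(side))
            assert mine.splits() == other_splits

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ConfigurationError):
            nj_tree(np.zeros((2, 2)), ["a", "b"])


class TestRescaledRF:
    def ref(self, tree, k_clades):
        return ConstraintTree(tree.leaves, tuple(k_clades))

    def test_all_reference_splits_present_gives_zero(self, rng):
        names = [f"t{i}" for i in range(8)]
        tree = random_binary_tree(names, rng)
        clades = list(tree.splits())[:3]
        assert rescaled_rf(tree, self.ref(tree, clades)) == 0.0

    def test_no_shared_splits_gives_one(self):
        names = [f"t{i}" for i in range(6)]
        rng = np.random.default_rng(1)
        tree = random_binary_tree(names, rng)
        # a clade that is no split of a binary tree drawn on a caterpillar:
        # find any 2-subset not in the tree's splits
        import itertools

        for pair in itertools.combinations(names, 2):
            if frozenset(pair) not in tree.splits() and names[0] not in pair:
                ref = self.ref(tree, [frozenset(pair)])
                assert rescaled_rf(tree, ref) == 1.0
                return
        pytest.skip("tree contained every cherry")

    def test_study_sized_example_half_distance(self):
        # 17 leaves, 4 reference splits, test tree carrying exactly 2 of them:
        # d = (14 - 2) + (4 - 2) = 14, rescaled (14 - 10)/(18 - 10) = 0.5
        bf = [f"BF{i:03d}" for i in range(1, 11)]
        mc = ["MC001", "MC002"]
        py = ["PY001", "PY002"]
        cm = ["CM001", "CM002", "CM003"]

        def caterpillar(ids, leaves, next_id):
            # returns (root_id, adjacency edges) joining leaves left-to-right
            edges = []
            cur = leaves[0]
            for leaf in leaves[1:]:
                node = next_id[0]
                next_id[0] += 1
                edges += [(node, cur), (node, leaf)]
                cur = node
            return cur, edges

        ids = {}
        for i, name in enumerate(bf + mc + py + cm):
            ids[name] = i
        next_id = [17]
        adjacency = {}

        def connect(a, b):
            adjacency.setdefault(a, []).append((b, 1.0))
            adjacency.setdefault(b, []).append((a, 1.0))

        bf_root, bf_edges = caterpillar(ids, [ids[x] for x in bf], next_id)
        for a, b in bf_edges:
            connect(a, b)
        py_node = next_id[0]
        next_id[0] += 1
        connect(py_node, ids["PY001"])
        connect(py_node, ids["PY002"])
        # chain breaking CM and the south clade: CM1,(MC1,(CM2,(MC2,CM3)))
        chain_spec = [
            ids["CM001"], ids["MC001"], ids["CM002"], ids["MC002"], ids["CM003"]
        ]
        cur = chain_spec[-1]
        for leaf in reversed(chain_spec[:-1]):
            node = next_id[0]
            next_id[0] += 1
            connect(node, cur)
            connect(node, leaf)
            cur = node
        top = next_id[0]
        next_id[0] += 1
        connect(top, bf_root)
        connect(top, py_node)
        connect(top, cur)
        tree = Tree(adjacency, {v: k for k, v in ids.items()})

        ref = ConstraintTree(
            tree.leaves,
            (frozenset(bf), frozenset(py), frozenset(cm), frozenset(py + cm)),
        )
        assert len(tree.splits()) == 14
        assert len(tree.splits() & ref.splits()) == 2
        assert rescaled_rf(tree, ref) == pytest.approx(0.5)

    def test_matches_independent_split_enumeration(self, rng):
        for n in (4, 5, 6, 7, 8):
            names = [f"t{i}" for i in range(n)]
            for rep in range(4):
                tree = random_binary_tree(names, rng)
                other = random_binary_tree(names, rng)
                clades = [set(s) for s in list(other.splits())[:2]]
                if not clades:
                    continue
                ref = ConstraintTree(tree.leaves, tuple(frozenset(c) for c in clades))
                t_splits = networkx_splits(tree)
                d = len(t_splits ^ ref.splits())
                b, k = len(t_splits), len(ref.splits())
                expected = (d - (b - k)) / (2 * k)
                assert rescaled_rf(tree, ref) == pytest.approx(expected)

    def test_leaf_mismatch_rejected(self, rng):
        t1 = random_binary_tree(["a", "b", "c", "d"], rng)
        ref = ConstraintTree(frozenset("wxyz"), (frozenset("wx"),))
        with pytest.raises(ConfigurationError):
            rescaled_rf(t1, ref)

    def test_star_reference_degenerate(self, rng):
        t1 = random_binary_tree(["a", "b", "c", "d"], rng)
        ref = ConstraintTree(t1.leaves, ())
        with pytest.raises(DegenerateInputError):
            rescaled_rf(t1, ref)


class TestConstraintTree:
    def test_study_constraint_has_four_splits(self):
        from radscape.simulate import rad_study_design

        pm = rad_study_design().popmap()
        ref = study_constraint(pm)
        assert len(ref.splits()) == 4

    def test_incompatible_clades_rejected(self):
        with pytest.raises(ConfigurationError):
            ConstraintTree(frozenset("abcde"), (frozenset("abc"), frozenset("bcd")))

    def test_restrict_drops_trivial_clades(self):
        ref = ConstraintTree(frozenset("abcdef"), (frozenset("ab"), frozenset("abcd")))
        sub = ref.restrict(frozenset("abef"))
        assert frozenset("ab") in sub.clades
        assert len(sub.clades) == 1
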