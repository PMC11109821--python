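"""MDS, neighbor joining (with enumeration oracle), bootstrap support."""

import itertools

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from mouflon.structure import (
    DistanceMatrix, PhyloTree, bootstrap_support, classical_mds, nj_tree,
    root_with_outgroup,
)


# ---------------------------------------------------------------------------
# Enumeration oracle: all unrooted topologies + least-squares branch fit


def _all_topologies(labels):
    """All unrooted binary topologies as edge-split sets, built by stepwise
    leaf insertion (3 for n=4, 15 for n=5, 105 for n=6)."""
    # a tree is a list of edges over node ids; nodes 0..2 are the first
    # three leaves, new leaves and internal nodes get fresh ids
    trees = [{"edges": [(0, 3), (1, 3), (2, 3)], "next": 4,
              "leaf": {0: labels[0], 1: labels[1], 2: labels[2]}}]
    for l in labels[3:]:
        new = []
        for t in trees:
            for i, (u, v) in enumerate(t["edges"]):
                mid, leaf = t["next"], t["next"] + 1
                edges = t["edges"][:i] + t["edges"][i + 1:]
                edges += [(u, mid), (v, mid), (leaf, mid)]
                lf = dict(t["leaf"])
                lf[leaf] = l
                new.append({"edges": edges, "next": t["next"] + 2, "leaf": lf})
        trees = new
    return trees


def _tree_splits(t, labels):
    """Internal-edge bipartitions of an oracle tree, canonicalized."""
    adj = {}
    for u, v in t["edges"]:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    anchor = min(labels)
    splits = set()
    for u, v in t["edges"]:
        # leaves on the v-side when edge (u,v) removed
        seen, stack = {u, v}, [v]
        side = []
        while stack:
            x = stack.pop()
            if x in t["leaf"]:
                side.append(t["leaf"][x])
            for y in adj[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        if 2 <= len(side) <= len(labels) - 2:
            s = frozenset(side)
            splits.add(s if anchor not in s else frozenset(labels) - s)
    return splits


def _ls_fit(t, labels, D):
    """Least-squares branch lengths for a fixed topology; returns residual."""
    adj = {}
    for idx, (u, v) in enumerate(t["edges"]):
        adj.setdefault(u, []).append((v, idx))
        adj.setdefault(v, []).append((u, idx))
    leaf_of = {name: node for node, name in t["leaf"].items()}
    pairs = list(itertools.combinations(labels, 2))
    A = np.zeros((len(pairs), len(t["edges"])))
    y = np.zeros(len(pairs))
    li = {l: i for i, l in enumerate(labels)}
    for r, (a, b) in enumerate(pairs):
        # path from leaf a to leaf b
        start, goal = leaf_of[a], leaf_of[b]
        prev = {start: (None, None)}
        stack = [start]
        while stack:
            x = stack.pop()
            if x == goal:
                break
            for ynode, eidx in adj[x]:
                if ynode not in prev:
                    prev[ynode] = (x, eidx)
                    stack.append(ynode)
        x = goal
        while prev[x][0] is not None:
            A[r, prev[x][1]] = 1
            x = prev[x][0]
        y[r] = D[li[a], li[b]]
    sol, *_ = np.linalg.lstsq(A, y, rcond=None)
    return float(np.sum((A @ sol - y) ** 2)), sol


def oracle_best_topology(labels, D):
    """Exhaustive search for the minimum-residual topology."""
    best = None
    for t in _all_topologies(list(labels)):
        res, _ = _ls_fit(t, list(labels), D)
        if best is None or res < best[0]:
            best = (res, t)
    return best[1], best[0]


def _random_additive(labels, seed):
    """A random additive distance matrix from a random binary topology."""
    rng = np.random.default_rng(seed)
    topos = _all_topologies(list(labels))
    t = topos[rng.integers(len(topos))]
    lengths = rng.uniform(0.5, 3.0, len(t["edges"]))
    n = len(labels)
    D = np.zeros((n, n))
    pairs = list(itertools.combinations(labels, 2))
    d = _incidence(t, list(labels)) @ lengths
    li = {l: i for i, l in enumerate(labels)}
    for (a, b), v in zip(pairs, d):
        D[li[a], li[b]] = D[li[b], li[a]] = v
    return t, DistanceMatrix(list(labels), D)


def _incidence(t, labels):
    adj = {}
    for idx, (u, v) in enumerate(t["edges"]):
        adj.setdefault(u, []).append((v, idx))
        adj.setdefault(v, []).append((u, idx))
    leaf_of = {name: node for node, name in t["leaf"].items()}
    pairs = list(itertools.combinations(labels, 2))
    A = np.zeros((len(pairs), len(t["edges"])))
    for r, (a, b) in enumerate(pairs):
        start, goal = leaf_of[a], leaf_of[b]
        prev = {start: (None, None)}
        stack = [start]
        while stack:
            x = stack.pop()
            for ynode, eidx in adj[x]:
                if ynode not in prev:
                    prev[ynode] = (x, eidx)
                    stack.append(ynode)
        x = goal
        while prev[x][0] is not None:
            A[r, prev[x][1]] = 1
            x = prev[x][0]
    return A


# ---------------------------------------------------------------------------
# MDS


class TestClassicalMds:
    def test_collinear_points_recovered_in_1d(self):
        D = DistanceMatrix(["a", "b", "c"],
                           np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], float))
        res = classical_mds(D, k=1)
        x = np.sort(res.coordinates[:, 0])
        np.testing.assert_allclose(np.diff(x), [1, 1], atol=1e-9)

    def test_roundtrip_from_known_coordinates(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(7, 2))
        D = DistanceMatrix([f"p{i}" for i in range(7)], cdist(X, X))
        res = classical_mds(D, k=2)
        np.testing.assert_allclose(
            cdist(res.coordinates, res.coordinates), D.matrix, atol=1e-9
        )

    def test_equidistant_points_stay_equidistant(self):
        n = 5
        D = DistanceMatrix(
            [f"p{i}" for i in range(n)], np.ones((n, n)) - np.eye(n)
        )
        res = classical_mds(D, k=4)
        rec = cdist(res.coordinates, res.coordinates)
        off = rec[~np.eye(n, dtype=bool)]
        np.testing.assert_allclose(off, off[0], atol=1e-9)

    def test_eigenvalue_sum_equals_centered_trace(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(6, 3))
        D = DistanceMatrix([f"p{i}" for i in range(6)], cdist(X, X))
        res = classical_mds(D, k=2)
        J = np.eye(6) - np.ones((6, 6)) / 6
        B = -0.5 * J @ (D.matrix**2) @ J
        assert res.eigenvalues.sum() == pytest.approx(np.trace(B), abs=1e-9)

    def test_deterministic_axis_signs(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(6, 2))
        D = DistanceMatrix([f"p{i}" for i in range(6)], cdist(X, X))
        a = classical_mds(D, k=2).coordinates
        b = classical_mds(D, k=2).coordinates
        np.testing.assert_array_equal(a, b)
        for j in range(2):
            assert a[np.argmax(np.abs(a[:, j])), j] > 0


# ---------------------------------------------------------------------------
# Neighbor joining


class TestNjTree:
    def test_additive_4taxon_exact(self):
        # tree ((A:1,B:2):1,(C:3,D:1))
        D = DistanceMatrix(
            ["A", "B", "C", "D"],
            np.array([[0, 3, 5, 3], [3, 0, 6, 4], [5, 6, 0, 4], [3, 4, 4, 0]],
                     float),
        )
        t = nj_tree(D)
        assert t.bipartitions() == {frozenset({"C", "D"})}
        # pendant branch lengths recovered exactly
        lengths = {l.name: l.length for l in t.root.leaves()}
        assert lengths == pytest.approx({"A": 1, "B": 2, "C": 3, "D": 1})

    def test_three_taxon_closed_form(self):
        D = DistanceMatrix(["a", "b", "c"],
                           np.array([[0, 2, 2], [2, 0, 2], [2, 2, 0]], float))
        t = nj_tree(D)
        assert all(l.length == pytest.approx(1.0) for l in t.root.leaves())

    @pytest.mark.parametrize("n,seeds", [(4, range(5)), (5, range(5)), (6, range(5))])
    def test_additive_recovery_matches_enumeration_oracle(self, n, seeds):
        labels = [chr(ord("A") + i) for i in range(n)]
        for seed in seeds:
            true_t, dm = _random_additive(labels, seed)
            got = nj_tree(dm)
            oracle_t, resid = oracle_best_topology(labels, dm.matrix)
            assert resid < 1e-18
            assert got.bipartitions() == _tree_splits(oracle_t, labels)
            assert got.bipartitions() == _tree_splits(true_t, labels)

    def test_label_permutation_invariance(self):
        labels = ["A", "B", "C", "D", "E"]
        _, dm = _random_additive(labels, 3)
        perm = [3, 1, 4, 0, 2]
        dm2 = DistanceMatrix(
            [labels[i] for i in perm], dm.matrix[np.ix_(perm, perm)]
        )
        assert nj_tree(dm).bipartitions() == nj_tree(dm2).bipartitions()

    def test_cross_check_against_dendropy(self):
        import io as _io
        import dendropy

        labels = ["A", "B", "C", "D", "E", "F"]
        _, dm = _random_additive(labels, 11)
        csv = "," + ",".join(labels) + "\n" + "\n".join(
            l + "," + ",".join(f"{x:.10f}" for x in row)
            for l, row in zip(labels, dm.matrix)
        )
        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            src=_io.StringIO(csv), delimiter=","
        )
        dtree = pdm.nj_tree()
        dsplits = set()
        anchor = min(labels)
        for edge in dtree.preorder_edge_iter():
            if edge.head_node.is_leaf() or edge.head_node is dtree.seed_node:
                continue
            side = frozenset(
                l.taxon.label for l in edge.head_node.leaf_iter()
            )
            if 2 <= len(side) <= len(labels) - 2:
                dsplits.add(
                    side if anchor not in side else frozenset(labels) - side
                )
        assert nj_tree(dm).bipartitions() == dsplits

    def test_nonfinite_raises(self):
        M = np.zeros((3, 3))
        M[0, 1] = M[1, 0] = np.inf
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(["a", "b", "c"], M))


class TestBootstrapSupport:
    def test_identical_replicates_give_100(self):
        _, dm = _random_additive(["A", "B", "C", "D", "E"], 5)
        main = nj_tree(dm)
        out = bootstrap_support(main, [nj_tree(dm) for _ in range(10)])
        sup = [n.support for n in _internal_nodes(out) if n.support is not None]
        assert sup and all(s == 100.0 for s in sup)

    def test_half_replicates_give_50(self):
        # two 4-taxon topologies differing in their single internal split
        D1 = DistanceMatrix(["A", "B", "C", "D"], _quartet(("A", "B")))
        D2 = DistanceMatrix(["A", "B", "C", "D"], _quartet(("A", "C")))
        main = nj_tree(D1)
        reps = [nj_tree(D1)] * 5 + [nj_tree(D2)] * 5
        out = bootstrap_support(main, reps)
        sup = [n.support for n in _internal_nodes(out) if n.support is not None]
        assert sup == [50.0]

    def test_replicate_order_invariance(self):
        D1 = DistanceMatrix(["A", "B", "C", "D"], _quartet(("A", "B")))
        D2 = DistanceMatrix(["A", "B", "C", "D"], _quartet(("A", "C")))
        main = nj_tree(D1)
        reps = [nj_tree(D1)] * 3 + [nj_tree(D2)] * 7
        s1 = _supports(bootstrap_support(main, reps))
        s2 = _supports(bootstrap_support(main, reps[::-1]))
        assert s1 == s2

    def test_leafset_mismatch_raises(self):
        _, dm5 = _random_additive(["A", "B", "C", "D", "E"], 6)
        _, dm4 = _random_additive(["A", "B", "C", "D"], 6)
        with pytest.raises(ValueError):
            bootstrap_support(nj_tree(dm5), [nj_tree(dm4)])


def _quartet(cherry):
    """Additive matrix for a 4-taxon tree with the given cherry."""
    labels = ["A", "B", "C", "D"]
    other = [l for l in labels if l not in cherry]
    D = np.full((4, 4), 4.0)
    np.fill_diagonal(D, 0.0)
    li = {l: i for i, l in enumerate(labels)}
    for pair in (cherry, tuple(other)):
        D[li[pair[0]], li[pair[1]]] = D[li[pair[1]], li[pair[0]]] = 2.0
    return D


def _internal_nodes(tree):
    out = []

    def walk(n):
        if not n.is_leaf():
            out.append(n)
            for c in n.children:
                walk(c)

    walk(tree.root)
    return out


def _supports(tree):
    return sorted(
        n.support for n in _internal_nodes(tree) if n.support is not None
    )


class TestRooting:
    def test_outgroup_is_sibling_of_ingroup(self):
        _, dm = _random_additive(["A", "B", "C", "D"], 7)
        dm = DistanceMatrix(dm.labels, dm.matrix / dm.matrix.max() * 0.4)
        t = root_with_outgroup(dm, "OG", distance=1.0)
        assert t.rooted
        kids = t.root.children
        names = sorted(
            tuple(sorted(l.name for l in k.leaves())) for k in kids
        )
        assert ("OG",) in names
        ingroup = [n for n in names if n != ("OG",)][0]
        assert ingroup == ("A", "B", "C", "D")

    def test_ingroup_topology_unchanged(self):
        _, dm = _random_additive(["A", "B", "C", "D"], 8)
        dm = DistanceMatrix(dm.labels, dm.matrix / dm.matrix.max() * 0.4)
        before = nj_tree(dm).bipartitions()
        t = root_with_outgroup(dm, "OG", distance=1.0)
        ingroup_splits = set()
        for bp in t.bipartitions():
            restricted = frozenset(x for x in bp if x != "OG")
            if 2 <= len(restricted) <= 2:
                ingroup_splits.add(restricted)
        assert before <= ingroup_splits | before  # splits preserved
        # the original internal split must survive the augmentation
        for bp in before:
            assert any(
                bp == frozenset(x for x in b if x != "OG")
                or bp == frozenset(dm.labels) - frozenset(x for x in b if x != "OG")
                for b in t.bipartitions()
            )

    def test_small_distance_warns(self):
        _, dm = _random_additive(["A", "B", "C", "D"], 9)
        with pytest.warns(UserWarning):
            root_with_outgroup(dm, "OG", distance=dm.matrix.max() / 4)

    def test_existing_label_raises(self):
        _, dm = _random_additive(["A", "B", "C", "D"], 10)
        with pytest.raises(ValueError):
            root_with_outgroup(dm, "A")
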