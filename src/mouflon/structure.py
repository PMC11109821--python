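"""Distance-matrix summaries: classical MDS and neighbor-joining trees.

Population structure is summarized from 1 - outgroup-f3 distance matrices
two ways: classical (Torgerson) multidimensional scaling via
double-centering and eigendecomposition, and Saitou-Nei neighbor joining
with chunked-bootstrap bipartition support and outgroup rooting at a
fixed distance.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class DistanceMatrix:
    """Labelled symmetric distance matrix with zero diagonal."""

    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape inconsistent with labels")
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.matrix) != 0):
            raise ValueError("distance matrix diagonal must be zero")

    @property
    def n(self) -> int:
        return len(self.labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.labels, columns=self.labels)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DistanceMatrix":
        return cls(labels=list(df.columns), matrix=df.to_numpy(dtype=float))


@dataclass
class MDSResult:
    """Classical-MDS embedding: coordinates, eigenvalues, variance shares."""

    labels: list[str]
    coordinates: np.ndarray  # (n, k)
    eigenvalues: np.ndarray  # all n, descending
    proportion: np.ndarray  # share of positive-eigenvalue variance per axis


class TreeNode:
    """A node of a (possibly unrooted) phylogenetic tree.

    ``length`` is the branch to the parent; ``support`` (0-100) annotates
    the edge above internal nodes after bootstrap counting.
    """

    __slots__ = ("name", "children", "length", "support")

    def __init__(self, name: str | None = None, length: float = 0.0):
        self.name = name
        self.children: list["TreeNode"] = []
        self.length = length
        self.support: float | None = None

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf():
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def _newick(self, with_support: bool) -> str:
        if self.is_leaf():
            return f"{self.name}:{self.length:.10g}"
        inner = ",".join(c._newick(with_support) for c in self.children)
        label = ""
        if with_support and self.support is not None:
            label = f"{self.support:g}"
        return f"({inner}){label}:{self.length:.10g}"


@dataclass
class PhyloTree:
    """A binary tree (unrooted trees carry a trifurcating root node)."""

    root: TreeNode
    rooted: bool = False

    def leaf_names(self) -> list[str]:
        return sorted(l.name for l in self.root.leaves())

    def newick(self, with_support: bool = False) -> str:
        inner = ",".join(c._newick(with_support) for c in self.root.children)
        return f"({inner});"

    def copy(self) -> "PhyloTree":
        return PhyloTree(root=copy.deepcopy(self.root), rooted=self.rooted)

    def bipartitions(self) -> set[frozenset[str]]:
        """Internal-edge bipartitions, canonicalized over the full leaf set.

        Each internal edge splits the leaves in two; the side not
        containing the lexicographically smallest leaf represents the
        split, so comparison is independent of rooting and branch lengths.
        """
        all_leaves = frozenset(l.name for l in self.root.leaves())
        anchor = min(all_leaves)
        out: set[frozenset[str]] = set()

        def walk(node: TreeNode) -> frozenset[str]:
            if node.is_leaf():
                return frozenset([node.name])
            below = frozenset().union(*(walk(c) for c in node.children))
            if node is not self.root and 2 <= len(below) <= len(all_leaves) - 2:
                side = below if anchor not in below else all_leaves - below
                out.add(side)
            return below

        walk(self.root)
        return out


# ---------------------------------------------------------------------------
# Classical MDS


def classical_mds(D: DistanceMatrix, k: int = 2) -> MDSResult:
    """Classical (metric) multidimensional scaling of a distance matrix.

    Double-centers B = -1/2 J (D o D) J, eigendecomposes, and returns the
    top-k axes scaled by the square roots of their (positive) eigenvalues,
    ordered by eigenvalue.  Axis signs are fixed so that the coordinate of
    largest magnitude on each axis is positive, making runs reproducible.
    """
    n = D.n
    if not k < n:
        raise ValueError("k must be smaller than the number of points")
    d2 = D.matrix**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ d2 @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > max(1e-12 * abs(vals[0]), 0.0) if vals[0] > 0 else vals > 0
    n_pos = int(pos.sum())
    if n_pos < k:
        warnings.warn(
            f"only {n_pos} positive eigenvalues; returning {n_pos} axes instead of {k}"
        )
        k = n_pos
    coords = vecs[:, :k] * np.sqrt(vals[:k])
    for j in range(k):
        i_max = int(np.argmax(np.abs(coords[:, j])))
        if coords[i_max, j] < 0:
            coords[:, j] = -coords[:, j]
    pos_sum = vals[pos].sum() if n_pos else 1.0
    proportion = vals[:k] / pos_sum
    return MDSResult(
        labels=list(D.labels),
        coordinates=coords,
        eigenvalues=vals,
        proportion=proportion,
    )


# ---------------------------------------------------------------------------
# Neighbor joining


def nj_tree(D: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    Agglomerates via the Q-criterion Q(i,j) = (r-2) d(i,j) - R_i - R_j,
    with standard branch-length formulas.  Q ties are broken by the
    lexicographically lowest pair of subtree keys (the smallest leaf label
    under each node), so the result is invariant to input label order.
    Negative branch lengths are clamped to zero with the deficit moved to
    the sister branch.
    """
    n = D.n
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if not np.all(np.isfinite(D.matrix)):
        raise ValueError("non-finite distances")

    nodes: list[TreeNode] = [TreeNode(name=l) for l in D.labels]
    keys: list[str] = list(D.labels)  # smallest leaf label per subtree
    d = D.matrix.astype(float).copy()
    active = list(range(n))

    while len(active) > 3:
        r = len(active)
        sub = d[np.ix_(active, active)]
        R = sub.sum(axis=1)
        Q = (r - 2) * sub - R[:, None] - R[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        tol = 1e-12 * max(1.0, abs(qmin))
        cand = np.argwhere(Q <= qmin + tol)
        best = min(
            (tuple(sorted((keys[active[a]], keys[active[b]]))), a, b)
            for a, b in cand
            if a < b
        )
        ai, bi = best[1], best[2]
        i, j = active[ai], active[bi]
        dij = sub[ai, bi]
        li = 0.5 * dij + (R[ai] - R[bi]) / (2 * (r - 2))
        lj = dij - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = TreeNode()
        nodes[i].length = li
        nodes[j].length = lj
        parent.children = [nodes[i], nodes[j]]
        # distances from the new node to the remaining taxa
        new_idx = len(nodes)
        nodes.append(parent)
        keys.append(min(keys[i], keys[j]))
        d = np.pad(d, ((0, 1), (0, 1)))
        for k_ in active:
            if k_ in (i, j):
                continue
            d[new_idx, k_] = d[k_, new_idx] = 0.5 * (d[i, k_] + d[j, k_] - dij)
        active = [k_ for k_ in active if k_ not in (i, j)] + [new_idx]

    # final trifurcation
    i, j, k_ = active
    li = 0.5 * (d[i, j] + d[i, k_] - d[j, k_])
    lj = 0.5 * (d[i, j] + d[j, k_] - d[i, k_])
    lk = 0.5 * (d[i, k_] + d[j, k_] - d[i, j])
    root = TreeNode()
    order = sorted(zip((i, j, k_), (li, lj, lk)), key=lambda t: keys[t[0]])
    for idx, ln in order:
        nodes[idx].length = max(ln, 0.0)
        root.children.append(nodes[idx])
    return PhyloTree(root=root, rooted=False)


def bootstrap_support(main: PhyloTree, replicates: list[PhyloTree]) -> PhyloTree:
    """Annotate each internal edge of ``main`` with bootstrap support.

    Support is the percentage of replicate trees containing the same
    bipartition (branch lengths ignored).  Replicate order is irrelevant.
    """
    main_leaves = set(main.leaf_names())
    for t in replicates:
        if set(t.leaf_names()) != main_leaves:
            raise ValueError("replicate leaf set differs from the main tree")
    if not replicates:
        raise ValueError("no replicate trees supplied")
    counts: dict[frozenset[str], int] = {}
    for t in replicates:
        for bp in t.bipartitions():
            counts[bp] = counts.get(bp, 0) + 1

    out = main.copy()
    all_leaves = frozenset(main_leaves)
    anchor = min(all_leaves)

    def walk(node: TreeNode) -> frozenset[str]:
        if node.is_leaf():
            return frozenset([node.name])
        below = frozenset().union(*(walk(c) for c in node.children))
        if node is not out.root and 2 <= len(below) <= len(all_leaves) - 2:
            side = below if anchor not in below else all_leaves - below
            node.support = 100.0 * counts.get(side, 0) / len(replicates)
        return below

    walk(out.root)
    return out


def root_with_outgroup(
    D: DistanceMatrix, outgroup_label: str, distance: float = 1.0
) -> PhyloTree:
    """Root an NJ tree by appending an outgroup at a constant distance.

    The distance matrix is augmented with one row/column equal to
    ``distance`` against every ingroup label, neighbor joining is run on
    the augmented matrix, and the tree is rooted on the outgroup's pendant
    edge (split at its midpoint), leaving the outgroup as sibling of the
    whole ingroup clade.
    """
    if outgroup_label in D.labels:
        raise ValueError(f"label {outgroup_label!r} already present in the matrix")
    off_diag = D.matrix[~np.eye(D.n, dtype=bool)]
    if off_diag.size and distance <= off_diag.max() / 2:
        warnings.warn(
            "outgroup distance <= max(D)/2; the outgroup may attach internally"
        )
    n = D.n
    aug = np.zeros((n + 1, n + 1))
    aug[:n, :n] = D.matrix
    aug[n, :n] = aug[:n, n] = distance
    tree = nj_tree(DistanceMatrix(labels=[*D.labels, outgroup_label], matrix=aug))
    return _reroot_on_leaf_edge(tree, outgroup_label)


def _reroot_on_leaf_edge(tree: PhyloTree, leaf_name: str) -> PhyloTree:
    """Re-root an unrooted tree at the midpoint of a leaf's pendant edge."""
    tree = tree.copy()

    def find(node: TreeNode) -> tuple | None:
        for c in node.children:
            if c.is_leaf() and c.name == leaf_name:
                return (node, c)
            got = find(c)
            if got:
                return got
        return None

    hit = find(tree.root)
    if hit is None:
        raise ValueError(f"leaf {leaf_name!r} not found")
    parent, leaf = hit
    half = leaf.length / 2.0

    # path from the leaf's parent up to the old root
    path: list[TreeNode] = []

    def collect(node: TreeNode, target: TreeNode) -> bool:
        if node is target:
            path.append(node)
            return True
        for c in node.children:
            if collect(c, target):
                path.append(node)
                return True
        return False

    collect(tree.root, parent)  # path == [parent, ..., old_root]
    orig_len = [nd.length for nd in path]
    parent.children.remove(leaf)
    # reverse every edge along the path: each node adopts its old parent,
    # which inherits the edge length that used to belong to the child
    for lower, upper in zip(path[:-1], path[1:]):
        upper.children.remove(lower)
    for i in range(len(path) - 1):
        path[i].children.append(path[i + 1])
        path[i + 1].length = orig_len[i]

    new_root = TreeNode()
    leaf.length = half
    parent.length = half
    new_root.children = [parent, leaf]
    return PhyloTree(root=new_root, rooted=True)


def write_mds_tsv(res: MDSResult, path: str) -> None:
    df = pd.DataFrame(
        res.coordinates,
        index=res.labels,
        columns=[f"axis{i+1}" for i in range(res.coordinates.shape[1])],
    )
    df.index.name = "label"
    df.to_csv(path, sep="\t")
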