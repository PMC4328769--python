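"""Unrooted trees: neighbor-joining, splits, and rescaled Robinson-Foulds.

The topology-saturation diagnostic compares neighbor-joining trees built
from locus subsamples against a partially resolved reference (constraint)
tree.  The symmetric-difference (Robinson-Foulds) count between the test
tree's nontrivial splits and the reference's splits is rescaled to [0, 1]
using its theoretical extremes for that reference: a binary test tree with
b = n-3 nontrivial splits can share at most all k reference splits
(d_min = b - k) or none (d_max = b + k).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, DegenerateInputError


class Tree:
    """Unrooted tree over named leaves (adjacency with branch lengths)."""

    def __init__(
        self,
        adjacency: dict[int, list[tuple[int, float]]],
        leaf_names: dict[int, str],
    ) -> None:
        self.adjacency = adjacency
        self.leaf_names = leaf_names

    @property
    def leaves(self) -> frozenset:
        return frozenset(self.leaf_names.values())

    def _side(self, u: int, v: int) -> set:
        """Leaf names reachable from v without crossing edge (u, v)."""
        seen, stack, names = {u, v}, [v], set()
        while stack:
            x = stack.pop()
            if x in self.leaf_names:
                names.add(self.leaf_names[x])
            for y, _ in self.adjacency[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        return names

    def splits(self) -> set:
        """Nontrivial bipartitions, each normalized to the side that does
        not contain the lexicographically smallest leaf."""
        anchor = min(self.leaves)
        n = len(self.leaves)
        out = set()
        seen_edges = set()
        for u, nbrs in self.adjacency.items():
            for v, _ in nbrs:
                if (v, u) in seen_edges:
                    continue
                seen_edges.add((u, v))
                side = self._side(u, v)
                if len(side) < 2 or len(side) > n - 2:
                    continue
                if anchor in side:
                    side = set(self.leaves) - side
                out.add(frozenset(side))
        return out

    def branch_length(self, name_a: str, name_b: str) -> float:
        """Path length between two leaves (for additive-matrix checks)."""
        ids = {v: k for k, v in self.leaf_names.items()}
        start, goal = ids[name_a], ids[name_b]
        dist = {start: 0.0}
        stack = [start]
        while stack:
            x = stack.pop()
            if x == goal:
                return dist[x]
            for y, w in self.adjacency[x]:
                if y not in dist:
                    dist[y] = dist[x] + w
                    stack.append(y)
        raise ConfigurationError("leaves not connected")

    def distance_matrix(self, order: list[str]) -> np.ndarray:
        n = len(order)
        out = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                out[i, j] = out[j, i] = self.branch_length(order[i], order[j])
        return out

    def newick(self) -> str:
        # root at the neighbour of the first leaf id for a stable layout
        leaf_ids = sorted(self.leaf_names)
        root = self.adjacency[leaf_ids[0]][0][0]

        def render(u: int, parent: int | None) -> str:
            children = [(v, w) for v, w in self.adjacency[u] if v != parent]
            if not children:
                return self.leaf_names[u]
            inner = ",".join(f"{render(v, u)}:{w:.6g}" for v, w in children)
            return f"({inner})"

        return render(root, None) + ";"


def nj_tree(distance_matrix: np.ndarray, names: list[str]) -> Tree:
    """Saitou-Nei neighbor joining; ties in the Q-matrix break toward the
    smallest (row, column) index pair.  Requires n >= 3 taxa."""
    D = np.asarray(distance_matrix, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n) or len(names) != n:
        raise ConfigurationError("distance matrix and name list disagree")
    if n < 3:
        raise ConfigurationError("neighbor joining needs at least 3 taxa")
    if not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0.0):
        raise ConfigurationError("distance matrix must be symmetric with zero diagonal")
    if not np.all(np.isfinite(D)):
        raise ConfigurationError("distance matrix contains non-finite entries")

    adjacency: dict[int, list[tuple[int, float]]] = {i: [] for i in range(n)}
    leaf_names = {i: names[i] for i in range(n)}
    active = list(range(n))  # creation order; ties pick earliest pair
    dist = {i: {j: D[i, j] for j in range(n) if j != i} for i in range(n)}
    next_id = n

    def connect(a: int, b: int, w: float) -> None:
        adjacency.setdefault(a, []).append((b, w))
        adjacency.setdefault(b, []).append((a, w))

    while len(active) > 3:
        r = len(active)
        R = {i: sum(dist[i][j] for j in active if j != i) for i in active}
        best, best_q = None, np.inf
        for ai in range(r):
            for bi in range(ai + 1, r):
                i, j = active[ai], active[bi]
                q = (r - 2) * dist[i][j] - R[i] - R[j]
                if q < best_q - 1e-12:
                    best_q, best = q, (i, j)
        i, j = best
        d_ij = dist[i][j]
        li = 0.5 * d_ij + (R[i] - R[j]) / (2 * (r - 2))
        lj = d_ij - li
        u = next_id
        next_id += 1
        connect(u, i, li)
        connect(u, j, lj)
        dist[u] = {}
        for k in active:
            if k in (i, j):
                continue
            d_uk = 0.5 * (dist[i][k] + dist[j][k] - d_ij)
            dist[u][k] = d_uk
            dist[k][u] = d_uk
        active = [k for k in active if k not in (i, j)] + [u]

    a, b, c = active
    u = next_id
    la = 0.5 * (dist[a][b] + dist[a][c] - dist[b][c])
    lb = 0.5 * (dist[a][b] + dist[b][c] - dist[a][c])
    lc = 0.5 * (dist[a][c] + dist[b][c] - dist[a][b])
    connect(u, a, la)
    connect(u, b, lb)
    connect(u, c, lc)
    return Tree(adjacency, leaf_names)


@dataclass(frozen=True)
class ConstraintTree:
    """Partially resolved reference topology: required clades only.

    Clades must be pairwise nested or disjoint and nontrivial
    (2 <= |clade| <= n-2)."""

    leaves: frozenset
    clades: tuple[frozenset, ...]

    def __post_init__(self) -> None:
        n = len(self.leaves)
        for c in self.clades:
            if not c <= self.leaves:
                raise ConfigurationError("clade contains unknown leaves")
            if len(c) < 2 or len(c) > n - 2:
                raise ConfigurationError("clades must be nontrivial bipartition sides")
        for a in self.clades:
            for b in self.clades:
                if not (a <= b or b <= a or not (a & b)):
                    # a and b may still be the two sides of the same split
                    if a | b != self.leaves:
                        raise ConfigurationError("clades must be nested or disjoint")

    def splits(self) -> set:
        anchor = min(self.leaves)
        out = set()
        for c in self.clades:
            side = set(c)
            if anchor in side:
                side = set(self.leaves) - side
            out.add(frozenset(side))
        return out

    def restrict(self, leaves) -> "ConstraintTree":
        leaves = frozenset(leaves)
        n = len(leaves)
        kept = []
        for c in self.clades:
            cc = c & leaves
            if 2 <= len(cc) <= n - 2 and cc not in kept:
                kept.append(cc)
        return ConstraintTree(leaves, tuple(kept))


def study_constraint(popmap) -> ConstraintTree:
    """The study's reference topology over RAD individuals:
    (((Black Forest), MC_1, MC_2), (Pyrenees, Cantabrian Mountains)) —
    one clade per region except the Massif Central, whose individuals float
    in the northern polytomy, plus the north/south split."""
    bf = frozenset(popmap.members("BF"))
    py = frozenset(popmap.members("PY"))
    cm = frozenset(popmap.members("CM"))
    leaves = frozenset(popmap.individuals)
    return ConstraintTree(leaves, (bf, py, cm, py | cm))


def rescaled_rf(tree: Tree, reference: ConstraintTree) -> float:
    """Symmetric-difference distance to the reference, rescaled to [0, 1]
    by its theoretical minimum and maximum for this reference."""
    if tree.leaves != reference.leaves:
        raise ConfigurationError("tree and reference must share one leaf set")
    t_splits = tree.splits()
    r_splits = reference.splits()
    b, k = len(t_splits), len(r_splits)
    if k == 0:
        raise DegenerateInputError(
            "reference tree is a star: rescaled distance is undefined"
        )
    d = len(t_splits ^ r_splits)
    d_min, d_max = b - k, b + k
    return (d - d_min) / (d_max - d_min)
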