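"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written against the *definitions* (path
enumeration, exhaustive topology search, exact assignment) and shares no
code with the package's implementations.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import nnls


# ---------------------------------------------------------------------------
# tuple trees: leaves are strings, internal nodes are tuples of subtrees
# ---------------------------------------------------------------------------


def rooted_topologies(labels: list[str]):
    """All rooted binary tree shapes on the labels ((2n-3)!! of them),
    generated by inserting each taxon at every node of every smaller tree."""
    if len(labels) == 1:
        yield labels[0]
        return
    for smaller in rooted_topologies(labels[:-1]):
        new = labels[-1]
        for inserted in _insert_everywhere(smaller, new):
            yield inserted


def _insert_everywhere(tree, leaf):
    # insert at this node (new root above it)
    yield (tree, leaf)
    if isinstance(tree, tuple):
        for i, child in enumerate(tree):
            for sub in _insert_everywhere(child, leaf):
                yield tree[:i] + (sub,) + tree[i + 1:]


def tuple_to_newick(tree) -> str:
    if isinstance(tree, tuple):
        return "(" + ",".join(tuple_to_newick(c) for c in tree) + ")"
    return tree


def tuple_leaves(tree) -> list[str]:
    if isinstance(tree, tuple):
        return [l for c in tree for l in tuple_leaves(c)]
    return [tree]


def oracle_gsi(tree, group: set[str]) -> float:
    """gsi by explicit uniting-node enumeration.

    Builds parent pointers, walks the path from every group tip to the
    group MRCA collecting every node on the way, and applies the degree
    normalization directly.
    """
    parent: dict[int, int] = {}
    children: dict[int, list[int]] = {}
    label: dict[int, str] = {}
    counter = itertools.count()

    def build(t) -> int:
        nid = next(counter)
        if isinstance(t, tuple):
            children[nid] = [build(c) for c in t]
            for cid in children[nid]:
                parent[cid] = nid
        else:
            children[nid] = []
            label[nid] = t
        return nid

    root = build(tree)
    tips = {lbl: nid for nid, lbl in label.items()}
    n_tips = len(tips)
    k = len(group)
    assert 2 <= k < n_tips

    def ancestors(nid: int) -> list[int]:
        out = []
        while nid in parent:
            nid = parent[nid]
            out.append(nid)
        return out

    anc_lists = {g: ancestors(tips[g]) for g in group}
    common = set.intersection(*(set(a) for a in anc_lists.values()))
    # MRCA: the common ancestor furthest from the root
    mrca = max(common, key=lambda nid: len(ancestors(nid)))
    uniting: set[int] = set()
    for g in group:
        node = tips[g]
        while node != mrca:
            node = parent[node]
            uniting.add(node)
    uniting.add(mrca)

    def degree(nid: int) -> int:
        # every node, the root included, carries an edge toward its
        # (possibly implicit) ancestor
        return len(children[nid]) + 1

    obs = sum(degree(u) - 2 for u in uniting)
    gs = (k - 1) / obs
    gs_min = (k - 1) / (n_tips - 1)
    return (gs - gs_min) / (1.0 - gs_min)


def random_tuple_tree(labels: list[str], rng: np.random.Generator):
    """A uniformly random rooted binary topology (random insertion order
    and uniform insertion point at each step)."""
    labels = list(labels)
    rng.shuffle(labels)
    tree = labels[0]
    for leaf in labels[1:]:
        spots = list(_insert_everywhere(tree, leaf))
        tree = spots[rng.integers(len(spots))]
    return tree


# ---------------------------------------------------------------------------
# least-squares tree-search oracle for neighbor joining
# ---------------------------------------------------------------------------


def unrooted_topologies(labels: list[str]):
    """All unrooted binary topologies, as adjacency edge lists over node
    ids; leaves carry their labels in a side dict."""
    n = len(labels)
    assert n >= 3
    # start from the 3-star, then insert each further taxon into every edge
    base_edges = [(0, n), (1, n), (2, n)]
    states = [(base_edges, n + 1)]
    for taxon in range(3, n):
        new_states = []
        for edges, next_id in states:
            for ei, (a, b) in enumerate(edges):
                mid = next_id
                new_edges = edges[:ei] + edges[ei + 1:] + [
                    (a, mid), (b, mid), (taxon, mid)
                ]
                new_states.append((new_edges, next_id + 1))
        states = new_states
    for edges, _ in states:
        yield edges


def _paths_matrix(edges, n_leaves: int) -> np.ndarray:
    """Pair × edge incidence matrix of leaf-to-leaf paths."""
    adj: dict[int, list[tuple[int, int]]] = {}
    for ei, (a, b) in enumerate(edges):
        adj.setdefault(a, []).append((b, ei))
        adj.setdefault(b, []).append((a, ei))
    pairs = list(itertools.combinations(range(n_leaves), 2))
    mat = np.zeros((len(pairs), len(edges)))

    def path(src: int, dst: int) -> list[int]:
        stack = [(src, -1, [])]
        while stack:
            node, prev, used = stack.pop()
            if node == dst:
                return used
            for nxt, ei in adj[node]:
                if nxt != prev:
                    stack.append((nxt, node, used + [ei]))
        raise AssertionError("disconnected tree")

    for r, (i, j) in enumerate(pairs):
        for ei in path(i, j):
            mat[r, ei] = 1.0
    return mat


def least_squares_topology(dist: np.ndarray) -> frozenset[frozenset[int]]:
    """Exhaustive search: the unrooted topology minimizing the nonnegative
    least-squares fit to the distances, returned as its split set."""
    n = dist.shape[0]
    target = np.array([
        dist[i, j] for i, j in itertools.combinations(range(n), 2)
    ])
    best = None
    best_ssq = np.inf
    for edges in unrooted_topologies(list(range(n))):
        mat = _paths_matrix(edges, n)
        bl, _ = nnls(mat, target)
        ssq = float((((mat @ bl) - target) ** 2).sum())
        if ssq < best_ssq - 1e-12:
            best_ssq = ssq
            best = edges
    return splits_of_edges(best, n)


def splits_of_edges(edges, n_leaves: int) -> frozenset[frozenset[int]]:
    """Non-trivial splits (leaf subsets) induced by the internal edges."""
    adj: dict[int, list[int]] = {}
    for a, b in edges:
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)
    splits: set[frozenset[int]] = set()
    for a, b in edges:
        # leaves on a's side when edge (a,b) removed
        seen = {a}
        stack = [a]
        while stack:
            node = stack.pop()
            for nxt in adj[node]:
                if nxt != b and nxt not in seen and not (node == a and nxt == b):
                    seen.add(nxt)
                    stack.append(nxt)
        side = frozenset(x for x in seen if x < n_leaves)
        if 2 <= len(side) <= n_leaves - 2:
            splits.add(min(side, frozenset(range(n_leaves)) - side, key=sorted))
    return frozenset(splits)


def random_additive_matrix(
    n: int, rng: np.random.Generator
) -> tuple[np.ndarray, frozenset[frozenset[int]]]:
    """Distances that are exactly additive on a random unrooted topology
    with strictly positive branch lengths; returns (matrix, true splits)."""
    topologies = list(unrooted_topologies(list(range(n))))
    edges = topologies[rng.integers(len(topologies))]
    lengths = rng.uniform(0.5, 2.0, size=len(edges))
    mat = _paths_matrix(edges, n)
    vec = mat @ lengths
    dist = np.zeros((n, n))
    for r, (i, j) in enumerate(itertools.combinations(range(n), 2)):
        dist[i, j] = dist[j, i] = vec[r]
    return dist, splits_of_edges(edges, n)


def dendropy_splits(tree, labels: list[str]) -> frozenset[frozenset[int]]:
    """Non-trivial splits of a dendropy tree in label-index space
    (unrooted interpretation)."""
    index = {lbl: i for i, lbl in enumerate(labels)}
    n = len(labels)
    splits: set[frozenset[int]] = set()
    for node in tree.preorder_internal_node_iter():
        if node.parent_node is None:
            continue
        side = frozenset(index[lf.taxon.label] for lf in node.leaf_iter())
        if 2 <= len(side) <= n - 2:
            splits.add(min(side, frozenset(range(n)) - side, key=sorted))
    return frozenset(splits)


# ---------------------------------------------------------------------------
# recombination lower bound by exhaustive interval packing
# ---------------------------------------------------------------------------


def oracle_rm(pairs: list[tuple[int, int]]) -> int:
    """Maximum number of pairwise non-overlapping open intervals, found by
    exhaustive take/skip recursion (small inputs only)."""

    def overlap(p: tuple[int, int], q: tuple[int, int]) -> bool:
        return max(p[0], q[0]) < min(p[1], q[1])

    def rec(remaining: tuple[tuple[int, int], ...]) -> int:
        if not remaining:
            return 0
        first, rest = remaining[0], remaining[1:]
        best = rec(rest)  # skip
        compatible = tuple(p for p in rest if not overlap(first, p))
        return max(best, 1 + rec(compatible))  # take

    return rec(tuple(pairs))
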