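"""Per-locus tree collections, consensus trees, and monophyly support.

The downstream statistics (genealogical sorting indices, monophyly
probabilities) consume only a collection of rooted trees; where they come
from is orthogonal.  This module builds such collections as site-resampled
bootstrap samples over neighbor-joining trees on Jukes–Cantor distances —
the documented surrogate for a Bayesian posterior sample — and accepts
imported newick posterior collections interchangeably
(:func:`delimix.formats.read_newick_collection`).

Neighbor joining is the canonical Q-matrix algorithm with two documented
reproducibility rules: ties in Q are broken toward the lowest index pair,
and negative branch lengths are clamped to zero with the remainder shifted
to the sibling branch.  Rooting is by outgroup when outgroup tips are
given, otherwise at the midpoint (the sorting index requires rooted trees).
"""

from __future__ import annotations

import numpy as np
import dendropy

from .formats import LocusAlignment, TreeCollection


class SaturationError(ValueError):
    """A pairwise difference proportion at or beyond the JC domain bound."""


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------


def jc_distance_matrix(
    aln: LocusAlignment, columns: np.ndarray | None = None
) -> tuple[np.ndarray, list[str]]:
    """Jukes–Cantor corrected pairwise distances.

    d = -(3/4) ln(1 - 4p/3) with p the proportion of differing sites over
    pairwise non-missing columns.  ``columns`` optionally restricts/reorders
    sites (used by the bootstrap).  Raises :class:`SaturationError` when a
    pair reaches p >= 0.75.
    """
    mat = aln.matrix()
    if columns is not None:
        mat = mat[:, columns]
    obs = (mat != ord("-")) & (mat != ord("N"))
    n = mat.shape[0]
    if n < 2:
        raise ValueError("need at least 2 sequences")
    diff = (mat[:, None, :] != mat[None, :, :]) & obs[:, None, :] & obs[None, :, :]
    comp = (obs[:, None, :] & obs[None, :, :]).sum(axis=2)
    ndiff = diff.sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(comp > 0, ndiff / np.maximum(comp, 1), 0.0)
    bad = np.argwhere(np.triu(p >= 0.75, k=1))
    if bad.size:
        i, j = bad[0]
        raise SaturationError(
            f"pair ({aln.copy_ids[i]!r}, {aln.copy_ids[j]!r}) is saturated "
            f"(p = {p[i, j]:.3f} >= 0.75); JC correction undefined"
        )
    d = -0.75 * np.log1p(-4.0 * p / 3.0)
    np.fill_diagonal(d, 0.0)
    return d, list(aln.copy_ids)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------


def neighbor_joining(dist: np.ndarray, labels: list[str]) -> dendropy.Tree:
    """Canonical NJ; returns an unrooted dendropy tree (trifurcating root).

    Tie-break: the (i, j) pair minimizing Q with the lowest row-major index
    wins.  Negative branch lengths are clamped to 0 and the deficit moved
    to the sibling branch.
    """
    n = len(labels)
    if dist.shape != (n, n):
        raise ValueError("distance matrix / labels size mismatch")
    if n < 2:
        raise ValueError("need at least 2 taxa")
    ns = dendropy.TaxonNamespace()
    nodes = [dendropy.Node(taxon=ns.new_taxon(lbl)) for lbl in labels]
    if n == 2:
        root = dendropy.Node()
        for node, bl in zip(nodes, (dist[0, 1] / 2, dist[0, 1] / 2)):
            root.add_child(node)
            node.edge.length = max(bl, 0.0)
        tree = dendropy.Tree(taxon_namespace=ns)
        tree.seed_node = root
        tree.is_rooted = False
        return tree

    d = dist.astype(float).copy()
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        totals = sub.sum(axis=1)
        q = (m - 2) * sub - totals[:, None] - totals[None, :]
        np.fill_diagonal(q, np.inf)
        flat = int(np.argmin(q))  # argmin returns first (lowest index) tie
        ai, aj = divmod(flat, m)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = d[i, j]
        li = 0.5 * dij + (totals[ai] - totals[aj]) / (2.0 * (m - 2))
        lj = dij - li
        # clamp negatives, shifting the remainder to the sibling branch
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = li
        parent.add_child(nodes[j])
        nodes[j].edge.length = lj
        # distances from the new node
        new_d = 0.5 * (d[i, active] + d[j, active] - dij)
        d[i, active] = new_d
        d[active, i] = new_d
        d[i, i] = 0.0
        nodes[i] = parent
        active.remove(j)

    root = dendropy.Node()
    a, b, c = active
    sub = d[np.ix_(active, active)]
    la = 0.5 * (sub[0, 1] + sub[0, 2] - sub[1, 2])
    lb = 0.5 * (sub[0, 1] + sub[1, 2] - sub[0, 2])
    lc = 0.5 * (sub[0, 2] + sub[1, 2] - sub[0, 1])
    for idx, bl in zip((a, b, c), (la, lb, lc)):
        root.add_child(nodes[idx])
        nodes[idx].edge.length = max(bl, 0.0)
    tree = dendropy.Tree(taxon_namespace=ns)
    tree.seed_node = root
    tree.is_rooted = False
    return tree


def root_by_outgroup(tree: dendropy.Tree, outgroup: list[str]) -> dendropy.Tree:
    """Root on the branch separating the outgroup from the ingroup.

    Falls back to midpoint rooting (with a ``rooting_fallback`` annotation)
    when the outgroup tips are not separable on one side of a branch.
    """
    taxa = {lf.taxon.label for lf in tree.leaf_node_iter()}
    missing = set(outgroup) - taxa
    if missing:
        raise ValueError(f"outgroup tips absent from tree: {sorted(missing)}")
    tree.is_rooted = True  # treat the seed node as a provisional root
    mrca = tree.mrca(taxon_labels=outgroup)
    og_leaves = {lf.taxon.label for lf in mrca.leaf_iter()} if mrca else taxa
    if mrca is None or og_leaves != set(outgroup):
        # outgroup not separable from the ingroup: midpoint-root and flag
        tree = midpoint_root(tree)
        tree.annotations.add_new("rooting_fallback", "midpoint")
        return tree
    bl = mrca.edge.length or 0.0
    tree.reroot_at_edge(
        mrca.edge, length1=bl / 2.0, length2=bl / 2.0,
        update_bipartitions=False,
    )
    tree.is_rooted = True
    return tree


def midpoint_root(tree: dendropy.Tree) -> dendropy.Tree:
    total = sum(
        (e.length or 0.0) for e in tree.preorder_edge_iter()
    )
    if total <= 0:
        tree.is_rooted = True  # star/zero-length tree: rooting arbitrary
        return tree
    try:
        tree.reroot_at_midpoint(update_bipartitions=False)
    except AssertionError:
        # (near-)zero spread between the two farthest tips: keep the
        # current seed node as the root
        tree.annotations.add_new("rooting_fallback", "seed-node")
    tree.is_rooted = True
    return tree


# ---------------------------------------------------------------------------
# bootstrap collections
# ---------------------------------------------------------------------------


def bootstrap_trees(
    aln: LocusAlignment,
    n_trees: int = 100,
    seed: int = 0,
    outgroup: list[str] | None = None,
) -> TreeCollection:
    """Site-resampled NJ bootstrap collection of rooted trees, equal weight.

    With no variable sites the trees are star-like; the collection is
    flagged ``invariant-alignment`` rather than erroring.
    """
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    rng = np.random.default_rng(seed)
    ns = dendropy.TaxonNamespace()
    trees = dendropy.TreeList(taxon_namespace=ns)
    flags: list[str] = []
    mat = aln.matrix()
    obs = (mat != ord("-")) & (mat != ord("N"))
    invariant = True
    for j in range(mat.shape[1]):
        col = mat[obs[:, j], j]
        if col.size and np.unique(col).size >= 2:
            invariant = False
            break
    if invariant:
        flags.append("invariant-alignment")
    for _ in range(n_trees):
        cols = rng.integers(0, aln.length, size=aln.length)
        d, labels = jc_distance_matrix(aln, columns=cols)
        tree = neighbor_joining(d, labels)
        tree = (
            root_by_outgroup(tree, outgroup) if outgroup else midpoint_root(tree)
        )
        tree = dendropy.Tree.get(
            data=tree.as_string(
                schema="newick", suppress_rooting=True,
                unquoted_underscores=True,
            ),
            schema="newick", preserve_underscores=True, taxon_namespace=ns,
        )
        tree.is_rooted = True
        trees.append(tree)
    return TreeCollection(trees, source="bootstrap", flags=flags)


# ---------------------------------------------------------------------------
# monophyly support and consensus
# ---------------------------------------------------------------------------


def is_monophyletic(tree: dendropy.Tree, tips: set[str]) -> bool:
    """Do ``tips`` form a clade on this rooted tree?"""
    node = tree.mrca(taxon_labels=tips)
    if node is None:
        raise ValueError("group has no MRCA on this tree")
    clade = {lf.taxon.label for lf in node.leaf_iter()}
    return clade == set(tips)


def monophyly_probability(
    collection: TreeCollection, tips: set[str]
) -> float:
    """Weighted fraction of trees where the tips form a clade.

    This is the collection analogue of a posterior probability of
    monophyly: filtering a posterior sample for trees satisfying the
    monophyly constraint and reporting the retained mass.
    """
    tips = set(tips)
    if len(tips) < 2:
        raise ValueError("monophyly support needs a group of >= 2 tips")
    absent = tips - collection.tip_labels
    if absent:
        raise ValueError(f"group tips absent from collection: {sorted(absent)}")
    w = collection.normalized_weights()
    support = 0.0
    for tree, wt in zip(collection.trees, w):
        if is_monophyletic(tree, tips):
            support += wt
    return float(support)


def majority_rule_consensus(collection: TreeCollection) -> dendropy.Tree:
    """Weighted majority-rule consensus of rooted trees.

    Clades (rooted bipartitions) with weighted frequency > 0.5 are
    retained and annotated with their frequency as node support; no greedy
    completion of compatible minority clades is performed.
    """
    w = collection.normalized_weights()
    freqs: dict[frozenset[str], float] = {}
    all_tips: frozenset[str] = collection.tip_labels
    for tree, wt in zip(collection.trees, w):
        for node in tree.preorder_node_iter():
            if node.is_leaf() or node.parent_node is None:
                continue
            clade = frozenset(lf.taxon.label for lf in node.leaf_iter())
            if len(clade) < len(all_tips):
                freqs[clade] = freqs.get(clade, 0.0) + wt
    keep = {c: f for c, f in freqs.items() if f > 0.5}

    ns = dendropy.TaxonNamespace()
    tip_nodes = {
        lbl: dendropy.Node(taxon=ns.new_taxon(lbl)) for lbl in sorted(all_tips)
    }
    root = dendropy.Node()
    clade_nodes: list[tuple[frozenset[str], dendropy.Node]] = [
        (frozenset(all_tips), root)
    ]
    for clade in sorted(keep, key=len, reverse=True):
        node = dendropy.Node()
        node.label = f"{keep[clade]:.3f}"
        node.annotations.add_new("support", keep[clade])
        # attach under the smallest already-placed clade containing it
        parent = min(
            (c for c, _ in clade_nodes if clade < c), key=len
        )
        parent_node = next(nd for c, nd in clade_nodes if c == parent)
        parent_node.add_child(node)
        clade_nodes.append((clade, node))
    for lbl, tnode in tip_nodes.items():
        containing = [c for c, _ in clade_nodes if lbl in c]
        parent = min(containing, key=len)
        parent_node = next(nd for c, nd in clade_nodes if c == parent)
        parent_node.add_child(tnode)
    tree = dendropy.Tree(taxon_namespace=ns)
    tree.seed_node = root
    tree.is_rooted = True
    return tree
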