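"""Genealogical sorting index (gsi) on rooted trees and tree collections.

For a labeled group of tips on a rooted (possibly multifurcating) tree the
gsi quantifies the degree of exclusive ancestry on a standardized [0, 1]
scale: 1 for monophyly, 0 for maximal dispersion across the genealogy.

Definition.  Let the *uniting nodes* U of a group of k tips be every
internal node on a path from a group tip up to (and including) the group's
MRCA.  The observed sorting score is

    gs = (k - 1) / sum_{u in U} (deg(u) - 2)

where deg counts edges incident to u, the root included with its implicit
ancestral edge (so every bifurcating internal node contributes 1).  For
any clade containing exactly the group the denominator telescopes to
k - 1 and gs = 1, and only clades achieve it: a dispersed group picks up
one extra unit per foreign subtree hanging off its uniting paths.  When
the group is spread so that U is the whole set of internal nodes the
denominator is T - 1 for T tips, regardless of multifurcation.  The index
rescales gs between these extremes:

    gsi = (gs - gs_min) / (1 - gs_min),    gs_min = (k - 1) / (T - 1).

Significance is assessed by permuting group labels across tips (sizes
preserved) and recomputing; p-values use the add-one rule
(b + 1) / (m + 1) and are therefore never 0.  Because the index takes few
distinct values on small trees, ties between the observed and permuted
statistics are broken uniformly at random (a shared jitter rank), which
makes the p-value exactly uniform on its grid under the null instead of
conservative.  For tree collections the
ensemble statistic gsi_T is the weighted mean of per-tree gsi values, and
each permutation replicate draws one label permutation applied to every
tree in the collection — trees are dependent samples of one history, and
permuting per tree would overstate significance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from .formats import TreeCollection, copy_to_individual


def _rank_p(obs: float, perm_vals: np.ndarray, rng: np.random.Generator) -> float:
    """Add-one permutation p-value with randomized tie-breaking.

    b counts permutations strictly beating the observed statistic, plus a
    uniformly random subset of the ties; under exchangeability the result
    is exactly uniform on {1, ..., m+1}/(m+1) rather than conservative,
    which matters because the index is discrete on small trees.
    """
    tol = 1e-12
    greater = int((perm_vals > obs + tol).sum())
    ties = int((np.abs(perm_vals - obs) <= tol).sum())
    if ties:
        u_obs = rng.random()
        greater += int((rng.random(ties) > u_obs).sum())
    return (greater + 1) / (len(perm_vals) + 1)


class UnrootedTreeError(ValueError):
    """gsi requires rooted trees; route the input through a rooting
    operation (outgroup or midpoint) first."""


class TreeIndex:
    """Array representation of one rooted tree for repeated gsi evaluation.

    Precomputes a postorder node ordering, parent pointers and node degrees
    so that a single gsi evaluation is one O(nodes) pass.
    """

    def __init__(self, tree: dendropy.Tree):
        if not tree.is_rooted:
            raise UnrootedTreeError(
                "tree is unrooted; gsi is defined on rooted trees"
            )
        nodes = list(tree.postorder_node_iter())
        for nd in nodes:
            if nd.parent_node is None and len(nd.child_nodes()) == 1:
                raise ValueError("tree has a unifurcating root")
        self._index = {id(nd): i for i, nd in enumerate(nodes)}
        n = len(nodes)
        self.parent = np.full(n, -1, dtype=np.int64)
        self.degree = np.zeros(n, dtype=np.int64)
        self.is_tip = np.zeros(n, dtype=bool)
        self.tip_label: dict[str, int] = {}
        for i, nd in enumerate(nodes):
            nc = len(nd.child_nodes())
            # the root carries an implicit ancestral edge: without it a
            # root-child tip plus one near-root tip would score gs = 1
            # despite not being a clade
            self.degree[i] = nc + 1
            if nd.parent_node is not None:
                self.parent[i] = self._index[id(nd.parent_node)]
            if nc == 0:
                self.is_tip[i] = True
                self.tip_label[nd.taxon.label] = i
        self.n_nodes = n
        self.n_tips = int(self.is_tip.sum())
        if self.n_tips < 3:
            raise ValueError("gsi needs trees with at least 3 tips")
        self.deg_minus2 = self.degree - 2

    def tip_indices(self, labels) -> np.ndarray:
        try:
            return np.array([self.tip_label[l] for l in labels], dtype=np.int64)
        except KeyError as exc:
            raise ValueError(f"tip {exc.args[0]!r} absent from tree") from exc

    def gsi(self, group_tips: np.ndarray) -> float:
        """gsi for the group given as tip node indices."""
        k = len(group_tips)
        if k < 2:
            raise ValueError("group must contain at least 2 tips")
        if k >= self.n_tips:
            raise ValueError("group must be a proper subset of the tips")
        cnt = np.zeros(self.n_nodes, dtype=np.int64)
        cnt[group_tips] = 1
        parent = self.parent
        # postorder accumulation (nodes are already postorder-indexed)
        for i in range(self.n_nodes - 1):
            if cnt[i]:
                cnt[parent[i]] += cnt[i]
        internal = ~self.is_tip
        touched = internal & (cnt > 0)
        obs = int(self.deg_minus2[touched].sum())
        # subtract proper ancestors of the MRCA (all hold the full count)
        full = np.nonzero(touched & (cnt == k))[0]
        mrca = full[0]  # postorder: deepest full node first
        node = parent[mrca]
        while node != -1:
            obs -= int(self.deg_minus2[node])
            node = parent[node]
        gs = (k - 1) / obs
        gs_min = (k - 1) / (self.n_tips - 1)
        return float((gs - gs_min) / (1.0 - gs_min))


def gsi_single(tree: dendropy.Tree | TreeIndex, group: set[str]) -> float:
    """gsi of a copy-level label set on one rooted tree."""
    idx = tree if isinstance(tree, TreeIndex) else TreeIndex(tree)
    return idx.gsi(idx.tip_indices(sorted(group)))


def gsi_permutation_p(
    tree: dendropy.Tree | TreeIndex,
    group: set[str],
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """(observed gsi, permutation p-value) on a single tree.

    Labels are permuted across all tips with the group size preserved;
    p = (#{perm >= obs} + 1) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    idx = tree if isinstance(tree, TreeIndex) else TreeIndex(tree)
    tips = idx.tip_indices(sorted(group))
    obs = idx.gsi(tips)
    rng = np.random.default_rng(seed)
    all_tips = np.nonzero(idx.is_tip)[0]
    k = len(tips)
    vals = np.array([
        idx.gsi(rng.choice(all_tips, size=k, replace=False))
        for _ in range(n_perm)
    ])
    return obs, _rank_p(obs, vals, rng)


@dataclass
class GsiReport:
    """gsi results for one group on one tree collection (or consensus set)."""

    group: str
    per_tree: np.ndarray
    gsi_t: float
    p_value: float
    n_permutations: int
    seed: int
    locus: str = ""
    per_tree_p: np.ndarray | None = None

    @property
    def min_max(self) -> tuple[float, float]:
        return float(self.per_tree.min()), float(self.per_tree.max())

    def __post_init__(self) -> None:
        assert np.all((self.per_tree >= -1e-9) & (self.per_tree <= 1 + 1e-9))
        lo, hi = self.min_max
        assert lo - 1e-9 <= self.gsi_t <= hi + 1e-9
        assert 0 < self.p_value <= 1


def _individual_groups(collection: TreeCollection) -> tuple[list[str], dict[str, list[str]]]:
    """Individuals in the collection and individual -> tip labels map."""
    by_ind: dict[str, list[str]] = {}
    for lbl in sorted(collection.tip_labels):
        by_ind.setdefault(copy_to_individual(lbl), []).append(lbl)
    return sorted(by_ind), by_ind


def gsi_ensemble(
    collection: TreeCollection,
    group_individuals: set[str],
    n_perm: int = 1000,
    seed: int = 0,
    group_label: str = "group",
    locus: str = "",
    compute_per_tree_p: bool = False,
) -> GsiReport:
    """Ensemble gsi_T over a tree collection with a shared-label permutation null.

    The group is given at the individual level and lifted to allele copies
    on each tree.  gsi_T is the weighted mean of per-tree gsi.  Each of the
    ``n_perm`` null replicates permutes individual labels once and applies
    the same permuted labels to every tree, preserving the across-tree
    dependence of the collection.
    """
    individuals, by_ind = _individual_groups(collection)
    group_inds = sorted(set(group_individuals) & set(individuals))
    if len(group_inds) < 1:
        raise ValueError("group has no individuals in the tip namespace")
    indices = [TreeIndex(t) for t in collection.trees]
    w = collection.normalized_weights()

    def tips_for(inds, idx: TreeIndex) -> np.ndarray:
        labels = [l for ind in inds for l in by_ind[ind] if l in idx.tip_label]
        return idx.tip_indices(labels)

    per_tree = np.array([idx.gsi(tips_for(group_inds, idx)) for idx in indices])
    gsi_t = float((per_tree * w).sum())

    rng = np.random.default_rng(seed)
    k_ind = len(group_inds)
    ens_vals = np.empty(n_perm)
    per_tree_b = np.zeros(len(indices)) if compute_per_tree_p else None
    for r in range(n_perm):
        perm_inds = list(
            np.array(individuals)[rng.choice(len(individuals), size=k_ind, replace=False)]
        )
        vals = np.array([idx.gsi(tips_for(perm_inds, idx)) for idx in indices])
        ens_vals[r] = float((vals * w).sum())
        if per_tree_b is not None:
            per_tree_b += vals >= per_tree - 1e-12
    report = GsiReport(
        group=group_label,
        per_tree=per_tree,
        gsi_t=gsi_t,
        p_value=_rank_p(gsi_t, ens_vals, rng),
        n_permutations=n_perm,
        seed=seed,
        locus=locus,
        per_tree_p=(
            (per_tree_b + 1) / (n_perm + 1) if per_tree_b is not None else None
        ),
    )
    return report


def gsi_multilocus(
    consensus_trees: dict[str, dendropy.Tree],
    group_individuals: set[str],
    n_perm: int = 1000,
    seed: int = 0,
    group_label: str = "group",
) -> GsiReport:
    """Ensemble gsi_T over the per-locus majority-rule consensus trees.

    Each locus contributes its consensus tree with equal weight; tips map
    to the shared individual namespace through the allele-copy suffix
    convention, and a locus missing an individual simply contributes its
    available copies.  The permutation scheme is the shared-label scheme of
    :func:`gsi_ensemble`.
    """
    indices = {name: TreeIndex(t) for name, t in consensus_trees.items()}
    by_ind_per_locus: dict[str, dict[str, list[str]]] = {}
    individuals: set[str] = set()
    for name, idx in indices.items():
        by_ind: dict[str, list[str]] = {}
        for lbl in idx.tip_label:
            by_ind.setdefault(copy_to_individual(lbl), []).append(lbl)
        by_ind_per_locus[name] = by_ind
        individuals.update(by_ind)
    ind_list = sorted(individuals)
    group_inds = sorted(set(group_individuals) & individuals)
    if not group_inds:
        raise ValueError("group has no individuals in any locus")

    def value(inds) -> tuple[float, np.ndarray]:
        vals = []
        for name, idx in indices.items():
            labels = [
                l for ind in inds for l in by_ind_per_locus[name].get(ind, [])
            ]
            vals.append(idx.gsi(idx.tip_indices(labels)))
        arr = np.array(vals)
        return float(arr.mean()), arr

    gsi_t, per_tree = value(group_inds)
    rng = np.random.default_rng(seed)
    ens_vals = np.empty(n_perm)
    for r in range(n_perm):
        perm = list(
            np.array(ind_list)[
                rng.choice(len(ind_list), size=len(group_inds), replace=False)
            ]
        )
        ens_vals[r], _ = value(perm)
    return GsiReport(
        group=group_label,
        per_tree=per_tree,
        gsi_t=gsi_t,
        p_value=_rank_p(gsi_t, ens_vals, rng),
        n_permutations=n_perm,
        seed=seed,
        locus="all-loci",
    )
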