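"""Neighbour-joining trees, column bootstrap and monophyly tests.

Trees are held as :class:`dendropy.Tree` objects (unrooted; the seed
node is a trifurcation). Neighbour joining follows the Saitou-Nei
Q-criterion agglomeration on the raw-difference matrix. Because the
input distances are raw counts, branch lengths are in units of base
differences. Determinism rules:

* when several pairs tie on the minimal Q value, the lexicographically
  smallest label pair is joined (a cluster is keyed by the smallest
  original leaf label it contains);
* negative intermediate branch lengths are clamped to 0 with the
  deficit transferred to the sister edge, the common convention.

"Clade" on an unrooted tree means an edge-induced bipartition side, and
reciprocal monophyly of two groups is assessed on the tree restricted
to their union, which is how the species-recognition criterion treats
guide-tree topology.
"""

from __future__ import annotations

import math
from typing import Iterable

import dendropy
import numpy as np

from .distance import DistanceMatrix, pairwise_differences
from .seq_core import Alignment, Sequence

__all__ = [
    "PhyloError",
    "neighbor_joining",
    "bootstrap_support",
    "edge_bipartitions",
    "is_bipartition_clade",
    "reciprocal_monophyly",
    "parse_newick",
    "write_newick",
    "tree_to_dict",
]

_TIE_EPS = 1e-9


class PhyloError(ValueError):
    pass


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbour joining; returns an unrooted tree.

    Requires >= 3 labels and a fully defined matrix (no pair with zero
    comparable sites).
    """
    labels = list(dm.labels)
    n = len(labels)
    if n < 3:
        raise PhyloError("neighbour joining requires >= 3 labels")
    undefined = dm.undefined_pairs()
    if undefined:
        raise PhyloError(f"undefined distances for pairs: {undefined}")

    tns = dendropy.TaxonNamespace(labels)
    nodes = []
    for lab in labels:
        node = dendropy.Node(taxon=tns.get_taxon(lab))
        nodes.append(node)
    # cluster key = smallest original label in the cluster (tie-break order)
    keys = list(labels)
    D = dm.values.astype(np.float64).copy()

    while len(keys) > 3:
        m = len(keys)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        candidates = [(i, j) for i in range(m) for j in range(i + 1, m)
                      if Q[i, j] <= qmin + _TIE_EPS]
        i, j = min(candidates, key=lambda ij: tuple(sorted((keys[ij[0]], keys[ij[1]]))))
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = D[i, j] - li
        if li < 0:
            lj, li = D[i, j], 0.0
        elif lj < 0:
            li, lj = D[i, j], 0.0
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = li
        parent.add_child(nodes[j])
        nodes[j].edge.length = lj
        d_new = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        D = np.vstack([D[np.ix_(keep, keep)],
                       d_new[keep][None, :]])
        D = np.hstack([D, np.append(d_new[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [parent]
        keys = [keys[k] for k in keep] + [min(keys[i], keys[j])]

    # Final three clusters join at the unrooted central node; closed form.
    dab, dac, dbc = D[0, 1], D[0, 2], D[1, 2]
    la = max(0.0, 0.5 * (dab + dac - dbc))
    lb = max(0.0, 0.5 * (dab + dbc - dac))
    lc = max(0.0, 0.5 * (dac + dbc - dab))
    center = dendropy.Node()
    for node, length in zip(nodes, (la, lb, lc)):
        center.add_child(node)
        node.edge.length = length
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=center)
    tree.is_rooted = False
    return tree


def _leaf_labels(tree: dendropy.Tree) -> frozenset:
    return frozenset(leaf.taxon.label for leaf in tree.leaf_node_iter())


def edge_bipartitions(tree: dendropy.Tree,
                      include_trivial: bool = False) -> set:
    """Canonical bipartition sides induced by the tree's edges.

    Each side is returned as the frozenset of leaf labels containing the
    lexicographically smallest leaf (so sides are comparable across
    trees on the same leaf set). By default only internal (non-trivial)
    edges are reported.
    """
    leaves = _leaf_labels(tree)
    if not leaves:
        return set()
    anchor = min(leaves)
    n = len(leaves)
    splits = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        below = frozenset(l.taxon.label for l in node.leaf_iter())
        if not include_trivial and (len(below) < 2 or len(below) > n - 2):
            continue
        if len(below) == 0 or len(below) == n:
            continue
        splits.add(below if anchor in below else leaves - below)
    return splits


def is_bipartition_clade(tree: dendropy.Tree, tips: Iterable[str]) -> bool:
    """True iff some edge induces the bipartition (tips | rest).

    Singletons and the full leaf set are clades by convention.
    """
    tips = frozenset(tips)
    if not tips:
        raise PhyloError("tips must be non-empty")
    leaves = _leaf_labels(tree)
    unknown = tips - leaves
    if unknown:
        raise PhyloError(f"unknown tip labels: {sorted(unknown)}")
    n = len(leaves)
    if len(tips) in (1, n - 1, n):
        # singleton sides are induced by the leaf's own edge
        return True
    anchor = min(leaves)
    canon = tips if anchor in tips else leaves - tips
    return canon in edge_bipartitions(tree)


def restrict_tree(tree: dendropy.Tree, tips: Iterable[str]) -> dendropy.Tree:
    """The induced subtree on a subset of leaves (unifurcations removed)."""
    tips = set(tips)
    sub = tree.extract_tree_with_taxa_labels(labels=tips)
    sub.is_rooted = False
    return sub


def reciprocal_monophyly(tree: dendropy.Tree, group_a: Iterable[str],
                         group_b: Iterable[str]) -> bool:
    """Reciprocal monophyly of two groups on the restricted tree.

    The tree is first restricted to group_a | group_b; both groups must
    then be bipartition-clades of the restriction. Taxa outside the two
    groups therefore never break monophyly, matching how pairs of
    candidate species are compared on a guide tree containing others.
    """
    a, b = frozenset(group_a), frozenset(group_b)
    if a & b:
        raise PhyloError(f"groups overlap: {sorted(a & b)}")
    if not a or not b:
        raise PhyloError("both groups must be non-empty")
    leaves = _leaf_labels(tree)
    unknown = (a | b) - leaves
    if unknown:
        raise PhyloError(f"unknown tip labels: {sorted(unknown)}")
    sub = restrict_tree(tree, a | b)
    return is_bipartition_clade(sub, a) and is_bipartition_clade(sub, b)


def bootstrap_support(aln: Alignment, replicates: int = 1000,
                      seed: int = 0) -> dendropy.Tree:
    """Column-resampling bootstrap supports on the point-estimate NJ tree.

    Columns are resampled with replacement to the original alignment
    length; each replicate runs pairwise differences + neighbour joining.
    Each internal edge of the point-estimate tree is annotated (node
    label and ``edge.head_node.support``) with the percentage of
    replicate trees containing its bipartition. Replicates producing an
    undefined distance are discarded and counted; more than 10%
    discarded is an error. Deterministic for a fixed seed.
    """
    if replicates < 1:
        raise PhyloError("replicates must be >= 1")
    point_dm = pairwise_differences(aln)
    tree = neighbor_joining(point_dm)
    leaves = _leaf_labels(tree)
    anchor = min(leaves)
    counts: dict = {split: 0 for split in edge_bipartitions(tree)}

    rng = np.random.default_rng(seed)
    length = aln.length
    discarded = 0
    used = 0
    for _ in range(replicates):
        cols = rng.integers(0, length, size=length)
        resampled = Alignment(
            [Sequence(id=s.id,
                      residues="".join(s.residues[c] for c in cols),
                      marker=s.marker)
             for s in aln],
            marker=aln.marker,
        )
        dm = pairwise_differences(resampled)
        if dm.undefined_pairs():
            discarded += 1
            continue
        rep_tree = neighbor_joining(dm)
        used += 1
        rep_splits = edge_bipartitions(rep_tree)
        for split in counts:
            if split in rep_splits:
                counts[split] += 1
    if discarded > 0.10 * replicates:
        raise PhyloError(
            f"{discarded}/{replicates} bootstrap replicates discarded "
            "(undefined distances); data too sparse for bootstrap"
        )
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        below = frozenset(l.taxon.label for l in node.leaf_iter())
        if len(below) < 2 or len(below) > len(leaves) - 2:
            continue
        canon = below if anchor in below else leaves - below
        support = 100.0 * counts[canon] / used if used else math.nan
        node.support = support
        node.label = f"{support:g}"
    tree.bootstrap_replicates = replicates
    tree.bootstrap_used = used
    tree.bootstrap_discarded = discarded
    return tree


def parse_newick(text: str) -> dendropy.Tree:
    """Parse a newick string; internal node labels are read as supports."""
    try:
        tree = dendropy.Tree.get(data=text, schema="newick",
                                 suppress_internal_node_taxa=True,
                                 preserve_underscores=True)
    except Exception as exc:
        raise PhyloError(f"newick parse error: {exc}") from exc
    labels = [l.taxon.label for l in tree.leaf_node_iter()]
    dupes = {l for l in labels if labels.count(l) > 1}
    if dupes:
        raise PhyloError(f"duplicate leaf labels: {sorted(dupes)}")
    tree.is_rooted = False
    for node in tree.preorder_node_iter():
        if not node.is_leaf() and node.label is not None:
            try:
                node.support = float(node.label)
            except ValueError:
                pass
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    """Serialize with branch lengths (10 significant digits) and supports."""
    return tree.as_string(schema="newick", suppress_rooting=True,
                          unquoted_underscores=True,
                          real_value_format_specifier=".10g").strip()


def tree_to_dict(tree: dendropy.Tree) -> dict:
    """JSON-serializable summary of a (support-annotated) tree."""
    supports = {}
    leaves = _leaf_labels(tree)
    anchor = min(leaves) if leaves else None
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        support = getattr(node, "support", None)
        if support is None:
            continue
        below = frozenset(l.taxon.label for l in node.leaf_iter())
        canon = below if anchor in below else leaves - below
        supports["|".join(sorted(canon))] = support
    return {"newick": write_newick(tree),
            "leaves": sorted(leaves),
            "supports": supports}
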