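"""Phylogeny handling: Newick I/O, pruning, and the phylogenetic covariance.

Under Brownian motion on a rooted tree, trait covariance between two tips
equals the length of the path shared between the root and their most
recent common ancestor.  ``phylo_vcv`` builds that matrix; Pagel's lambda
rescales its off-diagonal to interpolate between a star phylogeny
(lambda = 0, no phylogenetic signal) and full Brownian structure
(lambda = 1).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np


class TreeError(ValueError):
    """Invalid tree input."""


def read_newick(path: str | Path) -> dendropy.Tree:
    """Read a rooted Newick tree with branch lengths.

    Negative branch lengths and zero-length terminal branches are
    rejected; tip labels must be unique.
    """
    tree = dendropy.Tree.get(
        path=str(path), schema="newick", preserve_underscores=True
    )
    validate_tree(tree)
    return tree


def validate_tree(tree: dendropy.Tree) -> None:
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        dups = sorted({l for l in labels if labels.count(l) > 1})
        raise TreeError(f"duplicate tip labels: {dups}")
    for edge in tree.preorder_edge_iter():
        if edge.tail_node is None:
            continue  # root edge may be absent
        length = edge.length if edge.length is not None else 0.0
        if length < 0:
            raise TreeError(f"negative branch length {length}")
        if length == 0 and edge.head_node.is_leaf():
            raise TreeError(
                f"zero-length terminal branch at tip "
                f"{edge.head_node.taxon.label!r}"
            )


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def prune(tree: dendropy.Tree, species: Iterable[str]) -> dendropy.Tree:
    """Restrict the tree to ``species``, preserving path lengths.

    Unifurcations created by the pruning are collapsed with their branch
    lengths summed.  Requesting a tip that is absent raises
    :class:`TreeError` listing the missing labels.
    """
    wanted = set(species)
    present = set(tip_labels(tree))
    missing = sorted(wanted - present)
    if missing:
        raise TreeError(f"species not in tree: {missing}")
    pruned = tree.clone(depth=1)
    keep = [t for t in pruned.taxon_namespace if t.label in wanted]
    pruned.retain_taxa(keep)
    # dendropy suppresses unifurcations during retain_taxa, summing lengths
    return pruned


def phylo_vcv(
    tree: dendropy.Tree, order: Sequence[str] | None = None
) -> tuple[np.ndarray, list[str]]:
    """Brownian-motion covariance matrix from shared root-to-MRCA paths.

    Returns ``(C, labels)`` where ``C[i, j]`` is the depth of the MRCA of
    tips i and j and ``C[i, i]`` the root-to-tip depth.  ``order`` fixes
    the row order (default: leaf iteration order).
    """
    labels = tip_labels(tree)
    if order is not None:
        order = list(order)
        missing = sorted(set(order) - set(labels))
        if missing:
            raise TreeError(f"species not in tree: {missing}")
        labels = order
    index = {label: i for i, label in enumerate(labels)}
    n = len(labels)
    C = np.zeros((n, n))

    # depth of every node from the root (root edge length, if any, ignored)
    depth: dict[dendropy.Node, float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            depth[node] = 0.0
        else:
            length = node.edge.length if node.edge.length is not None else 0.0
            if length < 0:
                raise TreeError(f"negative branch length {length}")
            depth[node] = depth[node.parent_node] + length

    # postorder sweep: at each internal node, pairs of tips drawn from two
    # different child subtrees have their MRCA exactly here
    below: dict[dendropy.Node, np.ndarray] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            if node.taxon.label in index:
                below[node] = np.array([index[node.taxon.label]], dtype=np.intp)
            else:
                below[node] = np.empty(0, dtype=np.intp)
            continue
        child_sets = [below.pop(c) for c in node.child_nodes()]
        d = depth[node]
        for a in range(len(child_sets)):
            for b in range(a + 1, len(child_sets)):
                ia, ib = child_sets[a], child_sets[b]
                if len(ia) and len(ib):
                    C[np.ix_(ia, ib)] = d
                    C[np.ix_(ib, ia)] = d
        below[node] = np.concatenate(child_sets) if child_sets else np.empty(0, dtype=np.intp)

    for leaf in tree.leaf_node_iter():
        if leaf.taxon.label in index:
            i = index[leaf.taxon.label]
            C[i, i] = depth[leaf]
    return C, labels


def pagel_transform(C: np.ndarray, lam: float) -> np.ndarray:
    """Multiply off-diagonal covariances by lambda; diagonal unchanged."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must lie in [0, 1], got {lam}")
    V = C * lam
    np.fill_diagonal(V, np.diag(C))
    return V


def tree_depth(tree: dendropy.Tree) -> float:
    """Maximum root-to-tip distance."""
    return max(
        leaf.distance_from_root() for leaf in tree.leaf_node_iter()
    )
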