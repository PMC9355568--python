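"""Shared helpers over dendropy trees.

All screen stages operate on one rooted, branch-length-bearing species
tree.  Leaf labels are the species identifiers used in every table; they
must match byte-for-byte after the standard name normalisation
(spaces -> underscores).
"""

from __future__ import annotations

from typing import Callable, Iterable

import dendropy
import numpy as np

__all__ = [
    "leaf_labels",
    "check_species_in_tree",
    "maximal_uniform_clades",
    "brownian_covariance",
    "node_label",
    "clade_leaves",
]


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


def check_species_in_tree(tree: dendropy.Tree, species: Iterable[str]) -> None:
    leaves = set(leaf_labels(tree))
    bad = sorted(set(species) - leaves)
    if bad:
        raise KeyError(f"species not found in tree: {', '.join(bad)}")


def clade_leaves(node: dendropy.Node) -> list[str]:
    return [lf.taxon.label for lf in node.leaf_iter()]


def node_label(node: dendropy.Node) -> str:
    """Stable label for a branch: leaf name, node label, or mrca(...)."""
    if node.is_leaf():
        return node.taxon.label
    if node.label:
        return node.label
    leaves = sorted(clade_leaves(node))
    return f"mrca({leaves[0]},{leaves[-1]})"


def maximal_uniform_clades(
    tree: dendropy.Tree,
    in_state: Callable[[str], bool],
    uninformative: Callable[[str], bool] = lambda s: False,
) -> list[tuple[dendropy.Node, frozenset[str]]]:
    """Maximal clades whose informative leaves are all in the target state.

    Returns ``(node, leaf set in state)`` pairs for the deepest nodes whose
    every non-uninformative descendant leaf satisfies ``in_state`` and that
    contain at least one such leaf.  Clades made only of uninformative
    leaves are not reported.  This single routine backs both the
    foreground-lineage partition and Dollo loss-event placement.
    """
    out: list[tuple[dendropy.Node, frozenset[str]]] = []

    def walk(node: dendropy.Node) -> None:
        members: list[str] = []
        pure = True
        for lf in node.leaf_iter():
            name = lf.taxon.label
            if uninformative(name):
                continue
            if in_state(name):
                members.append(name)
            else:
                pure = False
                break
        if pure and members:
            out.append((node, frozenset(members)))
            return
        if not node.is_leaf():
            for ch in node.child_nodes():
                walk(ch)

    walk(tree.seed_node)
    return out


def brownian_covariance(
    tree: dendropy.Tree, species: list[str]
) -> np.ndarray:
    """Brownian-motion covariance: V_ij = shared root-to-tip path length.

    Computed as ``(d_i + d_j - d_ij) / 2`` from root-to-leaf depths and
    patristic distances, which is exact on any rooted tree.
    """
    check_species_in_tree(tree, species)
    depth: dict[str, float] = {}
    node_depth: dict[dendropy.Node, float] = {}
    for node in tree.preorder_node_iter():
        el = node.edge.length or 0.0
        parent = node.parent_node
        d = (node_depth[parent] if parent is not None else 0.0) + (
            el if parent is not None else 0.0
        )
        node_depth[node] = d
        if node.is_leaf():
            depth[node.taxon.label] = d
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(species)
    V = np.empty((n, n))
    for i, a in enumerate(species):
        V[i, i] = depth[a]
        for j in range(i + 1, n):
            b = species[j]
            d_ij = pdm.patristic_distance(taxa[a], taxa[b])
            V[i, j] = V[j, i] = 0.5 * (depth[a] + depth[b] - d_ij)
    return V
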