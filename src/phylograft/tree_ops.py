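"""Core dated-tree algebra: ages, MRCA, pruning, rescaling, renaming.

Ages are expressed as time before present with tips at 0; the only place
branch lengths are converted to ages is :func:`node_ages`.  All public
operations are pure — they clone their input and return a new tree —
while ``*_inplace`` variants exist for the hot pipeline loop.
"""

from __future__ import annotations

import warnings
from typing import Iterable

import dendropy

from .errors import ContractError

#: Relative tolerance under which a chronogram counts as ultrametric.
ULTRAMETRIC_RTOL = 1e-9


def tip_labels(tree: dendropy.Tree) -> frozenset[str]:
    return frozenset(l.taxon.label for l in tree.leaf_node_iter())


def _node_depths(tree: dendropy.Tree) -> dict[dendropy.Node, float]:
    depths: dict[dendropy.Node, float] = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        if parent is None:
            depths[node] = 0.0
        else:
            depths[node] = depths[parent] + (node.edge.length or 0.0)
    return depths


def tree_height(tree: dendropy.Tree) -> float:
    """Maximum root-to-tip path length (the crown depth)."""
    depths = _node_depths(tree)
    return max(depths[l] for l in tree.leaf_node_iter())


def is_ultrametric(tree: dendropy.Tree, rel_tol: float = ULTRAMETRIC_RTOL) -> bool:
    """True iff all root-to-tip paths agree within ``rel_tol`` × height."""
    depths = _node_depths(tree)
    leaf_depths = [depths[l] for l in tree.leaf_node_iter()]
    height = max(leaf_depths)
    if height == 0:
        return True
    return (height - min(leaf_depths)) <= rel_tol * height


def node_ages(tree: dendropy.Tree) -> dict[dendropy.Node, float]:
    """Map every node to its age (height − depth from the root).

    For an ultrametric tree tips get age 0 and the root gets the tree
    height.  A non-ultrametric input is accepted with a warning; ages are
    then heights above the deepest tip.
    """
    if not is_ultrametric(tree, rel_tol=1e-6):
        warnings.warn(
            "tree is not ultrametric; node ages computed as height - depth",
            stacklevel=2,
        )
    depths = _node_depths(tree)
    height = max(depths[l] for l in tree.leaf_node_iter())
    return {node: height - d for node, d in depths.items()}


def mrca(tree: dendropy.Tree, labels: Iterable[str]) -> dendropy.Node:
    """Most recent common ancestor of the given tip labels.

    A single label resolves to the tip itself.  Unknown labels raise
    :class:`ContractError` naming the offender.
    """
    wanted = set(labels)
    if not wanted:
        raise ContractError("mrca requires at least one label")
    by_label = {l.taxon.label: l for l in tree.leaf_node_iter()}
    missing = wanted - by_label.keys()
    if missing:
        raise ContractError(f"labels not in tree: {sorted(missing)}")
    if len(wanted) == 1:
        return by_label[next(iter(wanted))]
    # Walk up from an arbitrary target tip; the MRCA is the first ancestor
    # whose leaf set covers all targets.
    target_tips = {by_label[lbl] for lbl in wanted}
    node = next(iter(target_tips))
    while node.parent_node is not None:
        if target_tips <= set(node.leaf_iter()):
            return node
        node = node.parent_node
    if not target_tips <= set(node.leaf_iter()):
        raise ContractError("disconnected tree: no common ancestor found")
    return node


def _strip_root_edge(tree: dendropy.Tree) -> None:
    tree.seed_node.edge.length = None


def remove_taxa_inplace(tree: dendropy.Tree, labels: Iterable[str]) -> dendropy.Tree:
    drop = set(labels)
    if not drop:
        return tree
    present = tip_labels(tree)
    missing = drop - present
    if missing:
        raise ContractError(f"cannot remove absent taxa: {sorted(missing)}")
    if len(present - drop) < 2:
        raise ContractError(
            f"removing {len(drop)} taxa would leave fewer than 2 tips"
        )
    taxa = [l.taxon for l in tree.leaf_node_iter() if l.taxon.label in drop]
    tree.prune_taxa(taxa, suppress_unifurcations=True)
    # Pruning can leave the old root position as a stem above the MRCA of
    # the retained tips; collapse it so the root is that MRCA.
    while len(tree.seed_node.child_nodes()) == 1:
        child = tree.seed_node.child_nodes()[0]
        child.parent_node = None
        tree.seed_node = child
    _strip_root_edge(tree)
    return tree


def remove_taxa(tree: dendropy.Tree, labels: Iterable[str]) -> dendropy.Tree:
    """Delete the listed tips, suppressing unifurcations by summing the
    incident branch lengths.  Pairwise path lengths among retained tips
    are unchanged; the new root is the MRCA of the retained tips.
    """
    return remove_taxa_inplace(tree.clone(depth=1), labels)


def extract_clade(tree: dendropy.Tree, node: dendropy.Node) -> dendropy.Tree:
    """Return the subtree rooted at ``node`` as a standalone tree.

    For ultrametric input the extracted tree's height equals the node's
    age.  ``node`` must be internal.
    """
    if node.is_leaf():
        raise ContractError("cannot extract a clade from a tip")
    labels = {l.taxon.label for l in node.leaf_iter()}
    clone = tree.clone(depth=1)
    sub = mrca(clone, labels)
    if sub.parent_node is not None:
        sub.parent_node.remove_child(sub)
    sub.edge.length = None
    out = dendropy.Tree(seed_node=sub, taxon_namespace=clone.taxon_namespace)
    out.is_rooted = True
    out.migrate_taxon_namespace(dendropy.TaxonNamespace())
    return out


def rescale_to_crown_age(tree: dendropy.Tree, target_age: float) -> dendropy.Tree:
    """Multiply all branch lengths so the crown depth equals ``target_age``.

    Topology and all age *ratios* are unchanged — the operation is a pure
    change of time scale.
    """
    if target_age <= 0:
        raise ContractError(f"target crown age must be positive, got {target_age}")
    height = tree_height(tree)
    if height <= 0:
        raise ContractError("cannot rescale a tree of zero depth")
    out = tree.clone(depth=1)
    out.scale_edges(target_age / height)
    return out


def rescale_inplace(tree: dendropy.Tree, target_age: float) -> dendropy.Tree:
    if target_age <= 0:
        raise ContractError(f"target crown age must be positive, got {target_age}")
    height = tree_height(tree)
    if height <= 0:
        raise ContractError("cannot rescale a tree of zero depth")
    tree.scale_edges(target_age / height)
    return tree


def rename_tip_inplace(tree: dendropy.Tree, old: str, new: str) -> dendropy.Tree:
    present = tip_labels(tree)
    if old not in present:
        raise ContractError(f"tip {old!r} not in tree")
    if new in present:
        raise ContractError(f"tip label {new!r} already present")
    for leaf in tree.leaf_node_iter():
        if leaf.taxon.label == old:
            leaf.taxon.label = new
            break
    return tree


def rename_tip(tree: dendropy.Tree, old: str, new: str) -> dendropy.Tree:
    """Rename one tip; topology and branch lengths untouched."""
    out = tree.clone(depth=1)
    out.migrate_taxon_namespace(dendropy.TaxonNamespace())
    return rename_tip_inplace(out, old, new)


def path_length_matrix(tree: dendropy.Tree) -> dict[tuple[str, str], float]:
    """All pairwise tip-to-tip path lengths, keyed by sorted label pair.

    Quadratic and label-based; intended for verification rather than the
    pipeline hot path.
    """
    depths = _node_depths(tree)
    leaves = list(tree.leaf_node_iter())
    # ancestor sets per leaf for naive LCA
    anc: dict[dendropy.Node, list[dendropy.Node]] = {}
    for l in leaves:
        chain = []
        n = l
        while n is not None:
            chain.append(n)
            n = n.parent_node
        anc[l] = chain
    out: dict[tuple[str, str], float] = {}
    for i, a in enumerate(leaves):
        chain_a = set(anc[a])
        for b in leaves[i + 1 :]:
            lca = next(n for n in anc[b] if n in chain_a)
            d = depths[a] + depths[b] - 2 * depths[lca]
            key = tuple(sorted((a.taxon.label, b.taxon.label)))
            out[key] = d
    return out
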