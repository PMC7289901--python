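"""Replacing backbone clades with rescaled subclade trees.

The grafting rule mirrors the study design: for each unit, the crown
node of the corresponding backbone clade is located from anchor labels,
*all* backbone lineages below it are removed, and the prepared subclade
sample (substitutions applied, outgroups removed, rescaled so its crown
depth equals the backbone crown age) is attached in their place.  Only
the stem branch of the original clade is kept; its new length is the
stem age minus the grafted crown age, so the result stays ultrametric
and every node age outside the replaced clades is untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import dendropy

from . import tree_ops
from .errors import (
    AgeConflictError,
    ConfigError,
    ContractError,
    MonophylyError,
)
from .treeio import TreeTrace

_MODES = ("mrca", "mrca_excluding", "split", "crown_of_unit")


@dataclass(frozen=True)
class AttachmentSpec:
    """Where a unit attaches on the backbone.

    ``mrca``           — crown = MRCA of ``anchors``.
    ``mrca_excluding`` — crown = MRCA of the clade spanned by ``anchors``
                         after discarding ``exclusions`` (the rule used to
                         leave an early-diverging lineage in place).
    ``split``          — crown = MRCA of the union of ``anchors`` and
                         ``anchors_b`` (two sister clades grafted as one).
    ``crown_of_unit``  — crown = MRCA of the unit's ingroup labels that
                         exist in the backbone.
    """

    mode: str
    anchors: frozenset[str]
    anchors_b: Optional[frozenset[str]] = None
    exclusions: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ConfigError(f"unknown attachment mode {self.mode!r}")
        if not self.anchors:
            raise ConfigError("attachment anchors must be non-empty")
        if self.mode == "split":
            if not self.anchors_b:
                raise ConfigError("split mode needs two anchor sets")
            if self.anchors & self.anchors_b:
                raise ConfigError(
                    "split anchor sets must be disjoint: "
                    f"{sorted(self.anchors & self.anchors_b)}"
                )
        elif self.anchors_b:
            raise ConfigError("anchors_b only valid in split mode")
        if self.exclusions and self.mode != "mrca_excluding":
            raise ConfigError("exclusions only valid in mrca_excluding mode")


@dataclass
class SubcladeUnit:
    """One grafting unit: posterior trace, outgroups, attachment rule.

    ``substitutions`` maps an existing label to its replacement; a
    substitution whose old label is a *backbone* tip is applied to the
    backbone before attachment resolution (the placeholder-tip rule),
    otherwise to the subclade samples.  ``drop_after_outgroups`` lists
    ingroup taxa removed after outgroup removal, before rescaling.
    """

    name: str
    trace: Optional[TreeTrace]
    outgroups: Sequence[str]
    attachment: AttachmentSpec
    substitutions: Mapping[str, str] = field(default_factory=dict)
    drop_after_outgroups: Sequence[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.trace is not None:
            tips = self.trace.tip_labels()
            missing = set(self.outgroups) - tips
            if missing:
                raise ConfigError(
                    f"unit {self.name!r}: outgroups not in trace: {sorted(missing)}"
                )
            clash = set(self.substitutions.values()) & tips
            if clash:
                raise ConfigError(
                    f"unit {self.name!r}: substitution targets already in "
                    f"trace: {sorted(clash)}"
                )


def _leafsets(tree: dendropy.Tree) -> dict[dendropy.Node, frozenset[str]]:
    """Descendant tip-label set per node, one postorder pass."""
    below: dict[dendropy.Node, frozenset[str]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[node] = frozenset((node.taxon.label,))
        else:
            below[node] = frozenset().union(*(below[c] for c in node.child_nodes()))
    return below


def _mrca_from_leafsets(tree, below, labels):
    want = frozenset(labels)
    for node in tree.postorder_node_iter():
        if want <= below[node]:
            return node
    raise ContractError("no common ancestor found")


def resolve_attachment(
    backbone: dendropy.Tree,
    spec: AttachmentSpec,
    _below: Optional[dict] = None,
    _ages: Optional[dict] = None,
):
    """Locate the crown node a unit replaces and the age of its stem node.

    Returns ``(crown_node, stem_parent_age)``; ``stem_parent_age`` is
    ``None`` when the crown node is the backbone root.  ``_below`` and
    ``_ages`` are precomputed leaf-set and age maps used by the
    replicate loop to avoid re-traversing one backbone sample per unit.
    """
    below = _below if _below is not None else _leafsets(backbone)
    backbone_tips = below[backbone.seed_node]
    if spec.mode == "crown_of_unit":
        present = spec.anchors & backbone_tips
        if not present:
            raise ConfigError(
                "crown_of_unit: no anchor labels present in the backbone"
            )
        anchor_labels = present
    elif spec.mode == "split":
        anchor_labels = spec.anchors | spec.anchors_b
    else:
        anchor_labels = spec.anchors
    missing = set(anchor_labels) - backbone_tips
    if missing:
        raise ConfigError(f"anchor labels not in backbone: {sorted(missing)}")
    node = _mrca_from_leafsets(backbone, below, anchor_labels)
    if spec.mode == "mrca_excluding":
        missing_ex = spec.exclusions - backbone_tips
        if missing_ex:
            raise ConfigError(
                f"exclusion labels not in backbone: {sorted(missing_ex)}"
            )
        remaining = below[node] - spec.exclusions
        if not remaining:
            raise ConfigError(
                "mrca_excluding: exclusions cover the whole anchor clade"
            )
        node = _mrca_from_leafsets(backbone, below, remaining)
    if node.is_leaf():
        raise ContractError(
            f"attachment resolves to a single tip {node.taxon.label!r}"
        )
    if node.parent_node is None:
        return node, None
    ages = _ages if _ages is not None else tree_ops.node_ages(backbone)
    return node, ages[node.parent_node]


def check_ingroup_monophyly(subclade_tree: dendropy.Tree, outgroups) -> bool:
    """True iff the non-outgroup tips form a clade excluding all outgroups."""
    ogs = set(outgroups) & tree_ops.tip_labels(subclade_tree)
    return not _intruding_outgroups(subclade_tree, ogs)


def _intruding_outgroups(tree: dendropy.Tree, ogs: set[str]) -> set[str]:
    if not ogs:
        return set()
    ingroup = tree_ops.tip_labels(tree) - ogs
    if not ingroup:
        raise ContractError("no ingroup tips left after outgroup removal")
    node = tree_ops.mrca(tree, ingroup)
    inside = {l.taxon.label for l in node.leaf_iter()}
    return inside & ogs


def prepare_subclade(
    sample: dendropy.Tree,
    unit: SubcladeUnit,
    target_crown_age: float,
    info: Optional[dict] = None,
) -> dendropy.Tree:
    """Turn one posterior subclade sample into a graftable ingroup tree.

    Applies the unit's sample-level substitutions, verifies ingroup
    monophyly, removes the outgroups and any ``drop_after_outgroups``
    taxa, and rescales so the crown depth equals ``target_crown_age``.
    """
    tree = sample.clone(depth=1)
    tree.migrate_taxon_namespace(dendropy.TaxonNamespace())
    tips = tree_ops.tip_labels(tree)
    for old in sorted(unit.substitutions):
        if old in tips:
            tree_ops.rename_tip_inplace(tree, old, unit.substitutions[old])
            tips = tree_ops.tip_labels(tree)
    ogs = set(unit.outgroups) & tips
    intruders = _intruding_outgroups(tree, ogs)
    if intruders:
        raise MonophylyError(
            f"unit {unit.name!r}: outgroups intrude into the ingroup: "
            f"{sorted(intruders)}",
            intruders=intruders,
        )
    if ogs:
        tree_ops.remove_taxa_inplace(tree, ogs)
    drops = set(unit.drop_after_outgroups) & tree_ops.tip_labels(tree)
    if drops:
        tree_ops.remove_taxa_inplace(tree, drops)
    if info is not None:
        info["pre_rescale_height"] = tree_ops.tree_height(tree)
    return tree_ops.rescale_inplace(tree, target_crown_age)


def _graft_at(
    backbone: dendropy.Tree,
    crown_node: dendropy.Node,
    stem_parent_age: Optional[float],
    prepared: dendropy.Tree,
) -> None:
    """Replace ``crown_node``'s subtree with ``prepared`` (consumed), in
    place.  The caller guarantees ``prepared`` has a private taxon
    namespace and is not reused afterwards."""
    h = tree_ops.tree_height(prepared)
    removed = {l.taxon.label for l in crown_node.leaf_iter()}
    keep = tree_ops.tip_labels(backbone) - removed
    clash = keep & tree_ops.tip_labels(prepared)
    if clash:
        raise ContractError(
            f"grafted tips collide with backbone tips: {sorted(clash)}"
        )
    new = prepared.seed_node
    if stem_parent_age is None:
        new.edge.length = None
        new.parent_node = None
        backbone.seed_node = new
        return
    if h > stem_parent_age * (1 + 1e-12):
        raise AgeConflictError(
            f"prepared subclade height {h:.6g} exceeds stem age "
            f"{stem_parent_age:.6g}"
        )
    parent = crown_node.parent_node
    idx = parent.child_nodes().index(crown_node)
    parent.remove_child(crown_node)
    new.edge.length = stem_parent_age - h
    parent.insert_child(idx, new)


def graft_one(
    backbone: dendropy.Tree, prepared: dendropy.Tree, spec: AttachmentSpec
) -> dendropy.Tree:
    """Graft one prepared subclade onto a backbone; returns a new tree.

    The stem branch is kept: its new length is the stem-node age minus
    the prepared tree's height, so the grafted crown sits exactly at the
    backbone's crown age for that clade and the root age is unchanged.
    """
    bb = backbone.clone(depth=1)
    bb.migrate_taxon_namespace(dendropy.TaxonNamespace())
    node, stem_age = resolve_attachment(bb, spec)
    sub = prepared.clone(depth=1)
    sub.migrate_taxon_namespace(dendropy.TaxonNamespace())
    _graft_at(bb, node, stem_age, sub)
    bb.migrate_taxon_namespace(dendropy.TaxonNamespace())
    bb.is_rooted = True
    return bb


def graft_all(
    backbone: dendropy.Tree,
    units: Sequence[SubcladeUnit],
    samples: Mapping[str, dendropy.Tree],
    records: Optional[list] = None,
) -> dendropy.Tree:
    """Graft every unit's sample onto one backbone sample.

    Backbone-side substitutions are applied first, then all attachment
    nodes are resolved and checked for pairwise disjointness before any
    surgery, so the result is independent of unit order.  ``records``,
    if given, collects one dict per unit with the crown age and scale
    factor used.
    """
    bb = backbone.clone(depth=1)
    bb.migrate_taxon_namespace(dendropy.TaxonNamespace())
    bb_tips = tree_ops.tip_labels(bb)
    for unit in units:
        for old in sorted(unit.substitutions):
            if old in bb_tips:
                tree_ops.rename_tip_inplace(bb, old, unit.substitutions[old])
                bb_tips = tree_ops.tip_labels(bb)

    ages = tree_ops.node_ages(bb)
    below = _leafsets(bb)
    resolved: list[tuple[SubcladeUnit, dendropy.Node, Optional[float]]] = []
    claimed: dict[str, str] = {}
    for unit in units:
        node, stem_age = resolve_attachment(bb, unit.attachment, _below=below, _ages=ages)
        leaves = below[node]
        for lbl in leaves:
            if lbl in claimed:
                raise ConfigError(
                    f"attachment clades of units {claimed[lbl]!r} and "
                    f"{unit.name!r} overlap (e.g., tip {lbl!r})"
                )
        for lbl in leaves:
            claimed[lbl] = unit.name
        resolved.append((unit, node, stem_age))

    for unit, node, stem_age in resolved:
        target = ages[node]
        info: dict = {}
        prepared = prepare_subclade(samples[unit.name], unit, target, info=info)
        if records is not None:
            records.append(
                {
                    "unit": unit.name,
                    "crown_age": target,
                    "scale_factor": target / info["pre_rescale_height"],
                }
            )
        _graft_at(bb, node, stem_age, prepared)

    bb.migrate_taxon_namespace(dendropy.TaxonNamespace())
    bb.is_rooted = True
    return bb
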