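"""Majority-rule consensus with clade support and node-age summaries.

Because every tree in a grafted posterior is a rooted chronogram,
support is counted over *rooted clades* (descendant tip sets), not
unrooted bipartitions.  The consensus contains exactly the clades seen
in more than half the trees (strict majority; ties at exactly 0.5 are
excluded).  Such clades are pairwise compatible, so the consensus always
exists, with multifurcations wherever no majority clade resolves a
region.

Node ages are summarized per consensus clade over the whole trace.  The
default convention uses every tree's MRCA of the clade's tips, whether
or not the tree contains the clade (uses all samples; standard for
dated summaries); ``method="conditional"`` restricts to trees that do
contain the clade.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from hashlib import sha1
from typing import Optional

import dendropy
import numpy as np

from .errors import ContractError, TraceFormatError
from .treeio import TreeTrace, write_newick


@dataclass
class CladeTable:
    """Occurrence counts of rooted clades across a trace."""

    counts: dict[frozenset[str], int]
    n_trees: int

    def frequency(self, clade: frozenset[str]) -> float:
        return self.counts.get(frozenset(clade), 0) / self.n_trees

    def majority_clades(self) -> list[frozenset[str]]:
        """Clades with strict-majority frequency, largest first."""
        out = [c for c, k in self.counts.items() if 2 * k > self.n_trees]
        return sorted(out, key=lambda c: (-len(c), sorted(c)))


@dataclass
class CladeAges:
    median: float
    lower: float   # 2.5% quantile
    upper: float   # 97.5% quantile


@dataclass
class ConsensusSummary:
    """Majority-rule consensus tree with per-clade support and ages.

    ``support`` is in percent.  ``ages`` is filled by
    :func:`summarize_clade_ages`; consensus branch lengths are parent
    minus child median ages, floored at zero (``floored_edges`` counts
    how often the floor was applied).
    """

    tree: dendropy.Tree
    support: dict[frozenset[str], float]
    ages: dict[frozenset[str], CladeAges] = field(default_factory=dict)
    floored_edges: int = 0
    age_method: Optional[str] = None
    n_trees: int = 0


def _tree_clades(tree: dendropy.Tree) -> dict[dendropy.Node, frozenset[str]]:
    """Descendant tip-label set of every internal node (including root)."""
    below: dict[dendropy.Node, frozenset[str]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[node] = frozenset((node.taxon.label,))
        else:
            below[node] = frozenset().union(
                *(below[c] for c in node.child_nodes())
            )
    return {n: s for n, s in below.items() if not n.is_leaf()}


def clade_frequencies(trace: TreeTrace) -> CladeTable:
    """Count every rooted clade observed anywhere in the trace."""
    trace.validate_shared_tips()
    counts: dict[frozenset[str], int] = {}
    for tree in trace:
        for clade in set(_tree_clades(tree).values()):
            counts[clade] = counts.get(clade, 0) + 1
    return CladeTable(counts=counts, n_trees=len(trace))


def _build_consensus_tree(
    clades: list[frozenset[str]], all_tips: frozenset[str]
) -> dendropy.Tree:
    """Nest strict-majority clades into a (possibly multifurcating) tree.

    Clades are inserted largest-first under the smallest clade that
    contains them; strict-majority clades are pairwise compatible, so
    containment is always clean.  Children are ordered by their
    alphabetically smallest tip for deterministic output.
    """
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.is_rooted = True
    nodes: dict[frozenset[str], dendropy.Node] = {all_tips: tree.seed_node}
    ordered = sorted(
        (c for c in clades if c != all_tips),
        key=lambda c: (-len(c), sorted(c)),
    )
    for clade in ordered:
        parent_clade = min(
            (c for c in nodes if clade < c), key=len, default=None
        )
        if parent_clade is None or not clade < parent_clade:
            raise ContractError(
                "incompatible majority clades (cannot happen for strict "
                "majorities over one trace)"
            )
        node = dendropy.Node()
        nodes[parent_clade].add_child(node)
        nodes[clade] = node
    for tip in all_tips:
        parent_clade = min((c for c in nodes if tip in c), key=len)
        leaf = dendropy.Node(taxon=tns.new_taxon(tip))
        nodes[parent_clade].add_child(leaf)
    # deterministic child order
    for node in tree.preorder_node_iter():
        children = node.child_nodes()
        if len(children) > 1:
            keyed = sorted(
                children,
                key=lambda ch: min(l.taxon.label for l in ch.leaf_iter()),
            )
            node.set_child_nodes(keyed)
    return tree


def majority_rule_consensus(trace: TreeTrace) -> ConsensusSummary:
    """Strict majority-rule consensus of a rooted-tree trace.

    The returned topology contains exactly the clades with frequency
    > 0.5; each internal node carries its support in percent.
    """
    table = clade_frequencies(trace)
    all_tips = trace.tip_labels()
    majority = table.majority_clades()
    tree = _build_consensus_tree(majority, all_tips)
    support = {c: 100.0 * table.frequency(c) for c in majority}
    if all_tips not in support:
        support[all_tips] = 100.0
    for node, clade in _tree_clades(tree).items():
        node.label = f"{support[clade]:.1f}"
    return ConsensusSummary(
        tree=tree, support=support, n_trees=len(trace)
    )


def _mrca_age_index(tree: dendropy.Tree):
    """Precompute per-node tip bitmasks and ages for fast MRCA-age lookup."""
    labels = sorted(l.taxon.label for l in tree.leaf_node_iter())
    bit = {lbl: 1 << i for i, lbl in enumerate(labels)}
    masks: dict[dendropy.Node, int] = {}
    depths: dict[dendropy.Node, float] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            masks[node] = bit[node.taxon.label]
        else:
            m = 0
            for c in node.child_nodes():
                m |= masks[c]
            masks[node] = m
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        depths[node] = (
            0.0 if parent is None else depths[parent] + (node.edge.length or 0.0)
        )
    height = max(depths[l] for l in tree.leaf_node_iter())
    return bit, masks, {n: height - d for n, d in depths.items()}


def _descend_mrca_age(tree, masks, ages, query_mask) -> float:
    node = tree.seed_node
    while True:
        for child in node.child_nodes():
            if masks[child] & query_mask == query_mask:
                node = child
                break
        else:
            return ages[node]


def summarize_clade_ages(
    trace: TreeTrace,
    summary: ConsensusSummary,
    method: str = "common_ancestor",
) -> ConsensusSummary:
    """Attach median ages and central 95% intervals to a consensus.

    ``method="common_ancestor"`` (default) collects, for each consensus
    clade, the age of the MRCA of the clade's tips in *every* trace
    tree.  ``method="conditional"`` uses only trees containing the clade
    exactly.  Consensus branch lengths are set to parent − child median
    age, floored at 0; the floored-edge count is recorded.
    """
    if method not in ("common_ancestor", "conditional"):
        raise ContractError(f"unknown age summary method {method!r}")
    clades = list(summary.support)
    samples: dict[frozenset[str], list[float]] = {c: [] for c in clades}
    for tree in trace:
        bit, masks, ages = _mrca_age_index(tree)
        for clade in clades:
            qm = 0
            for lbl in clade:
                qm |= bit[lbl]
            if method == "conditional":
                # only count trees where the clade occurs exactly
                node = tree.seed_node
                found = None
                while True:
                    for child in node.child_nodes():
                        if masks[child] & qm == qm:
                            node = child
                            break
                    else:
                        found = node
                        break
                if masks[found] != qm:
                    continue
                samples[clade].append(ages[found])
            else:
                samples[clade].append(_descend_mrca_age(tree, masks, ages, qm))
    age_map: dict[frozenset[str], CladeAges] = {}
    for clade, vals in samples.items():
        if not vals:
            raise TraceFormatError(
                "no trees contain a consensus clade (conditional method "
                "on a majority clade cannot be empty)"
            )
        arr = np.asarray(vals)
        age_map[clade] = CladeAges(
            median=float(np.median(arr)),
            lower=float(np.quantile(arr, 0.025)),
            upper=float(np.quantile(arr, 0.975)),
        )
    # rebuild consensus branch lengths from age differences
    floored = 0
    node_clades = _tree_clades(summary.tree)
    node_age: dict[dendropy.Node, float] = {}
    for node in summary.tree.preorder_node_iter():
        if node.is_leaf():
            node_age[node] = 0.0
        else:
            node_age[node] = age_map[node_clades[node]].median
    for node in summary.tree.preorder_node_iter():
        parent = node.parent_node
        if parent is None:
            node.edge.length = None
            continue
        length = node_age[parent] - node_age[node]
        if length < 0:
            length = 0.0
            floored += 1
        node.edge.length = length
    summary.ages = age_map
    summary.floored_edges = floored
    summary.age_method = method
    summary.n_trees = len(trace)
    return summary


def clade_hash(clade: frozenset[str]) -> str:
    """Stable short identifier for a clade (first 10 hex chars of the
    SHA-1 of its sorted, newline-joined tip labels)."""
    return sha1("\n".join(sorted(clade)).encode()).hexdigest()[:10]


def write_consensus(summary: ConsensusSummary, prefix) -> None:
    """Write ``<prefix>.nwk`` (support as internal labels) and
    ``<prefix>_clades.tsv`` (clade hash, support %, median age, 95%
    interval, members)."""
    with open(f"{prefix}.nwk", "w") as fh:
        fh.write(write_newick(summary.tree))
    with open(f"{prefix}_clades.tsv", "w") as fh:
        fh.write(
            "clade_hash\tsupport_pct\tmedian_age\tage_lower_2.5\t"
            "age_upper_97.5\tn_tips\tmembers\n"
        )
        for clade in sorted(
            summary.support, key=lambda c: (-len(c), sorted(c))
        ):
            ages = summary.ages.get(clade)
            med = f"{ages.median:.6g}" if ages else ""
            lo = f"{ages.lower:.6g}" if ages else ""
            hi = f"{ages.upper:.6g}" if ages else ""
            fh.write(
                f"{clade_hash(clade)}\t{summary.support[clade]:.2f}\t"
                f"{med}\t{lo}\t{hi}\t{len(clade)}\t"
                f"{'|'.join(sorted(clade))}\n"
            )
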