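"""Reading and writing rooted trees and posterior tree traces.

Trees are :class:`dendropy.Tree` objects throughout the package.  Two
conventions are enforced at the boundary and assumed everywhere else:

* every tree is rooted (dated chronograms are rooted by construction);
* tip labels are preserved verbatim — no underscore/space conversion in
  either direction, so panel matching never depends on silent renames.

A posterior trace is a thin ordered container of trees sharing one tip
set, carrying the burn-in fraction that was applied and whether branch
lengths are in absolute time (Ma) or relative units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import dendropy

from .errors import TraceFormatError, TreeParseError

#: Significant digits used when serializing branch lengths.  Twelve digits
#: sit below floating-point noise but far above biological meaning.
BRANCH_LENGTH_DIGITS = 12

#: Burn-in fraction assumed when a trace does not state one.
DEFAULT_BURNIN = 0.10

_READ_KWARGS = dict(preserve_underscores=True)


def _validate_tree(tree: dendropy.Tree) -> dendropy.Tree:
    tree.is_rooted = True
    labels = []
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is None:
            raise TreeParseError("unlabelled tip in tree")
        labels.append(leaf.taxon.label)
    dupes = {x for x in labels if labels.count(x) > 1}
    if dupes:
        raise TreeParseError(f"duplicate tip labels: {sorted(dupes)}")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            head = edge.head_node
            name = head.taxon.label if head.taxon else "<internal>"
            raise TreeParseError(
                f"negative branch length {edge.length} on edge to {name!r}"
            )
    return tree


def read_newick(text: str) -> dendropy.Tree:
    """Parse a single rooted tree from a Newick string.

    Supports branch lengths, quoted labels and internal-node labels.
    Raises :class:`TreeParseError` on unbalanced parentheses, duplicate
    tip labels or negative branch lengths; the underlying parser message
    includes the offending line/column.
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            **_READ_KWARGS,
        )
    except TreeParseError:
        raise
    except Exception as exc:  # dendropy raises assorted DataError subclasses
        raise TreeParseError(f"Newick parse failure: {exc}") from exc
    return _validate_tree(tree)


def write_newick(tree: dendropy.Tree, precision: int = BRANCH_LENGTH_DIGITS) -> str:
    """Serialize a tree to one deterministic Newick line.

    Children are emitted in stored order; labels containing spaces or
    Newick punctuation are single-quoted, everything else is written
    verbatim.  The root edge is omitted when it has no length.
    """
    out = tree.as_string(
        schema="newick",
        real_value_format_specifier=f".{precision}g",
        unquoted_underscores=True,
        preserve_spaces=True,
        suppress_rooting=True,
        suppress_internal_taxon_labels=False,
    )
    return out.strip() + "\n"


@dataclass
class TreeTrace:
    """An ordered sample of rooted trees from one or more MCMC runs.

    Parameters
    ----------
    trees:
        The retained (post burn-in) trees, in sampling order.
    burnin_fraction:
        Fraction of each source run that was discarded before these trees
        were collected.  Recorded so downstream steps can assert burn-in
        was applied.
    time_units:
        ``"absolute"`` for fossil-calibrated chronograms in Ma,
        ``"relative"`` for trees whose depths are proportional to time only.
    sources:
        Identifiers of the runs the trees came from.
    """

    trees: list[dendropy.Tree]
    burnin_fraction: float = 0.0
    time_units: str = "absolute"
    sources: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.time_units not in ("absolute", "relative"):
            raise TraceFormatError(
                f"time_units must be 'absolute' or 'relative', got {self.time_units!r}"
            )
        if not self.trees:
            raise TraceFormatError("empty tree trace")

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self) -> Iterator[dendropy.Tree]:
        return iter(self.trees)

    def __getitem__(self, i):
        return self.trees[i]

    def tip_labels(self) -> frozenset[str]:
        """Tip-label set of the first tree (all trees must share it)."""
        return frozenset(l.taxon.label for l in self.trees[0].leaf_node_iter())

    def validate_shared_tips(self) -> None:
        ref = self.tip_labels()
        for i, t in enumerate(self.trees):
            tips = frozenset(l.taxon.label for l in t.leaf_node_iter())
            if tips != ref:
                diff = sorted(tips.symmetric_difference(ref))
                raise TraceFormatError(
                    f"tree {i} tip set differs from first tree: {diff}"
                )


def read_nexus_trace(
    path, burnin_fraction: float = DEFAULT_BURNIN, time_units: str = "absolute"
) -> TreeTrace:
    """Read a NEXUS trees block (translate table resolved) and drop burn-in.

    The first ``floor(burnin_fraction * n)`` trees are discarded; the
    applied fraction is recorded on the returned trace.
    """
    if not (0 <= burnin_fraction < 1):
        raise TraceFormatError(
            f"burn-in fraction must be in [0, 1), got {burnin_fraction}"
        )
    try:
        trees = dendropy.TreeList.get(
            path=str(path),
            schema="nexus",
            rooting="force-rooted",
            **_READ_KWARGS,
        )
    except Exception as exc:
        raise TraceFormatError(f"cannot read NEXUS trace {path}: {exc}") from exc
    if len(trees) == 0:
        raise TraceFormatError(f"no trees found in {path}")
    drop = int(burnin_fraction * len(trees))
    kept = [_validate_tree(t) for t in trees[drop:]]
    trace = TreeTrace(
        trees=kept,
        burnin_fraction=burnin_fraction,
        time_units=time_units,
        sources=[str(path)],
    )
    trace.validate_shared_tips()
    return trace


def write_nexus_trace(trace: TreeTrace, path) -> None:
    """Write a trace as a NEXUS trees block with a translate table."""
    tns = dendropy.TaxonNamespace()
    tl = dendropy.TreeList(taxon_namespace=tns)
    for t in trace.trees:
        c = t.clone(depth=1)
        c.migrate_taxon_namespace(tns)
        tl.append(c)
    with open(path, "w") as fh:
        fh.write(
            tl.as_string(
                schema="nexus",
                translate_tree_taxa=True,
                unquoted_underscores=True,
                preserve_spaces=True,
                real_value_format_specifier=f".{BRANCH_LENGTH_DIGITS}g",
            )
        )


def write_newick_trace(trace: TreeTrace, path) -> None:
    """Write a trace as plain Newick, one tree per line."""
    with open(path, "w") as fh:
        for t in trace.trees:
            fh.write(write_newick(t))


def read_newick_trace(
    path, burnin_fraction: float = 0.0, time_units: str = "absolute"
) -> TreeTrace:
    """Read a one-tree-per-line Newick file as a trace."""
    with open(path) as fh:
        text = fh.read()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise TraceFormatError(f"no trees found in {path}")
    drop = int(burnin_fraction * len(lines))
    trees = [read_newick(ln) for ln in lines[drop:]]
    trace = TreeTrace(
        trees=trees,
        burnin_fraction=burnin_fraction,
        time_units=time_units,
        sources=[str(path)],
    )
    trace.validate_shared_tips()
    return trace


def combine_traces(
    traces: Sequence[TreeTrace], allow_unburned: bool = False
) -> TreeTrace:
    """Concatenate post burn-in traces from independent runs.

    All inputs must share one tip set and one time-units flag.  Each
    input must record a positive burn-in fraction unless
    ``allow_unburned`` is set (e.g., for synthetic traces that never had
    a burn-in phase).
    """
    if not traces:
        raise TraceFormatError("no traces to combine")
    ref = traces[0].tip_labels()
    for tr in traces[1:]:
        tips = tr.tip_labels()
        if tips != ref:
            diff = sorted(tips.symmetric_difference(ref))
            raise TraceFormatError(f"tip-set mismatch between traces: {diff}")
        if tr.time_units != traces[0].time_units:
            raise TraceFormatError("cannot combine absolute and relative traces")
    for tr in traces:
        if tr.burnin_fraction <= 0 and not allow_unburned:
            raise TraceFormatError(
                "trace has no recorded burn-in; pass allow_unburned=True "
                "if burn-in was handled upstream"
            )
    trees: list[dendropy.Tree] = []
    sources: list[str] = []
    for tr in traces:
        trees.extend(tr.trees)
        sources.extend(tr.sources)
    return TreeTrace(
        trees=trees,
        burnin_fraction=min(tr.burnin_fraction for tr in traces),
        time_units=traces[0].time_units,
        sources=sources,
    )
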