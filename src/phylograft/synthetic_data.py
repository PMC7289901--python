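"""Synthetic backbone and subclade posteriors with recorded ground truth.

The real study grafts Bayesian posterior samples of 12 butterfly
subclades onto a fossil-calibrated genus-level backbone posterior.  This
module fabricates the same artifact structure at desk scale:

* an ultrametric birth–death backbone whose node ages carry posterior-style
  jitter from sample to sample (topology fixed, as in the backbone study);
* per-unit subclade traces in *relative* time (ingroup crown depth
  normalized to 1) with 2–3 outgroups attached outside the ingroup and
  free ingroup topology (nearest-neighbour-interchange moves);
* the exact generating trees and crown ages, kept as ground truth for
  recovery tests.

Everything is driven by one master seed; each unit draws its own
substream so edits to one unit leave the others byte-identical.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass
from typing import Mapping

import dendropy

from . import tree_ops
from .errors import ConfigError, ContractError, ParameterError
from .graft import AttachmentSpec, SubcladeUnit
from .treeio import TreeTrace

#: Stem ages of successively attached outgroups, as multiples of the
#: ingroup crown age.  Arbitrary but fixed; outside the ingroup by
#: construction.
OUTGROUP_STEM_MULTIPLIERS = (1.3, 1.6, 1.9, 2.2)


@dataclass
class SimulationParams:
    """Knobs of the synthetic posterior.

    ``birth_rate``/``death_rate`` are in events per lineage per Ma;
    ``jitter_sd`` is the log-scale standard deviation of the
    multiplicative node-age perturbation between posterior samples;
    ``topology_shuffle_prob`` is the per-sample probability of one
    nearest-neighbour interchange.
    """

    n_tips: int = 50
    birth_rate: float = 0.12
    death_rate: float = 0.06
    jitter_sd: float = 0.05
    topology_shuffle_prob: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tips < 2:
            raise ParameterError("n_tips must be at least 2")
        if self.birth_rate <= 0:
            raise ParameterError("birth_rate must be positive")
        if self.death_rate < 0:
            raise ParameterError("death_rate must be non-negative")
        if self.death_rate >= self.birth_rate:
            raise ParameterError("death_rate must be below birth_rate")
        if self.jitter_sd < 0:
            raise ParameterError("jitter_sd must be non-negative")
        if not (0 <= self.topology_shuffle_prob <= 1):
            raise ParameterError("topology_shuffle_prob must be in [0, 1]")

    def with_(self, **kw) -> "SimulationParams":
        d = self.__dict__.copy()
        d.update(kw)
        return SimulationParams(**d)


@dataclass
class StudyTruth:
    """The generating trees behind a synthetic study.

    ``true_subclade_trees`` are the ingroup trees in absolute time, so
    each one's height equals its entry in ``true_crown_ages``.  ``panel``
    is the subset of final tip labels designated "regional" for pruning
    tests.
    """

    true_backbone: dendropy.Tree
    true_subclade_trees: dict[str, dendropy.Tree]
    true_crown_ages: dict[str, float]
    panel: frozenset[str]


def simulate_bd_tree(params: SimulationParams, label_prefix: str = "T") -> dendropy.Tree:
    """Simulate an ultrametric birth–death tree with exactly ``n_tips``.

    Forward simulation from a crown split at time 0; runs where the
    clade dies out are rejected and restarted.  The simulation is frozen
    at a uniform point within the first inter-event interval in which
    the extant count reaches ``n_tips``, so every pendant branch has
    strictly positive length.  Extinct lineages are pruned.
    """
    rng = random.Random(params.seed)
    b, d, n = params.birth_rate, params.death_rate, params.n_tips
    for _attempt in range(10000):
        tree = _simulate_once(rng, b, d, n)
        if tree is not None:
            for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
                leaf.taxon = tree.taxon_namespace.new_taxon(f"{label_prefix}{i}")
            tree.is_rooted = True
            return tree
    raise ParameterError(
        "birth-death simulation failed to reach the requested tip count"
    )


def _simulate_once(rng, b, d, n):
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    root = tree.seed_node
    root.birth_time = 0.0
    left, right = dendropy.Node(), dendropy.Node()
    left.birth_time = right.birth_time = 0.0
    root.add_child(left)
    root.add_child(right)
    alive = [left, right]
    dead = []
    t = 0.0
    while True:
        k = len(alive)
        if k == 0:
            return None  # extinction: reject
        dt = rng.expovariate(k * (b + d))
        if k == n:
            t += rng.random() * dt
            break
        t += dt
        idx = rng.randrange(k)
        node = alive[idx]
        if rng.random() < b / (b + d):
            node.edge.length = t - node.birth_time
            c1, c2 = dendropy.Node(), dendropy.Node()
            c1.birth_time = c2.birth_time = t
            node.add_child(c1)
            node.add_child(c2)
            alive[idx] = c1
            alive.append(c2)
        else:
            node.edge.length = t - node.birth_time
            dead.append(node)
            alive.pop(idx)
    for node in alive:
        node.edge.length = t - node.birth_time
    if dead:
        for node in dead:
            _remove_dead(node)
    while len(tree.seed_node.child_nodes()) == 1:
        child = tree.seed_node.child_nodes()[0]
        child.parent_node = None
        tree.seed_node = child
    tree.seed_node.edge.length = None
    if sum(1 for _ in tree.leaf_node_iter()) != n:
        return None
    return tree


def _remove_dead(node):
    # delete an extinct pendant lineage, suppressing the unifurcation it
    # leaves behind by summing the incident branch lengths
    parent = node.parent_node
    if parent is None:
        return
    parent.remove_child(node)
    if len(parent.child_nodes()) == 1 and parent.parent_node is not None:
        only = parent.child_nodes()[0]
        grand = parent.parent_node
        only.edge.length = (only.edge.length or 0.0) + (parent.edge.length or 0.0)
        idx = grand.child_nodes().index(parent)
        grand.remove_child(parent)
        grand.insert_child(idx, only)


def _jitter_ages(tree, ages, rng, jitter_sd):
    """Resample internal node ages root-to-tip with multiplicative
    lognormal jitter, truncated into (max original child age, new parent
    age) so the result is always a valid chronogram."""
    new_age: dict = {}
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            new_age[node] = 0.0
            continue
        parent = node.parent_node
        hi = math.inf if parent is None else new_age[parent]
        lo = max(
            (ages[c] for c in node.child_nodes() if not c.is_leaf()), default=0.0
        )
        a = None
        for _ in range(100):
            cand = ages[node] * math.exp(rng.gauss(0.0, jitter_sd))
            if lo < cand < hi:
                a = cand
                break
        if a is None:
            a = lo + rng.random() * ((hi if hi < math.inf else ages[node] * 2) - lo)
        new_age[node] = a
    return new_age


def _nni(tree, new_age, rng):
    """One random nearest-neighbour interchange on an internal edge,
    repairing the rearranged node's age if the swap violated ordering."""
    edges = [
        nd
        for nd in tree.preorder_node_iter()
        if not nd.is_leaf() and nd.parent_node is not None
    ]
    if not edges:
        return
    v = rng.choice(edges)
    u = v.parent_node
    siblings = [c for c in u.child_nodes() if c is not v]
    s = rng.choice(siblings)
    c = rng.choice(v.child_nodes())
    si = u.child_nodes().index(s)
    ci = v.child_nodes().index(c)
    u.remove_child(s)
    v.remove_child(c)
    u.insert_child(si, c)
    v.insert_child(ci, s)
    max_child = max(new_age[x] for x in v.child_nodes())
    if new_age[v] <= max_child:
        new_age[v] = max_child + rng.random() * (new_age[u] - max_child)


def perturb_trace(
    tree: dendropy.Tree, n_samples: int, params: SimulationParams
) -> TreeTrace:
    """Emulate a posterior trace around one ultrametric tree.

    Each sample re-draws every internal node age with lognormal
    multiplicative jitter (sd ``params.jitter_sd`` on the log scale),
    preserving parent-older-than-child ordering, and applies one random
    NNI move with probability ``params.topology_shuffle_prob``.  Tips
    stay at age 0.  With zero jitter and zero shuffle probability the
    samples are exact copies of the input.
    """
    if n_samples < 1:
        raise ParameterError("n_samples must be at least 1")
    if not tree_ops.is_ultrametric(tree, rel_tol=1e-6):
        raise ContractError("perturb_trace requires an ultrametric input tree")
    rng = random.Random(params.seed)
    ages0 = tree_ops.node_ages(tree)
    samples = []
    for _ in range(n_samples):
        clone = tree.clone(depth=1)
        # map original nodes onto clone nodes (clone preserves traversal order)
        pairs = list(
            zip(tree.preorder_node_iter(), clone.preorder_node_iter())
        )
        ages = {cn: ages0[on] for on, cn in pairs}
        new_age = _jitter_ages(clone, ages, rng, params.jitter_sd)
        if rng.random() < params.topology_shuffle_prob:
            _nni(clone, new_age, rng)
        for node in clone.preorder_node_iter():
            if node.parent_node is not None:
                node.edge.length = new_age[node.parent_node] - new_age[node]
        clone.seed_node.edge.length = None
        samples.append(clone)
    return TreeTrace(
        trees=samples,
        burnin_fraction=0.0,
        time_units="absolute",
        sources=["perturb_trace"],
    )


def attach_outgroups(tree: dendropy.Tree, outgroup_labels) -> dendropy.Tree:
    """Attach outgroup tips successively rootward of the ingroup crown.

    The k-th outgroup's stem sits at ``OUTGROUP_STEM_MULTIPLIERS[k]`` ×
    the ingroup crown age, so the ingroup (topology and relative ages)
    is preserved and is always monophyletic in the result.
    """
    labels = list(outgroup_labels)
    if not (1 <= len(labels) <= 4):
        raise ContractError("between 1 and 4 outgroups supported")
    if len(set(labels)) != len(labels):
        raise ContractError(f"duplicate outgroup labels: {labels}")
    present = tree_ops.tip_labels(tree)
    clash = present.intersection(labels)
    if clash:
        raise ContractError(f"outgroup labels already in tree: {sorted(clash)}")
    out = tree.clone(depth=1)
    out.migrate_taxon_namespace(dendropy.TaxonNamespace())
    crown = tree_ops.tree_height(out)
    inner = out.seed_node
    inner_age = crown
    for k, lbl in enumerate(labels):
        stem_age = OUTGROUP_STEM_MULTIPLIERS[k] * crown
        new_root = dendropy.Node()
        inner.edge.length = stem_age - inner_age
        og = dendropy.Node(taxon=out.taxon_namespace.new_taxon(lbl))
        og.edge.length = stem_age
        new_root.add_child(inner)
        new_root.add_child(og)
        inner = new_root
        inner_age = stem_age
    out.seed_node = inner
    out.seed_node.parent_node = None
    out.seed_node.edge.length = None
    out.is_rooted = True
    return out


def _select_anchor_clades(backbone, unit_names, rng):
    """Pick pairwise-disjoint internal clades of the backbone, one per
    unit, to serve as the lineages each grafted subclade replaces."""
    n_tips = sum(1 for _ in backbone.leaf_node_iter())
    n_units = len(unit_names)
    cap = max(2, n_tips // max(2, n_units))
    candidates = [
        nd
        for nd in backbone.preorder_internal_node_iter()
        if nd.parent_node is not None
        and 2 <= sum(1 for _ in nd.leaf_iter()) <= cap
    ]
    if len(candidates) < n_units:
        raise ConfigError(
            f"backbone of {n_tips} tips cannot host {n_units} disjoint "
            f"graft clades (only {len(candidates)} candidate clades)"
        )
    for _ in range(200):
        rng.shuffle(candidates)
        chosen = []
        used: set = set()
        for nd in candidates:
            leaves = {l.taxon.label for l in nd.leaf_iter()}
            if leaves.isdisjoint(used):
                chosen.append((nd, leaves))
                used |= leaves
                if len(chosen) == n_units:
                    return chosen
    raise ConfigError(
        f"could not place {n_units} disjoint graft clades on a "
        f"{n_tips}-tip backbone"
    )


def make_study(
    n_backbone_tips: int,
    unit_sizes: Mapping[str, int],
    n_samples: int,
    params: SimulationParams,
):
    """Build a complete runnable synthetic study plus its ground truth.

    Returns ``(StudyConfig, StudyTruth)``.  The backbone trace is in
    absolute time with fixed topology and jittered node ages; each unit's
    trace is in relative time (ingroup crown depth 1) with outgroups
    attached and free ingroup topology.
    """
    from .pipeline import StudyConfig  # local import to avoid a cycle

    if not unit_sizes:
        raise ConfigError("at least one subclade unit is required")
    for name, size in unit_sizes.items():
        if size < 2:
            raise ConfigError(f"unit {name!r} must have at least 2 tips")
    master = random.Random(params.seed)
    backbone_seed = master.randrange(2**31)
    backbone_trace_seed = master.randrange(2**31)
    unit_seeds = {name: master.randrange(2**31) for name in unit_sizes}
    anchor_seed = master.randrange(2**31)
    panel_seed = master.randrange(2**31)

    backbone = simulate_bd_tree(
        params.with_(n_tips=n_backbone_tips, seed=backbone_seed), label_prefix="B"
    )
    anchors = _select_anchor_clades(
        backbone, list(unit_sizes), random.Random(anchor_seed)
    )
    backbone_ages = tree_ops.node_ages(backbone)

    units: list[SubcladeUnit] = []
    true_subclades: dict[str, dendropy.Tree] = {}
    true_crown_ages: dict[str, float] = {}
    replaced_labels: set[str] = set()
    for (name, size), (anchor_node, anchor_leaves) in zip(
        unit_sizes.items(), anchors
    ):
        crown_age = backbone_ages[anchor_node]
        urng = random.Random(unit_seeds[name])
        sim_seed = urng.randrange(2**31)
        trace_seed = urng.randrange(2**31)
        n_outgroups = urng.choice((2, 3))
        ingroup = simulate_bd_tree(
            params.with_(n_tips=size, seed=sim_seed), label_prefix=f"{name}_sp"
        )
        ingroup = tree_ops.rescale_to_crown_age(ingroup, crown_age)
        true_subclades[name] = ingroup
        true_crown_ages[name] = crown_age
        replaced_labels |= anchor_leaves

        og_labels = [f"{name}_out{k + 1}" for k in range(n_outgroups)]
        abs_trace = perturb_trace(
            ingroup, n_samples, params.with_(seed=trace_seed)
        )
        rel_trees = []
        for sample in abs_trace:
            h = tree_ops.tree_height(sample)
            with_ogs = attach_outgroups(sample, og_labels)
            # normalize so the ingroup crown depth is exactly 1
            with_ogs.scale_edges(1.0 / h)
            rel_trees.append(with_ogs)
        rel_trace = TreeTrace(
            trees=rel_trees,
            burnin_fraction=0.0,
            time_units="relative",
            sources=[f"synthetic:{name}"],
        )
        units.append(
            SubcladeUnit(
                name=name,
                trace=rel_trace,
                outgroups=og_labels,
                attachment=AttachmentSpec(
                    mode="mrca", anchors=frozenset(anchor_leaves)
                ),
                substitutions={},
                drop_after_outgroups=[],
            )
        )

    backbone_trace = perturb_trace(
        backbone,
        n_samples,
        params.with_(seed=backbone_trace_seed, topology_shuffle_prob=0.0),
    )

    final_tips = (
        {l.taxon.label for l in backbone.leaf_node_iter()} - replaced_labels
    ) | {
        l.taxon.label
        for t in true_subclades.values()
        for l in t.leaf_node_iter()
    }
    prng = random.Random(panel_seed)
    panel_size = max(2, int(0.6 * len(final_tips)))
    panel = frozenset(prng.sample(sorted(final_tips), panel_size))

    config = StudyConfig(
        backbone_trace=backbone_trace,
        units=units,
        n_replicates=n_samples,
        seed=params.seed,
        pairing="indexed",
        panel=panel,
        burnin=0.0,
    )
    truth = StudyTruth(
        true_backbone=backbone,
        true_subclade_trees=true_subclades,
        true_crown_ages=true_crown_ages,
        panel=panel,
    )
    return config, truth
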