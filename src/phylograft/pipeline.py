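"""Replicate loop: pair posterior samples, graft, and collect the output.

One replicate pairs a backbone posterior sample with one posterior
sample per subclade unit, grafts every unit, and yields one complete
tree; repeating over the posterior gives the grafted posterior
distribution the study is built on.  Study configurations round-trip
through a plain-text directory (NEXUS traces + YAML config) so runs are
reproducible from disk.
"""

from __future__ import annotations

import hashlib
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import dendropy
import yaml

from . import tree_ops
from .errors import ConfigError, MonophylyError
from .graft import AttachmentSpec, SubcladeUnit, graft_all, resolve_attachment
from .treeio import (
    TreeTrace,
    read_nexus_trace,
    write_newick_trace,
    write_nexus_trace,
)


@dataclass
class StudyConfig:
    """Everything needed to run the grafting pipeline once.

    ``pairing`` is ``"indexed"`` (replicate i takes the i-th post
    burn-in sample of every trace — deterministic alignment of the
    sample streams) or ``"random"`` (seeded uniform draws).  ``burnin``
    is the fraction applied when the traces were loaded.
    """

    backbone_trace: TreeTrace
    units: list[SubcladeUnit]
    n_replicates: int
    seed: int = 0
    pairing: str = "indexed"
    panel: Optional[frozenset[str]] = None
    burnin: float = 0.0

    def __post_init__(self) -> None:
        if self.pairing not in ("indexed", "random"):
            raise ConfigError(f"unknown pairing mode {self.pairing!r}")
        if self.n_replicates < 1:
            raise ConfigError("n_replicates must be positive")
        names = [u.name for u in self.units]
        if len(set(names)) != len(names):
            raise ConfigError(f"duplicate unit names: {names}")
        if self.backbone_trace.time_units != "absolute":
            raise ConfigError("backbone trace must be in absolute time")
        for u in self.units:
            if u.trace is not None and u.trace.time_units != "relative":
                raise ConfigError(
                    f"unit {u.name!r} trace must be in relative time"
                )
        if self.pairing == "indexed":
            for name, m in self._stream_sizes():
                if self.n_replicates > m:
                    raise ConfigError(
                        f"indexed pairing needs ≥{self.n_replicates} samples "
                        f"in stream {name!r}, found {m}"
                    )

    def _stream_sizes(self):
        yield "backbone", len(self.backbone_trace)
        for u in self.units:
            if u.trace is not None:
                yield u.name, len(u.trace)


def _subsample_indices(m: int, n: int) -> list[int]:
    """Evenly spaced indices (first sample, then a fixed stride) used
    when a trace holds more post burn-in samples than replicates."""
    if m == n:
        return list(range(m))
    return [(k * m) // n for k in range(n)]


def run_replicates(
    config: StudyConfig,
    skip_bad_replicates: bool = False,
    records: Optional[list] = None,
) -> TreeTrace:
    """Produce the grafted posterior distribution.

    Returns ``n_replicates`` grafted trees (fewer only if monophyly
    violations are skipped under ``skip_bad_replicates``).  ``records``
    collects one dict per unit per replicate with the crown age and
    rescale factor used, replicate-stamped.
    """
    n = config.n_replicates
    if config.pairing == "indexed":
        bb_idx = _subsample_indices(len(config.backbone_trace), n)
        unit_idx = {
            u.name: _subsample_indices(len(u.trace), n) for u in config.units
        }
        pair = lambda r: (
            bb_idx[r],
            {u.name: unit_idx[u.name][r] for u in config.units},
        )
    else:
        rng = random.Random(config.seed)
        draws = []
        for _ in range(n):
            bi = rng.randrange(len(config.backbone_trace))
            ui = {u.name: rng.randrange(len(u.trace)) for u in config.units}
            draws.append((bi, ui))
        pair = lambda r: draws[r]

    out: list[dendropy.Tree] = []
    for r in range(n):
        bi, ui = pair(r)
        backbone = config.backbone_trace[bi]
        samples = {u.name: u.trace[ui[u.name]] for u in config.units}
        rep_records: list = [] if records is not None else None
        try:
            tree = graft_all(backbone, config.units, samples, records=rep_records)
        except MonophylyError as exc:
            if skip_bad_replicates:
                continue
            raise MonophylyError(
                f"replicate {r}: {exc}", intruders=exc.intruders
            ) from exc
        if records is not None:
            for rec in rep_records:
                rec["replicate"] = r
                records.append(rec)
        out.append(tree)
    if not out:
        raise ConfigError("all replicates were skipped")
    trace = TreeTrace(
        trees=out,
        burnin_fraction=config.burnin,
        time_units="absolute",
        sources=["grafted"],
    )
    trace.validate_shared_tips()
    return trace


def prune_to_panel(trace: TreeTrace, panel) -> TreeTrace:
    """Prune every tree in a trace down to a species panel.

    Path lengths among panel tips are preserved; each pruned tree's root
    is the MRCA of the panel in that tree.
    """
    panel = frozenset(panel)
    if len(panel) < 2:
        raise ConfigError("panel must contain at least 2 labels")
    tips = trace.tip_labels()
    missing = panel - tips
    if missing:
        raise ConfigError(f"panel labels absent from trace: {sorted(missing)}")
    pruned = [tree_ops.remove_taxa(t, tips - panel) for t in trace.trees]
    return TreeTrace(
        trees=pruned,
        burnin_fraction=trace.burnin_fraction,
        time_units=trace.time_units,
        sources=trace.sources + ["pruned-to-panel"],
    )


# ---------------------------------------------------------------------------
# study directory round-trip

_CONFIG_NAME = "study.yaml"


def _unit_to_yaml(unit: SubcladeUnit, trace_file: str) -> dict:
    att = {
        "mode": unit.attachment.mode,
        "anchors": sorted(unit.attachment.anchors),
    }
    if unit.attachment.anchors_b:
        att["anchors_b"] = sorted(unit.attachment.anchors_b)
    if unit.attachment.exclusions:
        att["exclusions"] = sorted(unit.attachment.exclusions)
    return {
        "name": unit.name,
        "trace": trace_file,
        "outgroups": list(unit.outgroups),
        "attachment": att,
        "substitutions": dict(sorted(unit.substitutions.items())),
        "drop_after_outgroups": list(unit.drop_after_outgroups),
    }


def _unit_from_yaml(d: dict, base: Path, burnin: float) -> SubcladeUnit:
    att = d["attachment"]
    spec = AttachmentSpec(
        mode=att["mode"],
        anchors=frozenset(att["anchors"]),
        anchors_b=frozenset(att["anchors_b"]) if att.get("anchors_b") else None,
        exclusions=frozenset(att.get("exclusions", ())),
    )
    trace = read_nexus_trace(
        base / d["trace"], burnin_fraction=burnin, time_units="relative"
    )
    return SubcladeUnit(
        name=d["name"],
        trace=trace,
        outgroups=list(d.get("outgroups", ())),
        attachment=spec,
        substitutions=dict(d.get("substitutions", {})),
        drop_after_outgroups=list(d.get("drop_after_outgroups", ())),
    )


def write_study(config: StudyConfig, outdir, truth=None) -> Path:
    """Write a study as a plain-text directory.

    Layout: ``study.yaml`` (configuration), ``backbone.trees`` and one
    ``unit_<name>.trees`` NEXUS trace per unit (translate tables),
    ``panel.txt`` (one label per line) and, when ground truth is given,
    ``truth.tsv`` (unit, true crown age).  Stored traces are post
    burn-in, so the written config sets ``burnin: 0.0``.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_nexus_trace(config.backbone_trace, out / "backbone.trees")
    unit_entries = []
    for unit in config.units:
        fname = f"unit_{unit.name}.trees"
        write_nexus_trace(unit.trace, out / fname)
        unit_entries.append(_unit_to_yaml(unit, fname))
    doc = {
        "backbone": {"trace": "backbone.trees"},
        "units": unit_entries,
        "n_replicates": config.n_replicates,
        "seed": config.seed,
        "pairing": config.pairing,
        "burnin": 0.0,
    }
    if config.panel is not None:
        doc["panel"] = "panel.txt"
        with open(out / "panel.txt", "w") as fh:
            for lbl in sorted(config.panel):
                fh.write(lbl + "\n")
    with open(out / _CONFIG_NAME, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False, allow_unicode=True)
    if truth is not None:
        with open(out / "truth.tsv", "w") as fh:
            fh.write("unit\ttrue_crown_age\n")
            for name in truth.true_crown_ages:
                fh.write(f"{name}\t{truth.true_crown_ages[name]:.12g}\n")
    return out


def load_config(path) -> StudyConfig:
    """Load and fully validate a study directory (or its ``study.yaml``).

    Beyond parsing, this checks that every referenced trace is readable,
    that every anchor label occurs in the first backbone sample, and
    that the units' attachment clades are pairwise disjoint there.
    """
    p = Path(path)
    if p.is_dir():
        p = p / _CONFIG_NAME
    if not p.exists():
        raise ConfigError(f"no study configuration at {p}")
    base = p.parent
    with open(p) as fh:
        doc = yaml.safe_load(fh)
    try:
        burnin = float(doc.get("burnin", 0.0))
        backbone = read_nexus_trace(
            base / doc["backbone"]["trace"],
            burnin_fraction=burnin,
            time_units="absolute",
        )
        units = [_unit_from_yaml(d, base, burnin) for d in doc["units"]]
        panel = None
        if doc.get("panel"):
            with open(base / doc["panel"]) as fh:
                panel = frozenset(
                    ln.strip() for ln in fh if ln.strip()
                )
        config = StudyConfig(
            backbone_trace=backbone,
            units=units,
            n_replicates=int(doc["n_replicates"]),
            seed=int(doc.get("seed", 0)),
            pairing=doc.get("pairing", "indexed"),
            panel=panel,
            burnin=burnin,
        )
    except KeyError as exc:
        raise ConfigError(f"missing configuration key: {exc}") from exc
    # anchor/overlap validation against the first backbone sample
    first = config.backbone_trace[0]
    claimed: dict[str, str] = {}
    for unit in config.units:
        try:
            node, _ = resolve_attachment(first, unit.attachment)
        except ConfigError as exc:
            raise ConfigError(f"unit {unit.name!r}: {exc}") from exc
        for leaf in node.leaf_iter():
            lbl = leaf.taxon.label
            if lbl in claimed:
                raise ConfigError(
                    f"attachment clades of units {claimed[lbl]!r} and "
                    f"{unit.name!r} overlap in the backbone (tip {lbl!r})"
                )
            claimed[lbl] = unit.name
    return config


def config_digest(path) -> str:
    """SHA-256 of the study.yaml file, for provenance headers."""
    p = Path(path)
    if p.is_dir():
        p = p / _CONFIG_NAME
    return hashlib.sha256(p.read_bytes()).hexdigest()[:16]


def run_study(
    config: StudyConfig,
    outdir,
    skip_bad_replicates: bool = False,
    panel: Optional[frozenset[str]] = None,
    provenance: Optional[dict] = None,
) -> TreeTrace:
    """Run the replicate loop and write the grafted distribution to disk.

    Writes ``grafted.trees`` (NEXUS), ``grafted.nwk`` (one Newick per
    line), ``run_log.tsv`` (replicate, unit, crown age, scale factor)
    and ``provenance.txt``.  Panel pruning is applied only when a panel
    is passed explicitly.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    records: list = []
    trace = run_replicates(
        config, skip_bad_replicates=skip_bad_replicates, records=records
    )
    if panel is not None:
        trace = prune_to_panel(trace, panel)
    write_nexus_trace(trace, out / "grafted.trees")
    write_newick_trace(trace, out / "grafted.nwk")
    with open(out / "run_log.tsv", "w") as fh:
        fh.write("replicate\tunit\tcrown_age\tscale_factor\n")
        for rec in records:
            fh.write(
                f"{rec['replicate']}\t{rec['unit']}\t"
                f"{rec['crown_age']:.12g}\t{rec['scale_factor']:.12g}\n"
            )
    with open(out / "provenance.txt", "w") as fh:
        fh.write(f"seed\t{config.seed}\n")
        fh.write(f"pairing\t{config.pairing}\n")
        fh.write(f"n_replicates\t{config.n_replicates}\n")
        fh.write(f"burnin\t{config.burnin}\n")
        for key, val in (provenance or {}).items():
            fh.write(f"{key}\t{val}\n")
    return trace
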