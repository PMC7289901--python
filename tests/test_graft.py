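"""Attachment resolution, subclade preparation and grafting surgery."""

import pytest

from phylograft import (
    AgeConflictError,
    AttachmentSpec,
    ConfigError,
    ContractError,
    MonophylyError,
    SimulationParams,
    SubcladeUnit,
    check_ingroup_monophyly,
    extract_clade,
    graft_all,
    graft_one,
    mrca,
    node_ages,
    prepare_subclade,
    read_newick,
    resolve_attachment,
    tree_height,
    write_newick,
)
from phylograft.synthetic_data import make_study
from phylograft.tree_ops import tip_labels

# A backbone shaped like the early-diverging-lineage case: one relict tip
# stays in place while the rest of the family is replaced.
BACKBONE = "((Baronia:50,(X:30,Y:30):20):10,Out:60);"


@pytest.fixture
def backbone():
    return read_newick(BACKBONE)


class TestResolveAttachment:
    def test_mrca_excluding(self, backbone):
        spec = AttachmentSpec(
            mode="mrca_excluding",
            anchors=frozenset({"Baronia", "X", "Y"}),
            exclusions=frozenset({"Baronia"}),
        )
        node, stem_age = resolve_attachment(backbone, spec)
        assert {l.taxon.label for l in node.leaf_iter()} == {"X", "Y"}
        assert node_ages(backbone)[node] == pytest.approx(30.0)
        assert stem_age == pytest.approx(50.0)

    def test_plain_mrca_same_node(self, backbone):
        spec = AttachmentSpec(mode="mrca", anchors=frozenset({"X", "Y"}))
        node, stem_age = resolve_attachment(backbone, spec)
        assert {l.taxon.label for l in node.leaf_iter()} == {"X", "Y"}
        assert stem_age == pytest.approx(50.0)

    def test_split_mode_resolves_common_parent(self):
        t = read_newick(
            "(((H1:10,H2:10):10,(L1:12,L2:12):8):20,Out:40);"
        )
        spec = AttachmentSpec(
            mode="split",
            anchors=frozenset({"H1", "H2"}),
            anchors_b=frozenset({"L1", "L2"}),
        )
        node, stem_age = resolve_attachment(t, spec)
        assert {l.taxon.label for l in node.leaf_iter()} == {"H1", "H2", "L1", "L2"}
        assert stem_age == pytest.approx(40.0)

    def test_crown_of_unit_ignores_missing_anchors(self, backbone):
        spec = AttachmentSpec(
            mode="crown_of_unit",
            anchors=frozenset({"X", "Y", "species_not_in_backbone"}),
        )
        node, _ = resolve_attachment(backbone, spec)
        assert {l.taxon.label for l in node.leaf_iter()} == {"X", "Y"}

    def test_root_crown_has_no_stem_age(self, backbone):
        spec = AttachmentSpec(
            mode="mrca", anchors=frozenset({"Baronia", "Out"})
        )
        node, stem_age = resolve_attachment(backbone, spec)
        assert node is backbone.seed_node
        assert stem_age is None

    def test_tip_resolution_rejected(self, backbone):
        with pytest.raises(ContractError):
            resolve_attachment(
                backbone, AttachmentSpec(mode="mrca", anchors=frozenset({"X"}))
            )

    def test_unknown_anchor_named(self, backbone):
        with pytest.raises(ConfigError, match="Zeta"):
            resolve_attachment(
                backbone,
                AttachmentSpec(mode="mrca", anchors=frozenset({"X", "Zeta"})),
            )

    def test_exclusions_covering_clade_rejected(self, backbone):
        with pytest.raises(ConfigError):
            resolve_attachment(
                backbone,
                AttachmentSpec(
                    mode="mrca_excluding",
                    anchors=frozenset({"X", "Y"}),
                    exclusions=frozenset({"X", "Y"}),
                ),
            )


class TestMonophyly:
    def test_nested_outgroups_ok(self):
        t = read_newick("(O1:4,(O2:3,(A:1,(B:0.5,C:0.5):0.5):2):1);")
        assert check_ingroup_monophyly(t, {"O1", "O2"})

    def test_intruding_outgroup_detected(self):
        t = read_newick("((A:1,O1:1):1,(B:1.5,C:1.5):0.5);")
        assert not check_ingroup_monophyly(t, {"O1"})


def _unit(name="u", outgroups=("O1", "O2"), subs=None, drops=()):
    return SubcladeUnit(
        name=name,
        trace=None,
        outgroups=list(outgroups),
        attachment=AttachmentSpec(mode="mrca", anchors=frozenset({"X", "Y"})),
        substitutions=subs or {},
        drop_after_outgroups=list(drops),
    )


class TestPrepareSubclade:
    def test_outgroup_and_relict_removal_then_rescale(self):
        # 6-tip sample: 3 outgroups, one early-diverging taxon to drop
        sample = read_newick(
            "(O3:2.2,(O2:1.9,(O1:1.6,(Relict:1.3,(P:1,(Q:0.6,R:0.6):0.4)"
            ":0.3):0.3):0.3):0.3);"
        )
        unit = _unit(outgroups=("O1", "O2", "O3"), drops=("Relict",))
        prepared = prepare_subclade(sample, unit, 30.0)
        assert tip_labels(prepared) == {"P", "Q", "R"}
        assert tree_height(prepared) == pytest.approx(30.0)

    def test_identity_when_nothing_to_do(self):
        sample = read_newick("(P:1,(Q:0.6,R:0.6):0.4);")
        unit = _unit(outgroups=())
        prepared = prepare_subclade(sample, unit, 1.0)
        assert write_newick(prepared) == write_newick(sample)

    def test_substitution_applied_to_sample(self):
        sample = read_newick("(O1:2,(P:1,(Q:0.6,R:0.6):0.4):1);")
        unit = _unit(outgroups=("O1",), subs={"P": "P_new"})
        prepared = prepare_subclade(sample, unit, 10.0)
        assert tip_labels(prepared) == {"P_new", "Q", "R"}

    def test_monophyly_violation_names_intruders(self):
        sample = read_newick("((P:1,O1:1):1,(Q:1.5,R:1.5):0.5);")
        unit = _unit(outgroups=("O1",))
        with pytest.raises(MonophylyError, match="O1"):
            prepare_subclade(sample, unit, 10.0)

    def test_tip_set_algebra_random_unit(self):
        config, _ = make_study(
            30, {"a": 6}, 1, SimulationParams(seed=37, jitter_sd=0.05)
        )
        unit = config.units[0]
        sample = unit.trace[0]
        prepared = prepare_subclade(sample, unit, 12.0)
        assert tip_labels(prepared) == tip_labels(sample) - set(unit.outgroups)


class TestGraftOne:
    def test_stem_rule_fixture(self, backbone):
        prepared = read_newick("(P:30,(Q:18,R:18):12);")
        spec = AttachmentSpec(mode="mrca", anchors=frozenset({"X", "Y"}))
        result = graft_one(backbone, prepared, spec)
        expected = read_newick(
            "((Baronia:50,(P:30,(Q:18,R:18):12):20):10,Out:60);"
        )
        assert write_newick(result) == write_newick(expected)

    def test_idempotent_self_graft(self, backbone):
        node = mrca(backbone, {"X", "Y"})
        clade = extract_clade(backbone, node)
        spec = AttachmentSpec(mode="mrca", anchors=frozenset({"X", "Y"}))
        result = graft_one(backbone, clade, spec)
        assert write_newick(result) == write_newick(backbone)

    def test_age_conflict_reported(self, backbone):
        prepared = read_newick("(P:55,(Q:30,R:30):25);")  # older than stem (50)
        spec = AttachmentSpec(mode="mrca", anchors=frozenset({"X", "Y"}))
        with pytest.raises(AgeConflictError, match="55.*50|50.*55"):
            graft_one(backbone, prepared, spec)

    def test_label_collision_rejected(self, backbone):
        prepared = read_newick("(Out:30,(Q:18,R:18):12);")
        spec = AttachmentSpec(mode="mrca", anchors=frozenset({"X", "Y"}))
        with pytest.raises(ContractError, match="Out"):
            graft_one(backbone, prepared, spec)


class TestGraftAll:
    @pytest.fixture
    def study(self):
        return make_study(
            40, {"u1": 5, "u2": 4, "u3": 6}, 2, SimulationParams(seed=41)
        )

    def test_tip_set_algebra(self, study):
        config, _ = study
        bb = config.backbone_trace[0]
        samples = {u.name: u.trace[0] for u in config.units}
        result = graft_all(bb, config.units, samples)
        expected = set(tip_labels(bb))
        for u in config.units:
            node, _ = resolve_attachment(bb, u.attachment)
            expected -= {l.taxon.label for l in node.leaf_iter()}
            expected |= tip_labels(samples[u.name]) - set(u.outgroups)
        assert tip_labels(result) == expected

    def test_unit_order_independence(self, study):
        config, _ = study
        bb = config.backbone_trace[0]
        samples = {u.name: u.trace[0] for u in config.units}
        forward = graft_all(bb, config.units, samples)
        backward = graft_all(bb, list(reversed(config.units)), samples)
        assert write_newick(forward) == write_newick(backward)

    def test_zero_units_is_identity(self, study):
        config, _ = study
        bb = config.backbone_trace[0]
        assert write_newick(graft_all(bb, [], {})) == write_newick(bb)

    def test_overlapping_units_rejected(self, backbone):
        u1 = SubcladeUnit(
            name="first",
            trace=None,
            outgroups=[],
            attachment=AttachmentSpec(mode="mrca", anchors=frozenset({"X", "Y"})),
        )
        u2 = SubcladeUnit(
            name="second",
            trace=None,
            outgroups=[],
            attachment=AttachmentSpec(
                mode="mrca", anchors=frozenset({"Baronia", "X"})
            ),
        )
        sub = read_newick("(P:10,Q:10);")
        with pytest.raises(ConfigError, match="first.*second|second.*first"):
            graft_all(backbone, [u1, u2], {"first": sub, "second": sub})

    def test_backbone_substitution_rule(self, backbone):
        """A substitution whose old label is a backbone tip renames the
        backbone before attachment resolution (placeholder-tip rule)."""
        unit = SubcladeUnit(
            name="u",
            trace=None,
            outgroups=[],
            attachment=AttachmentSpec(mode="mrca", anchors=frozenset({"X", "Y"})),
            substitutions={"Baronia": "Baronia renamed"},
        )
        sub = read_newick("(P:20,Q:20);")
        result = graft_all(backbone, [unit], {"u": sub})
        assert "Baronia renamed" in tip_labels(result)
        assert "Baronia" not in tip_labels(result)
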