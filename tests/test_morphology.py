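"""Terminal-tree construction, plasticity transforms, and SWC round-trips."""

import math

import pytest

from nociterm import (
    MorphologyError,
    apply_branching,
    apply_elongation,
    build_terminal_tree,
    total_membrane_area,
    validate_tree,
)
from nociterm.morphology import SIZ_LENGTH, PROPAGATION_LENGTH
from nociterm.swc import SwcFormatError, read_swc, write_swc


class TestBuild:
    def test_generic_default_layout(self, generic_tree):
        endings = generic_tree.by_role("free_ending")
        sizes = generic_tree.by_role("navless_siz")
        props = generic_tree.by_role("propagation")
        assert len(endings) == 14
        assert all(e.length == 32.0 for e in endings)
        assert len(sizes) == 14 and all(s.length == SIZ_LENGTH == 25.0 for s in sizes)
        assert len(props) == 14 and all(p.length == PROPAGATION_LENGTH == 50.0 for p in props)
        assert generic_tree.by_role("de_novo_branch") == []

    def test_minimal_single_ending_tree(self):
        tree = build_terminal_tree("generic", n_endings=1)
        validate_tree(tree)
        roles = [s.role_tag for s in tree.sections]
        for role in ("soma", "stem", "peripheral_axon", "central_axon",
                     "distal_axon", "propagation", "navless_siz", "free_ending"):
            assert roles.count(role) == 1

    def test_peptidergic_combined_condition(self):
        tree = build_terminal_tree(
            "peptidergic", n_endings=7, branch_increase_pct=200.0, elongation_target=44.6
        )
        assert all(s.channel_densities.get("nav1p9", 0.0) == 0.0 for s in tree.sections)
        assert all(e.length == pytest.approx(44.6) for e in tree.by_role("free_ending"))
        denovo = tree.by_role("de_novo_branch")
        assert len(denovo) == 14  # 200% of 7 endings
        per_prop = {}
        for d in denovo:
            per_prop[d.parent] = per_prop.get(d.parent, 0) + 1
        assert set(per_prop.values()) == {2}  # round-robin: two per ending

    def test_free_endings_carry_terminal_passives(self, generic_tree):
        ending = generic_tree.by_role("free_ending")[0]
        axon = generic_tree.section("peripheral_axon")
        assert ending.axial_resistivity == pytest.approx(15.0 * axon.axial_resistivity)
        assert ending.membrane_resistance == pytest.approx(4.0 * 10_000.0)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_endings": 0},
            {"branch_increase_pct": -10.0},
            {"ending_length": -1.0},
            {"elongation_target": 10.0},  # below baseline
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(MorphologyError):
            build_terminal_tree("generic", **kwargs)

    def test_unknown_class_rejected(self):
        with pytest.raises(MorphologyError):
            build_terminal_tree("cholinergic")


class TestElongation:
    def test_elongation_sets_all_ending_lengths(self, generic_tree):
        out = apply_elongation(generic_tree, 46.0)
        assert all(e.length == 46.0 for e in out.by_role("free_ending"))
        assert len(out.sections) == len(generic_tree.sections)

    def test_elongation_to_current_length_is_identity(self, generic_tree):
        out = apply_elongation(generic_tree, generic_tree.ending_length)
        assert [s.length for s in out.sections] == [s.length for s in generic_tree.sections]

    def test_peptidergic_elongation_ratio(self):
        tree = build_terminal_tree("peptidergic")
        out = apply_elongation(tree, 44.6)
        ratio = out.ending_length / tree.ending_length
        assert ratio == pytest.approx(44.6 / 26.0)
        assert ratio == pytest.approx(1.715, abs=5e-4)

    def test_propagation_scaling_follows_ending_ratio(self, generic_tree):
        out = apply_elongation(generic_tree, 46.0, scale_propagation=True)
        assert all(
            p.length == pytest.approx(50.0 * 46.0 / 32.0)
            for p in out.by_role("propagation")
        )
        frozen = apply_elongation(generic_tree, 46.0, scale_propagation=False)
        assert all(p.length == 50.0 for p in frozen.by_role("propagation"))

    def test_invalid_length_rejected(self, generic_tree):
        with pytest.raises(MorphologyError):
            apply_elongation(generic_tree, 0.0)


class TestBranching:
    def test_full_branching_adds_one_branch_per_ending(self, generic_tree):
        out = apply_branching(generic_tree, 100.0)
        assert len(out.by_role("de_novo_branch")) == generic_tree.n_endings

    def test_zero_percent_is_identity(self, generic_tree):
        out = apply_branching(generic_tree, 0.0)
        assert len(out.sections) == len(generic_tree.sections)

    def test_branches_attach_at_propagation_and_are_navless(self, generic_tree):
        out = apply_branching(generic_tree, 100.0)
        for d in out.by_role("de_novo_branch"):
            assert out.section(d.parent).role_tag == "propagation"
            assert all(
                d.channel_densities.get(na, 0.0) == 0.0
                for na in ("nav1p8", "nav1p9", "nattxs", "nap")
            )

    def test_negative_percent_rejected(self, generic_tree):
        with pytest.raises(MorphologyError):
            apply_branching(generic_tree, -5.0)


class TestInvariants:
    @pytest.mark.parametrize("n_endings", [4, 7, 14])
    @pytest.mark.parametrize("neuron_class", ["generic", "peptidergic"])
    def test_built_trees_validate(self, neuron_class, n_endings):
        for pct, elong in ((0.0, None), (100.0, None), (0.0, 50.0), (200.0, 50.0)):
            tree = build_terminal_tree(
                neuron_class, n_endings=n_endings,
                branch_increase_pct=pct, elongation_target=elong,
            )
            validate_tree(tree)

    def test_branching_and_elongation_commute(self, generic_tree):
        be = apply_elongation(apply_branching(generic_tree, 100.0), 46.0)
        eb = apply_branching(apply_elongation(generic_tree, 46.0), 100.0)
        lengths_be = sorted((s.role_tag, round(s.length, 9)) for s in be.sections)
        lengths_eb = sorted((s.role_tag, round(s.length, 9)) for s in eb.sections)
        assert lengths_be == lengths_eb
        assert len(be.sections) == len(eb.sections)

    def test_membrane_area_increases_under_plasticity(self, generic_tree):
        base = total_membrane_area(generic_tree)
        assert total_membrane_area(apply_elongation(generic_tree, 46.0)) > base
        assert total_membrane_area(apply_branching(generic_tree, 100.0)) > base


class TestSwc:
    def test_round_trip_preserves_geometry_and_roles(self, generic_tree):
        swc, sidecar = write_swc(generic_tree)
        back = read_swc(swc, sidecar)
        assert len(back.sections) == len(generic_tree.sections)
        for a in generic_tree.sections:
            b = back.section(a.id)
            assert b.role_tag == a.role_tag
            assert b.parent == a.parent
            assert b.length == pytest.approx(a.length, abs=0.01)
            assert b.diameter == pytest.approx(a.diameter, abs=0.01)
            assert b.channel_densities == a.channel_densities
        validate_tree(back)

    def test_single_soma_swc(self):
        tree = read_swc("1 1 0 0 0 12.5 -1\n")
        assert len(tree.sections) == 1
        assert tree.sections[0].diameter == pytest.approx(25.0)

    def test_orphan_node_is_a_format_error(self):
        with pytest.raises(SwcFormatError):
            read_swc("1 1 0 0 0 12.5 -1\n2 2 10 0 0 0.125 7\n")

    def test_multiple_roots_rejected(self):
        with pytest.raises(SwcFormatError):
            read_swc("1 1 0 0 0 12.5 -1\n2 1 50 0 0 12.5 -1\n")


def test_analytic_area_matches_cylinder_sum(generic_tree):
    by_hand = sum(math.pi * s.diameter * s.length for s in generic_tree.sections)
    assert total_membrane_area(generic_tree) == pytest.approx(by_hand, rel=1e-12)
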