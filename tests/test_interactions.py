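"""Classifier rules: H-bond criterion, SI, A-minor, base pairs, 4BPh,
chi window, stacking cutoffs, suites, ion shells, aggregation."""

import math

import numpy as np
import pytest

from kturn.interactions import (
    CATALOGUE,
    FrameView,
    HBondCriterion,
    MissingHydrogenError,
    basepair_flags,
    classify_aminor,
    classify_chi,
    classify_si,
    classify_stacking,
    classify_suites,
    detect_bph4,
    feature_vector,
    hbond_present,
    ion_contacts,
)
from kturn.structure_io import Atom, KinkTurnAnnotation, Unresolvable
from kturn.synthetic import SYNTHETIC_ANNOTATION, build_template

from conftest import make_structure


def hbond_fixture(d, theta, donor_role="A_1n", donor="N6",
                  acceptor_role="G_1b", acceptor="N3", with_h=True):
    """Donor at origin, acceptor at (d,0,0), hydrogen on the arc giving a
    donor-H-acceptor angle of theta degrees."""
    atoms = {donor_role: {donor: (0.0, 0.0, 0.0)},
             acceptor_role: {acceptor: (d, 0.0, 0.0)}}
    if with_h:
        h = (d / 2.0, (d / 2.0) / math.tan(math.radians(theta / 2.0)), 0.0)
        hname = {"N6": "H61", "N2": "H21"}.get(donor, "H" + donor[1:])
        atoms[donor_role][hname] = h
        # a second, badly oriented hydrogen exercises the max-over-H rule
        if donor == "N6":
            atoms[donor_role]["H62"] = (-0.5, -0.8, 0.0)
    st, ann = make_structure(atoms)
    return FrameView(st, ann, 0)


class TestHBondCriterion:
    def test_present_within_distance_and_angle(self):
        view = hbond_fixture(3.9, 150.0)
        res = hbond_present(view, CATALOGUE["AG1_N6N3"])
        assert res.present is True
        assert res.distance == pytest.approx(3.9)
        assert res.best_angle == pytest.approx(150.0, abs=1e-6)

    def test_distance_beyond_cutoff_fails_despite_good_angle(self):
        view = hbond_fixture(4.1, 170.0)
        assert hbond_present(view, CATALOGUE["AG1_N6N3"]).present is False

    def test_bad_angle_fails_unless_o2prime_exempt(self):
        view = hbond_fixture(3.5, 100.0)
        assert hbond_present(view, CATALOGUE["AG1_N6N3"]).present is False
        # identical geometry under an O2'-donor spec: angle waived
        view2 = hbond_fixture(3.5, 100.0, donor_role="A_L3", donor="O2'",
                              acceptor_role="A_L2", acceptor="OP1",
                              with_h=False)
        assert hbond_present(view2, CATALOGUE["SP_AL3AL2"]).present is True

    def test_boundary_just_above_cutoff_absent(self):
        view = hbond_fixture(4.05, 170.0, donor_role="A_L3", donor="O2'",
                             acceptor_role="A_L2", acceptor="OP1",
                             with_h=False)
        assert hbond_present(view, CATALOGUE["SP_AL3AL2"]).present is False

    def test_missing_heavy_atom_is_sentinel(self):
        st, ann = make_structure({"A_1n": {"N6": (0, 0, 0)}})
        res = hbond_present(FrameView(st, ann, 0), CATALOGUE["AG1_N6N3"])
        assert isinstance(res.present, Unresolvable)

    def test_missing_hydrogen_raises_without_fallback(self):
        view = hbond_fixture(3.0, 150.0, with_h=False)
        with pytest.raises(MissingHydrogenError):
            hbond_present(view, CATALOGUE["AG1_N6N3"])

    def test_distance_only_fallback_warns_and_uses_distance(self):
        view = hbond_fixture(3.0, 150.0, with_h=False)
        crit = HBondCriterion(distance_only_fallback=True)
        with pytest.warns(UserWarning):
            res = hbond_present(view, CATALOGUE["AG1_N6N3"], crit)
        assert res.present is True

    def test_matches_literal_oracle_on_random_fixtures(self, rng):
        crit = HBondCriterion()
        for _ in range(200):
            d = rng.uniform(2.0, 6.0)
            theta = rng.uniform(60.0, 179.0)
            view = hbond_fixture(d, theta)
            # literal restatement of the criterion, evaluated independently
            dp = view.pos("A_1n", "N6")
            ap = view.pos("G_1b", "N3")
            angles = []
            for h in ("H61", "H62"):
                hp = view.pos("A_1n", h)
                u, v = dp - hp, ap - hp
                angles.append(math.degrees(math.acos(np.clip(
                    np.dot(u, v) / np.linalg.norm(u) / np.linalg.norm(v),
                    -1, 1))))
            expected = (np.linalg.norm(dp - ap) < 4.0) and max(angles) > 120.0
            got = hbond_present(view, CATALOGUE["AG1_N6N3"], crit).present
            assert got == expected

    def test_monotone_in_distance_along_fixed_angle_family(self):
        # hydrogen on the donor-acceptor axis: angle stays 180 while the
        # acceptor moves out, so presence can only switch present -> absent
        states = []
        for d in np.arange(2.5, 6.0, 0.25):
            st, ann = make_structure({
                "A_1n": {"N6": (0, 0, 0), "H61": (1.0, 0, 0),
                         "H62": (-1.0, 0, 0)},
                "G_1b": {"N3": (d, 0, 0)}})
            states.append(
                hbond_present(FrameView(st, ann, 0),
                              CATALOGUE["AG1_N6N3"]).present)
        flips = [(a, b) for a, b in zip(states, states[1:]) if a != b]
        assert all(a is True and b is False for a, b in flips)

    def test_tighter_distance_cutoff_never_adds_bonds(self, rng):
        loose = HBondCriterion(distance_cutoff=4.0)
        tight = HBondCriterion(distance_cutoff=3.5)
        for _ in range(50):
            view = hbond_fixture(rng.uniform(2.0, 6.0),
                                 rng.uniform(90.0, 179.0))
            a = hbond_present(view, CATALOGUE["AG1_N6N3"], loose).present
            b = hbond_present(view, CATALOGUE["AG1_N6N3"], tight).present
            assert not (b and not a)


def si_fixture(d_n1, d_n6):
    st, ann = make_structure({
        "G_L1": {"O2'": (0.0, 0.0, 0.0)},
        "A_1n": {"N1": (d_n1, 0.0, 0.0), "N6": (0.0, d_n6, 0.0)}})
    return FrameView(st, ann, 0)


class TestSignatureInteraction:
    @pytest.mark.parametrize("d_n1,d_n6,expected", [
        (2.8, 5.0, "native"),
        (4.5, 3.1, "non-native"),
        (5.0, 5.5, "absent"),
        (3.2, 3.0, "non-native"),   # both formed: shorter distance wins
        (3.0, 3.2, "native"),
    ])
    def test_state_rules(self, d_n1, d_n6, expected):
        res = classify_si(si_fixture(d_n1, d_n6))
        assert res.state == expected
        assert res.d_native == pytest.approx(d_n1)
        assert res.d_nonnative == pytest.approx(d_n6)

    def test_missing_atom_gives_sentinel_state(self):
        st, ann = make_structure({"G_L1": {"O2'": (0, 0, 0)},
                                  "A_1n": {"N1": (2.8, 0, 0)}})
        assert isinstance(classify_si(FrameView(st, ann, 0)).state,
                          Unresolvable)


class TestAMinor:
    def test_am0_via_decisive_bond_only(self):
        t = build_template({"aminor": "AM0"})
        res = classify_aminor(t.view())
        assert res.state == "AM0"
        assert res.flags["AM0_A"] is True
        assert res.flags["AMI_A"] is False

    def test_water_insertion_rule_keeps_ami_without_amib(self):
        t = build_template({"aminor": "AMI", "AMI_B": "off"})
        res = classify_aminor(t.view())
        assert res.state == "AMI"
        assert res.flags["AMI_B"] is False
        assert res.flags["AMI_A"] is True and res.flags["AMI_C"] is True

    def test_all_bonds_broken_is_none(self):
        t = build_template({"aminor": "none"})
        assert classify_aminor(t.view()).state == "none"

    def test_ami_outranks_am0(self):
        # AMI_A + AMI_C formed and AM0_A formed: type I takes precedence
        st, ann = make_structure({
            "G_-1n": {"O2'": (0, 0, 0), "N2": (2.9, -2.9, 0),
                      "H21": (2.9, -1.9, 0)},
            "A_2b": {"N3": (2.9, 0, 0), "N1": (0, 0, 2.9),
                     "O2'": (0, 5.5, 0)},
            "C_-1b": {"O2'": (0, 11.0, 0)}})
        assert classify_aminor(FrameView(st, ann, 0)).state == "AMI"

    def test_am0b_is_auxiliary_never_decisive(self):
        t = build_template({"aminor": "none", "AM0_B": "on"})
        res = classify_aminor(t.view())
        assert res.state == "none"
        assert res.flags["AM0_B"] is True


class TestBasePairsAndContacts:
    def test_all_nine_bonds_formed_on_default_template(self,
                                                       default_template):
        flags = basepair_flags(default_template.view())
        assert all(v is True for v in flags.values())

    def test_single_stretched_bond_goes_false(self):
        t = build_template({"AG1_N6N3": "off"})
        flags = basepair_flags(t.view())
        assert flags["AG1_N6N3"] is False
        assert all(v is True for k, v in flags.items() if k != "AG1_N6N3")

    @pytest.mark.parametrize("targets,expected", [
        ({"bph4": "on", "BPH4_N1": "on", "BPH4_N2": "off"}, True),
        ({"bph4": "on", "BPH4_N1": "off", "BPH4_N2": "on"}, True),
        ({"bph4": "on", "BPH4_N1": "on", "BPH4_N2": "on"}, True),
        ({"bph4": "off"}, False),
    ])
    def test_bph4_either_or_rule(self, targets, expected):
        t = build_template(targets)
        assert detect_bph4(t.view()) is expected

    def test_sugar_contacts_distance_only(self):
        on = build_template({"sugar_phosphate": "on", "sugar_base": "on"})
        fv = feature_vector(on.view())
        assert fv.sugar_phosphate is True and fv.sugar_base is True
        off = build_template({"sugar_phosphate": "off", "sugar_base": "off"})
        fv2 = feature_vector(off.view())
        assert fv2.sugar_phosphate is False and fv2.sugar_base is False


class TestChiWindow:
    @pytest.mark.parametrize("chi,expected", [
        (45.0, "syn"), (-170.0, "anti"),
        (89.0, "syn"), (-89.0, "syn"), (180.0, "anti"),
    ])
    def test_window_rule(self, chi, expected):
        t = build_template({"chi": chi})
        res = classify_chi(t.view())
        assert res.state == expected
        assert abs((res.value - chi + 180) % 360 - 180) < 1e-6

    @pytest.mark.parametrize("z,chi", [(1.0, 90.0), (-1.0, -90.0)])
    def test_exact_boundary_is_anti(self, z, chi):
        # coordinates chosen so the torsion is exactly +-90 in floating point
        st, ann = make_structure({"A_L2": {
            "O4'": (0.0, 1.0, 0.0), "C1'": (0.0, 0.0, 0.0),
            "N9": (1.5, 0.0, 0.0), "C4": (1.5, 0.0, z)}})
        res = classify_chi(FrameView(st, ann, 0))
        assert res.value == chi
        assert res.state == "anti"

    def test_missing_base_atom_is_sentinel(self):
        st, ann = make_structure({"A_L2": {"O4'": (0, 0, 0),
                                           "C1'": (1.5, 0, 0)}})
        assert isinstance(classify_chi(FrameView(st, ann, 0)).state,
                          Unresolvable)


def stacking_fixture(d1, d2):
    def square(center):
        cx, cy, cz = center
        return {"N1": (cx + 1.3, cy, cz), "N3": (cx, cy, cz + 1.3),
                "N7": (cx - 1.3, cy, cz), "N9": (cx, cy, cz - 1.3)}
    st, ann = make_structure({
        "A_L2": square((0, 0, 0)),
        "A_1n": square((d1, 0, 0)),
        "G_L1": square((0, d2, 0))})
    return FrameView(st, ann, 0)


class TestStacking:
    @pytest.mark.parametrize("d1,d2,expected", [
        (3.5, 6.0, "A_1n"),
        (5.0, 4.2, "G_L1"),
        (3.8, 4.0, "G_L1"),     # both pass; 4.0/4.5 < 3.8/4.0 by ratio
        (5.0, 6.0, "none"),
    ])
    def test_cutoff_and_ratio_tie_break(self, d1, d2, expected):
        res = classify_stacking(stacking_fixture(d1, d2))
        assert res.partner == expected
        assert res.d_a1n == pytest.approx(d1)
        assert res.d_gl1 == pytest.approx(d2)

    def test_missing_ring_nitrogen_is_sentinel(self):
        st, ann = make_structure({"A_L2": {"N1": (0, 0, 0)}})
        assert isinstance(classify_stacking(FrameView(st, ann, 0)).partner,
                          Unresolvable)


class TestSuites:
    def test_native_combinations(self, default_template):
        suites = classify_suites(default_template.view())
        assert suites["A_1n/G_-1n"].alpha_bin == "g+"
        assert suites["A_1n/G_-1n"].gamma_bin == "t"
        assert suites["G_L1/A_L2"].gamma_bin == "g-"
        assert suites["A_L2/A_L3"].gamma_bin == "g+"
        assert all(s.native is True for s in suites.values())

    def test_canonical_a_rna_is_non_native_for_all_suites(self):
        t = build_template({"suite_A_1n/G_-1n": "canonical",
                            "suite_G_L1/A_L2": "canonical",
                            "suite_A_L2/A_L3": "canonical"})
        suites = classify_suites(t.view())
        for s in suites.values():
            assert (s.alpha_bin, s.gamma_bin) == ("g-", "g+")
            assert s.native is False

    def test_missing_backbone_atom_is_sentinel(self):
        st, ann = make_structure({"A_L2": {"P": (0, 0, 0)}})
        suites = classify_suites(FrameView(st, ann, 0))
        assert isinstance(suites["G_L1/A_L2"].native, Unresolvable)


class TestIonContacts:
    def ion_view(self, kind, d):
        extra = [Atom("I", 90, kind, kind, kind)]
        st, ann = make_structure({"A_2b": {"OP2": (0.0, 0.0, 0.0)}},
                                 extra_atoms=extra,
                                 extra_xyz=[(d, 0.0, 0.0)])
        return FrameView(st, ann, 0)

    def test_potassium_within_cutoff_binds(self):
        rec = ion_contacts(self.ion_view("K", 3.4),
                           acceptors=[("A_2b", "OP2")])["A_2b(OP2)"]
        assert rec.monovalent_bound is True

    def test_potassium_outside_cutoff_unbound(self):
        rec = ion_contacts(self.ion_view("K", 3.6),
                           acceptors=[("A_2b", "OP2")])["A_2b(OP2)"]
        assert rec.monovalent_bound is False

    @pytest.mark.parametrize("d,shell", [
        (3.0, "inner"), (4.0, "outer"), (5.0, "unbound"),
    ])
    def test_magnesium_shells(self, d, shell):
        rec = ion_contacts(self.ion_view("MG", d),
                           acceptors=[("A_2b", "OP2")])["A_2b(OP2)"]
        assert rec.mg_shell == shell

    def test_no_ions_means_all_unbound(self):
        st, ann = make_structure({"A_2b": {"OP2": (0.0, 0.0, 0.0)}})
        rec = ion_contacts(FrameView(st, ann, 0),
                           acceptors=[("A_2b", "OP2")])["A_2b(OP2)"]
        assert rec.monovalent_bound is False
        assert rec.mg_shell == "unbound"


class TestFeatureVector:
    def test_crystal_like_template_is_all_native(self, default_template):
        fv = feature_vector(default_template.view())
        assert fv.si_state == "native"
        assert fv.aminor_state == "AM0"
        assert fv.chi_state == "syn"
        assert fv.stacking_partner == "A_1n"
        assert fv.bph4 is True
        assert all(s.native is True for s in fv.suites.values())

    def test_single_feature_perturbation_is_isolated(self, default_template):
        base = feature_vector(default_template.view()).to_row()
        flipped = feature_vector(build_template({"chi": 180.0}).view()).to_row()
        diffs = {k for k in base if base[k] != flipped[k]}
        assert diffs == {"chi_value", "chi_state"}

    def test_empty_annotation_yields_all_sentinels(self, default_template):
        empty = KinkTurnAnnotation(roles={})
        fv = feature_vector(default_template.structure, empty)
        assert isinstance(fv.si_state, Unresolvable)
        assert isinstance(fv.aminor_state, Unresolvable)
        assert isinstance(fv.chi_state, Unresolvable)
        assert isinstance(fv.stacking_partner, Unresolvable)
        assert all(isinstance(v, Unresolvable) for v in fv.hbonds.values())

    def test_rigid_body_invariance_of_all_classifiers(self, rng):
        from test_geometry import random_rotation
        for targets in ({}, {"si": "non-native", "aminor": "AMI"},
                        {"chi": "anti", "stacking": "G_L1",
                         "pucker": "O4'-endo"}):
            t = build_template(targets)
            ref = feature_vector(t.view()).to_row()
            rot = random_rotation(rng)
            shift = rng.normal(size=3) * 30
            moved = t.structure.coords[0] @ rot.T + shift
            view = FrameView(t.structure, t.annotation, coords=moved)
            got = feature_vector(view).to_row()
            for k, v in ref.items():
                if isinstance(v, float):
                    # torsions wrap at +-180: compare circularly
                    assert abs((got[k] - v + 180) % 360 - 180) < 1e-6, k
                else:
                    assert got[k] == v, k
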