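"""Structure loading, distances, dihedrals, contacts, four-site reports."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from allonmr import geometry, simulate
from allonmr.geometry import (
    Classification,
    atom_distance,
    chi1,
    classify,
    four_site_report,
    load_structure,
    polar_contact,
)
from allonmr.simulate import FIXTURE_RESIDUE_MAP, _phe_atoms, _place_atom

MINIMAL_PDB = """\
ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  GLY A   1       3.000   4.000   0.000  1.00  0.00           C
ATOM      3  C   GLY A   1       1.000   2.000   3.000  1.00  0.00           C
END
"""

ALTLOC_PDB = """\
ATOM      1  CA AGLY A   1       0.000   0.000   0.000  0.50  0.00           C
ATOM      2  CA BGLY A   1       9.000   9.000   9.000  0.50  0.00           C
END
"""


class TestLoadStructure:
    def test_three_atom_fixture_round_trip(self, tmp_path):
        p = tmp_path / "mini.pdb"
        p.write_text(MINIMAL_PDB)
        s = load_structure(p, chain="A")
        assert len(list(s.residue(1))) == 3
        assert s.atom(1, "CA").pos.x == pytest.approx(3.0)

    def test_only_altloc_a_retained(self, tmp_path):
        p = tmp_path / "altloc.pdb"
        p.write_text(ALTLOC_PDB)
        s = load_structure(p, chain="A")
        atoms = list(s.residue(1))
        assert len(atoms) == 1
        assert atoms[0].pos.x == pytest.approx(0.0)

    def test_missing_chain_lists_available(self, tmp_path):
        p = tmp_path / "mini.pdb"
        p.write_text(MINIMAL_PDB)
        with pytest.raises(ValueError, match="available"):
            load_structure(p, chain="Z")


class TestAtomDistance:
    def test_identical_selection_is_zero(self, tmp_path):
        p = tmp_path / "mini.pdb"
        p.write_text(MINIMAL_PDB)
        s = load_structure(p, chain="A")
        assert atom_distance(s, (1, "CA"), (1, "CA")) == 0.0

    def test_three_four_five_triangle(self, tmp_path):
        p = tmp_path / "mini.pdb"
        p.write_text(MINIMAL_PDB)
        s = load_structure(p, chain="A")
        assert atom_distance(s, (1, "N"), (1, "CA")) == pytest.approx(5.0)

    def test_symmetric_in_selections(self, active_structure):
        d1 = atom_distance(active_structure, (645, "CZ"), (549, "ND2"))
        d2 = atom_distance(active_structure, (549, "ND2"), (645, "CZ"))
        assert d1 == d2

    def test_missing_atom_names_the_selection(self, tmp_path):
        p = tmp_path / "mini.pdb"
        p.write_text(MINIMAL_PDB)
        s = load_structure(p, chain="A")
        with pytest.raises(KeyError, match="CB"):
            atom_distance(s, (1, "CB"), (1, "CA"))


class TestChi1:
    def test_constructed_rotamer_measured_exactly(self):
        """A side chain placed at chi1 = -60 by rotation reads back to 1e-6."""
        import gemmi

        from allonmr.simulate import _add_residue, _fixture_structure

        st, chain = _fixture_structure("chi")
        _add_residue(chain, 1, "PHE", _phe_atoms((0, 0, 0), -60.0))
        s = geometry.StructureModel(structure=st, chain="A")
        assert chi1(s, 1) == pytest.approx(-60.0, abs=1e-6)

    def test_coplanar_cis_arrangement_is_zero(self):
        import gemmi

        from allonmr.simulate import _add_residue, _fixture_structure

        st, chain = _fixture_structure("cis")
        _add_residue(chain, 1, "PHE", _phe_atoms((0, 0, 0), 0.0))
        s = geometry.StructureModel(structure=st, chain="A")
        assert chi1(s, 1) == pytest.approx(0.0, abs=1e-6)

    def test_invariant_under_rigid_body_rotation(self, active_structure):
        rot = Rotation.from_euler("xyz", [31.0, -57.0, 112.0], degrees=True).as_matrix()
        moved = active_structure.transformed(rot, np.array([5.0, -3.0, 8.0]))
        assert chi1(moved, 645) == pytest.approx(chi1(active_structure, 645), abs=1e-6)

    def test_glycine_has_no_chi1(self, active_structure):
        with pytest.raises(ValueError, match="no chi1"):
            chi1(active_structure, 647)  # strand fixture residue is GLY


class TestPolarContact:
    def test_engaged_and_disengaged_cutoffs(self, inhibited_structure):
        d, engaged = polar_contact(
            inhibited_structure, (549, None), (565, None), cutoff=3.5)
        assert engaged and d == pytest.approx(2.8, abs=0.01)
        d, engaged = polar_contact(
            inhibited_structure, (549, None), (641, None), cutoff=3.5)
        assert not engaged

    def test_salt_bridge_min_over_pairs_matches_brute_force(self, inhibited_structure):
        d, engaged = polar_contact(
            inhibited_structure, (664, ["NH1", "NH2"]), (626, ["OD1", "OD2"]),
            cutoff=4.0)
        brute = min(
            atom_distance(inhibited_structure, (664, n), (626, o))
            for n in ("NH1", "NH2") for o in ("OD1", "OD2")
        )
        assert d == pytest.approx(brute) and engaged

    def test_empty_selection_is_an_error(self, inhibited_structure):
        with pytest.raises((ValueError, KeyError)):
            polar_contact(inhibited_structure, (647, None), (626, ["OD1"]))


class TestFourSiteReport:
    def test_active_fixture_classified_activated(self, active_structure):
        rep = four_site_report(active_structure, FIXTURE_RESIDUE_MAP)
        assert rep.classification is Classification.activated_like
        assert not rep.brake_engaged and not rep.plug_engaged
        assert rep.beta9_present

    def test_inhibited_fixture_classified_autoinhibited(self, inhibited_structure):
        rep = four_site_report(inhibited_structure, FIXTURE_RESIDUE_MAP)
        assert rep.classification is Classification.autoinhibited_like
        assert rep.brake_engaged and rep.plug_engaged
        assert not rep.beta9_present

    def test_report_fields_match_primitive_recomputation(self, inhibited_structure):
        """Compositional oracle: every field re-derived from the primitives."""
        s = inhibited_structure
        rm = FIXTURE_RESIDUE_MAP
        rep = four_site_report(s, rm)
        d, e = polar_contact(s, (rm["brake_n"], None), (rm["brake_e"], None))
        assert rep.brake["n_e"] == (pytest.approx(d), e)
        plug, _ = polar_contact(s, (rm["plug_r"], ["NH1", "NH2", "NE"]),
                                (rm["plug_d"], ["OD1", "OD2"]), cutoff=4.0)
        assert rep.a_loop_plug == pytest.approx(plug)
        assert rep.chi1_dfg_phe == pytest.approx(chi1(s, rm["dfg_phe"]), abs=1e-9)
        for partner in ("latch_i1", "latch_i2", "latch_l"):
            names = ("CG1", "CG2", "CD1") if "i" in partner[-2:] else ("CG", "CD1", "CD2")
            brute = min(atom_distance(s, (rm["dfg_phe"], "CZ"), (rm[partner], n))
                        for n in names
                        if any(a.name == n for a in s.residue(rm[partner])))
            assert rep.dfg_latch[partner] == pytest.approx(brute)

    def test_classification_is_pure_function_of_report(self, active_structure,
                                                       inhibited_structure):
        for s in (active_structure, inhibited_structure):
            rep = four_site_report(s, FIXTURE_RESIDUE_MAP)
            assert classify(rep) is rep.classification

    def test_unmapped_marker_gives_partial_report(self, active_structure):
        rm = {k: v for k, v in FIXTURE_RESIDUE_MAP.items() if k != "plug_r"}
        rep = four_site_report(active_structure, rm)
        assert "plug_r" in rep.missing
        assert rep.a_loop_plug is None
        assert rep.classification is Classification.mixed


def test_all_measurements_invariant_under_rigid_body_motion(active_structure, rng):
    rot = Rotation.random(random_state=7).as_matrix()
    shift = rng.uniform(-30, 30, 3)
    moved = active_structure.transformed(rot, shift)
    rm = FIXTURE_RESIDUE_MAP
    d0 = atom_distance(active_structure, (645, "CZ"), (626, "OD1"))
    d1 = atom_distance(moved, (645, "CZ"), (626, "OD1"))
    assert d1 == pytest.approx(d0, abs=1e-6)
    rep0 = four_site_report(active_structure, rm)
    rep1 = four_site_report(moved, rm)
    assert rep1.classification is rep0.classification
    assert rep1.a_loop_plug == pytest.approx(rep0.a_loop_plug, abs=1e-6)
    assert rep1.chi1_dfg_phe == pytest.approx(rep0.chi1_dfg_phe, abs=1e-6)
    for k in rep0.ac_tether:
        assert rep1.ac_tether[k] == pytest.approx(rep0.ac_tether[k], abs=1e-6)
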