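"""Dihedrals, Ramachandran classification, burial and the 3D-1D profile."""

import math

import numpy as np
import pytest

from xlinkdock.errors import ConfigError
from xlinkdock.structure_io import Atom, Residue, Structure
from xlinkdock.synthetic_data import make_helix_backbone
from xlinkdock.validation import (DihedralRecord, accessible_area,
                                  backbone_dihedrals, classify_outcome,
                                  count_classifications, dihedral_angle,
                                  expected_high_score, load_regions,
                                  load_score_table, ramachandran_classify,
                                  secondary_structure_class, verify_score,
                                  VerifyProfile)


def _analytic_dihedral(p0, p1, p2, p3):
    """Independent oracle: Biopython's torsion calculation."""
    from Bio.PDB.vectors import Vector, calc_dihedral

    return math.degrees(calc_dihedral(*(Vector(*p) for p in (p0, p1, p2, p3))))


class TestDihedrals:
    def test_agrees_with_analytic_formula_on_random_atoms(self, rng):
        for _ in range(50):
            pts = rng.normal(0, 3, (4, 3))
            got = dihedral_angle(*pts)
            if got is None:
                continue
            want = _analytic_dihedral(*pts)
            assert math.isclose(math.sin(math.radians(got)),
                                math.sin(math.radians(want)), abs_tol=1e-6)
            assert math.isclose(math.cos(math.radians(got)),
                                math.cos(math.radians(want)), abs_tol=1e-6)

    def test_collinear_atoms_are_degenerate(self):
        pts = [np.array([float(i), 0, 0]) for i in range(4)]
        assert dihedral_angle(*pts) is None

    def test_single_residue_chain_has_no_angles(self):
        s = Structure("one")
        s.chains["A"] = [Residue("A", 1, "ALA", [
            Atom("N", "N", np.zeros(3)), Atom("CA", "C", np.array([1.5, 0, 0])),
            Atom("C", "C", np.array([2.0, 1.4, 0]))])]
        rec = backbone_dihedrals(s)[0]
        assert rec.phi is None and rec.psi is None
        assert rec.reason

    def test_missing_backbone_atom_reported_not_raised(self):
        s = make_helix_backbone(5)
        s.chains["H"][2].atoms = [a for a in s.chains["H"][2].atoms
                                  if a.name != "CA"]
        records = backbone_dihedrals(s)
        assert records[2].phi is None
        assert "missing backbone atom" in records[2].reason


class TestRamachandran:
    def test_alpha_helix_point_is_favorable(self):
        rec = DihedralRecord(("H", 1, ""), -57.0, -47.0)
        assert ramachandran_classify([rec])[0].classification == "favorable"

    def test_disallowed_point_is_unfavorable(self):
        rec = DihedralRecord(("H", 1, ""), 60.0, -120.0)
        assert ramachandran_classify([rec])[0].classification == "unfavorable"

    @pytest.mark.parametrize("shift", [-360.0, 0.0, 360.0])
    def test_invariant_to_full_turn_shifts(self, shift):
        rec = DihedralRecord(("H", 1, ""), -57.0 + shift, -47.0 + shift)
        assert ramachandran_classify([rec])[0].classification == "favorable"

    def test_beta_region_wraps_across_psi_180(self):
        assert ramachandran_classify(
            [DihedralRecord(("H", 1, ""), -120.0, 175.0)])[0].classification == \
            "favorable"
        assert ramachandran_classify(
            [DihedralRecord(("H", 1, ""), -120.0, -175.0)])[0].classification == \
            "favorable"

    def test_undefined_angles_stay_undefined(self):
        rec = DihedralRecord(("H", 1, ""), None, -47.0)
        assert ramachandran_classify([rec])[0].classification == "undefined"

    def test_malformed_region_file_is_config_error(self, tmp_path):
        bad = tmp_path / "regions.txt"
        bad.write_text("region alpha\n-57 x\n")
        with pytest.raises(ConfigError):
            load_regions(str(bad))

    def test_counts(self, helix10):
        records = ramachandran_classify(backbone_dihedrals(helix10))
        counts = count_classifications(records)
        assert counts == {"favorable": 8, "unfavorable": 0, "undefined": 2}


class TestAccessibleArea:
    def test_isolated_residue_is_unburied(self):
        s = Structure("iso")
        s.chains["A"] = [Residue("A", 1, "ALA", [
            Atom("CA", "C", np.zeros(3)), Atom("CB", "C", np.array([1.5, 0, 0]))])]
        buried = accessible_area(s, n_points=128)
        assert buried[("A", 1, "")] == pytest.approx(0.0, abs=1e-9)

    def test_caged_residue_is_buried(self, rng):
        s = Structure("cage")
        s.chains["A"] = [Residue("A", 1, "ALA", [
            Atom("CA", "C", np.zeros(3)), Atom("CB", "C", np.array([1.0, 0, 0]))])]
        cage = []
        idx = 2
        # dense shell of pseudo-atoms around the residue
        for _ in range(200):
            v = rng.normal(size=3)
            v = 4.0 * v / np.linalg.norm(v)
            cage.append(Residue("A", idx, "GLY", [Atom("CA", "C", v)]))
            idx += 1
        s.chains["A"].extend(cage)
        buried = accessible_area(s, n_points=128)
        assert buried[("A", 1, "")] > 0.9

    def test_point_count_convergence(self, block_system):
        coarse = accessible_area(block_system.ligand_reference, n_points=128)
        fine = accessible_area(block_system.ligand_reference, n_points=256)
        for rid, val in coarse.items():
            assert abs(val - fine[rid]) < 0.05

    def test_point_count_floor(self, block_system):
        with pytest.raises(ValueError):
            accessible_area(block_system.ligand_reference, n_points=50)


class TestVerifyScore:
    def test_expected_low_is_45_percent_of_high(self):
        profile = verify_score(make_helix_backbone(6), expected_high=184.27)
        assert profile.expected_low == pytest.approx(82.92, abs=0.005)

    def test_ratio_holds_across_lengths(self):
        for n in (5, 8, 12):
            profile = verify_score(make_helix_backbone(n))
            assert profile.expected_low == pytest.approx(
                0.45 * profile.expected_high)
        assert expected_high_score(100) > expected_high_score(10) > 0

    def test_empty_structure_scores_zero(self):
        profile = verify_score(Structure("void"))
        assert profile.verify_score == 0.0
        assert profile.expected_high == 0.0

    def test_total_is_sum_of_residue_scores(self, helix10):
        profile = verify_score(helix10)
        assert profile.verify_score == pytest.approx(
            sum(p.score for p in profile.residues))

    def test_additive_over_distant_fragments(self):
        a = make_helix_backbone(6)
        b = make_helix_backbone(6)
        combined = Structure("two")
        combined.chains["H"] = [r for r in a.chains["H"]]
        moved = b.transformed(np.eye(3), np.array([200.0, 0, 0]))
        for res in moved.chains["H"]:
            res.chain_id = "I"
        combined.chains["I"] = moved.chains["H"]
        pa = verify_score(a)
        pc = verify_score(combined)
        assert pc.verify_score == pytest.approx(2 * pa.verify_score, abs=1e-6)

    def test_score_table_covers_all_environments(self):
        table = load_score_table()
        assert len(table) == 20 * 18


class TestClassifyOutcome:
    def test_between_band_is_mostly_correct(self):
        profile = VerifyProfile([], 167.31, 184.27, 82.92)
        outcome = classify_outcome(profile)
        assert outcome.label == "mostly_correct"
        assert outcome.band == "intermediate"

    def test_below_low_is_grossly_misfolded(self):
        profile = VerifyProfile([], 50.0, 184.27, 82.92)
        assert classify_outcome(profile).label == "grossly_misfolded"

    def test_boundary_at_expected_low_is_inclusive(self):
        profile = VerifyProfile([], 82.92, 184.27, 82.92)
        outcome = classify_outcome(profile)
        assert outcome.label == "mostly_correct"
        assert outcome.band == "intermediate"

    def test_above_high_band(self):
        profile = VerifyProfile([], 200.0, 184.27, 82.92)
        assert classify_outcome(profile).band == "above_expected_high"


class TestSecondaryStructure:
    @pytest.mark.parametrize("phi,psi,expected", [
        (-57.0, -47.0, "helix"),
        (-120.0, 130.0, "sheet"),
        (60.0, 40.0, "other"),
        (None, -47.0, "other"),
    ])
    def test_bins(self, phi, psi, expected):
        assert secondary_structure_class(phi, psi) == expected
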