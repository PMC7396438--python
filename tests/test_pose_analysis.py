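"""Interface maps, clustering, density and criteria filtering."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from xlinkdock.docking import Pose
from xlinkdock.errors import ConfigError
from xlinkdock.pose_analysis import (Cluster, FilterCriteria, InterfaceMap,
                                     PoseRecord, cluster_poses,
                                     export_pose_table,
                                     export_score_density_points, filter_poses,
                                     interface_residues, pose_density,
                                     read_criteria_yaml, read_pose_table,
                                     write_criteria_yaml)
from xlinkdock.structure_io import Atom, Residue, Structure, min_distance


def _point_structure(chain, points, spacing_id=1):
    s = Structure(chain)
    s.chains[chain] = [
        Residue(chain, i + 1, "ALA", [Atom("CA", "C", np.array(p, float))])
        for i, p in enumerate(points)
    ]
    return s


def _pose_at(pose_id, offset):
    return Pose(pose_id, np.array([1.0, 0, 0, 0]), np.array(offset, float))


def _random_structure(rng, chain, n_res, n_atoms=3, scale=10.0):
    s = Structure(chain)
    s.chains[chain] = []
    for i in range(n_res):
        center = rng.uniform(-scale, scale, 3)
        atoms = [Atom(f"C{j}", "C", center + rng.normal(0, 1, 3))
                 for j in range(n_atoms)]
        s.chains[chain].append(Residue(chain, i + 1, "ALA", atoms))
    return s


class TestInterface:
    @pytest.mark.parametrize("gap,expected", [(4.9, 1), (5.1, 0)])
    def test_cutoff_boundary(self, gap, expected):
        r = _point_structure("A", [(0, 0, 0)])
        l = _point_structure("S", [(gap, 0, 0)])
        iface = interface_residues(r, l, cutoff=5.0)
        assert len(iface.contact_pairs) == expected

    def test_matches_brute_force_oracle(self, rng):
        receptor = _random_structure(rng, "A", 30)
        ligand = _random_structure(rng, "S", 30)
        iface = interface_residues(receptor, ligand, cutoff=5.0)
        expected = set()
        for rres in receptor.residues():
            for lres in ligand.residues():
                if min_distance(rres, lres) <= 5.0:
                    expected.add((rres.id, lres.id))
        assert {(a, b) for a, b, _ in iface.contact_pairs} == expected
        assert iface.receptor_residues == {a for a, _, _ in iface.contact_pairs}
        assert iface.ligand_residues == {b for _, b, _ in iface.contact_pairs}

    def test_pair_distances_equal_min_distance(self, rng):
        receptor = _random_structure(rng, "A", 10)
        ligand = _random_structure(rng, "S", 10)
        iface = interface_residues(receptor, ligand, cutoff=6.0)
        for rid, lid, d in iface.contact_pairs:
            assert d == pytest.approx(
                min_distance(receptor.residue(*rid), ligand.residue(*lid)))


class TestClustering:
    def test_identical_poses_form_one_cluster(self, block_system):
        poses = [_pose_at(i, (0, 0, 0)) for i in range(3)]
        clusters = cluster_poses(poses, block_system.ligand_reference, 10.0)
        assert len(clusters) == 1
        assert sorted(clusters[0].member_pose_ids) == [0, 1, 2]

    def test_distant_poses_form_singletons(self, block_system):
        poses = [_pose_at(0, (0, 0, 0)), _pose_at(1, (25, 0, 0))]
        clusters = cluster_poses(poses, block_system.ligand_reference, 10.0)
        assert [len(c.member_pose_ids) for c in clusters] == [1, 1]

    def test_two_planted_sites_recovered(self, block_system, rng):
        site_a = [_pose_at(i, rng.normal(0, 1.0, 3)) for i in range(25)]
        site_b = [_pose_at(25 + i, np.array([40.0, 0, 0]) + rng.normal(0, 1.0, 3))
                  for i in range(25)]
        clusters = cluster_poses(site_a + site_b,
                                 block_system.ligand_reference, 10.0)
        assert len(clusters) == 2
        members = sorted(clusters, key=lambda c: min(c.member_pose_ids))
        assert set(members[0].member_pose_ids) == set(range(25))
        assert set(members[1].member_pose_ids) == set(range(25, 50))

    def test_partition_and_representative_score(self, block_system, rng):
        poses = [Pose(i, np.array([1.0, 0, 0, 0]), rng.normal(0, 8, 3),
                      float(rng.integers(0, 50))) for i in range(40)]
        clusters = cluster_poses(poses, block_system.ligand_reference, 10.0)
        all_ids = [pid for c in clusters for pid in c.member_pose_ids]
        assert sorted(all_ids) == list(range(40))
        score = {p.id: p.primary_score for p in poses}
        for c in clusters:
            assert c.representative in c.member_pose_ids
            assert score[c.representative] == max(score[i] for i in c.member_pose_ids)

    def test_empty_pose_list(self, block_system):
        assert cluster_poses([], block_system.ligand_reference, 10.0) == []


class TestDensity:
    def test_single_pose_density_one(self, block_system):
        d = pose_density([_pose_at(0, (0, 0, 0))],
                         block_system.ligand_reference, 10.0)
        assert d == {0: 1}

    def test_coincident_poses_share_density(self, block_system):
        poses = [_pose_at(i, (0, 0, 0)) for i in range(4)]
        d = pose_density(poses, block_system.ligand_reference, 10.0)
        assert all(v == 4 for v in d.values())

    def test_matches_brute_force(self, block_system, rng):
        poses = [_pose_at(i, rng.normal(0, 12, 3)) for i in range(30)]
        centroid = block_system.ligand_reference.centroid()
        pts = np.array([p.apply(centroid[None, :])[0] for p in poses])
        d = pose_density(poses, block_system.ligand_reference, 10.0)
        for i, p in enumerate(poses):
            expected = int((np.linalg.norm(pts - pts[i], axis=1) <= 10.0).sum())
            assert d[p.id] == expected


def _record(pose_id, receptor_ids, ligand_ids, score=0.0):
    iface = InterfaceMap(set(receptor_ids), set(ligand_ids),
                         [(r, l, 4.0) for r in receptor_ids for l in ligand_ids])
    return PoseRecord(pose_id=pose_id, cluster_id=0, density=1,
                      primary_score=score, interface=iface)


class TestFiltering:
    def test_empty_criteria_pass_everything(self):
        records = [_record(i, {("A", 1, "")}, {("S", 1, "")}) for i in range(3)]
        passing = filter_poses(records, FilterCriteria())
        assert len(passing) == 3
        assert all(r.passed_filters and not r.failure_reasons for r in records)

    def test_required_residue_never_in_interface_fails_all(self):
        records = [_record(i, {("A", 1, "")}, {("S", 1, "")}) for i in range(3)]
        criteria = FilterCriteria(required_receptor_interface={("A", 99, "")})
        passing = filter_poses(records, criteria)
        assert passing == []
        for rec in records:
            assert len(rec.failure_reasons) == 1
            assert "A:99" in rec.failure_reasons[0]

    def test_domain_fraction_threshold(self):
        in_dom = {("S", 1, ""), ("S", 2, "")}
        out_dom = {("S", 3, ""), ("S", 4, ""), ("S", 5, "")}
        rec = _record(0, {("A", 1, "")}, in_dom | out_dom)
        criteria = FilterCriteria(required_ligand_domain=in_dom,
                                  min_domain_fraction=0.5)
        assert filter_poses([rec], criteria) == []
        criteria.min_domain_fraction = 0.4
        rec2 = _record(0, {("A", 1, "")}, in_dom | out_dom)
        assert filter_poses([rec2], criteria) == [rec2]

    def test_orientation_counts(self):
        rec = _record(0, {("A", 1, "")}, {("S", 1, ""), ("S", 9, "")})
        criteria = FilterCriteria(orientation_required={("S", 1, "")},
                                  orientation_forbidden={("S", 9, "")})
        assert filter_poses([rec], criteria) == []
        assert any("forbidden" in r for r in rec.failure_reasons)

    def test_criteria_on_absent_residue_is_config_error(self, block_system):
        rec = _record(0, {("A", 1, "")}, {("S", 1, "")})
        criteria = FilterCriteria(required_receptor_interface={("A", 999, "")})
        with pytest.raises(ConfigError, match="A:999"):
            filter_poses([rec], criteria, block_system.receptor,
                         block_system.ligand_reference)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.sets(st.integers(1, 12), max_size=6),
           st.sets(st.integers(1, 12), max_size=6))
    def test_filter_monotone_in_required_residues(self, base_req, extra):
        """Adding required interface residues never grows the passing set."""
        rng = np.random.default_rng(0)
        records = []
        for i in range(15):
            riface = {("A", int(n), "") for n in rng.choice(12, size=5) + 1}
            records.append(_record(i, riface, {("S", 1, "")}))
        req = {("A", n, "") for n in base_req}
        more = req | {("A", n, "") for n in extra}
        small = {r.pose_id for r in filter_poses(
            [_record(r.pose_id, r.interface.receptor_residues,
                     r.interface.ligand_residues) for r in records],
            FilterCriteria(required_receptor_interface=req))}
        large = {r.pose_id for r in filter_poses(
            [_record(r.pose_id, r.interface.receptor_residues,
                     r.interface.ligand_residues) for r in records],
            FilterCriteria(required_receptor_interface=more))}
        assert large <= small


class TestExports:
    def test_empty_records_write_header_only(self, tmp_path):
        path = tmp_path / "poses.tsv"
        export_pose_table([], str(path))
        lines = path.read_text().splitlines()
        assert len(lines) == 1
        assert lines[0].startswith("pose_id\t")

    def test_pose_table_round_trip(self, tmp_path):
        records = [_record(i, {("A", 1, "")}, {("S", 2, "")}, score=float(i))
                   for i in range(4)]
        for rec in records:
            rec.restraint_distances = {"planted_dsp": 10.0 + rec.pose_id}
            rec.restraints_satisfied = 1
            rec.passed_filters = rec.pose_id % 2 == 0
            rec.rescore = -1.5 * rec.pose_id
        path = tmp_path / "pose_table.tsv"
        export_pose_table(records, str(path))
        again = read_pose_table(str(path))
        assert len(again) == len(records)
        for a, b in zip(records, again):
            assert a.pose_id == b.pose_id
            assert a.primary_score == b.primary_score
            assert a.rescore == b.rescore
            assert a.passed_filters == b.passed_filters
            assert a.restraint_distances == b.restraint_distances
            assert a.interface.receptor_residues == b.interface.receptor_residues

    def test_score_density_points_row_count(self, tmp_path):
        records = [_record(i, {("A", 1, "")}, {("S", 1, "")}) for i in range(7)]
        path = tmp_path / "points.tsv"
        export_score_density_points(records, str(path))
        assert len(path.read_text().splitlines()) == 8

    def test_criteria_yaml_round_trip(self, tmp_path):
        criteria = FilterCriteria(
            required_receptor_interface={("A", 64, ""), ("A", 135, "")},
            required_ligand_domain={("S", n, "") for n in range(1, 10)},
            min_domain_fraction=0.5,
            orientation_required={("S", 1, "")},
            orientation_forbidden={("S", 18, "")},
            blocked={("B", 1, "")},
        )
        path = tmp_path / "criteria.yaml"
        write_criteria_yaml(criteria, str(path))
        again = read_criteria_yaml(str(path))
        assert again == criteria
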