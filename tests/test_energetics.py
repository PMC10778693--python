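"""Nonbonded pair energies, switching, per-region decomposition, contacts."""

import numpy as np
import pytest

from ensdock.energetics import (
    COULOMB_K,
    EnergeticsError,
    NonbondedOptions,
    ParamTable,
    contact_residues,
    energy_timeseries,
    nucleophile_proximity,
    pair_energy,
    records_to_frame,
    region_interaction_energy,
    switching_factor,
)
from ensdock.poses import Pose
from ensdock.structures import Atom, RegionMap, Structure
from ensdock.synthetic import builtin_param_table, make_snapshots, make_toy_ligand, make_toy_protein

from conftest import random_rotation, rigid


def _atom(coord, charge=1.0, eps=0.1, rmin_half=1.9, name="X", resname="ALA", resseq=1):
    return Atom(serial=1, name=name, element="C", resname=resname, chain="A",
                resseq=resseq, icode="", coord=np.asarray(coord, float),
                charge=charge, eps=eps, rmin_half=rmin_half)


class TestPairEnergy:
    def test_coulomb_closed_form_100_kcal(self):
        # k q1 q2 / r with unit charges at r = k/100 gives exactly 100 kcal/mol
        r = COULOMB_K / 100.0
        assert r == pytest.approx(3.320636)
        a = _atom([0.0, 0.0, 0.0])
        b = _atom([r, 0.0, 0.0])
        _, e_coul = pair_energy(a, b)
        assert e_coul == pytest.approx(100.0, abs=1e-9)

    def test_lj_minimum_is_minus_epsilon(self):
        a = _atom([0.0, 0.0, 0.0], charge=0.0, eps=0.2, rmin_half=1.9)
        b = _atom([3.8, 0.0, 0.0], charge=0.0, eps=0.2, rmin_half=1.9)  # r = Rmin_ij
        e_lj, _ = pair_energy(a, b)
        assert e_lj == pytest.approx(-0.2, abs=1e-12)

    def test_zero_beyond_cutoff(self):
        a = _atom([0.0, 0.0, 0.0])
        for r in (12.0, 12.5, 50.0):
            b = _atom([r, 0.0, 0.0])
            assert pair_energy(a, b) == (0.0, 0.0)

    def test_symmetric_and_rigid_motion_invariant(self, rng):
        a = _atom(rng.normal(size=3), charge=0.4, eps=0.15)
        b = _atom(rng.normal(size=3) + 4.0, charge=-0.3, eps=0.05)
        assert pair_energy(a, b) == pair_energy(b, a)
        rot, t = random_rotation(rng), rng.uniform(-10, 10, 3)
        a2 = _atom(rigid(a.coord[None], rot, t)[0], charge=0.4, eps=0.15)
        b2 = _atom(rigid(b.coord[None], rot, t)[0], charge=-0.3, eps=0.05)
        np.testing.assert_allclose(pair_energy(a2, b2), pair_energy(a, b), atol=1e-10)

    def test_unswitched_lj_limits(self):
        opts = NonbondedOptions(switching=False, switch_on=10.0, cutoff=1e9)
        a = _atom([0.0, 0.0, 0.0], charge=0.0)
        lj = []
        for r in (3.8, 5.0, 10.0, 50.0, 200.0):
            e, _ = pair_energy(a, _atom([r, 0, 0], charge=0.0), opts)
            lj.append(e)
        assert all(abs(x) > abs(y) for x, y in zip(lj[1:], lj[2:]))  # decays with r
        assert abs(lj[-1]) < 1e-9
        e_close, _ = pair_energy(a, _atom([0.5, 0, 0], charge=0.0), opts)
        assert e_close > 1e6  # steep repulsive wall

    def test_missing_parameters_name_the_atom(self):
        a = _atom([0, 0, 0])
        bad = Atom(serial=2, name="CB", element="C", resname="GLY", chain="A", resseq=7,
                   icode="", coord=np.array([3.0, 0.0, 0.0]))
        with pytest.raises(EnergeticsError, match="CB"):
            pair_energy(a, bad)


class TestSwitching:
    def test_continuity_at_switch_and_cutoff(self):
        opts = NonbondedOptions(switch_on=10.0, cutoff=12.0)
        for edge in (10.0, 12.0):
            below = switching_factor(edge - 1e-6, opts)
            above = switching_factor(edge + 1e-6, opts)
            assert abs(below - above) < 1e-5
        assert switching_factor(9.0, opts) == 1.0
        assert switching_factor(12.0, opts) == 0.0
        mid = switching_factor(11.0, opts)
        assert 0.0 < mid < 1.0

    def test_pair_energy_continuous_across_edges(self):
        opts = NonbondedOptions(switch_on=10.0, cutoff=12.0)
        a = _atom([0.0, 0.0, 0.0], charge=0.5)
        for edge in (10.0, 12.0):
            e1 = pair_energy(a, _atom([edge - 1e-6, 0, 0], charge=0.5), opts)
            e2 = pair_energy(a, _atom([edge + 1e-6, 0, 0], charge=0.5), opts)
            np.testing.assert_allclose(e1, e2, atol=1e-5)


@pytest.fixture
def complex_system():
    protein, region_map = make_toy_protein(n_domains=6, residues_per_domain=4, seed=9)
    table = builtin_param_table()
    protein = table.assign(protein)
    topo, template = make_toy_ligand(6, seed=9)
    lig_table = builtin_param_table(topo)
    lig_params = lig_table.for_topology(topo)
    site = protein.coords.mean(axis=0) + np.array([4.0, 0.0, 0.0])
    pose = Pose(topo.ligand_id, template - template.mean(0) + site, score=0.0, topology=topo)
    return protein, region_map, pose, lig_params


class TestRegionDecomposition:
    def test_far_ligand_gives_all_zero_records(self, complex_system):
        protein, region_map, pose, lig_params = complex_system
        far = Pose(pose.ligand_id, pose.coords + 500.0, score=0.0, topology=pose.topology)
        records = region_interaction_energy(protein, far, lig_params, region_map)
        assert all(r.e_lj == 0.0 and r.e_coul == 0.0 for r in records)
        assert {r.region for r in records} == set(region_map.names()) | {"other"}

    def test_matches_double_loop_oracle_and_additivity(self, complex_system):
        protein, region_map, pose, lig_params = complex_system
        records = region_interaction_energy(protein, pose, lig_params, region_map)
        # brute-force oracle: explicit pair loop accumulated per region
        oracle = {name: [0.0, 0.0] for name in region_map.names() + ["other"]}
        for atom in protein.atoms:
            region = region_map.region_of(atom.residue_id) or "other"
            for k in range(len(pose.coords)):
                lig_atom = _atom(pose.coords[k], *lig_params[k])
                e_lj, e_coul = pair_energy(atom, lig_atom)
                oracle[region][0] += e_lj
                oracle[region][1] += e_coul
        for rec in records:
            assert rec.e_lj == pytest.approx(oracle[rec.region][0], abs=1e-10)
            assert rec.e_coul == pytest.approx(oracle[rec.region][1], abs=1e-10)
            assert rec.e_total == pytest.approx(rec.e_lj + rec.e_coul, abs=1e-10)
        # additivity: regions + other = whole-protein interaction energy
        total = sum(r.e_total for r in records)
        whole = sum(sum(v) for v in oracle.values())
        assert total == pytest.approx(whole, abs=1e-9)

    def test_approach_deepens_local_lj_while_distant_regions_stay_zero(self):
        # one near region, one region far beyond the cutoff; the ligand walks
        # down the attractive tail (r > Rmin_ij = 3.8 A) toward the near region
        from ensdock.poses import LigandTopology

        near = _atom([0.0, 0.0, 0.0], resseq=1, name="CA")
        far = _atom([200.0, 0.0, 0.0], resseq=2, name="CA")
        protein = Structure("two-region", [near, far])
        region_map = RegionMap({"NBD1": [("A", 1, 1)], "NBD2": [("A", 2, 2)]})
        topo = LigandTopology("probe", (("C1", "C"),), ())
        lig_params = np.array([[0.0, 0.1, 1.9]])
        lj_values = []
        for d in (8.0, 7.0, 6.0, 5.0):
            pose = Pose("probe", np.array([[d, 0.0, 0.0]]), score=0.0, topology=topo)
            recs = {r.region: r
                    for r in region_interaction_energy(protein, pose, lig_params, region_map)}
            lj_values.append(recs["NBD1"].e_lj)
            assert recs["NBD2"].e_lj == 0.0 and recs["NBD2"].e_coul == 0.0
        assert lj_values[0] > lj_values[1] > lj_values[2] > lj_values[3]
        assert all(v < 0 for v in lj_values)


class TestTimeseries:
    def test_single_frame_reduces_to_region_energy(self, complex_system):
        protein, region_map, pose, lig_params = complex_system
        frame = protein.with_provenance("snapshot", time_ns=3.0)
        series = energy_timeseries([frame], [pose], lig_params, region_map)
        single = region_interaction_energy(frame, pose, lig_params, region_map)
        assert [(r.region, r.e_total) for r in series] == [
            (r.region, r.e_total) for r in sorted(single, key=lambda r: series_order(region_map, r))
        ]

    def test_record_count_is_frames_times_regions_plus_other(self, complex_system):
        protein, region_map, pose, lig_params = complex_system
        frames = [protein.with_provenance("snapshot", time_ns=float(t)) for t in range(0, 101, 10)]
        series = energy_timeseries(frames, [pose] * len(frames), lig_params, region_map)
        assert len(series) == 11 * (len(region_map.names()) + 1)
        df = records_to_frame(series)
        assert df["time_ns"].is_monotonic_increasing or len(df["time_ns"].unique()) == 11

    def test_static_complex_gives_constant_series(self, complex_system):
        protein, region_map, pose, lig_params = complex_system
        frames = [protein.with_provenance("snapshot", time_ns=float(t)) for t in (1.0, 2.0, 3.0)]
        series = energy_timeseries(frames, [pose] * 3, lig_params, region_map)
        by_region = {}
        for r in series:
            by_region.setdefault(r.region, []).append(r.e_total)
        for values in by_region.values():
            assert max(values) - min(values) < 1e-12

    def test_frame_pose_mismatch_rejected(self, complex_system):
        protein, region_map, pose, lig_params = complex_system
        with pytest.raises(EnergeticsError, match="frames"):
            energy_timeseries([protein], [pose, pose], lig_params, region_map)


def series_order(region_map, record):
    order = {name: i for i, name in enumerate(region_map.names() + ["other"])}
    return order[record.region]


class TestContacts:
    def _system(self):
        protein, region_map = make_toy_protein(n_domains=2, residues_per_domain=3, seed=2)
        topo, template = make_toy_ligand(4, seed=2)
        return protein, topo, template

    def test_residue_within_cutoff_included(self):
        protein, topo, template = self._system()
        anchor = protein.coords[0]
        coords = template - template[0] + anchor + np.array([3.0, 0.0, 0.0])
        pose = Pose(topo.ligand_id, coords, score=0.0, topology=topo)
        contacts = contact_residues(protein, pose, cutoff=4.0)
        assert protein.atoms[0].residue_id in contacts

    def test_all_beyond_cutoff_empty(self):
        protein, topo, template = self._system()
        pose = Pose(topo.ligand_id, template + 300.0, score=0.0, topology=topo)
        assert contact_residues(protein, pose, cutoff=4.0) == set()

    def test_matches_brute_force_oracle(self, rng):
        protein, topo, template = self._system()
        coords = template - template.mean(0) + protein.coords.mean(0) + rng.normal(scale=2, size=3)
        pose = Pose(topo.ligand_id, coords, score=0.0, topology=topo)
        got = contact_residues(protein, pose, cutoff=5.0)
        oracle = set()
        for i, atom in enumerate(protein.atoms):
            if atom.is_hydrogen:
                continue
            for lig in pose.heavy_coords():
                if np.linalg.norm(protein.coords[i] - lig) <= 5.0:
                    oracle.add(atom.residue_id)
        assert got == oracle


class TestNucleophileScan:
    def _frame_with(self, resname, atom_name, coord):
        atoms = [
            Atom(1, "CA", "C", "GLY", "A", 1, "", np.zeros(3)),
            Atom(2, "CA", "C", resname, "A", 2, "", np.asarray(coord) + [0.0, 1.5, 0.0]),
            Atom(3, atom_name, "S" if atom_name == "SG" else "O", resname, "A", 2, "",
                 np.asarray(coord, float)),
        ]
        return Structure("frame", atoms)

    def test_cysteine_sulfur_found_first(self, chain_topology, chain_coords):
        frame = self._frame_with("CYS", "SG", chain_coords[0] + [3.5, 0.0, 0.0])
        pose = Pose("chain", chain_coords, score=0.0, topology=chain_topology)
        hits = nucleophile_proximity(frame, pose, electrophile_atoms=[0], cutoff=5.0)
        assert hits and hits[0][1] == "CYS" and hits[0][2] == "SG"
        assert hits[0][3] == pytest.approx(3.5)

    def test_no_nucleophilic_residues_empty(self, chain_topology, chain_coords):
        frame = self._frame_with("GLY", "O", chain_coords[0] + [2.0, 0.0, 0.0])
        pose = Pose("chain", chain_coords, score=0.0, topology=chain_topology)
        assert nucleophile_proximity(frame, pose, [0], cutoff=5.0) == []

    def test_zero_cutoff_empty(self, chain_topology, chain_coords):
        frame = self._frame_with("CYS", "SG", chain_coords[0])
        pose = Pose("chain", chain_coords, score=0.0, topology=chain_topology)
        assert nucleophile_proximity(frame, pose, [0], cutoff=0.0) == []


class TestParamTable:
    def test_file_roundtrip(self, tmp_path):
        table = builtin_param_table()
        table.to_file(tmp_path / "params.tsv")
        back = ParamTable.from_file(tmp_path / "params.tsv")
        assert back.entries == {k: tuple(pytest.approx(x) for x in v)
                                for k, v in table.entries.items()}

    def test_strict_lookup_raises(self):
        table = builtin_param_table()
        with pytest.raises(EnergeticsError, match="XX"):
            table.lookup("ALA", "XX")

    def test_malformed_line_reports_number(self, tmp_path):
        (tmp_path / "bad.tsv").write_text("ALA CA 0.1\n")
        with pytest.raises(EnergeticsError, match=":1"):
            ParamTable.from_file(tmp_path / "bad.tsv")
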