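"""Pose I/O, ligand RMSD, redundancy/top-k filters, aggregation, hotspots."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ensdock.poses import (
    LigandTopology,
    Pose,
    PoseError,
    aggregate,
    hotspot_spheres,
    ligand_rmsd,
    nonredundant_filter,
    read_poses,
    rmsd_matrix,
    topk,
    write_poses_mol2,
    write_poses_sdf,
)
from ensdock.synthetic import make_pose_deck, make_toy_ligand

from conftest import make_pose


class TestPoseIO:
    def test_sdf_ranks_follow_scores(self, tmp_path, chain_topology, chain_coords):
        poses = [make_pose(chain_topology, chain_coords + i, score=s)
                 for i, s in enumerate([-90.0, -80.0, -95.0])]
        path = tmp_path / "deck.sdf"
        write_poses_sdf(poses, path)
        back = read_poses(path, chain_topology)
        assert [p.rank for p in back] == [2, 3, 1]
        assert [p.score for p in back] == [-90.0, -80.0, -95.0]

    @pytest.mark.parametrize("fmt", ["sdf", "mol2"])
    def test_roundtrip_preserves_coordinates(self, tmp_path, fmt, chain_topology, chain_coords, rng):
        writer = write_poses_sdf if fmt == "sdf" else write_poses_mol2
        poses = [make_pose(chain_topology, chain_coords + rng.normal(size=(5, 3)), score=-50.0 - i)
                 for i in range(3)]
        path = tmp_path / f"deck.{fmt}"
        writer(poses, path)
        back = read_poses(path, chain_topology)
        assert len(back) == 3
        for orig, rt in zip(poses, back):
            np.testing.assert_allclose(rt.coords, orig.coords, atol=1e-4)
            assert rt.score == pytest.approx(orig.score)

    def test_single_mol2_molecule(self, tmp_path, chain_topology, chain_coords):
        pose = make_pose(chain_topology, chain_coords, score=-77.5)
        path = tmp_path / "one.mol2"
        write_poses_mol2([pose], path)
        (back,) = read_poses(path, chain_topology)
        np.testing.assert_allclose(back.coords, chain_coords, atol=1e-4)
        assert back.score == pytest.approx(-77.5)

    def test_atom_count_mismatch_names_entry(self, tmp_path, chain_topology, chain_coords):
        pose = make_pose(chain_topology, chain_coords, score=-1.0)
        path = tmp_path / "deck.sdf"
        write_poses_sdf([pose], path)
        small = LigandTopology("small", (("C1", "C"), ("C2", "C")), ((0, 1, 1.0),))
        with pytest.raises(PoseError, match="entry 1"):
            read_poses(path, small)

    def test_missing_score_field_raises(self, tmp_path, chain_topology, chain_coords):
        pose = make_pose(chain_topology, chain_coords, score=-1.0)
        path = tmp_path / "deck.sdf"
        write_poses_sdf([pose], path, score_field="OTHER")
        with pytest.raises(PoseError, match="SCORE"):
            read_poses(path, chain_topology)


class TestLigandRmsd:
    def test_identical_poses_zero(self, chain_topology, chain_coords):
        a = make_pose(chain_topology, chain_coords)
        assert ligand_rmsd(a, a) == 0.0

    def test_uniform_translation_is_exact(self, chain_topology, chain_coords):
        a = make_pose(chain_topology, chain_coords)
        b = make_pose(chain_topology, chain_coords + [3.0, 0.0, 0.0])
        assert ligand_rmsd(a, b) == pytest.approx(3.0)

    def test_symmetry_aware_handles_equivalent_ends(self):
        # two-fold symmetric toy ligand: C-N-C path; end swap is an automorphism
        topo = LigandTopology("sym", (("C1", "C"), ("N2", "N"), ("C3", "C")),
                              ((0, 1, 1.0), (1, 2, 1.0)))
        coords = np.array([[0.0, 0.0, 0.0], [1.5, 0.5, 0.0], [3.0, 0.0, 0.7]])
        a = Pose("sym", coords, score=0.0, topology=topo)
        b = Pose("sym", coords[::-1].copy(), score=0.0, topology=topo)
        plain = ligand_rmsd(a, b)
        assert plain > 0.5
        assert ligand_rmsd(a, b, symmetry_aware=True) == pytest.approx(0.0, abs=1e-12)
        # brute-force oracle: minimum over all element/bond-preserving permutations
        best = np.inf
        for perm in itertools.permutations(range(3)):
            if [topo.elements[i] for i in perm] != list(topo.elements):
                continue
            bonds = {frozenset((i, j)) for i, j, _ in topo.bonds}
            if {frozenset((perm[i], perm[j])) for i, j, _ in topo.bonds} != bonds:
                continue
            d = coords - coords[::-1][list(perm)]
            best = min(best, float(np.sqrt(np.mean(np.sum(d * d, axis=1)))))
        assert ligand_rmsd(a, b, symmetry_aware=True) == pytest.approx(best, abs=1e-12)

    def test_frame_mismatch_rejected(self, chain_topology, chain_coords):
        a = make_pose(chain_topology, chain_coords)
        b = make_pose(chain_topology, chain_coords, frame="other")
        with pytest.raises(PoseError, match="frame"):
            ligand_rmsd(a, b)

    def test_pseudometric_on_random_triples(self, rng):
        topo, template = make_toy_ligand(7, seed=0)
        poses = make_pose_deck(topo, template, n=12, box=10.0, seed=2)
        for a, b, c in itertools.combinations(poses, 3):
            dab, dba = ligand_rmsd(a, b), ligand_rmsd(b, a)
            assert dab == pytest.approx(dba)
            assert dab >= 0
            assert dab <= ligand_rmsd(a, c) + ligand_rmsd(c, b) + 1e-12

    def test_matrix_equals_pairwise_calls(self):
        topo, template = make_toy_ligand(6, seed=1)
        poses = make_pose_deck(topo, template, n=15, box=20.0, seed=3)
        mat = rmsd_matrix(poses)
        for i, j in itertools.combinations(range(len(poses)), 2):
            assert mat[i, j] == pytest.approx(ligand_rmsd(poses[i], poses[j]), abs=1e-9)


class TestRedundancyFilter:
    def test_copies_collapse_to_one(self, chain_topology, chain_coords):
        poses = [make_pose(chain_topology, chain_coords, score=-90.0 + i) for i in range(10)]
        assert len(nonredundant_filter(poses, 2.0, 5000)) == 1

    def test_planted_deck_matches_greedy_oracle(self):
        topo, template = make_toy_ligand(6, seed=2)
        offsets = [0.0, 0.5, 1.9, 2.5, 4.0, 4.3, 9.0]  # known pairwise distances on x
        poses = [make_pose(topo, template + [d, 0.0, 0.0], score=-100.0 + i)
                 for i, d in enumerate(offsets)]
        kept = nonredundant_filter(poses, rmsd_threshold=2.0, cap=100)
        # exhaustive greedy on the explicit distance matrix
        dist = np.abs(np.subtract.outer(offsets, offsets))
        expect = []
        for i in range(len(offsets)):
            if all(dist[i, j] > 2.0 for j in expect):
                expect.append(i)
        assert [poses.index(p) for p in kept] == expect

    def test_cap_and_pairwise_separation_on_random_decks(self):
        topo, template = make_toy_ligand(6, seed=3)
        poses = make_pose_deck(topo, template, n=200, box=25.0, seed=7)
        kept = nonredundant_filter(poses, rmsd_threshold=2.0, cap=50)
        assert len(kept) <= 50
        mat = rmsd_matrix(kept)
        off = mat[~np.eye(len(kept), dtype=bool)]
        assert off.min() > 2.0


@given(seed=st.integers(min_value=0, max_value=2**16))
@settings(derandomize=True, max_examples=15, deadline=None)
def test_filter_then_topk_property(seed):
    """topk after redundancy filtering yields <= k poses, pairwise RMSD > threshold."""
    topo, template = make_toy_ligand(6, seed=99)
    poses = make_pose_deck(topo, template, n=80, box=20.0, seed=seed)
    kept = topk(nonredundant_filter(poses, rmsd_threshold=2.0, cap=5000), 10)
    assert len(kept) <= 10
    if len(kept) > 1:
        mat = rmsd_matrix(kept)
        assert mat[~np.eye(len(kept), dtype=bool)].min() > 2.0


class TestTopK:
    def test_top_ten_from_filtered_deck(self):
        topo, template = make_toy_ligand(6, seed=4)
        poses = make_pose_deck(topo, template, n=300, box=60.0, seed=8)
        kept = topk(nonredundant_filter(poses, 2.0, 5000), 10)
        assert len(kept) == 10
        scores = [p.score for p in kept]
        assert scores == sorted(scores)

    def test_small_deck_returns_all(self, chain_topology, chain_coords):
        poses = [make_pose(chain_topology, chain_coords + i, score=-i) for i in range(4)]
        assert len(topk(poses, 10)) == 4

    def test_ties_stable_by_file_order(self, chain_topology, chain_coords):
        p1 = make_pose(chain_topology, chain_coords, score=-90.0)
        p2 = make_pose(chain_topology, chain_coords + 1, score=-90.0)
        assert topk([p1, p2], 1) == [p1]
        assert topk([p2, p1], 1) == [p2]


class TestAggregate:
    def _tops(self, topo, template, n_searches, k, ensemble="closed"):
        out = []
        for ic in range(n_searches):
            deck = make_pose_deck(topo, template, n=40, box=40.0, seed=100 + ic,
                                  ensemble_label=ensemble, conformer_index=ic)
            out.append(topk(deck, k))
        return out

    def test_twelve_searches_of_ten_give_120(self):
        topo, template = make_toy_ligand(6, seed=5)
        agg = aggregate(self._tops(topo, template, 12, 10))
        assert len(agg) == 120
        assert agg.norm_scores.max() == pytest.approx(1.0)
        assert agg.norm_scores.min() == pytest.approx(0.05)
        best = int(np.argmin([p.score for p in agg.poses]))
        assert agg.norm_scores[best] == pytest.approx(1.0)

    def test_equal_scores_all_normalize_to_one(self, chain_topology, chain_coords):
        poses = [make_pose(chain_topology, chain_coords + i, score=-50.0) for i in range(5)]
        agg = aggregate([poses])
        np.testing.assert_allclose(agg.norm_scores, 1.0)

    def test_single_pose_normalizes_to_one(self, chain_topology, chain_coords):
        agg = aggregate([[make_pose(chain_topology, chain_coords, score=-12.0)]])
        np.testing.assert_allclose(agg.norm_scores, [1.0])

    def test_norm_monotone_and_permutation_invariant(self):
        topo, template = make_toy_ligand(6, seed=6)
        tops = self._tops(topo, template, 4, 5)
        agg = aggregate(tops)
        by_score = sorted(zip((p.score for p in agg.poses), agg.norm_scores))
        norms = [n for _, n in by_score]
        assert all(a >= b - 1e-12 for a, b in zip(norms, norms[1:]))  # lower score = better
        shuffled = aggregate([list(reversed(t)) for t in reversed(tops)])
        assert sorted(np.round(shuffled.norm_scores, 12)) == sorted(np.round(agg.norm_scores, 12))

    def test_mixed_ligand_or_ensemble_rejected(self, chain_topology, chain_coords):
        a = make_pose(chain_topology, chain_coords, score=-1.0)
        other = LigandTopology("other", chain_topology.atoms, chain_topology.bonds)
        b = make_pose(other, chain_coords, score=-2.0)
        with pytest.raises(PoseError, match="mixed ligands"):
            aggregate([[a], [b]])
        c = make_pose(chain_topology, chain_coords, score=-2.0, ensemble_label="open")
        with pytest.raises(PoseError, match="mixed ensembles"):
            aggregate([[a], [c]])


class TestHotspots:
    def test_radius_proportional_to_norm_score(self, chain_topology, chain_coords):
        best = make_pose(chain_topology, chain_coords, score=-100.0)
        mid = make_pose(chain_topology, chain_coords + 5, score=-50.0)
        agg = aggregate([[best, mid]], norm_floor=0.05)
        agg.norm_scores = np.array([1.0, 0.5])  # fixed norms for the proportionality check
        spheres = hotspot_spheres(agg, r_max=2.0)
        assert spheres[0].radius == pytest.approx(2.0)
        assert spheres[1].radius == pytest.approx(1.0)

    def test_center_is_heavy_atom_mean(self, chain_topology, chain_coords):
        pose = make_pose(chain_topology, chain_coords, score=-10.0)
        (sphere,) = hotspot_spheres(aggregate([[pose]]), r_max=1.5)
        np.testing.assert_allclose(sphere.center, chain_coords.mean(axis=0))
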