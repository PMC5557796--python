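"""Pose clustering: atom sets, RMSD, UPGMA, cut metrics, k selection."""

import numpy as np
import pytest
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import adjusted_rand_score

from bindmode import synthetic as syn
from bindmode.clustering import (
    PoseClustering,
    average_linkage,
    clustering_atom_set,
    cut_metrics,
    rmsd_matrix,
    select_k,
)
from bindmode.errors import StructureError
from bindmode.io import Atom, PoseEnsemble, Residue


def _mini_ensemble(lig_positions, receptor_positions=((0.0, 0.0, 3.0),)):
    """Tiny hand-built ensemble: carbon ligand atoms vs carbon residues."""
    receptor = [
        Residue(
            chain="A", number=10 + i, name="ALA",
            atoms=[Atom(name="CB", element="C", coords=np.asarray(p, float))],
        )
        for i, p in enumerate(receptor_positions)
    ]
    poses = [
        [
            Atom(name=f"C{j + 1}", element="C", coords=np.asarray(p, float))
            for j, p in enumerate(pose)
        ]
        for pose in lig_positions
    ]
    return PoseEnsemble(
        receptor=receptor,
        poses=poses,
        pose_ids=[f"p{i}" for i in range(len(poses))],
    )


class TestClusteringAtomSet:
    def test_nearby_residue_included_distant_excluded(self):
        ens = _mini_ensemble(
            [[(0, 0, 0)]],
            receptor_positions=[(0, 0, 3.0), (0, 0, 9.0)],
        )
        atom_set = clustering_atom_set(ens, pocket_radius=4.0)
        assert atom_set.pocket_residue_keys == [("A", 10)]
        assert atom_set.n_atoms == 2  # ligand C + one residue C

    def test_radius_zero_gives_ligand_only(self):
        ens = _mini_ensemble([[(0, 0, 0), (1.5, 0, 0)]])
        atom_set = clustering_atom_set(ens, pocket_radius=0.0)
        assert atom_set.receptor_atoms == []
        assert len(atom_set.ligand_idx) == 2

    def test_union_over_poses(self):
        """The fixed atom set contains every residue any single pose
        would include on its own."""
        ens = _mini_ensemble(
            [[(0, 0, 0)], [(0, 0, 6.0)]],
            receptor_positions=[(0, 0, 3.0), (0, 0, 9.0)],
        )
        both = clustering_atom_set(ens, 4.0).pocket_residue_keys
        for i in range(2):
            single = PoseEnsemble(
                receptor=ens.receptor, poses=[ens.poses[i]], pose_ids=["p"],
            )
            solo = clustering_atom_set(single, 4.0).pocket_residue_keys
            assert set(solo) <= set(both)

    def test_ligand_far_from_receptor_is_error(self):
        ens = _mini_ensemble([[(0, 0, -50.0)]])
        with pytest.raises(StructureError, match="4.0"):
            clustering_atom_set(ens, 4.0)

    def test_nonpolar_hydrogens_excluded(self, all_kinds_ensemble):
        ensemble, _ = all_kinds_ensemble
        atom_set = clustering_atom_set(ensemble, 4.0)
        for idx in atom_set.ligand_idx:
            a = ensemble.poses[0][idx]
            assert a.is_heavy or a.is_polar_h


class TestRmsdMatrix:
    def test_uniform_ligand_shift_is_exact(self):
        ens = _mini_ensemble([[(0, 0, 0), (1.5, 0, 0)],
                              [(1, 0, 0), (2.5, 0, 0)]])
        atom_set = clustering_atom_set(ens, pocket_radius=0.0)
        D = rmsd_matrix(ens, atom_set)
        assert D[0, 1] == pytest.approx(1.0)
        assert D[0, 0] == 0.0

    def test_identical_poses_zero(self):
        ens = _mini_ensemble([[(0, 0, 0)], [(0, 0, 0)]])
        D = rmsd_matrix(ens, clustering_atom_set(ens, 0.0))
        assert np.all(D == 0)

    def test_matches_naive_double_loop(self):
        rng = np.random.default_rng(5)
        poses = rng.uniform(-3, 3, size=(5, 7, 3))
        ens = _mini_ensemble([list(map(tuple, p)) for p in poses])
        atom_set = clustering_atom_set(ens, 0.0)
        D = rmsd_matrix(ens, atom_set)
        for i in range(5):
            for j in range(5):
                naive = np.sqrt(
                    np.mean(
                        [
                            np.sum((poses[i, a] - poses[j, a]) ** 2)
                            for a in range(7)
                        ]
                    )
                )
                assert D[i, j] == pytest.approx(naive, abs=1e-12)


class TestAverageLinkage:
    def test_forced_topology(self):
        D = np.array(
            [[0, 1, 10], [1, 0, 10], [10, 10, 0]], dtype=float
        )
        tree = average_linkage(D)
        assert set(tree.merges[0][0]) | set(tree.merges[0][1]) == {0, 1}
        assert tree.merges[1][2] == pytest.approx(10.0)

    def test_matches_brute_force_recomputation(self, brute_linkage):
        rng = np.random.default_rng(12)
        for _ in range(5):
            pts = rng.uniform(0, 10, size=(8, 2))
            D = np.sqrt(
                ((pts[:, None] - pts[None]) ** 2).sum(-1)
            )
            tree = average_linkage(D)
            expected = brute_linkage(D)
            for (ma, mb, h), (ea, eb, eh) in zip(tree.merges, expected):
                assert {frozenset(ma), frozenset(mb)} == {ea, eb}
                assert h == pytest.approx(eh, abs=1e-9)

    def test_matches_scipy_heights_and_partitions(self):
        """Independent cross-check against scipy's average linkage."""
        rng = np.random.default_rng(3)
        pts = rng.uniform(0, 10, size=(10, 3))
        D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        tree = average_linkage(D)
        Z = linkage(squareform(D, checks=False), method="average")
        np.testing.assert_allclose(tree.heights, Z[:, 2], atol=1e-9)
        for k in range(1, 11):
            ours = tree.cut(k)
            scipys = fcluster(Z, t=k, criterion="maxclust")
            assert adjusted_rand_score(ours, scipys) == pytest.approx(1.0)

    def test_all_equal_distances_tie_break(self):
        D = np.ones((4, 4)) - np.eye(4)
        tree = average_linkage(D)
        # smallest index pair first; tree stays a valid partition history
        assert set(tree.merges[0][0]) | set(tree.merges[0][1]) == {0, 1}
        labels = tree.cut(1)
        assert set(labels) == {0}

    def test_heights_non_decreasing(self, three_group_ensemble):
        ensemble, _ = three_group_ensemble
        model = PoseClustering(ensemble, 4.0)
        tree = average_linkage(model.rmsd)
        h = tree.heights
        assert np.all(np.diff(h) >= -1e-12)


class TestCutMetrics:
    def _toy(self):
        rng = np.random.default_rng(8)
        blob1 = rng.normal(0, 0.3, size=(5, 2))
        blob2 = rng.normal(8, 0.3, size=(5, 2))
        pts = np.vstack([blob1, blob2])
        return np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))

    def test_r2_boundaries(self):
        D = self._toy()
        tree = average_linkage(D)
        assert cut_metrics(tree, D, len(D))[0] == pytest.approx(1.0)
        assert cut_metrics(tree, D, 1)[0] == pytest.approx(0.0, abs=1e-12)

    def test_two_blob_r2(self, brute_r2):
        D = self._toy()
        tree = average_linkage(D)
        r2, _ = cut_metrics(tree, D, 2)
        assert r2 > 0.95
        assert r2 == pytest.approx(brute_r2(D, tree.cut(2)), abs=1e-12)

    def test_r2_monotone_in_k(self):
        D = self._toy()
        tree = average_linkage(D)
        r2s = [cut_metrics(tree, D, k)[0] for k in range(1, len(D) + 1)]
        assert np.all(np.diff(r2s) >= -1e-12)

    def test_strain_at_least_one_for_monotone_linkage(self):
        D = self._toy()
        tree = average_linkage(D)
        for k in range(1, len(D) + 1):
            assert cut_metrics(tree, D, k)[1] >= 1.0 - 1e-12

    def test_strain_boundary_is_one(self):
        D = self._toy()
        tree = average_linkage(D)
        n = len(D)
        assert cut_metrics(tree, D, n - 1)[1] == 1.0
        assert cut_metrics(tree, D, n)[1] == 1.0

    def test_k_out_of_range(self):
        D = self._toy()
        tree = average_linkage(D)
        with pytest.raises(ValueError):
            cut_metrics(tree, D, 0)


class TestSelectK:
    def test_planted_three_groups(self, three_group_ensemble):
        ensemble, truth = three_group_ensemble
        model = PoseClustering(ensemble, 4.0)
        tree = average_linkage(model.rmsd)
        k, labels, medoids = select_k(tree, model.rmsd, 0.7)
        assert k == 3
        assert adjusted_rand_score(truth["group_labels"], labels) == 1.0
        # one medoid from each planted group
        groups = {truth["group_labels"][m] for m in medoids}
        assert groups == {0, 1, 2}

    def test_threshold_zero_gives_one_cluster(self, three_group_ensemble):
        ensemble, _ = three_group_ensemble
        model = PoseClustering(ensemble, 4.0)
        tree = average_linkage(model.rmsd)
        k, _, _ = select_k(tree, model.rmsd, 0.0)
        assert k == 1

    def test_single_pose(self):
        ens = _mini_ensemble([[(0, 0, 0)]])
        res = PoseClustering(ens, 0.0).fit(0.7)
        assert res.k == 1
        assert res.medoid_indices == [0]

    def test_unreachable_threshold_falls_back_with_warning(self):
        D = np.zeros((3, 3))
        tree = average_linkage(D)
        with pytest.warns(UserWarning, match="unreachable"):
            k, _, _ = select_k(tree, D, 1.5)
        assert k == 3


class TestPermutationInvariance:
    def test_partition_invariant_up_to_relabeling(self, three_group_ensemble):
        ensemble, _ = three_group_ensemble
        rng = np.random.default_rng(9)
        perm = rng.permutation(ensemble.n_poses)
        permuted = PoseEnsemble(
            receptor=ensemble.receptor,
            poses=[ensemble.poses[i] for i in perm],
            pose_ids=[ensemble.pose_ids[i] for i in perm],
            ligand_resname=ensemble.ligand_resname,
        )
        res0 = PoseClustering(ensemble, 4.0).fit(0.7)
        res1 = PoseClustering(permuted, 4.0).fit(0.7)
        assert res1.k == res0.k
        assert (
            adjusted_rand_score(res0.labels[perm], res1.labels) == 1.0
        )
        assert set(res1.representative_ids) == set(res0.representative_ids)


class TestResultsObject:
    def test_summary_and_frames(self, three_group_ensemble):
        ensemble, _ = three_group_ensemble
        res = PoseClustering(ensemble, 4.0).fit(0.7)
        text = res.summary()
        assert "chosen k: 3" in text
        assert len(res.assignment_frame()) == ensemble.n_poses
        metrics = res.metrics_frame()
        assert list(metrics.columns) == ["k", "r2", "strain"]
        assert len(res.linkage_frame()) == ensemble.n_poses - 1

    def test_write_outputs(self, tmp_path, three_group_ensemble):
        ensemble, _ = three_group_ensemble
        res = PoseClustering(ensemble, 4.0).fit(0.7)
        res.write(tmp_path)
        assert (tmp_path / "metrics.csv").exists()
        assert len(list(tmp_path.glob("representative_*.pdb"))) == res.k
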