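"""Interaction detectors: canonical geometries, cutoffs, invariances."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from bindmode.errors import StructureError
from bindmode.interactions import (
    InteractionConfig,
    LigandContext,
    detect_aromatic,
    detect_hbond,
    detect_hydrophobic,
    detect_salt_bridge,
    fingerprint_ensemble,
    min_heavy_distance,
)
from bindmode.io import Atom, PoseEnsemble, Residue
from bindmode import synthetic as syn


def atom(name, element, xyz, charge=0, polar_h=False):
    return Atom(
        name=name, element=element, coords=np.asarray(xyz, float),
        formal_charge=charge, is_polar_h=polar_h,
    )


def residue(name, atoms, number=1):
    return Residue(chain="A", number=number, name=name, atoms=atoms)


def benzene_ring(center, normal="z"):
    """Six sp2 carbons on a regular hexagon of radius 1.39 Å."""
    center = np.asarray(center, float)
    if normal == "z":
        v, w = np.array([1.0, 0, 0]), np.array([0, 1.0, 0])
    else:
        v, w = np.array([0, 1.0, 0]), np.array([0, 0, 1.0])
    return [
        center + 1.39 * (np.cos(a) * v + np.sin(a) * w)
        for a in np.arange(6) * np.pi / 3
    ]


class TestMinHeavyDistance:
    def test_single_pair(self):
        res = residue("GLY", [atom("CA", "C", [0, 0, 0])])
        lig = [atom("C1", "C", [0, 0, 3.6])]
        assert min_heavy_distance(res, lig) == pytest.approx(3.6)

    @given(st.integers(0, 2 ** 31 - 1))
    def test_matches_exhaustive_pairwise_minimum(self, seed):
        rng = np.random.default_rng(seed)
        res_atoms = [
            atom(f"C{i}", "C", rng.uniform(-5, 5, 3)) for i in range(10)
        ]
        lig = [atom(f"L{i}", "C", rng.uniform(-5, 5, 3)) for i in range(10)]
        expected = min(
            np.linalg.norm(a.coords - b.coords)
            for a in res_atoms
            for b in lig
        )
        got = min_heavy_distance(residue("GLY", res_atoms), lig)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_identical_coordinates_flagged_as_clash(self):
        res = residue("GLY", [atom("CA", "C", [1, 1, 1])])
        with pytest.warns(UserWarning, match="clash"):
            assert min_heavy_distance(res, [atom("C1", "C", [1, 1, 1])]) == 0.0

    def test_hydrogens_only_is_error(self):
        res = residue("GLY", [atom("H1", "H", [0, 0, 0])])
        with pytest.raises(StructureError):
            min_heavy_distance(res, [atom("C1", "C", [0, 0, 1])])


class TestHbond:
    def test_canonical_geometry_with_hydrogen(self):
        # ligand hydroxyl donating to a backbone carbonyl at 2.9 Å, ~165°
        o_lig = np.array([0.0, 0.0, 0.0])
        o_res = np.array([0.0, 0.0, 2.9])
        h = o_lig + 0.97 * np.array([np.sin(0.26), 0, np.cos(0.26)])
        res = residue("GLY", [atom("O", "O", o_res)])
        lig = [atom("O1", "O", o_lig), atom("H1", "H", h, polar_h=True)]
        recs = detect_hbond(res, lig)
        assert len(recs) == 1
        assert recs[0].kind == "hbond"
        assert recs[0].distance == pytest.approx(2.9)

    def test_beyond_cutoff_empty(self):
        res = residue("GLY", [atom("O", "O", [0, 0, 3.8])])
        lig = [atom("O1", "O", [0, 0, 0])]
        assert detect_hbond(res, lig) == []

    def test_bad_angle_rejected(self):
        # hydrogen pointing away from the acceptor: D-H...A ~ 0°
        res = residue("GLY", [atom("O", "O", [0, 0, 2.9])])
        lig = [
            atom("O1", "O", [0, 0, 0]),
            atom("H1", "H", [0, 0, -0.97], polar_h=True),
        ]
        assert detect_hbond(res, lig) == []

    def test_no_hydrogens_distance_only(self):
        res = residue("ASN", [atom("OD1", "O", [0, 0, 2.9])])
        lig = [atom("N1", "N", [0, 0, 0])]
        recs = detect_hbond(res, lig)
        assert len(recs) == 1
        assert "no H" in recs[0].detail

    def test_planted_hydroxyl_to_asparagine(self, quinine_ensemble):
        """The planted quinine-like pose donates an H-bond to residue 93."""
        ensemble, _ = quinine_ensemble
        res = ensemble.residue(("A", 93))
        recs = detect_hbond(res, ensemble.poses[0])
        assert any(r.kind == "hbond" for r in recs)


class TestHydrophobic:
    @pytest.mark.parametrize(
        "dist,present", [(4.7, True), (5.0, True), (5.3, False)]
    )
    def test_cutoff_inclusive(self, dist, present):
        res = residue("LEU", [atom("CD1", "C", [0, 0, 0])])
        lig = [atom("C1", "C", [0, 0, dist])]
        recs = detect_hydrophobic(res, lig)
        assert bool(recs) is present

    def test_backbone_carbons_excluded(self):
        res = residue("LEU", [atom("CA", "C", [0, 0, 0])])
        lig = [atom("C1", "C", [0, 0, 3.0])]
        assert detect_hydrophobic(res, lig) == []

    def test_polar_ligand_atom_not_counted(self):
        res = residue("LEU", [atom("CD1", "C", [0, 0, 0])])
        lig = [atom("O1", "O", [0, 0, 3.0])]
        assert detect_hydrophobic(res, lig) == []


class TestAromatic:
    def _phe(self, center=(0, 0, 0)):
        names = ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]
        return residue(
            "PHE",
            [atom(n, "C", p) for n, p in zip(names, benzene_ring(center))],
        )

    def test_parallel_stack(self):
        res = self._phe()
        lig = [
            atom(f"C{i}", "C", p)
            for i, p in enumerate(benzene_ring([0, 0, 3.8]))
        ]
        recs = detect_aromatic(res, lig)
        assert any(r.kind == "pi_pi" for r in recs)
        pi = next(r for r in recs if r.kind == "pi_pi")
        assert pi.distance == pytest.approx(3.8, abs=1e-6)

    def test_centroids_beyond_cutoff(self):
        res = self._phe()
        lig = [
            atom(f"C{i}", "C", p)
            for i, p in enumerate(benzene_ring([0, 0, 6.2]))
        ]
        assert not [r for r in detect_aromatic(res, lig) if r.kind == "pi_pi"]

    def test_intermediate_tilt_rejected(self):
        # 45° interplanar angle is neither face (≤30°) nor edge (≥60°)
        res = self._phe()
        c, s = np.cos(np.pi / 4), np.sin(np.pi / 4)
        center = np.array([0, 0, 4.5])
        v = np.array([1.0, 0, 0])
        w = np.array([0, c, s])
        lig = [
            atom(f"C{i}", "C", center + 1.39 * (np.cos(a) * v + np.sin(a) * w))
            for i, a in enumerate(np.arange(6) * np.pi / 3)
        ]
        assert not [r for r in detect_aromatic(res, lig) if r.kind == "pi_pi"]

    def test_cation_over_residue_ring(self):
        res = self._phe()
        lig = [atom("N1", "N", [0, 0, 4.5], charge=+1)]
        recs = detect_aromatic(res, lig)
        assert any(r.kind == "cation_pi" for r in recs)

    def test_lysine_over_ligand_ring(self):
        res = residue("LYS", [atom("NZ", "N", [0, 0, 4.0])])
        lig = [
            atom(f"C{i}", "C", p) for i, p in enumerate(benzene_ring([0, 0, 0]))
        ]
        recs = detect_aromatic(res, lig)
        assert any(r.kind == "cation_pi" for r in recs)


class TestSaltBridge:
    def test_canonical_pair(self):
        res = residue("LYS", [atom("NZ", "N", [0, 0, 0])])
        lig = [atom("O1", "O", [0, 0, 3.2], charge=-1)]
        recs = detect_salt_bridge(res, lig)
        assert len(recs) == 1
        assert recs[0].distance == pytest.approx(3.2)

    def test_uncharged_ligand_oxygen_no_bridge(self):
        res = residue("LYS", [atom("NZ", "N", [0, 0, 0])])
        lig = [atom("O1", "O", [0, 0, 3.2])]
        assert detect_salt_bridge(res, lig) == []
        # ...though the geometry still qualifies as an H-bond
        assert detect_hbond(res, lig)

    def test_beyond_cutoff(self):
        res = residue("LYS", [atom("NZ", "N", [0, 0, 0])])
        lig = [atom("O1", "O", [0, 0, 4.5], charge=-1)]
        assert detect_salt_bridge(res, lig) == []


class TestLigandContext:
    def test_amine_heuristic_when_no_charges(self):
        # isolated aliphatic N with no explicit charges -> protonated
        lig = [atom("N1", "N", [0, 0, 0]), atom("C1", "C", [0, 0, 1.5])]
        ctx = LigandContext(lig)
        assert ctx.charges[0] == 1

    def test_explicit_charges_disable_heuristic(self):
        lig = [
            atom("N1", "N", [0, 0, 0]),
            atom("O1", "O", [0, 0, 5.0], charge=-1),
        ]
        ctx = LigandContext(lig)
        assert ctx.charges[0] == 0
        assert ctx.charges[1] == -1

    def test_ring_perception_from_distances(self):
        lig = [
            atom(f"C{i}", "C", p) for i, p in enumerate(benzene_ring([0, 0, 0]))
        ]
        ctx = LigandContext(lig)
        assert len(ctx.rings) == 1
        assert len(ctx.rings[0][0]) == 6


class TestFingerprintEnsemble:
    def test_planted_quinine_pattern_cells(self, quinine_ensemble, panel_numbers):
        """Non-empty cells exactly at the planted contact residues; the
        two untouched panel residues stay empty."""
        ensemble, truth = quinine_ensemble
        matrix = fingerprint_ensemble(ensemble, panel_numbers)
        pid = matrix.pose_ids[0]
        nonempty = {
            key[1] for key in matrix.residue_keys if matrix.kinds(pid, key)
        }
        assert nonempty == {93, 247, 181, 244, 185, 251}

    def test_translated_ligand_all_cells_empty(self, quinine_ensemble, panel_numbers):
        ensemble, _ = quinine_ensemble
        far_poses = [
            [
                Atom(a.name, a.element, a.coords + np.array([0, 0, 40.0]),
                     a.is_polar_h, a.formal_charge)
                for a in pose
            ]
            for pose in ensemble.poses
        ]
        far = PoseEnsemble(
            receptor=ensemble.receptor,
            poses=far_poses,
            pose_ids=ensemble.pose_ids,
            ligand_resname=ensemble.ligand_resname,
        )
        matrix = fingerprint_ensemble(far, panel_numbers)
        assert not matrix.records

    def test_matrix_equals_union_of_detectors(self, all_kinds_ensemble, panel_numbers):
        """A 1-pose matrix equals the union of the four detectors run
        separately on each panel residue."""
        ensemble, _ = all_kinds_ensemble
        single = PoseEnsemble(
            receptor=ensemble.receptor,
            poses=[ensemble.poses[0]],
            pose_ids=[ensemble.pose_ids[0]],
            ligand_resname=ensemble.ligand_resname,
        )
        matrix = fingerprint_ensemble(single, panel_numbers)
        ctx = LigandContext(single.poses[0])
        pid = single.pose_ids[0]
        for key in matrix.residue_keys:
            res = ensemble.residue(key)
            expected = set()
            for det in (
                detect_hbond, detect_salt_bridge, detect_aromatic,
                detect_hydrophobic,
            ):
                expected |= {r.kind for r in det(res, ctx, pose_id=pid)}
            assert matrix.kinds(pid, key) == expected

    def test_empty_panel_is_error(self, quinine_ensemble):
        ensemble, _ = quinine_ensemble
        with pytest.raises(StructureError):
            fingerprint_ensemble(ensemble, [])

    def test_absent_panel_residue_is_error(self, quinine_ensemble):
        ensemble, _ = quinine_ensemble
        with pytest.raises(StructureError, match="999"):
            fingerprint_ensemble(ensemble, [999])


def _rigid_transform(coords, rng):
    # random rotation (QR of a Gaussian matrix) + translation
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    t = rng.uniform(-20, 20, 3)
    return coords @ q.T + t, q, t


class TestInvariances:
    def test_rigid_motion_leaves_records_unchanged(self, all_kinds_ensemble, panel_numbers):
        """Rotating + translating the whole complex preserves every
        record's kind and distance to 1e-9 Å."""
        ensemble, _ = all_kinds_ensemble
        rng = np.random.default_rng(7)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        t = rng.uniform(-15, 15, 3)

        def move(a):
            return Atom(a.name, a.element, q @ a.coords + t,
                        a.is_polar_h, a.formal_charge)

        receptor = [
            Residue(r.chain, r.number, r.name, [move(a) for a in r.atoms])
            for r in ensemble.receptor
        ]
        moved = PoseEnsemble(
            receptor=receptor,
            poses=[[move(a) for a in p] for p in ensemble.poses],
            pose_ids=ensemble.pose_ids,
            ligand_resname=ensemble.ligand_resname,
        )
        m0 = fingerprint_ensemble(ensemble, panel_numbers)
        m1 = fingerprint_ensemble(moved, panel_numbers)
        for key, recs in m0.records.items():
            recs1 = m1.records[key]
            d0 = sorted((r.kind, round(r.distance, 9)) for r in recs)
            d1 = sorted((r.kind, round(r.distance, 9)) for r in recs1)
            assert d0 == d1

    def test_shrinking_cutoffs_never_adds_records(self, all_kinds_ensemble, panel_numbers):
        ensemble, _ = all_kinds_ensemble
        loose = fingerprint_ensemble(ensemble, panel_numbers)
        tight_cfg = InteractionConfig(
            hbond_max=3.0, hydrophobic_max=4.0, pi_centroid_max=4.0,
            cation_pi_max=5.0, salt_bridge_max=3.4,
        )
        tight = fingerprint_ensemble(ensemble, panel_numbers, tight_cfg)
        for pid in ensemble.pose_ids:
            for key in loose.residue_keys:
                assert tight.kinds(pid, key) <= loose.kinds(pid, key)
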