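"""Hierarchical pose clustering on ligand + pocket RMSD.

The ensemble is reduced to representative structures by unweighted
average-linkage (UPGMA) clustering of a pairwise RMSD matrix computed on
the ligand atoms plus the atoms of receptor residues within a pocket
radius of the ligand, excluding non-polar hydrogens.  Poses share one
coordinate frame, so the RMSD needs no superposition.

The number of clusters is chosen as the smallest k whose partition
explains a target fraction of the total pairwise dispersion
(R²(k) = 1 − SSW/SST on squared distances); each cluster is represented
by its medoid.  A "strain" diagnostic — the ratio of the linkage height
of the merge that produced the k-cluster partition to the height of the
merge before it — is reported alongside; values just above 1 indicate a
smooth dendrogram around the cut.

The linkage is implemented directly (O(N³) Lance–Williams) so that ties
are broken deterministically by the smallest (i, j) index pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import StructureError
from .io import PoseEnsemble, write_pose

__all__ = [
    "ClusteringAtomSet",
    "ClusterTree",
    "clustering_atom_set",
    "rmsd_matrix",
    "average_linkage",
    "cut_metrics",
    "select_k",
    "PoseClustering",
    "PoseClusteringResults",
]


@dataclass
class ClusteringAtomSet:
    """Atom bookkeeping for the RMSD metric.

    ``ligand_idx`` indexes into each pose's atom list; ``receptor_atoms``
    holds (residue index, atom index) pairs into the shared receptor.
    The set is fixed for the whole ensemble (union of per-pose pockets),
    so the induced RMSD is a true metric across poses.
    """

    ligand_idx: list[int]
    receptor_atoms: list[tuple[int, int]]
    pocket_residue_keys: list[tuple]

    @property
    def n_atoms(self) -> int:
        return len(self.ligand_idx) + len(self.receptor_atoms)


def _keep_atom(atom) -> bool:
    # heavy atoms and polar hydrogens; non-polar hydrogens excluded
    return atom.is_heavy or atom.is_polar_h


def clustering_atom_set(
    ensemble: PoseEnsemble, pocket_radius: float = 4.0
) -> ClusteringAtomSet:
    """Ligand atoms plus atoms of residues within ``pocket_radius`` Å.

    A receptor residue qualifies when any of its heavy atoms lies within
    the radius of any pose's ligand heavy atoms (union over poses).
    ``pocket_radius = 0`` yields the ligand atoms alone.
    """
    if pocket_radius < 0:
        raise ValueError("pocket_radius must be non-negative")
    ligand_idx = [
        i for i, a in enumerate(ensemble.poses[0]) if _keep_atom(a)
    ]
    if not ligand_idx:
        raise StructureError("ligand has no heavy atoms or polar hydrogens")
    pocket_res: list[int] = []
    if pocket_radius > 0:
        lig_coords = []
        for i in range(ensemble.n_poses):
            pose = ensemble.poses[i]
            lig_coords.append(
                np.array([a.coords for a in pose if a.is_heavy])
            )
        all_lig = np.vstack(lig_coords)
        for ri, res in enumerate(ensemble.receptor):
            rc = res.heavy_coords()
            if rc.size == 0:
                continue
            d2 = (
                (rc[:, None, :] - all_lig[None, :, :]) ** 2
            ).sum(axis=2)
            if np.min(d2) <= pocket_radius ** 2:
                pocket_res.append(ri)
        if not pocket_res:
            raise StructureError(
                f"no receptor residue within {pocket_radius} Å of the ligand "
                "in any pose"
            )
    receptor_atoms = [
        (ri, ai)
        for ri in pocket_res
        for ai, a in enumerate(ensemble.receptor[ri].atoms)
        if _keep_atom(a)
    ]
    return ClusteringAtomSet(
        ligand_idx=ligand_idx,
        receptor_atoms=receptor_atoms,
        pocket_residue_keys=[ensemble.receptor[ri].key for ri in pocket_res],
    )


def _pose_matrix(ensemble: PoseEnsemble, atom_set: ClusteringAtomSet) -> np.ndarray:
    """(n_poses, n_atoms, 3) coordinate tensor over the clustering atoms."""
    rec_coords = np.array(
        [
            ensemble.receptor[ri].atoms[ai].coords
            for ri, ai in atom_set.receptor_atoms
        ]
    ).reshape(-1, 3)
    frames = []
    for i in range(ensemble.n_poses):
        pose = ensemble.poses[i]
        lig = np.array([pose[j].coords for j in atom_set.ligand_idx])
        frames.append(
            np.vstack([lig, rec_coords]) if rec_coords.size else lig
        )
    return np.stack(frames)


def rmsd_matrix(
    ensemble: PoseEnsemble, atom_set: ClusteringAtomSet
) -> np.ndarray:
    """Symmetric pairwise coordinate RMSD (Å) without refitting."""
    coords = _pose_matrix(ensemble, atom_set)
    diff = coords[:, None, :, :] - coords[None, :, :, :]
    msd = (diff ** 2).sum(axis=3).mean(axis=2)
    out = np.sqrt(msd)
    np.fill_diagonal(out, 0.0)
    return out


@dataclass
class ClusterTree:
    """Merge history of an agglomerative clustering.

    Each merge records the member index tuples of the two clusters joined
    and the linkage height.  ``cut(k)`` replays the first n−k merges and
    returns labels 0..k−1, ordered by each cluster's smallest member.
    """

    n_leaves: int
    merges: list = field(default_factory=list)  # (members_a, members_b, height)

    @property
    def heights(self) -> np.ndarray:
        return np.array([m[2] for m in self.merges], dtype=float)

    def cut(self, k: int) -> np.ndarray:
        if not 1 <= k <= self.n_leaves:
            raise ValueError(f"k={k} out of range 1..{self.n_leaves}")
        clusters = [frozenset([i]) for i in range(self.n_leaves)]
        for members_a, members_b, _ in self.merges[: self.n_leaves - k]:
            sa, sb = frozenset(members_a), frozenset(members_b)
            clusters = [c for c in clusters if c != sa and c != sb]
            clusters.append(sa | sb)
        clusters.sort(key=min)
        labels = np.empty(self.n_leaves, dtype=int)
        for label, members in enumerate(clusters):
            for i in members:
                labels[i] = label
        return labels


def average_linkage(matrix: np.ndarray) -> ClusterTree:
    """UPGMA merge history from a pairwise distance matrix.

    Inter-cluster distance is the unweighted mean over all cross pairs;
    ties are broken by the smallest (i, j) pair of cluster representative
    indices (a cluster is represented by its smallest member).
    """
    D = np.asarray(matrix, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n) or not np.allclose(D, D.T, atol=1e-9):
        raise ValueError("distance matrix must be square and symmetric")
    tree = ClusterTree(n_leaves=n)
    if n == 1:
        return tree
    members: dict[int, tuple] = {i: (i,) for i in range(n)}
    dist = {
        (i, j): float(D[i, j]) for i in range(n) for j in range(i + 1, n)
    }
    active = sorted(members)
    for _ in range(n - 1):
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1:]:
                d = dist[(i, j)]
                if best is None or d < best[0] - 1e-12:
                    best = (d, i, j)
                # ties resolved by the (i, j) scan order: active is sorted,
                # so the smallest representative pair wins
        d, i, j = best
        tree.merges.append((members[i], members[j], d))
        ni, nj = len(members[i]), len(members[j])
        merged = tuple(sorted(members[i] + members[j]))
        for k in active:
            if k in (i, j):
                continue
            dik = dist[(min(i, k), max(i, k))]
            djk = dist[(min(j, k), max(j, k))]
            dist[(min(i, k), max(i, k))] = (ni * dik + nj * djk) / (ni + nj)
        members[i] = merged
        del members[j]
        active.remove(j)
    return tree


def _pairwise_ss(D: np.ndarray, idx: np.ndarray) -> float:
    sub = D[np.ix_(idx, idx)]
    return float((sub ** 2).sum()) / (2.0 * len(idx))


def cut_metrics(
    tree: ClusterTree, matrix: np.ndarray, k: int
) -> tuple[float, float]:
    """R² and strain of the k-cluster partition.

    R²(k) = 1 − SSW(k)/SST with sums of squared pairwise distances
    (SSW summed per cluster as Σ d²/(2 n_c)); strain(k) is the height of
    the merge that produced k clusters divided by the height of the merge
    before it, 1.0 at the boundaries.
    """
    n = tree.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range 1..{n}")
    D = np.asarray(matrix, dtype=float)
    sst = _pairwise_ss(D, np.arange(n))
    if sst <= 0:
        r2 = 1.0
    else:
        labels = tree.cut(k)
        ssw = sum(
            _pairwise_ss(D, np.flatnonzero(labels == c))
            for c in np.unique(labels)
        )
        r2 = 1.0 - ssw / sst
    h = tree.heights
    t = n - k - 1  # index of the merge that produced k clusters
    if t >= 1:
        if h[t - 1] > 0:
            strain = float(h[t] / h[t - 1])
        else:
            strain = float("inf") if h[t] > 0 else 1.0
    else:
        strain = 1.0
    return float(r2), strain


def select_k(
    tree: ClusterTree,
    matrix: np.ndarray,
    r2_threshold: float = 0.7,
) -> tuple[int, np.ndarray, list[int]]:
    """Smallest k with R²(k) ≥ threshold, plus labels and medoid indices.

    The representative of each cluster is its medoid (minimum summed
    intra-cluster distance, ties to the lowest pose index).
    """
    n = tree.n_leaves
    D = np.asarray(matrix, dtype=float)
    chosen = None
    for k in range(1, n + 1):
        r2, _ = cut_metrics(tree, D, k)
        if r2 >= r2_threshold:
            chosen = k
            break
    if chosen is None:
        warnings.warn(
            f"R² threshold {r2_threshold} unreachable; falling back to k={n}",
            stacklevel=2,
        )
        chosen = n
    labels = tree.cut(chosen)
    medoids = []
    for c in range(chosen):
        idx = np.flatnonzero(labels == c)
        sums = D[np.ix_(idx, idx)].sum(axis=1)
        medoids.append(int(idx[int(np.argmin(sums))]))
    return chosen, labels, medoids


class PoseClustering:
    """Average-linkage clustering model over a pose ensemble.

    Parameters
    ----------
    ensemble
        Shared-frame pose ensemble.
    pocket_radius
        Pocket inclusion radius in Å around the ligand (default 4.0).
    """

    def __init__(self, ensemble: PoseEnsemble, pocket_radius: float = 4.0):
        self.ensemble = ensemble
        self.pocket_radius = pocket_radius
        self.atom_set = clustering_atom_set(ensemble, pocket_radius)
        self.rmsd = rmsd_matrix(ensemble, self.atom_set)

    def fit(self, r2_threshold: float = 0.7) -> "PoseClusteringResults":
        tree = average_linkage(self.rmsd)
        k, labels, medoids = select_k(tree, self.rmsd, r2_threshold)
        return PoseClusteringResults(
            model=self,
            tree=tree,
            r2_threshold=r2_threshold,
            k=k,
            labels=labels,
            medoid_indices=medoids,
        )


@dataclass
class PoseClusteringResults:
    """Fitted clustering: chosen cut, assignments, representatives."""

    model: PoseClustering
    tree: ClusterTree
    r2_threshold: float
    k: int
    labels: np.ndarray
    medoid_indices: list[int]

    @property
    def ensemble(self) -> PoseEnsemble:
        return self.model.ensemble

    @property
    def representative_ids(self) -> list[str]:
        return [self.ensemble.pose_ids[i] for i in self.medoid_indices]

    @property
    def r2(self) -> float:
        return cut_metrics(self.tree, self.model.rmsd, self.k)[0]

    @property
    def strain(self) -> float:
        return cut_metrics(self.tree, self.model.rmsd, self.k)[1]

    def metrics_frame(self) -> pd.DataFrame:
        rows = []
        for k in range(1, self.tree.n_leaves + 1):
            r2, strain = cut_metrics(self.tree, self.model.rmsd, k)
            rows.append({"k": k, "r2": r2, "strain": strain})
        return pd.DataFrame(rows)

    def assignment_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pose": self.ensemble.pose_ids,
                "cluster": self.labels,
            }
        )

    def linkage_frame(self) -> pd.DataFrame:
        rows = []
        for t, (ma, mb, h) in enumerate(self.tree.merges):
            rows.append(
                {
                    "merge": t,
                    "members_a": "+".join(map(str, ma)),
                    "members_b": "+".join(map(str, mb)),
                    "height": h,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        r2, strain = self.r2, self.strain
        lines = [
            "Pose clustering (average linkage on ligand+pocket RMSD)",
            f"  poses: {self.tree.n_leaves}   pocket radius: "
            f"{self.model.pocket_radius:.1f} Å   atoms in metric: "
            f"{self.model.atom_set.n_atoms}",
            f"  chosen k: {self.k}  (smallest k with R² ≥ "
            f"{self.r2_threshold:.2f})",
            f"  R²: {r2:.3f}   strain: {strain:.3f}",
            "  representatives (medoids): "
            + ", ".join(self.representative_ids),
        ]
        return "\n".join(lines)

    def write(self, out_dir) -> None:
        """Write linkage, assignment and metrics tables plus medoid PDBs."""
        from pathlib import Path

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.linkage_frame().to_csv(out_dir / "linkage.csv", index=False)
        self.assignment_frame().to_csv(
            out_dir / "assignments.csv", index=False
        )
        self.metrics_frame().to_csv(out_dir / "metrics.csv", index=False)
        for i in self.medoid_indices:
            write_pose(
                self.ensemble,
                i,
                out_dir / f"representative_{self.ensemble.pose_ids[i]}.pdb",
            )
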