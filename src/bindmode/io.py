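"""Structure and table I/O plus the shared coordinate/residue data model.

Pose ensembles are plain PDB files sharing one receptor coordinate frame:
the receptor is read once (from the first file) and each file contributes
one ligand pose, identified by its HETATM residue name.  No structural
superposition is performed — poses are assumed to come from a refinement
protocol that keeps the receptor frame fixed.

Tabular inputs (dose-response measurements, docking scores) are delimited
text with fixed column names, parsed into pandas DataFrames.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import biotite.structure as struc
import biotite.structure.io.pdb as pdb

from .errors import StructureError, TableError

__all__ = [
    "Atom",
    "Residue",
    "PoseEnsemble",
    "BW_DEFAULT",
    "read_pose_ensemble",
    "write_pose_ensemble",
    "write_pose",
    "read_dose_response",
    "read_score_table",
    "annotate_bw",
    "DOSE_RESPONSE_COLUMNS",
    "SCORE_COLUMNS",
]

#: Hydrogens covalently within this distance (Å) of N/O/S count as polar.
POLAR_H_CUTOFF = 1.2

#: Backbone atom names excluded from side-chain interaction geometry.
BACKBONE_NAMES = frozenset({"N", "CA", "C", "O", "OXT"})

#: Default Ballesteros–Weinstein annotation for the 8-residue binding-site
#: panel of the chicken bitter receptor ggTas2r1 (TM3/5/6 positions).
BW_DEFAULT = {
    86: "3.29",
    89: "3.32",
    93: "3.36",
    181: "5.38",
    185: "5.42",
    244: "6.47",
    247: "6.51",
    251: "6.55",
}

DOSE_RESPONSE_COLUMNS = ("construct", "ligand", "conc_uM", "dFF", "replicate")
SCORE_COLUMNS = ("ligand", "score")


@dataclass
class Atom:
    """A single atom: label, element, Cartesian coordinates in Å.

    ``is_polar_h`` flags hydrogens bonded to N/O/S (the only hydrogens
    relevant for H-bond directionality and for RMSD atom selection);
    ``formal_charge`` carries the integer charge used by salt-bridge and
    cation-π detection.
    """

    name: str
    element: str
    coords: np.ndarray
    is_polar_h: bool = False
    formal_charge: int = 0

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise StructureError(
                f"atom {self.name!r}: coordinates must be a finite 3-vector"
            )
        if not self.element:
            raise StructureError(f"atom {self.name!r}: empty element symbol")
        if self.is_polar_h and self.element.upper() != "H":
            raise StructureError(
                f"atom {self.name!r}: is_polar_h set on non-hydrogen"
            )

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() != "H"


@dataclass
class Residue:
    """A receptor residue identified by (chain, number)."""

    chain: str
    number: int
    name: str
    atoms: list[Atom] = field(default_factory=list)
    bw_number: str | None = None

    @property
    def key(self) -> tuple[str, int]:
        return (self.chain, self.number)

    @property
    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.is_heavy]

    @property
    def side_chain_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.name not in BACKBONE_NAMES]

    def heavy_coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.heavy_atoms], dtype=float)


@dataclass
class PoseEnsemble:
    """A shared-frame receptor plus N ligand poses.

    All poses must have the same atom count and ordering so that pose i /
    pose j coordinate comparisons are meaningful without matching.
    """

    receptor: list[Residue]
    poses: list[list[Atom]]
    pose_ids: list[str]
    frame_tag: str = "shared"
    ligand_resname: str = "LIG"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.receptor:
            raise StructureError("ensemble has an empty receptor")
        if not self.poses:
            raise StructureError("ensemble needs at least one pose")
        if len(self.pose_ids) != len(self.poses):
            raise StructureError("pose_ids and poses length mismatch")
        names0 = [a.name for a in self.poses[0]]
        for pid, pose in zip(self.pose_ids, self.poses):
            names = [a.name for a in pose]
            if names != names0:
                raise StructureError(
                    f"pose {pid!r}: ligand atom ordering differs from first pose"
                )

    @property
    def n_poses(self) -> int:
        return len(self.poses)

    def residue(self, key: tuple[str, int]) -> Residue:
        for res in self.receptor:
            if res.key == key:
                return res
        raise StructureError(f"residue {key} not in receptor")

    def pose_coords(self, i: int) -> np.ndarray:
        return np.array([a.coords for a in self.poses[i]], dtype=float)


def _flag_polar_hydrogens(atoms: list[Atom]) -> None:
    """Mark hydrogens within POLAR_H_CUTOFF of any N/O/S as polar (in place).

    Connectivity is inferred geometrically because PDB files from
    refinement pipelines frequently lack CONECT records.
    """
    hyd = [a for a in atoms if a.element.upper() == "H"]
    don = [a for a in atoms if a.element.upper() in ("N", "O", "S")]
    if not hyd or not don:
        return
    dc = np.array([d.coords for d in don])
    for h in hyd:
        dist = np.linalg.norm(dc - h.coords, axis=1)
        if np.min(dist) <= POLAR_H_CUTOFF:
            h.is_polar_h = True


def _atoms_from_array(arr) -> list[Atom]:
    out = []
    charges = (
        arr.charge if "charge" in arr.get_annotation_categories() else None
    )
    for i in range(arr.array_length()):
        elem = str(arr.element[i]).strip() or str(arr.atom_name[i]).strip()[0]
        out.append(
            Atom(
                name=str(arr.atom_name[i]).strip(),
                element=elem.capitalize(),
                coords=np.array(arr.coord[i], dtype=float),
                formal_charge=int(charges[i]) if charges is not None else 0,
            )
        )
    return out


def _read_structure(path) -> struc.AtomArray:
    pdb_file = pdb.PDBFile.read(str(path))
    # Detect alternate locations on the raw records; biotite keeps the first.
    has_altloc = any(
        len(line) > 16 and line[16] not in (" ", "A")
        for line in pdb_file.lines
        if line.startswith(("ATOM", "HETATM"))
    )
    if has_altloc:
        warnings.warn(
            f"{path}: alternate locations present; keeping the first altloc",
            stacklevel=3,
        )
    arr = pdb_file.get_structure(
        model=1, altloc="first", extra_fields=["charge"]
    )
    if np.any(arr.ins_code != ""):
        raise StructureError(
            f"{path}: insertion codes are not supported "
            "(residue key is (chain, number))"
        )
    return arr


def _split_receptor_ligand(arr, ligand_resname, path):
    lig_mask = arr.res_name == ligand_resname
    if not np.any(lig_mask):
        raise StructureError(
            f"{path}: no ligand with residue name {ligand_resname!r}"
        )
    rec = arr[~lig_mask & (arr.res_name != "HOH")]
    return rec, arr[lig_mask]


def _receptor_residues(rec_arr) -> list[Residue]:
    residues: list[Residue] = []
    starts = struc.get_residue_starts(rec_arr, add_exclusive_stop=True)
    for s, e in zip(starts[:-1], starts[1:]):
        sub = rec_arr[s:e]
        res = Residue(
            chain=str(sub.chain_id[0]),
            number=int(sub.res_id[0]),
            name=str(sub.res_name[0]),
            atoms=_atoms_from_array(sub),
        )
        _flag_polar_hydrogens(res.atoms)
        residues.append(res)
    return residues


def read_pose_ensemble(
    paths: list, ligand_resname: str, frame_tag: str = "shared"
) -> PoseEnsemble:
    """Read one PDB file per pose into a shared-frame :class:`PoseEnsemble`.

    The receptor is taken from the first file; every file must contain one
    ligand (HETATM residue ``ligand_resname``) with identical atom count
    and ordering.  Pose ids are the file stems, in input order.
    """
    if not paths:
        raise StructureError("no pose files given")
    paths = [Path(p) for p in paths]
    receptor: list[Residue] = []
    poses: list[list[Atom]] = []
    names0: list[str] | None = None
    for i, path in enumerate(paths):
        if not path.exists():
            raise StructureError(f"{path}: file not found")
        arr = _read_structure(path)
        rec_arr, lig_arr = _split_receptor_ligand(arr, ligand_resname, path)
        if i == 0:
            receptor = _receptor_residues(rec_arr)
        lig_atoms = _atoms_from_array(lig_arr)
        _flag_polar_hydrogens(lig_atoms)
        names = [a.name for a in lig_atoms]
        if names0 is None:
            names0 = names
        elif names != names0:
            raise StructureError(
                f"{path}: ligand atom count/ordering "
                f"({len(names)} atoms) differs from {paths[0]} ({len(names0)})"
            )
        poses.append(lig_atoms)
    return PoseEnsemble(
        receptor=receptor,
        poses=poses,
        pose_ids=[p.stem for p in paths],
        frame_tag=frame_tag,
        ligand_resname=ligand_resname,
    )


def _ensemble_to_array(ensemble: PoseEnsemble, pose_index: int):
    n_rec = sum(len(r.atoms) for r in ensemble.receptor)
    pose = ensemble.poses[pose_index]
    arr = struc.AtomArray(n_rec + len(pose))
    arr.add_annotation("charge", int)
    j = 0
    for res in ensemble.receptor:
        for a in res.atoms:
            arr.chain_id[j] = res.chain
            arr.res_id[j] = res.number
            arr.res_name[j] = res.name
            arr.atom_name[j] = a.name
            arr.element[j] = a.element.upper()
            arr.coord[j] = a.coords
            arr.charge[j] = a.formal_charge
            arr.hetero[j] = False
            j += 1
    for a in pose:
        arr.chain_id[j] = "L"
        arr.res_id[j] = 900
        arr.res_name[j] = ensemble.ligand_resname
        arr.atom_name[j] = a.name
        arr.element[j] = a.element.upper()
        arr.coord[j] = a.coords
        arr.charge[j] = a.formal_charge
        arr.hetero[j] = True
        j += 1
    return arr


def write_pose(ensemble: PoseEnsemble, pose_index: int, path) -> None:
    """Write receptor plus one ligand pose as a PDB file."""
    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(_ensemble_to_array(ensemble, pose_index))
    pdb_file.write(str(path))


def write_pose_ensemble(ensemble: PoseEnsemble, out_dir) -> list:
    """Write one PDB file per pose (named by pose id); returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, pid in enumerate(ensemble.pose_ids):
        path = out_dir / f"{pid}.pdb"
        write_pose(ensemble, i, path)
        paths.append(path)
    return paths


def _read_delimited(path) -> pd.DataFrame:
    # comma or tab, auto-detected
    return pd.read_csv(path, sep=None, engine="python")


def read_dose_response(path) -> pd.DataFrame:
    """Read a dose-response table (construct, ligand, conc_uM, dFF, replicate).

    Rows with non-positive concentration are dropped with a warning giving
    the count; a (construct, ligand) series must provide >= 4 distinct
    concentrations to be fittable, which is checked at fit time.
    """
    df = _read_delimited(path)
    missing = [c for c in DOSE_RESPONSE_COLUMNS if c not in df.columns]
    if missing:
        raise TableError(
            f"{path}: missing column(s) {missing}; "
            f"required header: {list(DOSE_RESPONSE_COLUMNS)}"
        )
    df = df.loc[:, list(DOSE_RESPONSE_COLUMNS)].copy()
    df["conc_uM"] = pd.to_numeric(df["conc_uM"])
    df["dFF"] = pd.to_numeric(df["dFF"])
    bad = df["conc_uM"] <= 0
    if bad.any():
        warnings.warn(
            f"{path}: dropped {int(bad.sum())} row(s) with non-positive "
            "concentration",
            stacklevel=2,
        )
        df = df.loc[~bad]
    return df.reset_index(drop=True)


def read_score_table(path) -> pd.DataFrame:
    """Read a docking-score table (ligand, score in kcal/mol, lower = better)."""
    df = _read_delimited(path)
    missing = [c for c in SCORE_COLUMNS if c not in df.columns]
    if missing:
        raise TableError(
            f"{path}: missing column(s) {missing}; "
            f"required header: {list(SCORE_COLUMNS)}"
        )
    df = df.loc[:, list(SCORE_COLUMNS)].copy()
    df["score"] = pd.to_numeric(df["score"])
    if df["ligand"].duplicated().any():
        dups = df.loc[df["ligand"].duplicated(), "ligand"].tolist()
        raise TableError(f"{path}: duplicate ligand id(s): {dups}")
    return df.reset_index(drop=True)


def annotate_bw(
    receptor: list[Residue], mapping: dict[int, str] | None = None
) -> list[Residue]:
    """Attach Ballesteros–Weinstein TM.position labels to mapped residues.

    ``mapping`` maps residue numbers to BW labels; the packaged default is
    the 8-residue binding-site panel (:data:`BW_DEFAULT`).  Exactly the
    mapped residues end up annotated; mapping a number absent from the
    receptor is an error.
    """
    if mapping is None:
        mapping = BW_DEFAULT
    import re

    numbers = {r.number for r in receptor}
    for num, label in mapping.items():
        if not re.fullmatch(r"\d+\.\d+", str(label)):
            raise StructureError(f"BW label {label!r} must match 'digit.digits'")
        if num not in numbers:
            raise StructureError(f"BW mapping targets absent residue {num}")
    for res in receptor:
        if res.number in mapping:
            res.bw_number = str(mapping[res.number])
    return receptor
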