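"""Synthetic inputs with known ground truth for every pipeline stage.

The pose generator builds a geometric toy pocket: idealized side-chain
fragments for an 8-residue panel placed on a circle facing a central
ligand site, mimicking the topology of an orthosteric pocket between
TM helices without claiming structural realism.  Ligand poses are
assembled from per-residue probe groups planted at canonical interaction
geometries (H-bond 2.9 Å, hydrophobic 3.8 Å, parallel π-stack 3.8 Å,
salt bridge 3.2 Å, cation–π 4.5 Å); probes not active in a pose-group
are parked near the pocket axis, ≥ 8 Å from every residue.  Pose-groups
are separated along the pocket axis and jittered within groups by a
rigid translation whose norm is capped just below the tightest planted
margin, so planted patterns survive detection by construction.

Dose-response tables are Hill curves plus Gaussian noise clipped at 0;
analogue sets are peripheral element substitutions of a parent molecular
graph.  All generators are deterministic under their seed and record it
in the output metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError, StructureError
from .io import Atom, PoseEnsemble, Residue
from .screen import MoleculeGraph, env_fingerprint, tanimoto

__all__ = [
    "PlantSpec",
    "ResponseSpec",
    "gen_pose_ensemble",
    "gen_dose_response",
    "gen_analogue_set",
    "QUININE_POSE7_PATTERN",
    "ALL_KINDS_PATTERN",
    "PANEL_RESIDUES",
    "quinine_panel_spec",
    "QUININE_RESIDUE_MAP",
    "QUININE_SMILES",
    "quinine_analogue_library",
    "pattern_recovered",
]

#: The 8-residue binding-site panel: number -> (3-letter name).
PANEL_RESIDUES = {
    86: "LYS",
    89: "PHE",
    93: "ASN",
    181: "PHE",
    185: "LEU",
    244: "TYR",
    247: "ASN",
    251: "LEU",
}

#: Interaction kinds each residue type can realize in the toy pocket.
_FEASIBLE = {
    "ASN": {"hbond"},
    "LYS": {"salt_bridge"},
    "LEU": {"hydrophobic"},
    "PHE": {"pi_pi", "cation_pi", "hydrophobic"},
    "TYR": {"pi_pi", "cation_pi", "hydrophobic"},
}

#: Canonical probe offset (Å) from the residue anchor, per kind.
_CANONICAL = {
    "hbond": 2.9,
    "salt_bridge": 3.2,
    "hydrophobic": 3.8,
    "pi_pi": 3.8,
    "cation_pi": 4.5,
}

#: The agonist-bound quinine binding pattern: H-bonds to the two pocket
#: asparagines, a π-stack on F181 and hydrophobic contacts to L185, Y244
#: and L251; no contact with K86 or F89.
QUININE_POSE7_PATTERN = {
    93: "hbond",
    247: "hbond",
    181: "pi_pi",
    185: "hydrophobic",
    244: "hydrophobic",
    251: "hydrophobic",
}

#: A pattern exercising all five interaction kinds at once.
ALL_KINDS_PATTERN = {
    86: "salt_bridge",
    89: "cation_pi",
    93: "hbond",
    181: "pi_pi",
    185: "hydrophobic",
    244: "hydrophobic",
    247: "hbond",
    251: "hydrophobic",
}

#: Pocket circle radius (Å); fragments face the centre.
POCKET_RADIUS = 12.0
#: Rigid-translation jitter norm cap (Å), just under the 0.6 Å H-bond margin.
JITTER_CAP = 0.55


@dataclass
class PlantSpec:
    """Ground-truth specification for a synthetic pose ensemble."""

    patterns: list          # one {residue number -> kind} dict per group
    group_sizes: list
    jitter_sd: float = 0.3
    displacement: float = 8.0
    seed: int = 0
    ligand_resname: str = "LIG"

    def __post_init__(self):
        if len(self.patterns) != len(self.group_sizes):
            raise DataError("patterns and group_sizes length mismatch")
        if self.jitter_sd < 0:
            raise DataError("jitter_sd must be >= 0")
        if self.displacement <= 0:
            raise DataError("displacement must be > 0")
        for pattern in self.patterns:
            for num, kind in pattern.items():
                if num not in PANEL_RESIDUES:
                    raise DataError(f"residue {num} not in the toy panel")
                resname = PANEL_RESIDUES[num]
                if kind not in _FEASIBLE[resname]:
                    raise DataError(
                        f"residue {num} ({resname}) cannot realize "
                        f"{kind!r} in the toy pocket"
                    )


def _frames():
    """Anchor position and local (u, v, w) frame per panel residue."""
    numbers = sorted(PANEL_RESIDUES)
    out = {}
    for i, num in enumerate(numbers):
        theta = 2.0 * np.pi * i / len(numbers)
        radial = np.array([np.cos(theta), np.sin(theta), 0.0])
        anchor = POCKET_RADIUS * radial
        u = -radial                      # inward
        v = np.array([-np.sin(theta), np.cos(theta), 0.0])
        w = np.array([0.0, 0.0, 1.0])
        out[num] = (anchor, u, v, w)
    return out


def _ring_coords(center, v, w, radius=1.39):
    return [
        center + radius * (np.cos(a) * v + np.sin(a) * w)
        for a in np.arange(6) * np.pi / 3.0
    ]


def _residue_fragment(num: int) -> Residue:
    """Idealized side-chain fragment facing the pocket centre."""
    name = PANEL_RESIDUES[num]
    anchor, u, v, w = _frames()[num]
    out_dir = -u  # away from the pocket
    atoms = []

    def A(aname, element, pos, charge=0):
        atoms.append(
            Atom(name=aname, element=element, coords=np.asarray(pos, float),
                 formal_charge=charge)
        )

    if name == "ASN":
        A("OD1", "O", anchor)
        A("CG", "C", anchor + 1.23 * out_dir)
        A("ND2", "N", anchor + 1.8 * out_dir + 1.1 * v)
        A("CB", "C", anchor + 2.7 * out_dir - 0.5 * v)
    elif name == "LYS":
        A("NZ", "N", anchor, charge=+1)
        A("CE", "C", anchor + 1.5 * out_dir)
        A("CD", "C", anchor + 2.9 * out_dir + 0.5 * v)
        A("CG", "C", anchor + 4.3 * out_dir)
        A("CB", "C", anchor + 5.6 * out_dir + 0.4 * v)
    elif name == "LEU":
        A("CD1", "C", anchor)
        A("CG", "C", anchor + 1.53 * out_dir)
        A("CD2", "C", anchor + 2.1 * out_dir + 1.2 * v)
        A("CB", "C", anchor + 2.9 * out_dir - 0.7 * v)
    elif name in ("PHE", "TYR"):
        ring_names = ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]
        coords = _ring_coords(anchor, v, w)
        for aname, pos in zip(ring_names, coords):
            A(aname, "C", pos)
        cg = coords[0]
        A("CB", "C", cg + (cg - anchor) / 1.39 * 1.0 + 1.2 * out_dir)
        if name == "TYR":
            cz = coords[3]
            A("OH", "O", cz + (cz - anchor) / 1.39 * 1.36 + 0.3 * out_dir)
    else:  # pragma: no cover - panel is fixed
        raise StructureError(f"unsupported residue type {name}")
    return Residue(chain="A", number=num, name=name, atoms=atoms)


def build_toy_pocket() -> list[Residue]:
    """The fixed 8-residue receptor fragment set shared by all poses."""
    return [_residue_fragment(num) for num in sorted(PANEL_RESIDUES)]


def _group_center(g: int, n_groups: int, displacement: float) -> np.ndarray:
    """Parking centre of pose-group g.

    Groups sit on a lateral circle around the pocket axis so that every
    pair of groups is separated by ``displacement``; the circle radius is
    capped at 5 Å (clearance to the residue shell), with axial steps
    taking over beyond the cap.
    """
    if n_groups == 1:
        return np.array([0.0, 0.0, 4.0])
    r_lat = displacement / (2.0 * np.sin(np.pi / n_groups))
    z = 4.0
    if r_lat > 5.0:
        r_lat = 5.0
        z += g * displacement
    phi = 2.0 * np.pi * g / n_groups
    return np.array([r_lat * np.cos(phi), r_lat * np.sin(phi), z])


def _probe_atoms(kind: str, num: int, active: bool, center: np.ndarray,
                 slot: int):
    """Atoms of one probe group, either planted at the residue or parked.

    Parked probes stack 2.5 Å apart above their group centre, well clear
    of every residue anchor.
    """
    anchor, u, v, w = _frames()[num]
    if active:
        base = anchor + _CANONICAL[kind] * u
    else:
        base = center + np.array([0.0, 0.0, 2.5 * slot])
        v = np.array([1.0, 0.0, 0.0])
        w = np.array([0.0, 1.0, 0.0])
    atoms = []
    if kind == "hbond":
        atoms.append(("O", "O", base, 0))
        h_dir = (anchor - base) if active else np.array([0.0, 0.0, 1.0])
        h_dir = h_dir / np.linalg.norm(h_dir)
        atoms.append(("H", "H", base + 0.97 * h_dir, 0))
    elif kind == "salt_bridge":
        atoms.append(("O", "O", base, -1))
    elif kind == "hydrophobic":
        atoms.append(("C", "C", base, 0))
    elif kind == "pi_pi":
        for pos in _ring_coords(base, v, w):
            atoms.append(("C", "C", pos, 0))
    elif kind == "cation_pi":
        atoms.append(("N", "N", base, +1))
    else:  # pragma: no cover
        raise DataError(f"unknown probe kind {kind}")
    return atoms


def _truncated_shift(rng: np.random.Generator, sd: float) -> np.ndarray:
    """Rigid-translation jitter with norm capped at JITTER_CAP."""
    if sd == 0:
        return np.zeros(3)
    delta = rng.normal(0.0, sd, size=3)
    norm = float(np.linalg.norm(delta))
    if norm > JITTER_CAP:
        delta *= JITTER_CAP / norm
    return delta


def gen_pose_ensemble(spec: PlantSpec) -> tuple[PoseEnsemble, dict]:
    """Build a planted pose ensemble and its ground-truth labels.

    Returns ``(ensemble, truth)`` where ``truth`` records the group label
    of every pose, the planted pattern per group, and the seed.
    """
    rng = np.random.default_rng(spec.seed)
    receptor = build_toy_pocket()

    # template: one probe per (residue, kind) requested in any group,
    # in deterministic order; plus a 5-atom carbon carrier chain
    probe_keys: list[tuple[int, str]] = []
    for pattern in spec.patterns:
        for num in sorted(pattern):
            key = (num, pattern[num])
            if key not in probe_keys:
                probe_keys.append(key)
    probe_keys.sort()

    poses = []
    pose_ids = []
    group_labels = []
    pose_counter = 0
    n_groups = len(spec.patterns)
    for g, (pattern, size) in enumerate(zip(spec.patterns, spec.group_sizes)):
        center = _group_center(g, n_groups, spec.displacement)
        for _ in range(size):
            shift = _truncated_shift(rng, spec.jitter_sd)
            atoms: list[Atom] = []
            counters: dict[str, int] = {}
            for slot, (num, kind) in enumerate(probe_keys):
                active = pattern.get(num) == kind
                for aname, element, pos, charge in _probe_atoms(
                    kind, num, active, center, slot
                ):
                    counters[element] = counters.get(element, 0) + 1
                    atoms.append(
                        Atom(
                            name=f"{element}{counters[element]}",
                            element=element,
                            coords=np.asarray(pos, float) + shift,
                            is_polar_h=(element == "H"),
                            formal_charge=charge,
                        )
                    )
            # carrier chain below the group centre, displaced with the group
            for m in range(5):
                counters["C"] = counters.get("C", 0) + 1
                pos = center + np.array([0.0, 0.0, -2.0 - 1.5 * m])
                atoms.append(
                    Atom(
                        name=f"C{counters['C']}",
                        element="C",
                        coords=pos + shift,
                    )
                )
            poses.append(atoms)
            pose_ids.append(f"pose_{pose_counter:03d}")
            group_labels.append(g)
            pose_counter += 1

    ensemble = PoseEnsemble(
        receptor=receptor,
        poses=poses,
        pose_ids=pose_ids,
        frame_tag="toy-pocket",
        ligand_resname=spec.ligand_resname,
        metadata={"seed": spec.seed, "generator": "gen_pose_ensemble"},
    )
    truth = {
        "seed": spec.seed,
        "group_labels": group_labels,
        "patterns": [dict(p) for p in spec.patterns],
        "group_sizes": list(spec.group_sizes),
        "jitter_sd": spec.jitter_sd,
        "displacement": spec.displacement,
    }
    return ensemble, truth


def pattern_recovered(matrix, truth: dict, pose_index: int) -> bool:
    """True when a pose's detected fingerprint matches its planted pattern.

    Matching means: the planted kind is among the detected kinds at every
    planted residue, and residues without a planted interaction show no
    interaction at all.  (A planted π-stack legitimately co-detects as a
    hydrophobic contact; co-detections at planted residues are allowed.)
    """
    group = truth["group_labels"][pose_index]
    pattern = truth["patterns"][group]
    pose_id = matrix.pose_ids[pose_index]
    for key in matrix.residue_keys:
        num = key[1]
        kinds = matrix.kinds(pose_id, key)
        if num in pattern:
            if pattern[num] not in kinds:
                return False
        else:
            if kinds:
                return False
    return True


@dataclass
class ResponseSpec:
    """Ground-truth specification for a synthetic dose-response table."""

    constructs: dict        # name -> dict(f_min, f_max, ec50, hill_n)
    concentrations: list = field(
        default_factory=lambda: [0.1, 0.3, 1.0, 3.0, 10.0, 30.0, 100.0, 300.0]
    )
    replicates: int = 3
    noise_sd: float = 0.02
    ligand: str = "quinine"
    seed: int = 0

    def __post_init__(self):
        conc = np.asarray(self.concentrations, dtype=float)
        if np.any(conc <= 0) or len(np.unique(conc)) < 4:
            raise DataError(
                "concentrations must be positive with >= 4 distinct values"
            )
        if self.noise_sd < 0:
            raise DataError("noise_sd must be >= 0")


def gen_dose_response(spec: ResponseSpec) -> tuple[pd.DataFrame, dict]:
    """Hill curves plus Gaussian noise, clipped at 0.

    Returns ``(table, truth)``; the table has the standard dose-response
    columns and the truth dict echoes the generating parameters and seed.
    """
    rng = np.random.default_rng(spec.seed)
    conc = np.asarray(spec.concentrations, dtype=float)
    rows = []
    for construct, p in spec.constructs.items():
        clean = p["f_min"] + (p["f_max"] - p["f_min"]) / (
            1.0 + (p["ec50"] / conc) ** p["hill_n"]
        )
        for rep in range(1, spec.replicates + 1):
            noisy = clean + rng.normal(0.0, spec.noise_sd, size=len(conc))
            noisy = np.clip(noisy, 0.0, None)
            for c, y in zip(conc, noisy):
                rows.append(
                    {
                        "construct": construct,
                        "ligand": spec.ligand,
                        "conc_uM": c,
                        "dFF": float(y),
                        "replicate": rep,
                    }
                )
    table = pd.DataFrame(rows)
    truth = {
        "seed": spec.seed,
        "constructs": {k: dict(v) for k, v in spec.constructs.items()},
        "noise_sd": spec.noise_sd,
        "ligand": spec.ligand,
    }
    return table, truth


#: Mutant construct id -> mutated residue number, quinine panel.
QUININE_RESIDUE_MAP = {
    "K86A": 86, "F89A": 89, "N93A": 93, "F181A": 181,
    "L185A": 185, "Y244A": 244, "N247A": 247, "L251A": 251,
}


def quinine_panel_spec(seed: int = 0, noise_sd: float = 0.02) -> ResponseSpec:
    """A quinine-like 8-mutant alanine panel with wild type.

    Planted phenotypes: the two pocket asparagines, F181 and Y244
    abolish the response when mutated; L185 and L251 retain a residual
    response at high dose; K86A responds like wild type (planted at a
    slightly higher amplitude, since 'similar' efficacy that dips below
    the wild type by noise would be an ambiguous call by the strict
    rule); F89A is enhanced.
    """
    wt = {"f_min": 0.0, "f_max": 0.8, "ec50": 3.0, "hill_n": 1.2}
    flat = {"f_min": 0.0, "f_max": 0.0, "ec50": 3.0, "hill_n": 1.0}
    residual = {"f_min": 0.0, "f_max": 0.3, "ec50": 10.0, "hill_n": 1.2}
    constructs = {
        "WT": wt,
        "K86A": {**wt, "f_max": 0.85},
        "F89A": {"f_min": 0.0, "f_max": 1.0, "ec50": 1.0, "hill_n": 1.2},
        "N93A": flat,
        "F181A": flat,
        "Y244A": flat,
        "N247A": flat,
        "L185A": residual,
        "L251A": residual,
    }
    return ResponseSpec(constructs=constructs, noise_sd=noise_sd, seed=seed)


def gen_analogue_set(
    parent: MoleculeGraph,
    n_similar: int,
    n_dissimilar: int,
    seed: int = 0,
) -> tuple[list[MoleculeGraph], dict]:
    """Analogues of controlled 2D similarity to a parent graph.

    Similar molecules are the parent with up to two terminal-atom element
    substitutions (verified Tanimoto >= 0.7 by direct computation);
    dissimilar ones are unrelated small scaffolds.  Returns
    ``(molecules, truth)`` with planted similarity labels.
    """
    rng = np.random.default_rng(seed)
    parent_fp = env_fingerprint(parent)
    substitutable = {"C": "N", "N": "C", "O": "N", "S": "O"}
    terminals = [
        i for i in range(parent.n_atoms)
        if len(parent.neighbors(i)) == 1
        and parent.elements[i] in substitutable
    ]
    mols: list[MoleculeGraph] = []
    labels: dict[str, bool] = {}
    for s in range(n_similar):
        for n_subs in (2, 1, 0):
            elements = list(parent.elements)
            if terminals and n_subs > 0:
                picks = rng.choice(
                    terminals, size=min(n_subs, len(terminals)),
                    replace=False,
                )
                for i in picks:
                    elements[int(i)] = substitutable[elements[int(i)]]
            mol = MoleculeGraph(
                name=f"similar_{s + 1}",
                elements=elements,
                charges=list(parent.charges),
                aromatic=list(parent.aromatic),
                bonds=list(parent.bonds),
            )
            if tanimoto(env_fingerprint(mol), parent_fp) >= 0.7:
                break
        mols.append(mol)
        labels[mol.name] = True
    scaffolds = [
        "c1ccccc1", "C1CCCCC1", "NC(N)=O", "CCOCC", "OCC(O)CO",
        "c1ccncc1", "CC(C)=O", "CCCCCC",
    ]
    for d in range(n_dissimilar):
        smiles = scaffolds[d % len(scaffolds)]
        mol = MoleculeGraph.from_smiles(smiles, name=f"dissimilar_{d + 1}")
        mols.append(mol)
        labels[mol.name] = False
    truth = {"seed": seed, "similar": labels, "parent": parent.name}
    return mols, truth


#: Quinine 2D structure (stereochemistry irrelevant for 2D environments).
QUININE_SMILES = "COc1ccc2nccc([C@@H](O)[C@H]3C[C@@H]4CCN3C[C@@H]4C=C)c2c1"


def quinine_analogue_library():
    """The quinine analogue worked example: parent, candidates, scores.

    Three stereo/peripheral analogues of quinine (epiquinidine,
    ethylhydrocupreine, quinidine) dock as well as or better than the
    parent; the 9-amino analogue is the negative control with a less
    favorable score.  Scores in kcal/mol (Glide SP convention,
    lower = better).
    """
    parent = MoleculeGraph.from_smiles(QUININE_SMILES, name="quinine")
    candidates = [
        MoleculeGraph.from_smiles(QUININE_SMILES, name="epiquinidine"),
        MoleculeGraph.from_smiles(
            "CCOc1ccc2nccc([C@@H](O)[C@H]3C[C@@H]4CCN3C[C@@H]4CC)c2c1",
            name="ethylhydrocupreine",
        ),
        MoleculeGraph.from_smiles(QUININE_SMILES, name="quinidine"),
        MoleculeGraph.from_smiles(
            "COc1ccc2nccc([C@@H](N)[C@H]3C[C@@H]4CCN3C[C@@H]4C=C)c2c1",
            name="methoxycinchonan-9-amine",
        ),
    ]
    scores = pd.DataFrame(
        {
            "ligand": [
                "quinine",
                "epiquinidine",
                "ethylhydrocupreine",
                "quinidine",
                "methoxycinchonan-9-amine",
            ],
            "score": [-7.238, -7.882, -7.408, -7.979, -6.326],
        }
    )
    return parent, candidates, scores
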