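"""2D-similarity analogue screening against a parent agonist.

Candidate molecules are fingerprinted with an atom-environment scheme in
the MOLPRINT-2D family: for every heavy atom an environment string is
built from its own atom type plus the sorted multisets of neighbour atom
types at bond distances 1..radius, and the molecule's fingerprint is the
set of such strings.  Atom type = element + aromaticity flag +
heavy-neighbour count (an approximation of Sybyl typing).

A candidate passes when its Tanimoto coefficient to the parent lies in
[t_low, 1.0] and its docking score (kcal/mol, lower = better) is at
least as good as the parent's within a tolerance.  Docking scores are
consumed as input; no docking is performed here.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError

__all__ = [
    "MoleculeGraph",
    "AnalogueRecord",
    "env_fingerprint",
    "tanimoto",
    "screen",
    "read_smiles",
    "read_ctab",
]


@dataclass
class MoleculeGraph:
    """A 2D molecular graph: atoms (element, charge, aromatic flag), bonds.

    Built from SMILES (via RDKit, which supplies aromaticity perception)
    or from a minimal connection-table text format.  Hydrogens are
    implicit; only heavy atoms are represented.
    """

    name: str
    elements: list = field(default_factory=list)
    charges: list = field(default_factory=list)
    aromatic: list = field(default_factory=list)
    bonds: list = field(default_factory=list)  # (i, j, order)

    def __post_init__(self):
        n = len(self.elements)
        if len(self.charges) != n or len(self.aromatic) != n:
            raise DataError(f"{self.name}: atom annotation length mismatch")
        for i, j, _ in self.bonds:
            if not (0 <= i < n and 0 <= j < n) or i == j:
                raise DataError(f"{self.name}: bond ({i},{j}) out of range")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def neighbors(self, i: int) -> list[int]:
        out = []
        for a, b, _ in self.bonds:
            if a == i:
                out.append(b)
            elif b == i:
                out.append(a)
        return out

    def is_connected(self) -> bool:
        if self.n_atoms == 0:
            return False
        seen = {0}
        queue = deque([0])
        adj = {i: [] for i in range(self.n_atoms)}
        for a, b, _ in self.bonds:
            adj[a].append(b)
            adj[b].append(a)
        while queue:
            u = queue.popleft()
            for v in adj[u]:
                if v not in seen:
                    seen.add(v)
                    queue.append(v)
        return len(seen) == self.n_atoms

    @classmethod
    def from_smiles(cls, smiles: str, name: str = "") -> "MoleculeGraph":
        from rdkit import Chem

        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise DataError(f"unparseable SMILES: {smiles!r}")
        elements = [a.GetSymbol() for a in mol.GetAtoms()]
        charges = [a.GetFormalCharge() for a in mol.GetAtoms()]
        aromatic = [a.GetIsAromatic() for a in mol.GetAtoms()]
        bonds = [
            (
                b.GetBeginAtomIdx(),
                b.GetEndAtomIdx(),
                int(round(b.GetBondTypeAsDouble())),
            )
            for b in mol.GetBonds()
        ]
        return cls(
            name=name or smiles,
            elements=elements,
            charges=charges,
            aromatic=aromatic,
            bonds=bonds,
        )

    @classmethod
    def from_ctab(cls, text: str, name: str = "mol") -> "MoleculeGraph":
        """Minimal connection table: atom lines 'element charge', then a
        blank line, then bond lines 'i j order' (0-based indices)."""
        atom_block, _, bond_block = text.strip().partition("\n\n")
        elements, charges = [], []
        for line in atom_block.splitlines():
            parts = line.split()
            if not parts:
                continue
            elements.append(parts[0])
            charges.append(int(parts[1]) if len(parts) > 1 else 0)
        bonds = []
        for line in bond_block.splitlines():
            parts = line.split()
            if not parts:
                continue
            i, j = int(parts[0]), int(parts[1])
            order = int(parts[2]) if len(parts) > 2 else 1
            bonds.append((i, j, order))
        # no aromaticity perception in the plain table format
        aromatic = [False] * len(elements)
        return cls(
            name=name,
            elements=elements,
            charges=charges,
            aromatic=aromatic,
            bonds=bonds,
        )


def _atom_type(mol: MoleculeGraph, i: int) -> str:
    degree = len(mol.neighbors(i))
    ar = "ar" if mol.aromatic[i] else ""
    return f"{mol.elements[i]}{ar}.{degree}"


def env_fingerprint(mol: MoleculeGraph, radius: int = 2) -> frozenset:
    """Atom-environment fingerprint: one string per heavy atom.

    The string encodes the central atom type and, for each bond distance
    d = 1..radius, the sorted multiset of atom types found at exactly
    that distance.  The fingerprint is the *set* of environment strings
    (duplicates collapse, so symmetric atoms contribute once).
    """
    if mol.n_atoms == 0 or not mol.is_connected():
        raise DataError(f"{mol.name}: molecule graph must be connected")
    adj = {i: mol.neighbors(i) for i in range(mol.n_atoms)}
    envs = set()
    for i in range(mol.n_atoms):
        # BFS shells out to `radius`
        dist = {i: 0}
        frontier = [i]
        shells: dict[int, list[str]] = {d: [] for d in range(1, radius + 1)}
        for d in range(1, radius + 1):
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if v not in dist:
                        dist[v] = d
                        nxt.append(v)
                        shells[d].append(_atom_type(mol, v))
            frontier = nxt
        parts = [_atom_type(mol, i)]
        for d in range(1, radius + 1):
            parts.append(f"{d}:" + ",".join(sorted(shells[d])))
        envs.add("|".join(parts))
    return frozenset(envs)


def tanimoto(a: frozenset, b: frozenset) -> float:
    """|a ∩ b| / |a ∪ b|; two empty sets give 0 with a warning."""
    a, b = frozenset(a), frozenset(b)
    union = a | b
    if not union:
        warnings.warn("Tanimoto of two empty sets defined as 0", stacklevel=2)
        return 0.0
    return len(a & b) / len(union)


@dataclass
class AnalogueRecord:
    """A candidate molecule with similarity and score bookkeeping."""

    molecule: MoleculeGraph
    env_fp: frozenset = frozenset()
    tanimoto_to_parent: float = float("nan")
    score: float | None = None
    passes_similarity: bool = False
    passes_score: bool = False

    @property
    def name(self) -> str:
        return self.molecule.name


def screen(
    parent: AnalogueRecord | MoleculeGraph,
    candidates: list,
    scores: pd.DataFrame | None = None,
    t_low: float = 0.70,
    score_tolerance: float = 0.0,
    radius: int = 2,
) -> pd.DataFrame:
    """Similarity + score selection of analogues of a parent agonist.

    A candidate passes when Tanimoto(candidate, parent) ∈ [t_low, 1.0]
    and score ≤ parent score + score_tolerance.  Output is ranked by
    score ascending (best binding first); similarity-passing candidates
    without a score are flagged and excluded from the score ranking.

    ``scores`` is a (ligand, score) table containing at least the parent.
    """
    if isinstance(parent, MoleculeGraph):
        parent = AnalogueRecord(molecule=parent)
    if not parent.env_fp:
        parent.env_fp = env_fingerprint(parent.molecule, radius)
    score_map = {}
    if scores is not None:
        score_map = dict(zip(scores["ligand"], scores["score"]))
    if parent.score is None:
        if parent.name not in score_map:
            raise DataError(
                f"parent {parent.name!r} has no docking score"
            )
        parent.score = float(score_map[parent.name])

    rows = []
    for cand in candidates:
        if isinstance(cand, MoleculeGraph):
            cand = AnalogueRecord(molecule=cand)
        if not cand.env_fp:
            cand.env_fp = env_fingerprint(cand.molecule, radius)
        cand.tanimoto_to_parent = tanimoto(cand.env_fp, parent.env_fp)
        cand.passes_similarity = t_low <= cand.tanimoto_to_parent <= 1.0
        if cand.score is None and cand.name in score_map:
            cand.score = float(score_map[cand.name])
        missing_score = cand.score is None
        if missing_score and cand.passes_similarity:
            warnings.warn(
                f"{cand.name}: passes similarity but has no docking score; "
                "excluded from score ranking",
                stacklevel=2,
            )
        cand.passes_score = (
            not missing_score
            and cand.score <= parent.score + score_tolerance
        )
        rows.append(
            {
                "ligand": cand.name,
                "tanimoto": cand.tanimoto_to_parent,
                "score": cand.score if cand.score is not None else np.nan,
                "passes_similarity": cand.passes_similarity,
                "passes_score": cand.passes_score,
                "selected": cand.passes_similarity and cand.passes_score,
                "missing_score": missing_score,
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(
            columns=[
                "ligand", "tanimoto", "score", "passes_similarity",
                "passes_score", "selected", "missing_score",
            ]
        )
    df = df.sort_values(
        ["selected", "score"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    df.attrs["parent"] = parent.name
    df.attrs["parent_score"] = parent.score
    df.attrs["t_low"] = t_low
    df.attrs["score_tolerance"] = score_tolerance
    return df


def read_smiles(path) -> list[MoleculeGraph]:
    """Read a SMILES file: one molecule per line, name after whitespace."""
    mols = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(None, 1)
        smiles = parts[0]
        name = parts[1].strip() if len(parts) > 1 else smiles
        mols.append(MoleculeGraph.from_smiles(smiles, name=name))
    return mols


def read_ctab(path, name: str | None = None) -> MoleculeGraph:
    """Read one molecule from a minimal connection-table file."""
    text = Path(path).read_text()
    return MoleculeGraph.from_ctab(text, name=name or Path(path).stem)
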