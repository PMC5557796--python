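"""Selection of poses compatible with mutagenesis-derived involvement.

Each representative pose's interaction fingerprint is compared with the
phenotype vector: a residue *agrees* when it is classified involved and
the pose interacts with it, or classified not-involved and the pose does
not.  Ambiguous residues are excluded from the denominator.  A pose is
*hard-compatible* when every non-ambiguous residue agrees; the selected
binding mode is the set of hard-compatible poses, or failing that the
top-scoring pose(s) flagged as best-available.

Enhanced phenotypes (a mutation that improves the response) are treated
like wild-type-like ones: the wild-type residue must not make a
favorable contact in a compatible pose.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import pandas as pd

from .errors import DataError
from .doseresponse import PhenotypeVector
from .interactions import FingerprintMatrix

__all__ = [
    "PoseScore",
    "CompatibilityReport",
    "score_pose",
    "select_pose",
    "matrix_report",
]

#: Interaction kinds that count as "strong" for ranking tie-breaks.
STRONG_KINDS = frozenset({"hbond", "salt_bridge"})


@dataclass
class PoseScore:
    """Agreement bookkeeping for one pose."""

    pose_id: str
    agreements: int
    disagreements: list  # (residue_key, expected, observed)
    n_scored: int        # non-ambiguous residues
    strong_agreements: int

    @property
    def score(self) -> float:
        if self.n_scored == 0:
            return 1.0
        return self.agreements / self.n_scored

    @property
    def hard_compatible(self) -> bool:
        return not self.disagreements


def score_pose(
    fingerprint_row: dict,
    phenotype: PhenotypeVector,
    pose_id: str = "",
) -> PoseScore:
    """Score one pose's fingerprint row against the phenotype vector.

    ``fingerprint_row`` maps residue keys to sets of interaction kinds
    (empty set = no interaction).  The panels must overlap exactly on the
    phenotype's residues.
    """
    row = {tuple(k): frozenset(v) for k, v in fingerprint_row.items()}
    pheno_keys = set(map(tuple, phenotype.residue_keys))
    if not pheno_keys & set(row):
        raise DataError(
            "fingerprint and phenotype residue panels are disjoint"
        )
    missing = pheno_keys - set(row)
    if missing:
        raise DataError(
            f"fingerprint row lacks phenotype residues: {sorted(missing)}"
        )
    agreements = 0
    strong = 0
    disagreements = []
    n_scored = 0
    for key in sorted(pheno_keys):
        class_ = phenotype.class_of(key)
        if class_ == "ambiguous":
            continue
        n_scored += 1
        kinds = row[key]
        interacting = bool(kinds)
        expected = "interaction" if class_ == "involved" else "no interaction"
        observed = ";".join(sorted(kinds)) if kinds else "no interaction"
        if (class_ == "involved") == interacting:
            agreements += 1
            if class_ == "involved" and kinds & STRONG_KINDS:
                strong += 1
        else:
            disagreements.append((key, expected, observed))
    return PoseScore(
        pose_id=pose_id,
        agreements=agreements,
        disagreements=disagreements,
        n_scored=n_scored,
        strong_agreements=strong,
    )


@dataclass
class CompatibilityReport:
    """Ranked pose scores with the selected binding mode(s)."""

    pose_scores: list  # PoseScore, in ranked order
    selected: list     # pose ids
    hard_compatible: bool   # True when selection is hard-compatible
    non_informative: bool = False
    ties: bool = False

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rank, ps in enumerate(self.pose_scores, start=1):
            rows.append(
                {
                    "rank": rank,
                    "pose": ps.pose_id,
                    "score": ps.score,
                    "agreements": ps.agreements,
                    "n_scored": ps.n_scored,
                    "strong_agreements": ps.strong_agreements,
                    "hard_compatible": ps.hard_compatible,
                    "selected": ps.pose_id in self.selected,
                    "disagreements": "; ".join(
                        f"{k[0]}{k[1]}: expected {exp}, observed {obs}"
                        for k, exp, obs in ps.disagreements
                    ),
                }
            )
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        payload = {
            "selected": self.selected,
            "hard_compatible": self.hard_compatible,
            "non_informative": self.non_informative,
            "ties": self.ties,
            "poses": [
                {
                    "pose": ps.pose_id,
                    "score": ps.score,
                    "agreements": ps.agreements,
                    "n_scored": ps.n_scored,
                    "strong_agreements": ps.strong_agreements,
                    "hard_compatible": ps.hard_compatible,
                    "disagreements": [
                        {
                            "residue": list(k),
                            "expected": exp,
                            "observed": obs,
                        }
                        for k, exp, obs in ps.disagreements
                    ],
                }
                for ps in self.pose_scores
            ],
        }
        return json.dumps(payload, indent=2)

    def summary(self) -> str:
        head = (
            "hard-compatible" if self.hard_compatible else "best-available"
        )
        lines = [
            f"Compatibility selection: {len(self.selected)} {head} pose(s): "
            + ", ".join(self.selected)
        ]
        if self.non_informative:
            lines.append(
                "  WARNING: all residues ambiguous — selection vacuous"
            )
        if self.ties:
            lines.append("  note: ties among top-ranked poses")
        for ps in self.pose_scores[:10]:
            lines.append(
                f"  {ps.pose_id}: score {ps.score:.3f} "
                f"({ps.agreements}/{ps.n_scored}), "
                f"hard={ps.hard_compatible}"
            )
        return "\n".join(lines)


def select_pose(
    matrix: FingerprintMatrix, phenotype: PhenotypeVector
) -> CompatibilityReport:
    """Rank all poses against the phenotype and select the binding mode.

    Ranking: score descending, then strong (H-bond/salt-bridge)
    agreements descending, then pose input order.  Selected: all
    hard-compatible poses, else the top-scoring pose(s), flagged as
    best-available.
    """
    if not matrix.pose_ids:
        raise DataError("fingerprint matrix has no poses")
    scores = []
    for idx, pid in enumerate(matrix.pose_ids):
        ps = score_pose(matrix.row(pid), phenotype, pose_id=pid)
        scores.append((ps, idx))
    non_informative = all(ps.n_scored == 0 for ps, _ in scores)
    if non_informative:
        warnings.warn(
            "phenotype vector is all-ambiguous; every pose scores 1.0",
            stacklevel=2,
        )
    ranked = sorted(
        scores, key=lambda t: (-t[0].score, -t[0].strong_agreements, t[1])
    )
    hard = [ps for ps, _ in ranked if ps.hard_compatible]
    if hard:
        selected = [ps.pose_id for ps in hard]
        hard_flag = True
    else:
        top = ranked[0][0]
        selected = [
            ps.pose_id
            for ps, _ in ranked
            if ps.score == top.score
            and ps.strong_agreements == top.strong_agreements
        ]
        hard_flag = False
    ties = len(selected) > 1
    return CompatibilityReport(
        pose_scores=[ps for ps, _ in ranked],
        selected=selected,
        hard_compatible=hard_flag,
        non_informative=non_informative,
        ties=ties,
    )


def matrix_report(
    matrix: FingerprintMatrix, phenotype: PhenotypeVector | None = None
) -> pd.DataFrame:
    """Interact/no-interact grid with a phenotype header row.

    Rows are poses (plus a leading ``phenotype`` row when a phenotype is
    given); cells hold "interact"/"-" and the header row the involvement
    class per residue.
    """
    grid = matrix.interacting_frame().replace({True: "interact", False: "-"})
    if phenotype is None or not phenotype.entries:
        if phenotype is not None:
            warnings.warn("empty phenotype: grid written without header",
                          stacklevel=2)
        return grid
    header = {}
    for key in matrix.residue_keys:
        col = f"{key[0]}{key[1]}"
        if tuple(key) in phenotype.entries:
            header[col] = phenotype.class_of(tuple(key))
        else:
            header[col] = "-"
    header_row = pd.DataFrame(
        [header], index=pd.Index(["phenotype"], name="pose")
    )
    return pd.concat([header_row, grid])
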