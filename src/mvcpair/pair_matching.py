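"""All-vs-all comparison matrix and the lowest-common-value match rule.

Every left element is registered against every mirrored-right element to give
a grid of mesh-to-mesh values.  A pair is proposed when a cell holds the
lowest value of both its row (that left's best partner) and its column (that
right's best partner) — the mutual lowest-value rule.  True negatives are
created by deleting one side of a random subset of individuals, mimicking a
commingled assemblage in which not every element has its antimere present.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ManifestError
from .icp_core import ICPParams, TriangleSurface, register
from .mesh_io import CohortManifest, Side, TriangleMesh

__all__ = [
    "ComparisonMatrix",
    "GroundTruth",
    "MatchReport",
    "build_comparison_matrix",
    "inject_true_negatives",
    "lcv_match",
    "score_matches",
]

log = logging.getLogger(__name__)


@dataclass
class ComparisonMatrix:
    """Lefts x mirrored-rights grid of mesh-to-mesh values (mm)."""

    left_ids: List[str]
    right_ids: List[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.left_ids), len(self.right_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match ID lists "
                f"({len(self.left_ids)} x {len(self.right_ids)})"
            )
        if (self.values < 0).any():
            raise ValueError("mesh-to-mesh values must be non-negative")

    def value(self, left_id: str, right_id: str) -> float:
        return float(
            self.values[self.left_ids.index(left_id), self.right_ids.index(right_id)]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.left_ids, columns=self.right_ids)

    def to_csv(self, path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, index_label="left_id")
        return path

    @classmethod
    def from_csv(cls, path) -> "ComparisonMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(list(df.index.astype(str)), list(df.columns.astype(str)), df.values)


@dataclass
class GroundTruth:
    """Known left <-> right pairings; NONE means no partner exists."""

    left_to_right: Dict[str, Optional[str]]
    right_to_left: Dict[str, Optional[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        derived: Dict[str, Optional[str]] = dict(self.right_to_left)
        for l, r in self.left_to_right.items():
            if r is not None:
                cur = derived.get(r)
                if cur is not None and cur != l:
                    raise ManifestError(f"inconsistent ground truth at {r!r}")
                derived[r] = l
        partners = [r for r in self.left_to_right.values() if r is not None]
        if len(partners) != len(set(partners)):
            raise ManifestError("ground truth is not injective")
        self.right_to_left = derived

    @classmethod
    def from_manifest(cls, manifest: CohortManifest) -> "GroundTruth":
        lefts = {}
        rights = {}
        for row in manifest:
            if row.side == Side.LEFT:
                lefts[row.element_id] = row.individual_id
            else:
                rights[row.element_id] = row.individual_id
        by_ind = {v: k for k, v in rights.items() if v is not None}
        l2r = {l: by_ind.get(ind) for l, ind in lefts.items()}
        r2l = {r: None for r in rights}
        return cls(l2r, r2l)

    def restrict(self, left_ids, right_ids) -> "GroundTruth":
        lset, rset = set(left_ids), set(right_ids)
        l2r = {
            l: (r if r in rset else None)
            for l, r in self.left_to_right.items()
            if l in lset
        }
        r2l = {
            r: (l if l in lset else None)
            for r, l in self.right_to_left.items()
            if r in rset
        }
        return GroundTruth(l2r, r2l)


@dataclass
class MatchReport:
    """Per-element lowest-common-value determinations and the summary rates.

    Each left and each right element in the matrix receives exactly one
    determination (TP/TN/FP/FN); a correct mutual match contributes one TP on
    each side.  Specificity is None when no element is truly unpaired.
    """

    determinations: Dict[str, Tuple[str, Optional[str], Optional[float]]]
    tp: int
    tn: int
    fp: int
    fn: int
    sensitivity: Optional[float]
    specificity: Optional[float]
    deletion_seed: Optional[int] = None
    deleted_ids: List[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "element_id": e,
                "determination": d,
                "partner_id": p or "",
                "value": v if v is not None else np.nan,
            }
            for e, (d, p, v) in sorted(self.determinations.items())
        ]
        return pd.DataFrame(rows)

    def summary(self) -> dict:
        return {
            "tp": self.tp,
            "tn": self.tn,
            "fp": self.fp,
            "fn": self.fn,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "deletion_seed": self.deletion_seed,
            "deleted_ids": list(self.deleted_ids),
        }


def build_comparison_matrix(
    lefts: List[TriangleMesh],
    rights: List[TriangleMesh],
    params: Optional[ICPParams] = None,
) -> ComparisonMatrix:
    """Register every left against every mirrored-right.

    A failed registration poisons only its own cell (set to +inf and logged),
    never the whole matrix.  The fixed mesh's spatial index is reused across
    its whole column.
    """
    params = params or ICPParams()
    left_ids = [m.element_id for m in lefts]
    right_ids = [m.element_id for m in rights]
    if len(set(left_ids)) != len(left_ids) or len(set(right_ids)) != len(right_ids):
        raise ValueError("element IDs must be unique within each side")
    for m in rights:
        if m.side != Side.MIRRORED_RIGHT:
            raise ValueError(
                f"right-side mesh {m.element_id!r} must be mirrored before comparison"
            )
    values = np.full((len(lefts), len(rights)), np.inf)
    for j, fixed in enumerate(rights):
        surface = TriangleSurface(fixed)
        for i, moving in enumerate(lefts):
            try:
                res = register(moving, fixed, params, surface=surface)
                values[i, j] = res.mvc_value
            except Exception as exc:  # noqa: BLE001 - per-cell containment
                log.warning(
                    "registration failed for (%s, %s): %s",
                    moving.element_id,
                    fixed.element_id,
                    exc,
                )
    return ComparisonMatrix(left_ids, right_ids, values)


def inject_true_negatives(
    matrix: ComparisonMatrix,
    truth: GroundTruth,
    fraction: float,
    seed: int = 0,
) -> Tuple[ComparisonMatrix, GroundTruth, List[str]]:
    """Delete one element (whole row or column) of a random subset of
    individuals so the survivors become true negatives.

    round(fraction * n_individuals) individuals are chosen uniformly; for
    each, a random side's element is removed from the matrix and the
    surviving element's truth becomes NONE.  Returns the reduced matrix, the
    updated truth, and the removed element IDs.
    """
    if not 0.0 <= fraction < 1.0:
        raise ConfigurationError("deletion fraction must be in [0, 1)")
    pairs = [
        (l, r)
        for l, r in truth.left_to_right.items()
        if r is not None and l in matrix.left_ids and r in matrix.right_ids
    ]
    n_remove = int(round(fraction * len(pairs)))
    if len(pairs) - n_remove < 2:
        raise ConfigurationError(
            f"deleting {n_remove} of {len(pairs)} individuals leaves fewer than 2 pairs"
        )
    if n_remove == 0:
        return matrix, truth.restrict(matrix.left_ids, matrix.right_ids), []
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(pairs), size=n_remove, replace=False)
    drop_left, drop_right = set(), set()
    for k in chosen:
        l, r = pairs[k]
        if rng.random() < 0.5:
            drop_left.add(l)
        else:
            drop_right.add(r)
    keep_l = [i for i, l in enumerate(matrix.left_ids) if l not in drop_left]
    keep_r = [j for j, r in enumerate(matrix.right_ids) if r not in drop_right]
    reduced = ComparisonMatrix(
        [matrix.left_ids[i] for i in keep_l],
        [matrix.right_ids[j] for j in keep_r],
        matrix.values[np.ix_(keep_l, keep_r)],
    )
    new_truth = truth.restrict(reduced.left_ids, reduced.right_ids)
    removed = sorted(drop_left | drop_right)
    return reduced, new_truth, removed


def lcv_match(
    matrix: ComparisonMatrix, rank_window: int = 1
) -> List[Tuple[str, str]]:
    """Propose pairs by the lowest-common-value rule.

    rank_window=1: a cell is proposed iff it is strictly the minimum of both
    its row and its column; a tied row/column minimum abstains.  rank_window=k
    generalises to a greedy sweep in ascending value order over cells ranked
    within the k smallest of both their row and column, each element used at
    most once.
    """
    if rank_window < 1:
        raise ValueError("rank_window must be >= 1")
    V = matrix.values
    n_l, n_r = V.shape
    if n_l == 0 or n_r == 0:
        return []
    proposals: List[Tuple[str, str]] = []
    if rank_window == 1:
        row_min = V.min(axis=1)
        col_min = V.min(axis=0)
        row_unique = (V == row_min[:, None]).sum(axis=1) == 1
        col_unique = (V == col_min[None, :]).sum(axis=0) == 1
        for i in range(n_l):
            if not row_unique[i]:
                continue
            j = int(np.argmin(V[i]))
            if not col_unique[j]:
                continue
            if V[i, j] == col_min[j] and np.argmin(V[:, j]) == i:
                proposals.append((matrix.left_ids[i], matrix.right_ids[j]))
        return proposals
    row_rank_ok = np.argsort(np.argsort(V, axis=1, kind="stable"), axis=1) < rank_window
    col_rank_ok = np.argsort(np.argsort(V, axis=0, kind="stable"), axis=0) < rank_window
    order = np.argsort(V, axis=None, kind="stable")
    used_l = np.zeros(n_l, dtype=bool)
    used_r = np.zeros(n_r, dtype=bool)
    for flat in order:
        i, j = divmod(int(flat), n_r)
        if used_l[i] or used_r[j]:
            continue
        if row_rank_ok[i, j] and col_rank_ok[i, j]:
            proposals.append((matrix.left_ids[i], matrix.right_ids[j]))
            used_l[i] = True
            used_r[j] = True
    return proposals


def score_matches(
    proposals: List[Tuple[str, str]],
    truth: GroundTruth,
    matrix: ComparisonMatrix,
    deletion_seed: Optional[int] = None,
    deleted_ids: Optional[List[str]] = None,
) -> MatchReport:
    """Give every element in the matrix a TP/TN/FP/FN determination and the
    resulting sensitivity and specificity."""
    lset, rset = set(matrix.left_ids), set(matrix.right_ids)
    prop_l = {}
    prop_r = {}
    for l, r in proposals:
        if l not in lset or r not in rset:
            raise ValueError(f"proposal ({l!r}, {r!r}) references unknown element")
        if l in prop_l or r in prop_r:
            raise ValueError("an element appears in two proposals")
        prop_l[l] = r
        prop_r[r] = l
    det: Dict[str, Tuple[str, Optional[str], Optional[float]]] = {}

    def classify(elem: str, partner: Optional[str], true_partner: Optional[str], is_left: bool):
        if partner is not None:
            value = matrix.value(elem, partner) if is_left else matrix.value(partner, elem)
            kind = "TP" if partner == true_partner else "FP"
            det[elem] = (kind, partner, value)
        elif true_partner is not None:
            det[elem] = ("FN", None, None)
        else:
            det[elem] = ("TN", None, None)

    for l in matrix.left_ids:
        tp_r = truth.left_to_right.get(l)
        classify(l, prop_l.get(l), tp_r if tp_r in rset else None, True)
    for r in matrix.right_ids:
        tp_l = truth.right_to_left.get(r)
        classify(r, prop_r.get(r), tp_l if tp_l in lset else None, False)

    counts = {"TP": 0, "TN": 0, "FP": 0, "FN": 0}
    for kind, _, _ in det.values():
        counts[kind] += 1
    tp, tn, fp, fn = counts["TP"], counts["TN"], counts["FP"], counts["FN"]
    sens = tp / (tp + fn) if tp + fn > 0 else None
    spec = tn / (tn + fp) if tn + fp > 0 else None
    return MatchReport(
        determinations=det,
        tp=tp,
        tn=tn,
        fp=fp,
        fn=fn,
        sensitivity=sens,
        specificity=spec,
        deletion_seed=deletion_seed,
        deleted_ids=deleted_ids or [],
    )
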