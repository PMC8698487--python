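"""ROC decision analysis over mesh-to-mesh values.

Orientation: a *smaller* value means a more likely pair, so the classifier
predicts "true pair" when value <= threshold.  AUC is computed by the
trapezoidal rule (equivalently the Mann-Whitney concordance with ties counted
half), its standard error by the Hanley-McNeil formula (DeLong optional), and
the reported operating point maximises the Youden index J = sensitivity +
specificity - 1.  A fixed-sensitivity threshold supports triage use: pick the
cut-off keeping every true pair, then count how many non-pairs it excludes
before any confirmatory (e.g. DNA) testing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import stats as _stats

from .errors import StatisticsError
from .pair_matching import ComparisonMatrix, GroundTruth

__all__ = [
    "LabeledValues",
    "ROCResult",
    "roc_curve",
    "threshold_at_sensitivity",
    "auc_bootstrap",
]


@dataclass
class LabeledValues:
    """Mesh-to-mesh values with true-pair / non-pair labels."""

    values: np.ndarray
    labels: np.ndarray  # True = true pair

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64).ravel()
        self.labels = np.asarray(self.labels, dtype=bool).ravel()
        if len(self.values) != len(self.labels):
            raise ValueError("values and labels must have equal length")

    @classmethod
    def from_matrix(cls, matrix: ComparisonMatrix, truth: GroundTruth) -> "LabeledValues":
        """One observation per finite matrix cell; label true iff the cell is
        a known pair."""
        vals, labs = [], []
        for i, l in enumerate(matrix.left_ids):
            partner = truth.left_to_right.get(l)
            for j, r in enumerate(matrix.right_ids):
                v = matrix.values[i, j]
                if not np.isfinite(v):
                    continue
                vals.append(v)
                labs.append(partner == r)
        return cls(np.asarray(vals), np.asarray(labs))

    @property
    def n_pairs(self) -> int:
        return int(self.labels.sum())

    @property
    def n_non_pairs(self) -> int:
        return int((~self.labels).sum())


@dataclass
class ROCResult:
    thresholds: np.ndarray
    sensitivities: np.ndarray
    specificities: np.ndarray
    auc: float
    auc_se: float
    p_value: float
    criterion: float
    criterion_sensitivity: float
    criterion_specificity: float

    def summary(self) -> dict:
        return {
            "auc": self.auc,
            "auc_se": self.auc_se,
            "p_value": self.p_value,
            "criterion_mm": self.criterion,
            "criterion_sensitivity": self.criterion_sensitivity,
            "criterion_specificity": self.criterion_specificity,
        }


def _hanley_mcneil_se(auc: float, n1: int, n2: int) -> float:
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (
        auc * (1.0 - auc)
        + (n1 - 1) * (q1 - auc**2)
        + (n2 - 1) * (q2 - auc**2)
    ) / (n1 * n2)
    return float(np.sqrt(max(var, 0.0)))


def _delong_se(values: np.ndarray, labels: np.ndarray) -> float:
    """DeLong variance via placement values (smaller value = positive)."""
    pos = values[labels]
    neg = values[~labels]
    n1, n2 = len(pos), len(neg)
    # placement of each positive among negatives: P(neg > pos) + 0.5 P(tie)
    v10 = np.array([np.mean((neg > x) + 0.5 * (neg == x)) for x in pos])
    v01 = np.array([np.mean((pos < y) + 0.5 * (pos == y)) for y in neg])
    var = np.var(v10, ddof=1) / n1 + np.var(v01, ddof=1) / n2 if n1 > 1 and n2 > 1 else 0.0
    return float(np.sqrt(max(var, 0.0)))


def mann_whitney_auc(values: np.ndarray, labels: np.ndarray) -> float:
    """Concordance AUC: fraction of (pair, non-pair) value pairs with the
    pair's value smaller, ties counted half."""
    pos = values[labels]
    neg = values[~labels]
    less = (pos[:, None] < neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return float((less + 0.5 * ties) / (len(pos) * len(neg)))


def roc_curve(data: LabeledValues, se_method: str = "hanley") -> ROCResult:
    """Build the full ROC curve and its summary statistics.

    Thresholds are all distinct observed values plus a sentinel below the
    minimum; sensitivity at threshold t is the fraction of true pairs with
    value <= t, specificity the fraction of non-pairs with value > t.
    """
    n1, n2 = data.n_pairs, data.n_non_pairs
    if n1 == 0 or n2 == 0:
        raise StatisticsError("ROC needs at least one true pair and one non-pair")
    uniq = np.unique(data.values)
    thresholds = np.concatenate([[uniq[0] - 1.0], uniq])
    pos = np.sort(data.values[data.labels])
    neg = np.sort(data.values[~data.labels])
    sens = np.searchsorted(pos, thresholds, side="right") / n1
    fpr = np.searchsorted(neg, thresholds, side="right") / n2
    spec = 1.0 - fpr
    auc = float(np.trapezoid(sens, fpr))
    if se_method == "hanley":
        se = _hanley_mcneil_se(auc, n1, n2)
    elif se_method == "delong":
        se = _delong_se(data.values, data.labels)
    else:
        raise ValueError(f"unknown se_method {se_method!r}")
    if se > 0:
        z = (auc - 0.5) / se
        p = float(2.0 * _stats.norm.sf(abs(z)))
    else:
        p = 0.0 if auc != 0.5 else 1.0
    youden = sens + spec - 1.0
    k = int(np.argmax(youden))
    return ROCResult(
        thresholds=thresholds,
        sensitivities=sens,
        specificities=spec,
        auc=auc,
        auc_se=se,
        p_value=p,
        criterion=float(thresholds[k]),
        criterion_sensitivity=float(sens[k]),
        criterion_specificity=float(spec[k]),
    )


def threshold_at_sensitivity(
    result: ROCResult, target_sensitivity: float
) -> Tuple[float, float]:
    """Smallest threshold whose sensitivity reaches the target, with the
    specificity attained there.  target 1.0 captures every true pair."""
    if target_sensitivity > 1.0:
        raise ValueError("target sensitivity cannot exceed 1")
    ok = np.nonzero(result.sensitivities >= target_sensitivity)[0]
    k = int(ok[0])
    return float(result.thresholds[k]), float(result.specificities[k])


def auc_bootstrap(
    data: LabeledValues,
    n_boot: int = 1000,
    seed: int = 0,
    ci: float = 0.95,
) -> Tuple[float, float]:
    """Percentile bootstrap CI for AUC, resampling within each label class
    (stratified, so every resample keeps both classes)."""
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    pos = data.values[data.labels]
    neg = data.values[~data.labels]
    if len(pos) == 0 or len(neg) == 0:
        raise StatisticsError("bootstrap needs both classes")
    rng = np.random.default_rng(seed)
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        ps = rng.choice(pos, size=len(pos), replace=True)
        ns = rng.choice(neg, size=len(neg), replace=True)
        less = np.searchsorted(np.sort(ns), ps, side="left").sum()
        right = np.searchsorted(np.sort(ns), ps, side="right").sum()
        aucs[b] = 1.0 - (less + 0.5 * (right - less)) / (len(ps) * len(ns))
    alpha = (1.0 - ci) / 2.0
    lo, hi = np.quantile(aucs, [alpha, 1.0 - alpha])
    return float(lo), float(hi)
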