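"""ROC cut-point analysis of FAST totals against a binary TFC reference.

The score is validated against thoracic fluid content (TFC), an
impedance-cardiography measure used as the comparative reference: an
encounter is labelled positive when its TFC is high.  For each integer
cut ``c`` the rule "FAST >= c predicts fluid overload" has a sensitivity,
specificity and overall accuracy; the cut-point table is the machine twin
of the study's published table, with exact binomial (Clopper-Pearson)
95% intervals attached.

Also here: empirical (pair-counting) AUC, the AUC of a dichotomized
score, seeded stratified k-fold cross-validated AUC, and reconstruction
of a score x label dataset from per-class survivor proportions —
sensitivity is the positive-class survivor function of the score and
1 - specificity the negative-class one, so differencing them recovers
the per-score counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold
from statsmodels.stats.proportion import proportion_confint

logger = logging.getLogger(__name__)

__all__ = [
    "DegenerateInputError",
    "ReconstructionError",
    "LabeledScore",
    "CutpointRow",
    "ROCTable",
    "CVResult",
    "cutpoint_table",
    "select_cutpoint",
    "empirical_auc",
    "dichotomized_auc",
    "cv_auc",
    "reconstruct_fixture",
    "label_from_tfc",
]


class DegenerateInputError(ValueError):
    """Only one class present — ROC quantities are undefined."""


class ReconstructionError(ValueError):
    """Survivor proportions do not yield a consistent integer dataset."""


@dataclass(frozen=True)
class LabeledScore:
    """A (FAST total, binary high-TFC label) pair — the unit of ROC analysis."""

    encounter_id: str
    score: int
    tfc_high: bool

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError(f"score must be non-negative, got {self.score}")


@dataclass(frozen=True)
class CutpointRow:
    """Operating characteristics of the rule score >= cut."""

    cut: int
    sensitivity: float
    specificity: float
    correctly_classified: float
    sens_ci: tuple
    spec_ci: tuple


@dataclass
class ROCTable:
    """Ordered cut-point rows plus class sizes and the empirical AUC."""

    rows: list
    n_pos: int
    n_neg: int
    auc: float

    def row(self, cut: int) -> CutpointRow:
        for r in self.rows:
            if r.cut == cut:
                return r
        raise KeyError(f"cut {cut} not in table (cuts {self.rows[0].cut}..{self.rows[-1].cut})")

    def to_dataframe(self, percent: bool = False) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "cut": [r.cut for r in self.rows],
                "sensitivity": [r.sensitivity for r in self.rows],
                "specificity": [r.specificity for r in self.rows],
                "correctly_classified": [r.correctly_classified for r in self.rows],
            }
        )
        if percent:
            for col in ("sensitivity", "specificity", "correctly_classified"):
                df[col] = (df[col] * 100).map(lambda v: f"{v:.2f}%")
        return df

    def polygon(self) -> pd.DataFrame:
        """ROC polygon vertices (FPR, TPR) traced by the cut-point rows."""
        fpr = [1 - r.specificity for r in self.rows]
        tpr = [r.sensitivity for r in self.rows]
        return pd.DataFrame({"fpr": fpr, "tpr": tpr})


@dataclass
class CVResult:
    """Cross-validated AUC: per-fold values, mean, and a percentile interval."""

    cut: Union[int, str]
    fold_aucs: list
    mean_auc: float
    ci95: tuple
    n_folds: int
    n_repeats: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "cut": self.cut,
            "mean_auc": self.mean_auc,
            "ci95": list(self.ci95),
            "n_folds": self.n_folds,
            "n_repeats": self.n_repeats,
            "seed": self.seed,
            "fold_aucs": list(self.fold_aucs),
        }


def _split(data: Sequence[LabeledScore]):
    scores = np.array([d.score for d in data])
    labels = np.array([d.tfc_high for d in data], dtype=bool)
    return scores, labels


def _check_two_classes(labels: np.ndarray) -> None:
    n_pos = int(labels.sum())
    if n_pos == 0 or n_pos == len(labels):
        raise DegenerateInputError(
            f"need both classes: {n_pos} positive of {len(labels)} encounters"
        )


def cutpoint_table(
    data: Sequence[LabeledScore], cuts: Optional[Sequence[int]] = None
) -> ROCTable:
    """Sensitivity/specificity/accuracy of ``score >= c`` for each cut ``c``.

    ``cuts`` defaults to 0..max(score)+1 so the table spans the full ROC
    polygon from (1,1) down to (0,0).  Clopper-Pearson 95% intervals are
    attached to sensitivity and specificity.
    """
    scores, labels = _split(data)
    _check_two_classes(labels)
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if cuts is None:
        cuts = range(0, int(scores.max()) + 2)
    rows = []
    for c in cuts:
        tp = int(((scores >= c) & labels).sum())
        tn = int(((scores < c) & ~labels).sum())
        sens = tp / n_pos
        spec = tn / n_neg
        acc = (tp + tn) / (n_pos + n_neg)
        rows.append(
            CutpointRow(
                cut=int(c),
                sensitivity=sens,
                specificity=spec,
                correctly_classified=acc,
                sens_ci=tuple(proportion_confint(tp, n_pos, alpha=0.05, method="beta")),
                spec_ci=tuple(proportion_confint(tn, n_neg, alpha=0.05, method="beta")),
            )
        )
    return ROCTable(rows=rows, n_pos=n_pos, n_neg=n_neg, auc=empirical_auc(data))


def select_cutpoint(table: ROCTable, policy: str = "balanced") -> CutpointRow:
    """Pick the operating cut from a table under a named policy.

    ``balanced`` minimizes |sensitivity - specificity| (ties broken toward
    higher accuracy, then the lower cut); ``max_accuracy`` maximizes the
    correctly-classified proportion; ``youden`` maximizes
    sensitivity + specificity - 1.
    """
    if not table.rows:
        raise ValueError("empty cut-point table")
    if policy == "balanced":
        key = lambda r: (abs(r.sensitivity - r.specificity), -r.correctly_classified, r.cut)
    elif policy == "max_accuracy":
        key = lambda r: (-r.correctly_classified, r.cut)
    elif policy == "youden":
        key = lambda r: (-(r.sensitivity + r.specificity - 1), r.cut)
    else:
        raise ValueError(f"unknown policy {policy!r}")
    return min(table.rows, key=key)


def empirical_auc(data: Sequence[LabeledScore]) -> float:
    """Pair-counting AUC: P(score_pos > score_neg) + 0.5 P(tie).

    Computed through the midrank identity (equivalent to averaging over
    all pos x neg pairs with half credit for ties).
    """
    scores, labels = _split(data)
    _check_two_classes(labels)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    ranks = rankdata(scores)
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def dichotomized_auc(table: ROCTable, cut: int) -> float:
    """AUC of the binary predictor 1{score >= cut}: (sens + spec) / 2."""
    row = table.row(cut)
    return (row.sensitivity + row.specificity) / 2


def _fold_auc(scores: np.ndarray, labels: np.ndarray, cut) -> Optional[float]:
    """AUC on one held-out fold; None when the fold has a single class."""
    n_pos = int(labels.sum())
    if n_pos == 0 or n_pos == len(labels):
        return None
    if cut is None or cut == "continuous":
        n_neg = len(labels) - n_pos
        ranks = rankdata(scores)
        u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2
        return float(u / (n_pos * n_neg))
    sens = float((scores[labels] >= cut).mean())
    spec = float((scores[~labels] < cut).mean())
    return (sens + spec) / 2


def cv_auc(
    data: Sequence[LabeledScore],
    n_folds: int = 10,
    cut: Union[int, str, None] = None,
    seed: int = 0,
    n_repeats: int = 1,
) -> CVResult:
    """Stratified k-fold cross-validated AUC, fully reproducible from the seed.

    Fold assignment is stratified by the TFC label (class proportions
    preserved, remainders distributed deterministically from the seed).
    The score is fixed — nothing is refit per fold — so each fold simply
    evaluates the held-out encounters: dichotomized at ``cut`` when given
    (fold AUC = (sens + spec)/2), rank-based otherwise.  Folds that end
    up single-class are excluded from the mean with a logged warning.
    The 95% interval is the percentile interval across folds x repeats.
    """
    scores, labels = _split(data)
    _check_two_classes(labels)
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if min(int(labels.sum()), int((~labels).sum())) < n_folds:
        raise ValueError("each class must have at least n_folds members")
    fold_seeds = np.random.SeedSequence(seed).generate_state(n_repeats) % (2**31)
    fold_aucs = []
    n_degenerate = 0
    for r in range(n_repeats):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=int(fold_seeds[r]))
        for _, test_idx in skf.split(scores, labels):
            a = _fold_auc(scores[test_idx], labels[test_idx], cut)
            if a is None:
                n_degenerate += 1
            else:
                fold_aucs.append(a)
    if n_degenerate:
        logger.warning("%d single-class folds excluded from the CV mean", n_degenerate)
    if not fold_aucs:
        raise DegenerateInputError("every fold was single-class; CV AUC undefined")
    arr = np.array(fold_aucs)
    ci = tuple(np.percentile(arr, [2.5, 97.5]))
    return CVResult(
        cut="continuous" if cut in (None, "continuous") else int(cut),
        fold_aucs=[float(a) for a in fold_aucs],
        mean_auc=float(arr.mean()),
        ci95=(float(ci[0]), float(ci[1])),
        n_folds=n_folds,
        n_repeats=n_repeats,
        seed=seed,
    )


def reconstruct_fixture(
    survivor_pos: Sequence[float],
    survivor_neg: Sequence[float],
    n_pos: int,
    n_neg: int,
    id_prefix: str = "E",
) -> list[LabeledScore]:
    """Rebuild a score x label dataset from per-class survivor proportions.

    ``survivor_pos[c]`` is P(score >= c) among positives (the sensitivity
    column); ``survivor_neg[c]`` is P(score >= c) among negatives
    (1 - specificity).  Adjacent values are differenced, scaled by the
    class size and rounded to integer counts; scores at or above the last
    cut are lumped at that cut's value.  The result is validated: counts
    non-negative and each class summing exactly to its size.
    """
    counts = {}
    for name, surv, n in (("positive", survivor_pos, n_pos), ("negative", survivor_neg, n_neg)):
        surv = np.asarray(surv, dtype=float)
        if np.any(np.diff(surv) > 1e-9):
            raise ReconstructionError(f"{name}-class survivor proportions must be non-increasing")
        if abs(surv[0] - 1.0) > 1e-9:
            raise ReconstructionError(f"{name}-class survivor function must start at 1 (cut 0)")
        c = [round(n * (surv[k] - surv[k + 1])) for k in range(len(surv) - 1)]
        c.append(round(n * surv[-1]))
        if min(c) < 0:
            raise ReconstructionError(f"{name}-class counts went negative after rounding")
        if sum(c) != n:
            raise ReconstructionError(
                f"{name}-class counts sum to {sum(c)}, expected {n}; "
                "survivor proportions inconsistent with the class size"
            )
        counts[name] = c
    data = []
    i = 0
    for label, cls in ((True, "positive"), (False, "negative")):
        for score, k in enumerate(counts[cls]):
            for _ in range(k):
                i += 1
                data.append(LabeledScore(f"{id_prefix}{i:03d}", score, label))
    return data


def label_from_tfc(tfc_values: Sequence[float], threshold: float) -> np.ndarray:
    """Binary high-TFC labels from raw TFC values at a configurable threshold."""
    return np.asarray(tfc_values, dtype=float) >= threshold
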