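"""Evaluation metrics for lifestyle classification.

Temperate is the positive class throughout: TP is a temperate phage called
temperate, TN a virulent phage called virulent. Sensitivity = TP/(TP+FN)
and specificity = TN/(TN+FP) are therefore the recall of temperate and of
virulent classifications respectively; accuracy = (TP+TN)/(TP+FN+TN+FP).
The ROC curve thresholds the temperate probability over all unique score
values (equal scores grouped) and AUCROC is its trapezoidal area, which
equals the Mann-Whitney U statistic divided by n+ * n-.

The ROC-comparison significance test is deliberately not implemented (no
canonical choice); a clearly labeled seeded bootstrap CI for an AUC
difference is provided as an optional substitute.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "ConfusionCounts",
    "confusion",
    "metrics",
    "RocResult",
    "roc_auc",
    "bootstrap_auc_difference",
    "write_metrics_json",
    "write_roc_csv",
]

_VALID = ("temperate", "virulent")
UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FN/TN/FP with temperate as the positive class.

    ``n_unclassified`` counts records excluded from the table because no
    call could be made (e.g. geneless contigs).
    """

    tp: int
    fn: int
    tn: int
    fp: int
    n_unclassified: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp, self.n_unclassified) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp


def confusion(labels: Sequence[str], calls: Sequence[str]) -> ConfusionCounts:
    """Confusion counts from aligned label/call vectors.

    Calls of ``"unclassified"`` are excluded from the table and counted
    separately. Labels outside {temperate, virulent} raise ValueError.
    """
    if len(labels) != len(calls):
        raise ValueError("labels and calls must have equal length")
    tp = fn = tn = fp = unc = 0
    for label, call in zip(labels, calls):
        if label not in _VALID:
            raise ValueError(f"invalid label {label!r}")
        if call == UNCLASSIFIED:
            unc += 1
        elif call not in _VALID:
            raise ValueError(f"invalid call {call!r}")
        elif label == "temperate":
            tp, fn = (tp + 1, fn) if call == "temperate" else (tp, fn + 1)
        else:
            tn, fp = (tn + 1, fp) if call == "virulent" else (tn, fp + 1)
    return ConfusionCounts(tp, fn, tn, fp, unc)


def _ratio(num: int, den: int) -> float:
    return num / den if den else float("nan")


def metrics(c: ConfusionCounts) -> dict[str, float]:
    """Sensitivity, specificity and accuracy; NaN on empty denominators."""
    return {
        "sensitivity": _ratio(c.tp, c.tp + c.fn),
        "specificity": _ratio(c.tn, c.tn + c.fp),
        "accuracy": _ratio(c.tp + c.tn, c.total),
    }


class RocResult(NamedTuple):
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> RocResult:
    """ROC curve and trapezoidal AUCROC for temperate-probability scores.

    ``labels`` are 1 for the positive (temperate) class, 0 otherwise.
    Requires finite scores and both classes present.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to compute a ROC curve")
    fpr, tpr, thresholds = _sk_roc_curve(y, scores)
    auc = float(np.trapezoid(tpr, fpr))
    return RocResult(fpr, tpr, thresholds, auc)


def bootstrap_auc_difference(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    labels: Sequence[int],
    n_boot: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict[str, float]:
    """Seeded bootstrap CI for AUC(a) - AUC(b) on paired scores.

    This is an explicitly labeled substitute for a formal ROC-comparison
    test, not an implementation of any particular published test.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    y = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(seed)
    diffs = np.empty(n_boot)
    n = len(y)
    for i in range(n_boot):
        idx = rng.integers(0, n, size=n)
        while len(np.unique(y[idx])) < 2:
            idx = rng.integers(0, n, size=n)
        diffs[i] = (roc_auc(scores_a[idx], y[idx]).auc
                    - roc_auc(scores_b[idx], y[idx]).auc)
    point = roc_auc(scores_a, y).auc - roc_auc(scores_b, y).auc
    lo, hi = np.quantile(diffs, [alpha / 2, 1 - alpha / 2])
    return {"auc_difference": point, "ci_low": float(lo), "ci_high": float(hi),
            "method": "seeded bootstrap (substitute, not a formal ROC test)"}


def write_metrics_json(path: str | Path, c: ConfusionCounts,
                       extra: dict | None = None) -> None:
    payload = {"counts": {"tp": c.tp, "fn": c.fn, "tn": c.tn, "fp": c.fp,
                          "unclassified": c.n_unclassified},
               **metrics(c), **(extra or {})}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, allow_nan=True)
        fh.write("\n")


def write_roc_csv(path: str | Path, roc: RocResult) -> None:
    with open(path, "w") as fh:
        fh.write("fpr,tpr,threshold\n")
        for f, t, th in zip(roc.fpr, roc.tpr, roc.thresholds):
            fh.write(f"{f},{t},{th}\n")
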