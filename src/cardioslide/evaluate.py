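"""Patch-to-patient aggregation and evaluation metrics.

A patient's label is the majority vote of their patches' thresholded
scores (exact ties fall back to the patient's mean score).  Metrics
cover accuracy, the confusion matrix, the ROC curve with trapezoidal
AUC (equal, by construction, to the pair-counting probability that a
positive outscores a negative, with half credit for ties), and the
precision-recall curve with step-wise (right-continuous) interpolation
of the area.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import pandas as pd
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import precision_recall_curve, roc_curve

DEFAULT_THRESHOLD = 0.5


class MetricUndefinedError(ValueError):
    """Metric requires both classes (or at least one positive)."""


@dataclass(frozen=True)
class PatientPrediction:
    patient_id: str
    n_patches: int
    n_positive_votes: int
    positive_fraction: float
    mean_score: float
    predicted_label: int
    true_label: int
    tie_broken: bool


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total


@dataclass(frozen=True)
class CurvePoints:
    """Ordered operating points plus the scalar area under the curve."""

    x: np.ndarray
    y: np.ndarray
    area: float


def vote_patient(
    scores: pd.DataFrame, decision_threshold: float = DEFAULT_THRESHOLD
) -> PatientPrediction:
    """Majority vote over one patient's patch scores.

    Each patch votes positive iff its score exceeds the threshold.  An
    exact tie (possible with an even patch count) is broken by whether
    the patient's mean score exceeds the threshold, and flagged.
    """
    if len(scores) == 0:
        raise ValueError("patient has no patches to vote with")
    pids = scores["patient_id"].unique()
    if len(pids) != 1:
        raise ValueError(f"expected one patient, got {list(pids)}")
    s = scores["score"].to_numpy(dtype=float)
    votes = int((s > decision_threshold).sum())
    n = len(s)
    # sum in sorted order so the vote is exactly permutation-invariant
    mean_score = float(np.sort(s).mean())
    tie = (2 * votes) == n
    if tie:
        label = int(mean_score > decision_threshold)
    else:
        label = int(votes > n - votes)
    return PatientPrediction(
        patient_id=str(pids[0]),
        n_patches=n,
        n_positive_votes=votes,
        positive_fraction=votes / n,
        mean_score=mean_score,
        predicted_label=label,
        true_label=int(scores["true_label"].iloc[0]),
        tie_broken=bool(tie),
    )


def aggregate_patients(
    scores: pd.DataFrame, decision_threshold: float = DEFAULT_THRESHOLD
) -> pd.DataFrame:
    """One :func:`vote_patient` row per patient, sorted by patient id."""
    preds = [
        vote_patient(g, decision_threshold)
        for _, g in scores.groupby("patient_id", sort=True)
    ]
    return pd.DataFrame([p.__dict__ for p in preds])


def accuracy_rate(correct: int, total: int) -> float:
    """Percentage of correct predictions, to one decimal (e.g. 13/14 -> 92.9)."""
    if total < 1:
        raise ValueError("total must be >= 1")
    if not 0 <= correct <= total:
        raise ValueError("need 0 <= correct <= total")
    return round(100.0 * correct / total, 1)


def confusion(
    scores: pd.DataFrame, threshold: float = DEFAULT_THRESHOLD
) -> ConfusionMatrix:
    """Tally score-vs-label outcomes at a decision threshold."""
    y = scores["true_label"].to_numpy(dtype=int)
    pred = (scores["score"].to_numpy(dtype=float) > threshold).astype(int)
    return ConfusionMatrix(
        tp=int(((pred == 1) & (y == 1)).sum()),
        fp=int(((pred == 1) & (y == 0)).sum()),
        tn=int(((pred == 0) & (y == 0)).sum()),
        fn=int(((pred == 0) & (y == 1)).sum()),
    )


def roc_auc(scores: pd.DataFrame) -> CurvePoints:
    """ROC curve over the distinct-score threshold sweep, AUC by the
    trapezoidal rule (ties grouped, giving the half-credit identity)."""
    y = scores["true_label"].to_numpy(dtype=int)
    s = scores["score"].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise MetricUndefinedError("ROC needs both classes present")
    fpr, tpr, _ = roc_curve(y, s, drop_intermediate=False)
    return CurvePoints(x=fpr, y=tpr, area=float(_sk_auc(fpr, tpr)))


def pr_aupr(scores: pd.DataFrame) -> CurvePoints:
    """Precision-recall curve; area by step-wise interpolation
    (sum over recall increments of the precision at that threshold)."""
    y = scores["true_label"].to_numpy(dtype=int)
    s = scores["score"].to_numpy(dtype=float)
    if (y == 1).sum() == 0:
        raise MetricUndefinedError("PR curve needs at least one positive")
    precision, recall, _ = precision_recall_curve(y, s)
    # points arrive with recall decreasing; area = sum dR * P (step rule)
    area = float(-np.sum(np.diff(recall) * precision[:-1]))
    return CurvePoints(x=recall[::-1], y=precision[::-1], area=area)


def evaluation_report(
    scores: pd.DataFrame,
    threshold: float = DEFAULT_THRESHOLD,
    per_patient: bool = True,
) -> dict:
    """Full metric bundle for a ScoreTable, JSON-serialisable."""
    cm = confusion(scores, threshold)
    roc = roc_auc(scores)
    pr = pr_aupr(scores)
    report: dict = {
        "n_items": int(len(scores)),
        "threshold": threshold,
        "accuracy": cm.accuracy,
        "confusion": {"tp": cm.tp, "fp": cm.fp, "tn": cm.tn, "fn": cm.fn},
        "auc": roc.area,
        "aupr": pr.area,
    }
    if per_patient:
        pats = aggregate_patients(scores, threshold)
        correct = int((pats["predicted_label"] == pats["true_label"]).sum())
        report["patients"] = {
            "n": int(len(pats)),
            "correct": correct,
            "accuracy_rate_pct": accuracy_rate(correct, len(pats)),
            "table": pats.to_dict(orient="records"),
        }
    return report


def plot_curves(scores: pd.DataFrame, out_dir) -> list[str]:
    """Write ROC and PR curve PNGs; returns the file paths."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    roc = roc_auc(scores)
    pr = pr_aupr(scores)
    paths = []
    for name, curve, (xl, yl) in (
        ("roc", roc, ("False positive rate", "True positive rate")),
        ("pr", pr, ("Recall", "Precision")),
    ):
        fig, ax = plt.subplots(figsize=(4, 4))
        ax.plot(curve.x, curve.y)
        ax.set_xlabel(xl)
        ax.set_ylabel(yl)
        ax.set_title(f"{name.upper()} (area = {curve.area:.3f})")
        path = out / f"{name}_curve.png"
        fig.savefig(path, dpi=100)
        plt.close(fig)
        paths.append(str(path))
    return paths
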