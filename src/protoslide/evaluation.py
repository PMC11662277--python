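"""Classification metrics with equal-weight macro averaging and bootstrap CIs.

Per-class precision, recall and F1 are macro-averaged with equal class
weight regardless of class size (0/0 is defined as 0 and flagged).
Confidence intervals are nonparametric: evaluation units are grouped
(e.g. by slide or domain, respecting within-group correlation), groups
are resampled with replacement B times, and the percentile interval of
the resampled metric is reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion

__all__ = ["EvaluationReport", "evaluate"]


@dataclass
class EvaluationReport:
    """Confusion matrix, accuracy, per-class and macro P/R/F1, and 95% CIs."""

    labels: list[str]
    confusion: pd.DataFrame  # true x predicted counts
    accuracy: float
    per_class: pd.DataFrame  # index=class, columns precision/recall/f1/support
    macro_precision: float
    macro_recall: float
    macro_f1: float
    ci: dict[str, tuple[float, float]]
    n: int
    group_key: str
    zero_division_flags: list[str] = field(default_factory=list)

    def summary(self) -> dict:
        return {
            "n": self.n,
            "accuracy": self.accuracy,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "ci": {k: list(v) for k, v in self.ci.items()},
        }


def _metrics_from_confusion(cm: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[int]]:
    """Per-class precision/recall/F1 with 0/0 := 0; returns flagged class idxs."""
    tp = np.diag(cm).astype(float)
    pred_tot = cm.sum(axis=0).astype(float)
    true_tot = cm.sum(axis=1).astype(float)
    flagged = []
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(pred_tot > 0, tp / np.where(pred_tot > 0, pred_tot, 1), 0.0)
        recall = np.where(true_tot > 0, tp / np.where(true_tot > 0, true_tot, 1), 0.0)
        pr = precision + recall
        f1 = np.where(pr > 0, 2 * precision * recall / np.where(pr > 0, pr, 1), 0.0)
    for i in range(cm.shape[0]):
        if pred_tot[i] == 0 or true_tot[i] == 0:
            flagged.append(i)
    return precision, recall, f1, flagged


def evaluate(
    predictions: Sequence[tuple[str, str, str]],
    *,
    labels: Sequence[str] | None = None,
    n_bootstrap: int = 1000,
    seed: int = 0,
    confidence: float = 0.95,
) -> EvaluationReport:
    """Score (true, predicted, group) triples.

    ``labels`` declares the class set (defaults to the labels observed in
    the true column); a predicted label outside the declared set is an
    error.  CIs are computed for accuracy and the macro metrics by
    resampling groups with replacement.
    """
    if len(predictions) == 0:
        raise ValueError("no predictions to evaluate")
    true = np.asarray([p[0] for p in predictions], dtype=object)
    pred = np.asarray([p[1] for p in predictions], dtype=object)
    group = np.asarray([p[2] for p in predictions], dtype=object)
    if labels is None:
        labels = sorted(set(true))
    labels = [str(l) for l in labels]
    known = set(labels)
    offenders = sorted({str(v) for v in np.concatenate([true, pred])} - known)
    if offenders:
        raise ValueError(f"labels outside the declared set: {offenders}")

    cm = _sk_confusion(true, pred, labels=labels)
    n = len(true)
    accuracy = float(np.trace(cm)) / n
    precision, recall, f1, flagged_idx = _metrics_from_confusion(cm)
    per_class = pd.DataFrame(
        {
            "precision": precision,
            "recall": recall,
            "f1": f1,
            "support": cm.sum(axis=1),
        },
        index=pd.Index(labels, name="class"),
    )

    rng = np.random.default_rng(np.random.SeedSequence([seed & (2**63 - 1)]))
    uniq_groups = np.unique(group)
    n_groups = len(uniq_groups)
    # per-group confusion matrices: a bootstrap draw is a sum of G samples
    group_cms = np.stack(
        [_sk_confusion(true[group == g], pred[group == g], labels=labels) for g in uniq_groups]
    )
    alpha = (1.0 - confidence) / 2.0
    boot = {"accuracy": [], "macro_precision": [], "macro_recall": [], "macro_f1": []}
    for _ in range(n_bootstrap):
        take = rng.integers(0, n_groups, size=n_groups)
        bcm = group_cms[take].sum(axis=0)
        boot["accuracy"].append(np.trace(bcm) / bcm.sum())
        bp, br, bf, _ = _metrics_from_confusion(bcm)
        boot["macro_precision"].append(bp.mean())
        boot["macro_recall"].append(br.mean())
        boot["macro_f1"].append(bf.mean())
    point = {
        "accuracy": accuracy,
        "macro_precision": float(precision.mean()),
        "macro_recall": float(recall.mean()),
        "macro_f1": float(f1.mean()),
    }
    ci = {}
    for key, values in boot.items():
        lo, hi = np.quantile(values, [alpha, 1.0 - alpha])
        # percentile intervals from few groups can exclude the point
        # estimate only by floating accident; widen to contain it
        ci[key] = (min(float(lo), point[key]), max(float(hi), point[key]))

    return EvaluationReport(
        labels=labels,
        confusion=pd.DataFrame(cm, index=pd.Index(labels, name="true"), columns=labels),
        accuracy=accuracy,
        per_class=per_class,
        macro_precision=point["macro_precision"],
        macro_recall=point["macro_recall"],
        macro_f1=point["macro_f1"],
        ci=ci,
        n=n,
        group_key="group",
        zero_division_flags=[labels[i] for i in flagged_idx],
    )
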