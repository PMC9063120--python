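"""Metrics for imbalanced multi-target prediction and repeat aggregation.

Accuracy is the exact combination-match rate (every target right at
once).  Micro precision/recall/F1 pool true/false positives across all
targets of the decoded binary matrix before forming ratios, which keeps
the rare positive targets from being swamped by the dominant all-negative
profile.  Average precision (AP) is computed per target from soft scores
and macro-averaged across targets (a micro variant is reported
alongside).  Per-repeat reports aggregate as mean +/- sample standard
deviation, with accuracy formatted as a percentage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import average_precision_score

from . import labels as L


@dataclass
class MetricsReport:
    accuracy: float
    micro_precision: float
    micro_recall: float
    micro_f1: float
    average_precision: float | None = None       # macro over targets
    average_precision_micro: float | None = None

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "micro_precision": self.micro_precision,
            "micro_recall": self.micro_recall,
            "micro_f1": self.micro_f1,
            "average_precision": self.average_precision,
            "average_precision_micro": self.average_precision_micro,
        }


def per_target_scores(class_probs: np.ndarray, n_targets: int) -> np.ndarray:
    """Soft per-target activity scores from combination-class probabilities.

    The score of target j is the total probability of all classes in which
    target j is active (one-hot mode has no native per-target output).
    """
    C = class_probs.shape[1]
    if C != L.n_classes(n_targets):
        raise ValueError(f"{C} classes inconsistent with {n_targets} targets")
    members = np.vstack([L.decode_class(c, n_targets) for c in range(C)])
    return class_probs @ members.astype(np.float64)


def score(predicted: np.ndarray, truth: np.ndarray,
          scores: np.ndarray | None = None) -> MetricsReport:
    """Score a decoded binary prediction matrix against the truth matrix.

    ``scores`` (optional) are soft per-target values used for AP.
    """
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape:
        raise ValueError(f"shape mismatch: {predicted.shape} vs {truth.shape}")
    accuracy = float(np.mean(np.all(predicted == truth, axis=1)))
    tp = int(np.sum((predicted == 1) & (truth == 1)))
    fp = int(np.sum((predicted == 1) & (truth == 0)))
    fn = int(np.sum((predicted == 0) & (truth == 1)))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    ap_macro = ap_micro = None
    if scores is not None:
        scores = np.asarray(scores, dtype=np.float64)
        if scores.shape != truth.shape:
            raise ValueError(f"scores shape {scores.shape} != truth {truth.shape}")
        per_target = [
            average_precision_score(truth[:, j], scores[:, j])
            for j in range(truth.shape[1]) if truth[:, j].any()
        ]
        ap_macro = float(np.mean(per_target)) if per_target else 0.0
        if truth.any():
            ap_micro = float(average_precision_score(truth.ravel(), scores.ravel()))
        else:
            ap_micro = 0.0
    return MetricsReport(accuracy, precision, recall, f1, ap_macro, ap_micro)


def aggregate(reports: list[MetricsReport]) -> dict[str, tuple[float, float]]:
    """Per-metric mean and sample standard deviation over repeats."""
    if not reports:
        raise ValueError("need at least one report")
    out = {}
    for key in ("accuracy", "micro_precision", "micro_recall", "micro_f1",
                "average_precision", "average_precision_micro"):
        vals = [getattr(r, key) for r in reports]
        if any(v is None for v in vals):
            continue
        mean = float(np.mean(vals))
        sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        out[key] = (mean, sd)
    return out


def format_table(aggregated: dict[str, tuple[float, float]]) -> str:
    """Human-readable `value +/- sd` table; accuracy as percent (2 dp)."""
    lines = ["metric                     value"]
    for key, (mean, sd) in aggregated.items():
        if key == "accuracy":
            lines.append(f"{key:<26} {100 * mean:.2f} ± {100 * sd:.2f}")
        else:
            lines.append(f"{key:<26} {mean:.2f} ± {sd:.2f}")
    return "\n".join(lines)
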