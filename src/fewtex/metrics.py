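"""Confusion matrices, per-class and macro metrics, comparison tables.

Per class c (one-vs-rest): precision = TP/(TP+FP), recall = TP/(TP+FN),
F1 = 2*precision*recall/(precision+recall) = 2TP/(2TP+FP+FN), with the
0/0 cases fixed to 0.  Macro metrics are unweighted means over classes;
multi-class accuracy is trace/total, which on balanced data equals the
macro recall exactly.  Display values are rounded to 3 decimals, half
away from zero.
"""

from __future__ import annotations

import dataclasses
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd

__all__ = [
    "ClassMetrics", "MacroMetrics", "confusion_matrix", "per_class_metrics",
    "macro_metrics", "reconstruct_predicted_totals", "report", "display_round",
]


@dataclasses.dataclass(frozen=True)
class ClassMetrics:
    cls: int
    tp: int
    fp: int
    fn: int
    tn: int
    precision: float
    recall: float
    f1: float


@dataclasses.dataclass(frozen=True)
class MacroMetrics:
    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float


def confusion_matrix(true_labels, pred_labels, n_classes: int) -> np.ndarray:
    """counts[i, j] = number of items with true class i predicted as j."""
    true_labels = np.asarray(true_labels, dtype=int)
    pred_labels = np.asarray(pred_labels, dtype=int)
    if true_labels.shape != pred_labels.shape:
        raise ValueError("label sequences must have equal length")
    for name, lab in (("true", true_labels), ("predicted", pred_labels)):
        if lab.size and (lab.min() < 0 or lab.max() >= n_classes):
            raise ValueError(f"{name} label out of range [0, {n_classes})")
    cm = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(cm, (true_labels, pred_labels), 1)
    return cm


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0


def per_class_metrics(cm: np.ndarray) -> list[ClassMetrics]:
    """One-vs-rest TP/FP/FN/TN and precision/recall/F1 per class (0/0 -> 0)."""
    cm = np.asarray(cm)
    total = int(cm.sum())
    out = []
    for c in range(cm.shape[0]):
        tp = int(cm[c, c])
        fp = int(cm[:, c].sum()) - tp
        fn = int(cm[c, :].sum()) - tp
        tn = total - tp - fp - fn
        precision = _safe_div(tp, tp + fp)
        recall = _safe_div(tp, tp + fn)
        f1 = _safe_div(2 * tp, 2 * tp + fp + fn)
        out.append(ClassMetrics(c, tp, fp, fn, tn, precision, recall, f1))
    return out


def macro_metrics(metrics: list[ClassMetrics], cm: np.ndarray) -> MacroMetrics:
    """Unweighted class means plus multi-class accuracy = trace/total."""
    cm = np.asarray(cm)
    total = int(cm.sum())
    accuracy = _safe_div(float(np.trace(cm)), total)
    return MacroMetrics(
        accuracy=accuracy,
        macro_precision=float(np.mean([m.precision for m in metrics])),
        macro_recall=float(np.mean([m.recall for m in metrics])),
        macro_f1=float(np.mean([m.f1 for m in metrics])),
    )


def reconstruct_predicted_totals(
    correct_counts: list[int],
    precisions: list[float],
    query_count: int,
) -> list[int]:
    """Recover per-class predicted totals from TP counts and rounded precisions.

    A published table often prints only the per-class correct counts and
    the (3-decimal) precisions; since precision = TP / predicted_total,
    the predicted total is the nearest integer to TP / precision.
    Classes with TP = 0 carry no information, so they absorb the
    remainder needed for the totals to sum to the query count.  Raises if
    the reconstruction cannot be made consistent.
    """
    totals: list[int | None] = []
    for tp, prec in zip(correct_counts, precisions):
        if tp > 0:
            if prec <= 0:
                raise ValueError("class with TP > 0 must have positive precision")
            totals.append(int(round(tp / prec)))
        else:
            totals.append(None)
    known = sum(t for t in totals if t is not None)
    free = [i for i, t in enumerate(totals) if t is None]
    remainder = query_count - known
    if not free:
        if known != query_count:
            raise ValueError(
                f"reconstructed totals sum to {known}, expected {query_count}"
            )
        return [int(t) for t in totals]
    if remainder < 0:
        raise ValueError("reconstructed totals exceed the query count")
    share = remainder // len(free)
    for j, i in enumerate(free):
        totals[i] = share + (remainder - share * len(free) if j == len(free) - 1 else 0)
    return [int(t) for t in totals]


def display_round(value: float, decimals: int = 3) -> float:
    """Round half away from zero, the convention used for printed tables."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def report(systems: dict[str, np.ndarray]) -> tuple[dict, pd.DataFrame]:
    """Comparison report for one or more systems' confusion matrices.

    Returns ``(report_dict, table)``: the dict carries full-precision and
    3-decimal display values per class and macro; the table has one row
    per system, sorted by macro F1 descending.
    """
    if not systems:
        raise ValueError("at least one system is required")
    out = {}
    rows = []
    for name, cm in systems.items():
        pcm = per_class_metrics(cm)
        mac = macro_metrics(pcm, cm)
        out[name] = {
            "per_class": [
                {
                    "class": m.cls, "tp": m.tp, "fp": m.fp, "fn": m.fn,
                    "precision": m.precision, "recall": m.recall, "f1": m.f1,
                    "display": {
                        "precision": display_round(m.precision),
                        "recall": display_round(m.recall),
                        "f1": display_round(m.f1),
                    },
                }
                for m in pcm
            ],
            "macro": {
                "accuracy": mac.accuracy,
                "macro_precision": mac.macro_precision,
                "macro_recall": mac.macro_recall,
                "macro_f1": mac.macro_f1,
                "display": {
                    "accuracy": display_round(mac.accuracy),
                    "macro_precision": display_round(mac.macro_precision),
                    "macro_recall": display_round(mac.macro_recall),
                    "macro_f1": display_round(mac.macro_f1),
                },
            },
        }
        rows.append(
            {
                "system": name,
                "accuracy": mac.accuracy,
                "macro_precision": mac.macro_precision,
                "macro_recall": mac.macro_recall,
                "macro_f1": mac.macro_f1,
            }
        )
    table = pd.DataFrame(rows).sort_values("macro_f1", ascending=False, kind="stable").reset_index(drop=True)
    return out, table
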