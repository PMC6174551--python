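"""Micro-averaged precision/recall/F1 over the five evaluated relation
classes, per-class breakdown and confusion matrix.

Micro-averaging pools TP/FP/FN across the positive classes with NA
excluded from the positive set:

    Precision = TP / (TP + FP)
    Recall    = TP / (TP + FN)
    F1        = 2 * Precision * Recall / (Precision + Recall)

TP counts correctly predicted positive instances.  A gold-NA instance
predicted positive contributes one FP; a gold-positive instance predicted
NA contributes one FN; a gold-positive instance predicted as a *different*
positive class contributes one FP and one FN — the same convention the
official tuple comparison yields, where the mismatched tuple appears in
both difference sets.  All 0/0 cases are reported as 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .corpus_io import (
    EVALUATED_CPRS,
    LABELS,
    GoldRelation,
    PredictionRecord,
    read_gold_relations,
    read_predictions,
)

_LABEL_IDX = {lab: i for i, lab in enumerate(LABELS)}


@dataclass
class PerClass:
    support: int
    precision: float
    recall: float
    f1: float
    defined: bool = True  # False when the class has no gold and no predictions


@dataclass
class EvalReport:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float
    per_class: dict[str, PerClass] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "TP": self.tp, "FP": self.fp, "FN": self.fn,
            "precision": self.precision, "recall": self.recall, "f1": self.f1,
            "per_class": {
                k: {"support": v.support, "precision": v.precision,
                    "recall": v.recall, "f1": v.f1}
                for k, v in self.per_class.items()
            },
        }


def _prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    f = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f


def _to_labels(seq: Sequence) -> list[str]:
    out = []
    for x in seq:
        if isinstance(x, str):
            if x not in _LABEL_IDX:
                raise ValueError(f"unknown label {x!r}")
            out.append(x)
        else:
            out.append(LABELS[int(x)])
    return out


@dataclass
class ConfusionMatrix:
    """6x6 count table: rows = gold, columns = predicted, both ordered
    [NA, CPR:3, CPR:4, CPR:5, CPR:6, CPR:9]."""

    counts: np.ndarray
    labels: tuple[str, ...] = LABELS

    def row_normalized(self) -> np.ndarray:
        totals = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(totals > 0, self.counts / totals, 0.0)
        return out

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def confusion(gold, pred) -> ConfusionMatrix:
    gold_l, pred_l = _to_labels(gold), _to_labels(pred)
    if len(gold_l) != len(pred_l):
        raise ValueError(f"length mismatch: {len(gold_l)} gold vs {len(pred_l)} pred")
    counts = np.zeros((len(LABELS), len(LABELS)), dtype=np.int64)
    for g, p in zip(gold_l, pred_l):
        counts[_LABEL_IDX[g], _LABEL_IDX[p]] += 1
    return ConfusionMatrix(counts=counts)


def micro_prf(gold, pred) -> EvalReport:
    """Micro-averaged P/R/F1 over the five positive classes, with a
    per-class one-vs-rest breakdown attached."""
    gold_l, pred_l = _to_labels(gold), _to_labels(pred)
    if len(gold_l) != len(pred_l):
        raise ValueError(f"length mismatch: {len(gold_l)} gold vs {len(pred_l)} pred")
    tp = fp = fn = 0
    for g, p in zip(gold_l, pred_l):
        if g != "NA" and g == p:
            tp += 1
        else:
            if p != "NA":
                fp += 1
            if g != "NA":
                fn += 1
    prec, rec, f1 = _prf(tp, fp, fn)
    report = EvalReport(tp=tp, fp=fp, fn=fn, precision=prec, recall=rec, f1=f1)
    report.per_class = per_class_report(gold_l, pred_l)
    return report


def per_class_report(gold, pred) -> dict[str, PerClass]:
    """One-vs-rest precision/recall/F1 and support per positive class."""
    gold_l, pred_l = _to_labels(gold), _to_labels(pred)
    out = {}
    for lab in EVALUATED_CPRS:
        tp = sum(1 for g, p in zip(gold_l, pred_l) if g == lab and p == lab)
        fp = sum(1 for g, p in zip(gold_l, pred_l) if g != lab and p == lab)
        fn = sum(1 for g, p in zip(gold_l, pred_l) if g == lab and p != lab)
        support = tp + fn
        prec, rec, f1 = _prf(tp, fp, fn)
        out[lab] = PerClass(support=support, precision=prec, recall=rec, f1=f1,
                            defined=(support + fp) > 0)
    return out


def micro_from_confusion(cm: ConfusionMatrix) -> EvalReport:
    """Recompute the micro scores from a confusion matrix (cross-check)."""
    c = cm.counts
    pos = slice(1, len(LABELS))
    tp = int(np.trace(c[pos, pos]))
    fp = int(c[:, pos].sum() - np.trace(c[pos, pos]))
    fn = int(c[pos, :].sum() - np.trace(c[pos, pos]))
    prec, rec, f1 = _prf(tp, fp, fn)
    return EvalReport(tp=tp, fp=fp, fn=fn, precision=prec, recall=rec, f1=f1)


def tuple_eval(
    gold: str | Path | Sequence[GoldRelation],
    pred: str | Path | Sequence[PredictionRecord],
    gold_dialect: str = "gold_standard",
) -> EvalReport:
    """Official-style evaluation by set comparison of (pmid, CPR, arg1, arg2)
    tuples restricted to the evaluated classes.

    Gold relations whose arguments never co-occur in a sentence still
    appear in the gold set, so a same-sentence system pays for them as
    false negatives.
    """
    if isinstance(gold, (str, Path)):
        gold = read_gold_relations(gold, dialect=gold_dialect)
    if isinstance(pred, (str, Path)):
        pred = read_predictions(pred)
    gold_set = {
        (r.pmid, r.cpr, r.arg1, r.arg2) for r in gold if r.cpr in EVALUATED_CPRS
    }
    pred_set = {(r.pmid, r.cpr, r.arg1, r.arg2) for r in pred}
    tp = len(gold_set & pred_set)
    fp = len(pred_set - gold_set)
    fn = len(gold_set - pred_set)
    prec, rec, f1 = _prf(tp, fp, fn)
    return EvalReport(tp=tp, fp=fp, fn=fn, precision=prec, recall=rec, f1=f1)


def format_per_class(per_class: dict[str, PerClass]) -> str:
    """Render the per-class breakdown as an aligned text table."""
    lines = [f"{'Label':<8}{'Support':>8}{'Precision':>11}{'Recall':>8}{'F1':>8}"]
    for lab, pc in per_class.items():
        lines.append(
            f"{lab:<8}{pc.support:>8}{pc.precision:>11.3f}{pc.recall:>8.3f}{pc.f1:>8.3f}"
        )
    return "\n".join(lines)
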