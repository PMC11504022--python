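"""Region-level and patient-level evaluation statistics.

Region level: sensitivity (TPR), specificity (TNR), precision from a
confusion table; detection precision/recall and mean average precision
(101-point interpolation, IoU grid 0.50:0.05:0.95).

Patient level: ``fpavg`` (mean false positives per patient) and ``ppatient``
(fraction of patients whose CMB status is judged correctly).  ``ppatient``
has two modes because its defining formula and its prose description
disagree: the *literal* rule scores a CMB-negative patient correct whenever
the count of true-positive regions is zero — which is vacuously true no
matter how many false positives the patient received — while the *strict*
rule demands zero positive predictions of any kind for a negative patient.
The strict rule is the default report; the literal value is always computed
alongside.  ``ppatient(literal) >= ppatient(strict)`` for every input.

Undefined rates (zero denominators) propagate as ``None`` markers, never as 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .boxes import pairwise_iou

__all__ = ["ConfusionCounts", "PatientPredictions", "EvalReport", "rates", "fpavg",
           "ppatient", "match_and_map", "average_precision"]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be nonnegative")


@dataclass
class PatientPredictions:
    """Per-patient prediction bookkeeping for the patient-level metrics."""

    patient_id: str
    has_cmbs: bool
    tp_per_slice: dict[int, int] = field(default_factory=dict)   # slice -> true-CMB hits
    fp_per_slice: dict[int, int] = field(default_factory=dict)
    n_slices: int = 130

    def __post_init__(self) -> None:
        for d in (self.tp_per_slice, self.fp_per_slice):
            for s in d:
                if not 0 <= s < self.n_slices:
                    raise ValueError(f"slice index {s} outside [0, {self.n_slices})")

    @property
    def total_tp(self) -> int:
        return sum(self.tp_per_slice.values())

    @property
    def total_fp(self) -> int:
        return sum(self.fp_per_slice.values())

    @property
    def total_predictions(self) -> int:
        return self.total_tp + self.total_fp


@dataclass(frozen=True)
class EvalReport:
    sensitivity: float | None
    specificity: float | None
    precision: float | None
    fpavg: float
    ppatient_strict: float
    ppatient_literal: float
    map50: float | None = None
    map50_95: float | None = None
    counts: ConfusionCounts | None = None

    def to_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "precision": self.precision, "fpavg": self.fpavg,
            "ppatient_strict": self.ppatient_strict,
            "ppatient_literal": self.ppatient_literal,
            "map50": self.map50, "map50_95": self.map50_95,
            "counts": None if self.counts is None else vars(self.counts),
        }


def rates(c: ConfusionCounts) -> tuple[float | None, float | None, float | None]:
    """(sensitivity, specificity, precision); None where the denominator is zero."""
    sens = c.TP / (c.TP + c.FN) if (c.TP + c.FN) > 0 else None
    spec = c.TN / (c.TN + c.FP) if (c.TN + c.FP) > 0 else None
    prec = c.TP / (c.TP + c.FP) if (c.TP + c.FP) > 0 else None
    return sens, spec, prec


def fpavg(total_fp: int, n_patients: int) -> float:
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    if total_fp < 0:
        raise ValueError("total_fp must be >= 0")
    return total_fp / n_patients


def ppatient(preds: Sequence[PatientPredictions], mode: str = "strict") -> float:
    """Patient-level accuracy.

    literal: a CMB-positive patient is correct iff it received at least one
    true-positive region; a CMB-negative patient is correct iff it received
    zero true-positive regions (vacuous — false positives are not counted).
    strict: a negative patient is correct only with zero predictions of any kind.
    """
    if mode not in ("literal", "strict"):
        raise ValueError("mode must be 'literal' or 'strict'")
    if not preds:
        raise ValueError("need at least one patient")
    ids = [p.patient_id for p in preds]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate patient_ids")
    score = 0
    for p in preds:
        if p.has_cmbs:
            score += int(p.total_tp > 0)
        elif mode == "literal":
            score += int(p.total_tp == 0)
        else:
            score += int(p.total_predictions == 0)
    return score / len(preds)


# --- detection mAP ---------------------------------------------------------

def _match_image(det_boxes: np.ndarray, det_scores: np.ndarray, gt_boxes: np.ndarray,
                 iou_thr: float) -> np.ndarray:
    """Greedy one-to-one matching by descending score; returns TP flags per detection."""
    order = np.argsort(-det_scores, kind="stable")
    tp = np.zeros(len(det_boxes), dtype=bool)
    if len(gt_boxes) == 0 or len(det_boxes) == 0:
        return tp
    iou = pairwise_iou(det_boxes, gt_boxes)
    used = np.zeros(len(gt_boxes), dtype=bool)
    for i in order:
        j = -1
        best = iou_thr
        for k in range(len(gt_boxes)):
            if not used[k] and iou[i, k] >= best:
                best = iou[i, k]
                j = k
        if j >= 0:
            used[j] = True
            tp[i] = True
    return tp


def average_precision(tp_flags: np.ndarray, scores: np.ndarray, n_gt: int) -> float:
    """AP with 101-point interpolation over recall in [0, 1]."""
    if n_gt == 0:
        return 0.0
    order = np.argsort(-scores, kind="stable")
    tp = tp_flags[order].astype(np.float64)
    fp = 1.0 - tp
    cum_tp = np.cumsum(tp)
    cum_fp = np.cumsum(fp)
    recall = cum_tp / n_gt
    precision = cum_tp / np.maximum(cum_tp + cum_fp, 1e-12)
    # precision envelope, then sample at 101 recall points
    for i in range(len(precision) - 2, -1, -1):
        precision[i] = max(precision[i], precision[i + 1])
    ap = 0.0
    for r in np.linspace(0, 1, 101):
        idx = np.searchsorted(recall, r, side="left")
        ap += precision[idx] if idx < len(precision) else 0.0
    return ap / 101.0


def match_and_map(detections: Sequence[Sequence[tuple[np.ndarray, float]]],
                  ground_truth: Sequence[np.ndarray],
                  iou_thresholds: Sequence[float] | None = None) -> dict:
    """Detection P/R/mAP over a list of images.

    ``detections[i]`` is a list of (box (4,), score) for image i;
    ``ground_truth[i]`` an (M, 4) array.  Returns precision and recall at the
    first threshold (default 0.5) plus map50 and map50_95.
    """
    if iou_thresholds is None:
        iou_thresholds = np.round(np.linspace(0.50, 0.95, 10), 2)
    iou_thresholds = list(iou_thresholds)
    n_gt = int(sum(len(g) for g in ground_truth))
    aps = []
    p_at_50 = r_at_50 = None
    for t_i, thr in enumerate(iou_thresholds):
        all_tp, all_scores = [], []
        for dets, gts in zip(detections, ground_truth):
            if len(dets) == 0:
                continue
            boxes = np.asarray([d[0] for d in dets], dtype=np.float64).reshape(-1, 4)
            scores = np.asarray([d[1] for d in dets], dtype=np.float64)
            tp = _match_image(boxes, scores, np.asarray(gts, dtype=np.float64).reshape(-1, 4), thr)
            all_tp.append(tp)
            all_scores.append(scores)
        if all_tp:
            tp_cat = np.concatenate(all_tp)
            sc_cat = np.concatenate(all_scores)
            aps.append(average_precision(tp_cat, sc_cat, n_gt))
            if t_i == 0:
                n_det = len(tp_cat)
                p_at_50 = float(tp_cat.sum() / n_det) if n_det else None
                r_at_50 = float(tp_cat.sum() / n_gt) if n_gt else None
        else:
            aps.append(0.0)
            if t_i == 0:
                p_at_50, r_at_50 = (None, 0.0 if n_gt else None)
    return {"precision": p_at_50, "recall": r_at_50,
            "map50": float(aps[0]),
            "map50_95": float(np.mean(aps))}
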