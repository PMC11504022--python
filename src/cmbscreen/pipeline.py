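"""End-to-end two-stage screening per patient, plus timing/parameter bookkeeping.

``run_patient`` chains the stages: detect candidates on the SWI stack only,
crop a 4-slice volume around each surviving candidate, build and encode the
text prompts (with adjacency flags computed from the raw detection set),
classify each candidate, and score the result against ground truth.

``estimate_infertime`` is the closed-form per-patient inference-time model:
``(slices * detection_ms_per_slice + candidate_budget * classification_ms_per_region) / 1000``
seconds; wall-clock measurement is recorded for information only and never
used for reported timing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .boxes import boxes_to_array, pairwise_iou
from .classifier import (CFConfig, ClassificationResult, CmbsClassifier,
                         extract_candidate_volume)
from .detector import Detection, DetectorConfig, detect_patient
from .metrics import (ConfusionCounts, EvalReport, PatientPredictions, fpavg,
                      ppatient, rates)
from .phantom import PatientRecord
from .prompts import HashingEncoder, build_prompts, encode_prompts

__all__ = ["TimingModel", "estimate_infertime", "combination_report", "run_patient",
           "evaluate_patients", "adjacency_flags"]


@dataclass(frozen=True)
class TimingModel:
    """Per-patient inference-time bookkeeping constants."""

    num_image: int = 130          # slices per patient
    d_image_ms: float = 1.0       # detection time per slice, milliseconds
    c_image_ms: float = 1.0      # classification time per candidate region, ms
    candidates: int = 100         # standardized candidate budget

    def __post_init__(self) -> None:
        if min(self.num_image, self.candidates) <= 0:
            raise ValueError("num_image and candidates must be positive")
        if self.d_image_ms <= 0 or self.c_image_ms < 0:
            raise ValueError("per-stage times must be positive (classification may be 0)")


def _round2(x: float) -> float:
    """Round-half-up to 2 decimals (avoids banker's-rounding surprises)."""
    return math.floor(x * 100 + 0.5) / 100


def estimate_infertime(t: TimingModel) -> float:
    """Seconds per patient, rounded to 2 decimals."""
    ms = t.num_image * t.d_image_ms + t.candidates * t.c_image_ms
    return _round2(ms / 1000.0)


def combination_report(det_params_mb: float, cls_params_mb: float,
                       timing: TimingModel) -> dict:
    """One row of the detector x classifier combination table."""
    if det_params_mb < 0 or cls_params_mb < 0:
        raise ValueError("parameter counts must be nonnegative")
    return {
        "total_parameters_mb": _round2(det_params_mb + cls_params_mb),
        "total_inference_time_s": estimate_infertime(timing),
    }


# --- per-patient orchestration ---------------------------------------------

def adjacency_flags(det: Detection, all_dets: Sequence[Detection]) -> tuple[bool, bool]:
    """Was anything detected at the same position on the neighbouring slices?

    "Same position" = center within max(box side, 5 px) of this candidate's
    center on slice i-1 / i+1, judged on the raw detection set.
    """
    cx, cy = det.box.center
    tol = max(det.box.width, det.box.height, 5.0)
    prev_hit = next_hit = False
    for other in all_dets:
        ocx, ocy = other.box.center
        if abs(ocx - cx) <= tol and abs(ocy - cy) <= tol:
            if other.slice_index == det.slice_index - 1:
                prev_hit = True
            elif other.slice_index == det.slice_index + 1:
                next_hit = True
    return prev_hit, next_hit


def run_patient(rec: PatientRecord, detector, classifier: CmbsClassifier,
                det_cfg: DetectorConfig | None = None,
                encoder: Callable | None = None,
                threshold: float = 0.5,
                match_iou: float = 0.5) -> tuple[list[Detection], list[ClassificationResult], EvalReport]:
    """Detect -> crop -> prompt -> classify -> report for one patient.

    Detection reads the SWI stack only; the phase stack enters at the crop
    stage.  Candidates the classifier accepts (probability >= threshold) are
    scored against ground truth: a region is a TP if it overlaps a true CMB
    box on its slice at IoU >= ``match_iou``.
    """
    if rec.swi_stack.shape != rec.phase_stack.shape:
        raise ValueError("SWI and phase stacks must have matching shapes")
    det_cfg = det_cfg or getattr(detector, "cfg", None) or DetectorConfig()
    encoder = encoder or HashingEncoder()
    detections = detect_patient(detector, rec.swi_stack, det_cfg)

    results: list[ClassificationResult] = []
    accepted: list[Detection] = []
    use_text = classifier.cfg.with_text
    for det in detections:
        vol = extract_candidate_volume(rec.swi_stack, rec.phase_stack,
                                       det.slice_index, det.box, classifier.cfg)
        text = None
        if use_text:
            prev_hit, next_hit = adjacency_flags(det, detections)
            text = encode_prompts(build_prompts(rec.meta, det.box, prev_hit, next_hit),
                                  encoder)
        res = classifier.predict(vol, text, threshold=threshold)
        results.append(res)
        if res.label:
            accepted.append(det)

    report = evaluate_patients([(rec, accepted)], match_iou=match_iou)
    return detections, results, report


def evaluate_patients(pairs: Sequence[tuple[PatientRecord, Sequence[Detection]]],
                      match_iou: float = 0.5) -> EvalReport:
    """Region- and patient-level report for (patient, accepted detections) pairs."""
    tp = fp = fn = 0
    patient_preds: list[PatientPredictions] = []
    for rec, dets in pairs:
        pp = PatientPredictions(patient_id=rec.patient_id, has_cmbs=rec.has_cmbs,
                                n_slices=rec.n_slices)
        matched_gt = 0
        n_gt = sum(len(b) for b in rec.gt_boxes)
        for s in range(rec.n_slices):
            gtb = boxes_to_array(rec.gt_boxes[s]) if rec.gt_boxes[s] else np.zeros((0, 4))
            sdets = [d for d in dets if d.slice_index == s]
            used = np.zeros(len(gtb), dtype=bool)
            s_tp = s_fp = 0
            for d in sorted(sdets, key=lambda d: -d.score):
                hit = False
                if len(gtb):
                    iou = pairwise_iou(np.asarray(d.box.as_tuple())[None], gtb)[0]
                    iou[used] = 0.0
                    j = int(iou.argmax())
                    if iou[j] >= match_iou:
                        used[j] = True
                        hit = True
                if hit:
                    s_tp += 1
                else:
                    s_fp += 1
            if s_tp:
                pp.tp_per_slice[s] = s_tp
            if s_fp:
                pp.fp_per_slice[s] = s_fp
            matched_gt += s_tp
        tp += matched_gt
        fp += pp.total_fp
        fn += n_gt - matched_gt
        patient_preds.append(pp)

    counts = ConfusionCounts(TP=tp, TN=0, FP=fp, FN=fn)
    sens, _, prec = rates(counts)
    # region-level true negatives are undefined for detection-style output,
    # so specificity is reported as an explicit marker, not 0
    return EvalReport(
        sensitivity=sens, specificity=None, precision=prec,
        fpavg=fpavg(fp, len(patient_preds)),
        ppatient_strict=ppatient(patient_preds, "strict"),
        ppatient_literal=ppatient(patient_preds, "literal"),
        counts=counts,
    )
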