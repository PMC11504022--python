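"""Evaluation statistics: confusion rates, patient-level scores, mAP."""

import numpy as np
import pytest

from cmbscreen.boxes import Box
from cmbscreen.metrics import (ConfusionCounts, PatientPredictions, average_precision,
                               fpavg, match_and_map, ppatient, rates)
from cmbscreen.boxes import pairwise_iou


def test_rates_examples():
    sens, spec, prec = rates(ConfusionCounts(TP=94, TN=50, FP=10, FN=6))
    assert sens == pytest.approx(0.94)
    assert spec == pytest.approx(50 / 60)
    assert prec == pytest.approx(94 / 104)


def test_undefined_rates_are_markers_not_zero():
    sens, spec, prec = rates(ConfusionCounts(TP=0, TN=5, FP=0, FN=0))
    assert prec is None
    assert sens is None
    assert spec == pytest.approx(1.0)


def test_negative_counts_rejected():
    with pytest.raises(ValueError):
        ConfusionCounts(TP=-1, TN=0, FP=0, FN=0)


def test_rates_agree_with_shuffled_prediction_table(rng):
    # independent recomputation from a raw label/prediction table
    for _ in range(50):
        y = rng.integers(0, 2, 40)
        p = rng.integers(0, 2, 40)
        c = ConfusionCounts(TP=int(((y == 1) & (p == 1)).sum()),
                            TN=int(((y == 0) & (p == 0)).sum()),
                            FP=int(((y == 0) & (p == 1)).sum()),
                            FN=int(((y == 1) & (p == 0)).sum()))
        sens, spec, prec = rates(c)
        if y.sum():
            assert sens == pytest.approx(((y == 1) & (p == 1)).sum() / y.sum())
        if p.sum():
            assert prec == pytest.approx(((y == 1) & (p == 1)).sum() / p.sum())


def test_fpavg():
    assert fpavg(337, 100) == pytest.approx(3.37)
    assert fpavg(0, 7) == 0.0
    with pytest.raises(ValueError):
        fpavg(1, 0)


def test_fpavg_additivity(rng):
    fps_a, fps_b = int(rng.integers(0, 50)), int(rng.integers(0, 50))
    na, nb = 10, 30
    combined = fpavg(fps_a + fps_b, na + nb)
    weighted = (fpavg(fps_a, na) * na + fpavg(fps_b, nb) * nb) / (na + nb)
    assert combined == pytest.approx(weighted)


def _pp(pid, has, tp=0, fp=0):
    p = PatientPredictions(patient_id=pid, has_cmbs=has)
    if tp:
        p.tp_per_slice[3] = tp
    if fp:
        p.fp_per_slice[5] = fp
    return p


def test_ppatient_three_patient_example():
    preds = [_pp("a", True, tp=2), _pp("b", False), _pp("c", True, tp=0, fp=3)]
    assert ppatient(preds, "literal") == pytest.approx(2 / 3)
    assert ppatient(preds, "strict") == pytest.approx(2 / 3)


def test_ppatient_mode_contrast_on_negative_with_fps():
    preds = [_pp("neg", False, fp=5)]
    assert ppatient(preds, "literal") == 1.0
    assert ppatient(preds, "strict") == 0.0


def test_ppatient_all_correct():
    preds = [_pp("a", True, tp=1), _pp("b", False)]
    assert ppatient(preds, "literal") == 1.0
    assert ppatient(preds, "strict") == 1.0


def test_ppatient_literal_dominates_strict(rng):
    for _ in range(100):
        preds = []
        for i in range(int(rng.integers(1, 8))):
            preds.append(_pp(f"p{i}", bool(rng.integers(0, 2)),
                             tp=int(rng.integers(0, 3)), fp=int(rng.integers(0, 3))))
        assert ppatient(preds, "literal") >= ppatient(preds, "strict")


def test_ppatient_validation():
    with pytest.raises(ValueError):
        ppatient([], "strict")
    with pytest.raises(ValueError):
        ppatient([_pp("x", True), _pp("x", False)])
    with pytest.raises(ValueError):
        ppatient([_pp("x", True)], mode="other")
    with pytest.raises(ValueError):
        PatientPredictions("p", True, tp_per_slice={200: 1}, n_slices=130)


# --- mAP -------------------------------------------------------------------

def test_map_perfect_predictions():
    gt = [np.array([[0, 0, 10, 10], [20, 20, 30, 30]])]
    dets = [[(np.array([0, 0, 10, 10]), 0.9), (np.array([20, 20, 30, 30]), 0.8)]]
    r = match_and_map(dets, gt)
    assert r["map50"] == pytest.approx(1.0)
    assert r["map50_95"] == pytest.approx(1.0)
    assert r["precision"] == pytest.approx(1.0)
    assert r["recall"] == pytest.approx(1.0)


def test_map_no_predictions():
    r = match_and_map([[]], [np.array([[0, 0, 10, 10]])])
    assert r["map50"] == 0.0
    assert r["map50_95"] == 0.0


def test_map_single_pair_iou_threshold_grid():
    # one GT, one prediction overlapping at IoU 0.6: AP is 1 at thresholds
    # <= 0.6 (three of ten) and 0 above
    gt_box = np.array([[0.0, 0.0, 10.0, 10.0]])
    det_box = np.array([0.0, 0.0, 10.0, 6.0])     # IoU = 60/100
    assert pairwise_iou(det_box[None], gt_box)[0, 0] == pytest.approx(0.6)
    r = match_and_map([[(det_box, 0.9)]], [gt_box])
    assert r["map50"] == pytest.approx(1.0)
    assert r["map50_95"] == pytest.approx(3 / 10)


def _naive_ap_oracle(dets, gts, thr):
    """Independent brute force: rasterized IoU, greedy matching, direct PR sums."""
    flags, scores = [], []
    n_gt = sum(len(g) for g in gts)
    for d_list, g in zip(dets, gts):
        taken = set()
        for box, score in sorted(d_list, key=lambda t: -t[1]):
            best_j, best_iou = -1, thr
            for j, gb in enumerate(g):
                if j in taken:
                    continue
                # rasterized IoU on a fine integer grid
                sc = 10
                a = np.zeros((60 * sc, 60 * sc), dtype=bool)
                b = np.zeros_like(a)
                x1, y1, x2, y2 = (int(v * sc) for v in box)
                a[y1:y2, x1:x2] = True
                x1, y1, x2, y2 = (int(v * sc) for v in gb)
                b[y1:y2, x1:x2] = True
                iou = (a & b).sum() / (a | b).sum()
                if iou >= best_iou:
                    best_iou, best_j = iou, j
            if best_j >= 0:
                taken.add(best_j)
                flags.append(1)
            else:
                flags.append(0)
            scores.append(score)
    return average_precision(np.array(flags, dtype=bool), np.array(scores), n_gt)


def test_map_agrees_with_rasterized_oracle(rng):
    for trial in range(5):
        gts, dets = [], []
        for _ in range(3):                       # 3 images, <= 5 boxes each
            n_g, n_d = int(rng.integers(1, 5)), int(rng.integers(0, 6))
            g = []
            for _ in range(n_g):
                x, y = rng.integers(0, 40, 2)
                w, h = rng.integers(3, 15, 2)
                g.append([x, y, x + w, y + h])
            d = []
            for _ in range(n_d):
                x, y = rng.integers(0, 40, 2)
                w, h = rng.integers(3, 15, 2)
                d.append((np.array([x, y, x + w, y + h], dtype=float),
                          float(rng.random())))
            gts.append(np.array(g, dtype=float))
            dets.append(d)
        ours = match_and_map(dets, gts, iou_thresholds=[0.5])["map50"]
        oracle = _naive_ap_oracle(dets, gts, 0.5)
        assert ours == pytest.approx(oracle, abs=1e-9)
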