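"""Detector: configuration, decoding/NMS machinery, training smoke, loss duality."""

import numpy as np
import pytest

from cmbscreen.attention import parameter_count
from cmbscreen.boxes import Box, NwdConfig, combined_regression_loss
from cmbscreen.detector import (CmbDetector, DetectorConfig, Detection, build_detector,
                                combined_box_loss_tensor, detect_patient, nms,
                                train_detector)
from cmbscreen.nn import Tensor


def test_config_validation():
    with pytest.raises(ValueError):
        DetectorConfig(scale="Z")
    with pytest.raises(ValueError):
        DetectorConfig(input_size=100)
    with pytest.raises(ValueError):
        DetectorConfig(nms_iou=0.0)
    with pytest.raises(ValueError):
        DetectorConfig(nwd_mix=1.5)


def test_build_determinism(tiny_detector_cfg):
    a = build_detector(tiny_detector_cfg)
    b = build_detector(tiny_detector_cfg)
    assert a.checksum() == b.checksum()
    assert a.num_parameters() == b.num_parameters()


def test_scale_parameter_monotonicity():
    counts = [build_detector(DetectorConfig(scale=s, input_size=96, with_attention=False)
                             ).num_parameters() for s in ("N", "S", "M", "X6")]
    assert counts == sorted(counts)
    assert counts[0] < counts[-1]


def test_attention_adds_exactly_its_parameter_count():
    base = DetectorConfig(scale="N", input_size=96, channels=(8, 16, 32, 64), depth=1)
    with_att = build_detector(base)
    without = build_detector(
        DetectorConfig(scale="N", input_size=96, channels=(8, 16, 32, 64), depth=1,
                       with_attention=False))
    extra = sum(parameter_count(m.cfg) for m in
                (with_att.att_backbone_p3, with_att.att_backbone_p4,
                 with_att.att_neck_p3, with_att.att_neck_p2))
    assert with_att.num_parameters() - without.num_parameters() == extra


def test_forward_shapes(tiny_detector, rng):
    levels = tiny_detector(Tensor(rng.random((2, 3, 96, 96)).astype(np.float32)))
    assert [lvl["stride"] for lvl in levels] == [4, 8]
    assert levels[0]["cls"].shape == (2, 1, 24, 24)
    assert levels[0]["reg"].shape == (2, 4, 24, 24)
    assert levels[1]["cls"].shape == (2, 1, 12, 12)


# --- NMS -------------------------------------------------------------------

def test_nms_idempotent(rng):
    boxes = np.hstack([rng.uniform(0, 50, (30, 2)), np.zeros((30, 2))])
    boxes[:, 2:] = boxes[:, :2] + rng.uniform(3, 10, (30, 2))
    scores = rng.random(30)
    keep = nms(boxes, scores, 0.5)
    keep2 = nms(boxes[keep], scores[keep], 0.5)
    assert np.array_equal(keep2, np.arange(len(keep)))


def test_nms_suppresses_duplicates():
    boxes = np.array([[0, 0, 10, 10], [0.5, 0, 10.5, 10], [30, 30, 40, 40]], dtype=float)
    scores = np.array([0.9, 0.8, 0.7])
    keep = nms(boxes, scores, 0.5)
    assert list(keep) == [0, 2]


def test_nms_tie_break_deterministic():
    boxes = np.array([[5, 5, 10, 10], [0, 0, 4, 4]], dtype=float)
    scores = np.array([0.5, 0.5])
    keep = nms(boxes, scores, 0.5)
    assert list(keep) == [1, 0]           # equal scores: lexicographic box order


# --- detect_patient machinery ---------------------------------------------

class ConstantModel:
    """Stub emitting fixed logits; used to exercise decode/NMS contracts."""

    def __init__(self, logit=-10.0):
        self.logit = logit

    def __call__(self, x):
        B, _, H, W = x.shape
        out = []
        for stride in (4, 8):
            h, w = H // stride, W // stride
            out.append({"cls": Tensor(np.full((B, 1, h, w), self.logit, dtype=np.float32)),
                        "reg": Tensor(np.zeros((B, 4, h, w), dtype=np.float32)),
                        "stride": stride})
        return out


class DarknessModel:
    """Flip-equivariant stub: objectness from local darkness of the input."""

    def __call__(self, x):
        out = []
        for stride in (4, 8):
            B, _, H, W = x.shape
            h, w = H // stride, W // stride
            pooled = x.data[:, 0].reshape(B, h, stride, w, stride).mean(axis=(2, 4))
            logits = (0.45 - pooled) * 40.0
            out.append({"cls": Tensor(logits[:, None].astype(np.float32)),
                        "reg": Tensor(np.zeros((B, 4, h, w), dtype=np.float32)),
                        "stride": stride})
        return out


def test_score_threshold_one_gives_empty(positive_patient, tiny_detector_cfg):
    from dataclasses import replace
    cfg = replace(tiny_detector_cfg, score_threshold=1.0)
    dets = detect_patient(ConstantModel(logit=3.0), positive_patient.swi_stack, cfg)
    assert dets == []


def test_empty_stack_rejected(tiny_detector_cfg):
    with pytest.raises(ValueError):
        detect_patient(ConstantModel(), np.zeros((0, 96, 96), dtype=np.uint8),
                       tiny_detector_cfg)


def test_duplicate_slices_identical_detections(tiny_detector_cfg, rng):
    from dataclasses import replace
    sl = np.full((96, 96), 200, dtype=np.uint8)
    sl[40:48, 16:24] = 20
    sl[70:76, 60:66] = 30
    stack = np.stack([sl, sl, sl])
    # stay under the global candidate budget so truncation cannot break ties
    cfg = replace(tiny_detector_cfg, score_threshold=0.6)
    dets = detect_patient(DarknessModel(), stack, cfg)
    by_slice = {}
    for d in dets:
        by_slice.setdefault(d.slice_index, []).append((d.box.as_tuple(), round(d.score, 6)))
    vals = [sorted(v) for v in by_slice.values()]
    assert all(v == vals[0] for v in vals)


def test_candidate_budget_enforced(tiny_detector_cfg):
    from dataclasses import replace
    cfg = replace(tiny_detector_cfg, score_threshold=0.0, max_candidates_per_patient=100)
    stack = np.full((3, 96, 96), 200, dtype=np.uint8)
    dets = detect_patient(ConstantModel(logit=2.0), stack, cfg)
    assert len(dets) == 100
    scores = [d.score for d in dets]
    assert scores == sorted(scores, reverse=True)


def test_flip_equivariant_decode(tiny_detector_cfg, rng):
    from dataclasses import replace
    cfg = replace(tiny_detector_cfg, score_threshold=0.6)
    img = np.full((96, 96), 180, dtype=np.uint8)
    img[40:48, 16:24] = 20                 # one dark blob off-center
    stack = img[None]
    dets = detect_patient(DarknessModel(), stack, cfg)
    dets_f = detect_patient(DarknessModel(), img[:, ::-1][None], cfg)
    assert len(dets) == len(dets_f) > 0
    for d, df in zip(sorted(dets, key=lambda d: d.box.x1),
                     sorted(dets_f, key=lambda d: -d.box.x2)):
        assert df.box.x1 == pytest.approx(96 - d.box.x2)
        assert df.box.y1 == pytest.approx(d.box.y1)
        assert df.score == pytest.approx(d.score)


def test_boxes_clipped_to_image(tiny_detector_cfg):
    from dataclasses import replace
    cfg = replace(tiny_detector_cfg, score_threshold=0.5)

    class WideModel(ConstantModel):
        def __call__(self, x):
            out = super().__call__(x)
            for lvl in out:
                lvl["cls"].data[:] = 3.0
                lvl["reg"].data[:] = 5.0   # huge offsets -> out-of-bounds boxes
            return out

    dets = detect_patient(WideModel(), np.zeros((1, 96, 96), dtype=np.uint8), cfg)
    for d in dets:
        assert 0 <= d.box.x1 < d.box.x2 <= 96
        assert 0 <= d.box.y1 < d.box.y2 <= 96


# --- training --------------------------------------------------------------

def _tiny_data(rng, n=8):
    from cmbscreen.phantom import PhantomSpec, generate_patient
    spec = PhantomSpec(slices_per_patient=2, image_side=64, cmb_diameter=(4, 12))
    data = []
    seed = 0
    while len(data) < n:
        rec = generate_patient(spec, seed, force_positive=True)
        for i in range(rec.n_slices):
            img = np.repeat(rec.swi_stack[i][None], 3, 0).astype(np.float32) / 255
            data.append((img, rec.gt_boxes[i]))
        seed += 1
    return data[:n]


def test_train_smoke_and_determinism(rng):
    cfg = DetectorConfig(scale="N", input_size=64, channels=(8, 16, 32, 64), depth=1, seed=3)
    data = _tiny_data(rng)
    m1, t1 = train_detector(build_detector(cfg), data, epochs=1, seed=5, batch_size=4)
    assert all(np.isfinite(row["total"]) for row in t1)
    assert {"total", "cls", "box"} <= set(t1[0])
    m2, t2 = train_detector(build_detector(cfg), data, epochs=1, seed=5, batch_size=4)
    assert [r["total"] for r in t1] == [r["total"] for r in t2]
    assert m1.checksum() == pytest.approx(m2.checksum())


def test_train_rejects_empty_and_bad_epochs():
    cfg = DetectorConfig(scale="N", input_size=64, channels=(8, 16, 32, 64), depth=1)
    with pytest.raises(ValueError):
        train_detector(build_detector(cfg), [], epochs=1, seed=0)
    with pytest.raises(ValueError):
        train_detector(build_detector(cfg), [(np.zeros((3, 64, 64)), [])], epochs=0, seed=0)


def test_tensor_box_loss_matches_scalar_reference(rng):
    # dual route: the autograd loss against the closed-form scalar functions
    for mix in (0.0, 0.5, 1.0):
        pairs, expected = [], []
        for _ in range(10):
            x1, y1 = rng.uniform(0, 20, 2)
            w1, h1 = rng.uniform(1, 8, 2)
            x2, y2 = rng.uniform(0, 20, 2)
            w2, h2 = rng.uniform(1, 8, 2)
            a = Box(x1, y1, x1 + w1, y1 + h1)
            b = Box(x2, y2, x2 + w2, y2 + h2)
            pairs.append((a.as_tuple(), b.as_tuple()))
            expected.append(combined_regression_loss(a, b, NwdConfig(), mix))
        pred = Tensor(np.array([p[0] for p in pairs]), requires_grad=True)
        gt = np.array([p[1] for p in pairs])
        loss = combined_box_loss_tensor(pred, gt, mix)
        assert float(loss.data) == pytest.approx(np.mean(expected), abs=1e-5)
        loss.backward()
        assert np.all(np.isfinite(pred.grad))
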