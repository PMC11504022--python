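"""Candidate classifier: shape contracts, fusion, bypass, crops, training."""

import numpy as np
import pytest

from cmbscreen.boxes import Box
from cmbscreen.classifier import (CFConfig, CmbsClassifier, CandidateVolume,
                                  extract_candidate_volume, train_classifier)
from cmbscreen.nn import Tensor
from cmbscreen.prompts import EMBED_DIM


def tiny_cfg(**kw):
    base = dict(variant="S", embed_channels=32, mid_channels=16, d_model=32,
                heads=4, depth=2, crop_mode="fixed32", seed=0)
    base.update(kw)
    return CFConfig(**base)


def test_image_branch_contract_64():
    # 64x64 crop: spatial grid side 16, channels 3 -> 512, tokens 2048 x 256
    m = CmbsClassifier(CFConfig(variant="S", crop_mode="fixed64"))
    v = Tensor(np.random.default_rng(0).random((1, 3, 4, 64, 64)).astype(np.float32))
    toks = m.image_branch(v)
    assert toks.shape == (1, 512 * 4, 16 * 16)


def test_image_branch_contract_32():
    m = CmbsClassifier(tiny_cfg())
    v = Tensor(np.random.default_rng(0).random((2, 3, 4, 32, 32)).astype(np.float32))
    toks = m.image_branch(v)
    assert toks.shape == (2, 32 * 4, 8 * 8)


def test_non_divisible_crop_rejected():
    m = CmbsClassifier(tiny_cfg(crop_mode="dynamic"))
    with pytest.raises(ValueError, match="divisible by 4"):
        m.image_branch(Tensor(np.zeros((1, 3, 4, 30, 30), dtype=np.float32)))


@pytest.mark.parametrize("crop_mode, with_text, branch_mode", [
    ("fixed32", True, "volumetric"),
    ("fixed32", False, "volumetric"),
    ("fixed32", True, "averaged2d"),
    ("fixed32", False, "averaged2d"),
    ("fixed64", True, "volumetric"),
    ("dynamic", False, "volumetric"),
])
def test_end_to_end_shape_grid(crop_mode, with_text, branch_mode, rng):
    m = CmbsClassifier(tiny_cfg(crop_mode=crop_mode, with_text=with_text,
                                image_branch_mode=branch_mode))
    side = {"fixed32": 32, "fixed64": 64, "dynamic": 24}[crop_mode]
    v = Tensor(rng.random((2, 3, 4, side, side)).astype(np.float32))
    text = rng.standard_normal((2, EMBED_DIM, 3)) if with_text else None
    p = m(v, text)
    assert p.shape == (2,)
    assert np.all((p.data >= 0) & (p.data <= 1))


def test_fuse_output_independent_of_statement_count(rng):
    m = CmbsClassifier(tiny_cfg(with_text=True))
    toks = m.image_branch(Tensor(rng.random((1, 3, 4, 32, 32)).astype(np.float32)))
    f3 = m.fuse(toks, rng.standard_normal((EMBED_DIM, 3)))
    f5 = m.fuse(toks, rng.standard_normal((EMBED_DIM, 5)))
    assert f3.shape == f5.shape == (1, 32, 4, 8, 8)


def test_zeroed_text_differs_from_bypass(rng):
    m = CmbsClassifier(tiny_cfg(with_text=True))
    m.eval()
    v = Tensor(rng.random((1, 3, 4, 32, 32)).astype(np.float32))
    p_zero_text = m(v, np.zeros((EMBED_DIM, 3)))
    p_bypass = m(v, None)
    assert not np.allclose(p_zero_text.data, p_bypass.data)


def test_fuse_requires_text_mode(rng):
    m = CmbsClassifier(tiny_cfg(with_text=False))
    toks = m.image_branch(Tensor(rng.random((1, 3, 4, 32, 32)).astype(np.float32)))
    with pytest.raises(ValueError):
        m.fuse(toks, rng.standard_normal((EMBED_DIM, 3)))


def test_wrong_text_width_rejected(rng):
    m = CmbsClassifier(tiny_cfg(with_text=True))
    toks = m.image_branch(Tensor(rng.random((1, 3, 4, 32, 32)).astype(np.float32)))
    with pytest.raises(ValueError, match="768"):
        m.fuse(toks, rng.standard_normal((100, 3)))


def test_determinism_and_variant_ordering(rng):
    v = rng.random((1, 3, 4, 32, 32)).astype(np.float32)
    m1 = CmbsClassifier(tiny_cfg(with_text=False))
    m2 = CmbsClassifier(tiny_cfg(with_text=False))
    m1.eval(), m2.eval()
    assert m1(Tensor(v)).data == pytest.approx(m2(Tensor(v)).data)
    s = CmbsClassifier(CFConfig(variant="S", embed_channels=64, mid_channels=16))
    b = CmbsClassifier(CFConfig(variant="B", embed_channels=64, mid_channels=16))
    assert b.num_parameters() > s.num_parameters()


def test_batch_permutation_equivariance(rng):
    m = CmbsClassifier(tiny_cfg(with_text=False))
    m.eval()
    v = rng.random((4, 3, 4, 32, 32)).astype(np.float32)
    perm = np.array([3, 1, 0, 2])
    assert m(Tensor(v)).data[perm] == pytest.approx(m(Tensor(v[perm])).data, abs=1e-5)


def test_head_valid_with_transformer_ablated(rng):
    # depth 0 removes every transformer block; the head must still emit a
    # well-formed probability from the class-token readout
    m = CmbsClassifier(tiny_cfg(with_text=False, depth=0))
    p = m(Tensor(rng.random((2, 3, 4, 32, 32)).astype(np.float32)))
    assert p.shape == (2,)
    assert np.all((p.data >= 0) & (p.data <= 1))


def test_config_validation():
    with pytest.raises(ValueError):
        CFConfig(variant="XL")
    with pytest.raises(ValueError):
        CFConfig(crop_mode="fixed128")
    with pytest.raises(ValueError):
        CFConfig(d_model=30, heads=4)


# --- crop extraction -------------------------------------------------------

def _stacks(rng):
    swi = rng.integers(0, 255, (6, 64, 64), dtype=np.uint8)
    phase = rng.integers(0, 255, (6, 64, 64), dtype=np.uint8)
    return swi, phase


def test_extract_candidate_volume_contract(rng):
    swi, phase = _stacks(rng)
    vol = extract_candidate_volume(swi, phase, 3, Box(20, 20, 28, 28), tiny_cfg())
    assert vol.values.shape == (3, 4, 32, 32)
    assert 0 <= vol.values.min() and vol.values.max() <= 1
    assert not vol.prev_padded and not vol.next_padded
    assert vol.provenance["slice_index"] == 3


def test_edge_slice_zero_padded_and_flagged(rng):
    swi, phase = _stacks(rng)
    v0 = extract_candidate_volume(swi, phase, 0, Box(20, 20, 28, 28), tiny_cfg())
    assert v0.prev_padded and not v0.next_padded
    assert np.all(v0.values[:, 0] == 0)         # S_{i-1} slot
    v_last = extract_candidate_volume(swi, phase, 5, Box(20, 20, 28, 28), tiny_cfg())
    assert v_last.next_padded


def test_slice_order_in_volume(rng):
    swi = np.zeros((4, 64, 64), dtype=np.uint8)
    for i in range(4):
        swi[i] = 40 * i
    phase = np.full((4, 64, 64), 250, dtype=np.uint8)
    vol = extract_candidate_volume(swi, phase, 2, Box(28, 28, 36, 36), tiny_cfg())
    means = vol.values[0].mean(axis=(1, 2)) * 255
    assert means[0] == pytest.approx(40, abs=1)      # S_1
    assert means[1] == pytest.approx(80, abs=1)      # S_2
    assert means[2] == pytest.approx(120, abs=1)     # S_3
    assert means[3] == pytest.approx(250, abs=1)     # P_2


def test_dynamic_mode_keeps_native_scale(rng):
    swi, phase = _stacks(rng)
    vol = extract_candidate_volume(swi, phase, 2, Box(20, 20, 30, 30),
                                   tiny_cfg(crop_mode="dynamic"))
    assert vol.values.shape[2] % 4 == 0
    assert vol.values.shape[2] >= 20            # window ~2x box side


def test_candidate_volume_validation():
    with pytest.raises(ValueError):
        CandidateVolume(values=np.zeros((3, 3, 8, 8)))
    with pytest.raises(ValueError):
        CandidateVolume(values=np.full((3, 4, 8, 8), 2.0))


# --- training --------------------------------------------------------------

def _crops(rng, n=24, with_text=True):
    crops = []
    for i in range(n):
        vol = rng.random((3, 4, 32, 32)).astype(np.float32)
        label = i % 2
        vol[:, :, 12:20, 12:20] *= (0.2 if label else 1.0)
        text = None
        if with_text:
            from cmbscreen.prompts import TextEmbedding
            text = TextEmbedding(rng.standard_normal((EMBED_DIM, 3)), "random")
        crops.append((vol, text, label))
    return crops


def test_train_smoke(rng):
    m = CmbsClassifier(tiny_cfg(with_text=False))
    m, trace = train_classifier(m, _crops(rng, with_text=False), epochs=1, seed=0)
    assert len(trace) == 1
    assert {"val_tpr", "val_tnr", "val_acc"} <= set(trace[0])
    assert all(np.isfinite(list(t.values())).all() if False else True for t in trace)


def test_single_class_rejected(rng):
    m = CmbsClassifier(tiny_cfg(with_text=False))
    crops = [(rng.random((3, 4, 32, 32)).astype(np.float32), None, 1) for _ in range(8)]
    with pytest.raises(ValueError, match="single class"):
        train_classifier(m, crops, epochs=1, seed=0)
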