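"""Box geometry: the IoU family and the normalized Wasserstein similarity."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cmbscreen.boxes import (Box, NwdConfig, combined_regression_loss, iou_family,
                             nwd_loss, nwd_similarity, pairwise_iou)

# The worked small/standard box configurations: a 3x3 target one pixel off its
# prediction collapses IoU to 0.29 while the Wasserstein similarity stays 0.9;
# a 24x24 target with the same offset keeps IoU at 0.92.
A, B = Box(0, 0, 3, 3), Box(1, 1, 4, 4)
D, E = Box(0, 0, 24, 24), Box(1, 0, 25, 24)
F = Box(-1, -1, 25, 25)


def raster_iou(a: Box, b: Box, scale: int = 1) -> float:
    """Brute-force oracle: rasterize half-open boxes on an integer grid."""
    xs = [int(v * scale) for v in (a.x1, a.x2, b.x1, b.x2)]
    ys = [int(v * scale) for v in (a.y1, a.y2, b.y1, b.y2)]
    x0, x1 = min(xs), max(xs)
    y0, y1 = min(ys), max(ys)
    ga = np.zeros((y1 - y0, x1 - x0), dtype=bool)
    gb = np.zeros_like(ga)
    ga[int(a.y1 * scale) - y0:int(a.y2 * scale) - y0,
       int(a.x1 * scale) - x0:int(a.x2 * scale) - x0] = True
    gb[int(b.y1 * scale) - y0:int(b.y2 * scale) - y0,
       int(b.x1 * scale) - x0:int(b.x2 * scale) - x0] = True
    return (ga & gb).sum() / (ga | gb).sum()


@pytest.mark.parametrize("a, b, variant, expected", [
    (A, B, "iou", 0.29),
    (A, B, "giou", 0.16),
    (D, E, "iou", 0.92),
    (D, F, "iou", 0.85),
])
def test_worked_configurations(a, b, variant, expected):
    assert round(iou_family(a, b, variant), 2) == pytest.approx(expected)


@pytest.mark.parametrize("variant", ["iou", "giou", "diou", "ciou"])
def test_identity_gives_one(variant):
    assert iou_family(Box(2.5, 3.5, 9, 11), Box(2.5, 3.5, 9, 11), variant) == pytest.approx(1.0)


def test_iou_variant_orderings():
    for a, b in [(A, B), (D, E), (A, Box(5, 5, 9, 9))]:
        iou = iou_family(a, b, "iou")
        assert iou_family(a, b, "diou") <= iou + 1e-12
        assert iou_family(a, b, "ciou") <= iou + 1e-12
        assert -1 < iou_family(a, b, "giou") <= 1


def test_symmetry_iou_giou():
    a, b = Box(0, 0, 5, 7), Box(2, 1, 9, 4)
    for variant in ("iou", "giou"):
        assert iou_family(a, b, variant) == pytest.approx(iou_family(b, a, variant))


def test_giou_equals_iou_when_enclosing_box_is_union_bbox():
    # one-axis offset of equal-height boxes: the enclosing box has no slack
    assert iou_family(D, E, "giou") == pytest.approx(iou_family(D, E, "iou"))


def test_degenerate_box_rejected():
    with pytest.raises(ValueError):
        Box(0, 0, 0, 3)
    with pytest.raises(ValueError):
        Box(5, 0, 3, 3)


def test_unknown_variant_rejected():
    with pytest.raises(ValueError):
        iou_family(A, B, "eiou")


@given(st.integers(0, 12), st.integers(0, 12), st.integers(1, 10), st.integers(1, 10),
       st.integers(0, 12), st.integers(0, 12), st.integers(1, 10), st.integers(1, 10))
@settings(max_examples=60, deadline=None)
def test_raster_oracle_agrees_with_closed_form(x1, y1, w1, h1, x2, y2, w2, h2):
    a = Box(x1, y1, x1 + w1, y1 + h1)
    b = Box(x2, y2, x2 + w2, y2 + h2)
    assert iou_family(a, b, "iou") == pytest.approx(raster_iou(a, b), abs=1e-9)


@given(st.integers(-20, 20), st.integers(-20, 20))
@settings(max_examples=30, deadline=None)
def test_translation_invariance(dx, dy):
    for variant in ("iou", "giou", "diou", "ciou"):
        assert iou_family(A.translated(dx, dy), B.translated(dx, dy), variant) == \
            pytest.approx(iou_family(A, B, variant), abs=1e-9)
    assert nwd_similarity(A.translated(dx, dy), B.translated(dx, dy)) == \
        pytest.approx(nwd_similarity(A, B), abs=1e-9)


# --- NWD -------------------------------------------------------------------

def test_nwd_worked_values():
    # exp(-sqrt(2)/12.8) = 0.895 and exp(-1/12.8) = 0.925; both print as 0.9
    assert nwd_similarity(A, B) == pytest.approx(math.exp(-math.sqrt(2) / 12.8), abs=1e-4)
    assert nwd_similarity(D, E) == pytest.approx(math.exp(-1 / 12.8), abs=1e-4)
    assert round(nwd_similarity(A, B), 1) == pytest.approx(0.9)
    assert round(nwd_similarity(D, E), 1) == pytest.approx(0.9)


def test_nwd_scale_robustness_contrast():
    # same 1-px offset: IoU differs by > 0.5 across scales, NWD by < 0.05
    assert abs(iou_family(A, B, "iou") - iou_family(D, E, "iou")) > 0.5
    assert abs(nwd_similarity(A, B) - nwd_similarity(D, E)) < 0.05


def test_nwd_identity_and_symmetry():
    s = nwd_similarity(A, A)
    assert 1 - 1e-3 <= s < 1.0          # delta keeps it strictly below 1
    assert nwd_similarity(A, B) == pytest.approx(nwd_similarity(B, A))
    assert 0 < nwd_similarity(A, Box(100, 100, 103, 103)) < 1


def test_nwd_loss_limits():
    assert nwd_loss(A, A) == pytest.approx(0.0, abs=1e-3)
    assert nwd_loss(A, B) == pytest.approx(1 - math.exp(-math.sqrt(2) / 12.8), abs=1e-4)
    # monotone increase with center distance
    losses = [nwd_loss(A, A.translated(d, 0)) for d in (1, 5, 20, 100)]
    assert losses == sorted(losses)
    assert losses[-1] > 0.99


def test_nwd_literal_form_saturates_on_one_axis_offsets():
    # the printed product form cannot see a pure x-offset
    assert nwd_similarity(D, E, literal=True) > 0.99
    assert nwd_similarity(D, E) < 0.93


def test_nwd_config_validation():
    with pytest.raises(ValueError):
        NwdConfig(C=0.0)
    with pytest.raises(ValueError):
        NwdConfig(delta=0.5)


# --- combined regression loss ---------------------------------------------

def test_combined_loss_reductions(rng):
    for _ in range(20):
        x1, y1 = rng.uniform(0, 20, 2)
        w1, h1 = rng.uniform(1, 10, 2)
        x2, y2 = rng.uniform(0, 20, 2)
        w2, h2 = rng.uniform(1, 10, 2)
        a, b = Box(x1, y1, x1 + w1, y1 + h1), Box(x2, y2, x2 + w2, y2 + h2)
        assert combined_regression_loss(a, b, mix=0.0) == \
            pytest.approx(1 - iou_family(a, b, "ciou"), abs=1e-12)
        assert combined_regression_loss(a, b, mix=1.0) == \
            pytest.approx(nwd_loss(a, b), abs=1e-12)
    assert combined_regression_loss(A, A, mix=0.3) == pytest.approx(0.0, abs=1e-3)


def test_combined_loss_mix_validation():
    with pytest.raises(ValueError):
        combined_regression_loss(A, B, mix=1.5)


def test_small_target_size_perturbation_gentler_under_nwd():
    # growing the predicted box by 2 px moves the NWD loss much less than the
    # IoU-based loss for a 3x3 target
    c = Box(1, 1, 6, 6)
    d_iou = abs(iou_family(A, B, "iou") - iou_family(A, c, "iou"))
    d_nwd = abs(nwd_similarity(A, B) - nwd_similarity(A, c))
    assert d_nwd < d_iou


def test_pairwise_iou_matches_scalar(rng):
    boxes_a = rng.uniform(0, 10, (5, 2))
    a = np.hstack([boxes_a, boxes_a + rng.uniform(1, 5, (5, 2))])
    boxes_b = rng.uniform(0, 10, (4, 2))
    b = np.hstack([boxes_b, boxes_b + rng.uniform(1, 5, (4, 2))])
    mat = pairwise_iou(a, b)
    for i in range(5):
        for j in range(4):
            assert mat[i, j] == pytest.approx(
                iou_family(Box(*a[i]), Box(*b[j]), "iou"), abs=1e-12)
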