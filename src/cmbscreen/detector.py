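"""Lightweight anchor-free single-stage detector for microbleed candidates.

The detector follows the familiar single-stage recipe — a convolutional
backbone with residual (C2f-style) blocks, a top-down fusion neck, and a
decoupled head predicting an objectness logit and a distribution-free
left/top/right/bottom box offset at every cell of two feature levels
(strides 4 and 8, sized for 4-32 px targets).  Saliency attention blocks can
be inserted after the last backbone stages and after each neck merge.

The box-regression loss is the combined CIoU + normalized-Wasserstein loss:
``(1-mix)*(1-CIoU) + mix*(1-NWD)``.  ``mix=0`` is the plain CIoU baseline.

Scales N/S/M/X6 reuse the usual depth/width multipliers of the baseline
family; matching any published parameter count is not attempted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .attention import SaliencyAttention, SaliencyAttentionConfig
from .boxes import Box, NwdConfig, pairwise_iou
from .nn import (Adam, BatchNorm2d, Conv2d, Module, ModuleList, Tensor,
                 bilinear_resize, clip_grad_norm, concatenate, maximum, minimum)

__all__ = ["DetectorConfig", "Detection", "CmbDetector", "build_detector",
           "train_detector", "detect_patient", "nms", "combined_box_loss_tensor"]

_SCALES = {"N": (0.34, 0.25), "S": (0.34, 0.50), "M": (0.67, 0.75), "X6": (1.0, 1.25)}
_BASE_CHANNELS = (64, 128, 256, 512)   # stem, P2, P3, P4 before width multiplier
_BASE_DEPTH = 2


@dataclass(frozen=True)
class DetectorConfig:
    scale: str = "N"
    input_size: int = 512
    num_classes: int = 1
    with_attention: bool = True
    attention_heads: int = 4
    nms_iou: float = 0.5
    score_threshold: float = 0.25
    max_candidates_per_patient: int = 100
    nwd_mix: float = 0.5
    seed: int = 0
    # overrides for desk-scale experiments; None keeps the scale defaults
    channels: tuple[int, int, int, int] | None = None
    depth: int | None = None

    def __post_init__(self) -> None:
        if self.scale not in _SCALES:
            raise ValueError(f"unknown scale {self.scale!r}; expected one of {sorted(_SCALES)}")
        if self.input_size % 32:
            raise ValueError("input_size must be divisible by 32")
        for t in (self.nms_iou,):
            if not 0 < t < 1:
                raise ValueError("nms_iou must be in (0, 1)")
        if not 0 <= self.score_threshold <= 1:
            raise ValueError("score_threshold must be in [0, 1]")
        if not 0 <= self.nwd_mix <= 1:
            raise ValueError("nwd_mix must be in [0, 1]")

    def resolved_channels(self) -> tuple[int, int, int, int]:
        if self.channels is not None:
            return self.channels
        _, wm = _SCALES[self.scale]
        return tuple(max(8, int(round(c * wm / 8)) * 8) for c in _BASE_CHANNELS)

    def resolved_depth(self) -> int:
        if self.depth is not None:
            return self.depth
        dm, _ = _SCALES[self.scale]
        return max(1, round(_BASE_DEPTH * dm))


@dataclass(frozen=True)
class Detection:
    slice_index: int
    box: Box
    score: float

    def to_coco(self) -> dict:
        x, y, w, h = self.box.as_xywh()
        return {"slice_index": self.slice_index, "bbox": [x, y, w, h],
                "score": self.score, "category_id": 0}


class ConvBlock(Module):
    def __init__(self, c_in: int, c_out: int, rng, k: int = 3, stride: int = 1):
        super().__init__()
        self.conv = Conv2d(c_in, c_out, k, rng, stride=stride, bias=False)
        self.bn = BatchNorm2d(c_out)

    def forward(self, x):
        return self.bn(self.conv(x)).silu()


class ResidualStage(Module):
    """n bottleneck blocks with residual connections (C2f-style, simplified)."""

    def __init__(self, c: int, n: int, rng):
        super().__init__()
        self.blocks = ModuleList([ConvBlock(c, c, rng) for _ in range(2 * n)])

    def forward(self, x):
        for i in range(0, len(self.blocks), 2):
            x = x + self.blocks[i + 1](self.blocks[i](x))
        return x


class Head(Module):
    """Decoupled objectness / box head for one feature level."""

    def __init__(self, c: int, rng):
        super().__init__()
        self.cls_conv = ConvBlock(c, c, rng)
        self.cls_out = Conv2d(c, 1, 1, rng)
        self.reg_conv = ConvBlock(c, c, rng)
        self.reg_out = Conv2d(c, 4, 1, rng)
        # bias objectness towards "background" at init for stable early training
        self.cls_out.b.data[:] = -3.0

    def forward(self, x):
        return self.cls_out(self.cls_conv(x)), self.reg_out(self.reg_conv(x))


class CmbDetector(Module):
    """Backbone + fusion neck + per-level heads; detection levels at strides 4 and 8."""

    strides = (4, 8)

    def __init__(self, cfg: DetectorConfig):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        c1, c2, c3, c4 = cfg.resolved_channels()
        n = cfg.resolved_depth()
        self.stem = ConvBlock(3, c1, rng, stride=2)                 # /2
        self.down1 = ConvBlock(c1, c2, rng, stride=2)               # /4
        self.stage1 = ResidualStage(c2, n, rng)
        self.down2 = ConvBlock(c2, c3, rng, stride=2)               # /8
        self.stage2 = ResidualStage(c3, n, rng)
        self.down3 = ConvBlock(c3, c4, rng, stride=2)               # /16
        self.stage3 = ResidualStage(c4, n, rng)

        def att(c, stride):
            heads = cfg.attention_heads if c % cfg.attention_heads == 0 else 1
            fmap = cfg.input_size // stride
            return SaliencyAttention(
                SaliencyAttentionConfig(channels=c, heads=heads,
                                        query_grid=min(4, fmap), key_grid=min(8, fmap)),
                rng)

        if cfg.with_attention:
            # after the last two backbone stages and after each neck merge
            self.att_backbone_p3 = att(c3, 8)
            self.att_backbone_p4 = att(c4, 16)
            self.att_neck_p3 = att(c3, 8)
            self.att_neck_p2 = att(c2, 4)
        self.neck_p3 = ConvBlock(c4 + c3, c3, rng)
        self.neck_p2 = ConvBlock(c3 + c2, c2, rng)
        self.head_p2 = Head(c2, rng)
        self.head_p3 = Head(c3, rng)

    def forward(self, x: Tensor) -> list[dict]:
        """x: (B, 3, H, W) in [0, 1].  Returns per-level dicts with cls/reg maps."""
        cfg = self.cfg
        p1 = self.stem(x)
        p2 = self.stage1(self.down1(p1))
        p3 = self.stage2(self.down2(p2))
        if cfg.with_attention:
            p3 = self.att_backbone_p3(p3)
        p4 = self.stage3(self.down3(p3))
        if cfg.with_attention:
            p4 = self.att_backbone_p4(p4)
        up3 = bilinear_resize(p4, p3.shape[2:], mode="nearest")
        n3 = self.neck_p3(concatenate([up3, p3], axis=1))
        if cfg.with_attention:
            n3 = self.att_neck_p3(n3)
        up2 = bilinear_resize(n3, p2.shape[2:], mode="nearest")
        n2 = self.neck_p2(concatenate([up2, p2], axis=1))
        if cfg.with_attention:
            n2 = self.att_neck_p2(n2)
        out = []
        for feat, head, stride in ((n2, self.head_p2, 4), (n3, self.head_p3, 8)):
            cls, reg = head(feat)
            out.append({"cls": cls, "reg": reg, "stride": stride})
        return out


def build_detector(cfg: DetectorConfig) -> CmbDetector:
    return CmbDetector(cfg)


# --- decoding / NMS --------------------------------------------------------

def _cell_centers(h: int, w: int, stride: int) -> tuple[np.ndarray, np.ndarray]:
    cx = (np.arange(w) + 0.5) * stride
    cy = (np.arange(h) + 0.5) * stride
    return np.meshgrid(cx, cy)


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def decode_level(cls: np.ndarray, reg: np.ndarray, stride: int) -> tuple[np.ndarray, np.ndarray]:
    """cls: (1, h, w) logits; reg: (4, h, w).  Returns (boxes (N,4), scores (N,))."""
    _, h, w = cls.shape
    cx, cy = _cell_centers(h, w, stride)
    ltrb = _softplus(reg) * stride
    x1 = (cx - ltrb[0]).ravel()
    y1 = (cy - ltrb[1]).ravel()
    x2 = (cx + ltrb[2]).ravel()
    y2 = (cy + ltrb[3]).ravel()
    scores = (1.0 / (1.0 + np.exp(-cls[0]))).ravel()
    return np.stack([x1, y1, x2, y2], axis=1), scores


def nms(boxes: np.ndarray, scores: np.ndarray, iou_threshold: float) -> np.ndarray:
    """Greedy class-agnostic NMS; returns kept indices (deterministic tie-break:
    higher score first, ties by lexicographic box coordinates)."""
    if len(boxes) == 0:
        return np.empty(0, dtype=int)
    order = np.lexsort((boxes[:, 3], boxes[:, 2], boxes[:, 1], boxes[:, 0], -scores))
    keep = []
    suppressed = np.zeros(len(boxes), dtype=bool)
    iou = pairwise_iou(boxes, boxes)
    for i in order:
        if suppressed[i]:
            continue
        keep.append(i)
        suppressed |= iou[i] > iou_threshold
        suppressed[i] = True
    return np.asarray(keep, dtype=int)


def _prepare_stack(swi_stack: np.ndarray) -> np.ndarray:
    """(S, H, W) or (S, 3, H, W) in 0-255 -> (S, 3, H, W) float32 in [0, 1]."""
    arr = np.asarray(swi_stack)
    if arr.ndim == 3:
        arr = np.repeat(arr[:, None], 3, axis=1)
    return (arr.astype(np.float32) / 255.0).clip(0, 1)


def detect_patient(model, swi_stack: np.ndarray,
                   cfg: DetectorConfig | None = None,
                   batch_size: int = 8) -> list[Detection]:
    """Per-slice inference + NMS + global truncation to the candidate budget.

    ``model`` is any callable mapping a (B, 3, H, W) tensor to per-level
    cls/reg maps (normally a :class:`CmbDetector`).
    """
    arr = _prepare_stack(swi_stack)
    if arr.shape[0] == 0:
        raise ValueError("empty slice stack")
    cfg = cfg or getattr(model, "cfg", None) or DetectorConfig()
    H, W = arr.shape[2], arr.shape[3]
    if isinstance(model, Module):
        model.eval()
    detections: list[Detection] = []
    for lo in range(0, arr.shape[0], batch_size):
        chunk = arr[lo:lo + batch_size]
        levels = model(Tensor(chunk))
        for bi in range(chunk.shape[0]):
            boxes_all, scores_all = [], []
            for lvl in levels:
                b, s = decode_level(lvl["cls"].data[bi], lvl["reg"].data[bi], lvl["stride"])
                boxes_all.append(b)
                scores_all.append(s)
            boxes = np.concatenate(boxes_all)
            scores = np.concatenate(scores_all)
            mask = scores >= cfg.score_threshold
            boxes, scores = boxes[mask], scores[mask]
            boxes[:, [0, 2]] = boxes[:, [0, 2]].clip(0, W)
            boxes[:, [1, 3]] = boxes[:, [1, 3]].clip(0, H)
            ok = (boxes[:, 2] - boxes[:, 0] > 1e-3) & (boxes[:, 3] - boxes[:, 1] > 1e-3)
            boxes, scores = boxes[ok], scores[ok]
            keep = nms(boxes, scores, cfg.nms_iou)
            for i in keep:
                detections.append(Detection(lo + bi, Box(*boxes[i]), float(scores[i])))
    detections.sort(key=lambda d: (-d.score, d.slice_index, d.box.as_tuple()))
    return detections[:cfg.max_candidates_per_patient]


# --- training --------------------------------------------------------------

def combined_box_loss_tensor(pred: Tensor, gt: np.ndarray, mix: float,
                             nwd_cfg: NwdConfig = NwdConfig()) -> Tensor:
    """Differentiable combined CIoU + NWD loss, mean over (N, 4) box pairs.

    ``pred`` is an (N, 4) tensor of (x1, y1, x2, y2); ``gt`` a matching array.
    """
    g = Tensor(gt.astype(pred.data.dtype))
    eps = 1e-9
    px1, py1, px2, py2 = pred[:, 0], pred[:, 1], pred[:, 2], pred[:, 3]
    gx1, gy1, gx2, gy2 = g[:, 0], g[:, 1], g[:, 2], g[:, 3]
    pw, ph = px2 - px1, py2 - py1
    gw, gh = gx2 - gx1, gy2 - gy1
    iw = (minimum(px2, gx2) - maximum(px1, gx1)).relu()
    ih = (minimum(py2, gy2) - maximum(py1, gy1)).relu()
    inter = iw * ih
    union = pw * ph + gw * gh - inter
    iou = inter / (union + eps)
    ex1, ey1 = minimum(px1, gx1), minimum(py1, gy1)
    ex2, ey2 = maximum(px2, gx2), maximum(py2, gy2)
    rho2 = ((px1 + px2 - gx1 - gx2) * 0.5) ** 2.0 + ((py1 + py2 - gy1 - gy2) * 0.5) ** 2.0
    diag2 = (ex2 - ex1) ** 2.0 + (ey2 - ey1) ** 2.0 + eps
    v = (4.0 / math.pi ** 2) * ((pw / (ph + eps)).arctan() - (gw / (gh + eps)).arctan()) ** 2.0
    alpha = Tensor(v.data / (1.0 - iou.data + v.data + eps))    # detached, per CIoU convention
    ciou = iou - rho2 / diag2 - alpha * v
    ciou_loss = 1.0 - ciou

    delta = nwd_cfg.delta
    d2 = (((px1 + px2 - gx1 - gx2) * 0.5) ** 2.0 + delta
          + ((py1 + py2 - gy1 - gy2) * 0.5) ** 2.0 + delta
          + ((pw - gw) * 0.5) ** 2.0 + delta
          + ((ph - gh) * 0.5) ** 2.0 + delta)
    nwd_loss_t = 1.0 - (-(d2 ** 0.5) * (1.0 / nwd_cfg.C)).exp()
    loss = (1.0 - mix) * ciou_loss + mix * nwd_loss_t
    return loss.mean()


def _assign_targets(levels: list[dict], gt_boxes: Sequence[Box], img_index: int,
                    size_split: float = 24.0) -> list[tuple]:
    """Center-based assignment.  For each GT pick a level by box size, mark the
    cell containing the box center (plus in-box neighbours within 1.5 cells)."""
    assignments = []   # (level_idx, row, col, gt_array)
    for b in gt_boxes:
        side = math.sqrt(b.area)
        li = 0 if side < size_split else 1
        stride = levels[li]["stride"]
        _, _, h, w = levels[li]["cls"].shape
        cx, cy = b.center
        col0 = min(max(int(cx / stride), 0), w - 1)
        row0 = min(max(int(cy / stride), 0), h - 1)
        cells = {(row0, col0)}
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                r, c = row0 + dr, col0 + dc
                if 0 <= r < h and 0 <= c < w:
                    ccx, ccy = (c + 0.5) * stride, (r + 0.5) * stride
                    if (b.x1 <= ccx <= b.x2 and b.y1 <= ccy <= b.y2
                            and abs(ccx - cx) <= 1.5 * stride and abs(ccy - cy) <= 1.5 * stride):
                        cells.add((r, c))
        arr = np.array(b.as_tuple(), dtype=np.float32)
        for r, c in cells:
            assignments.append((li, img_index, r, c, arr))
    return assignments


def detection_loss(levels: list[dict], batch_gt: Sequence[Sequence[Box]],
                   mix: float, nwd_cfg: NwdConfig = NwdConfig()) -> tuple[Tensor, Tensor, Tensor]:
    """Returns (total, cls_loss, box_loss) for one forward pass."""
    assignments: list[tuple] = []
    for bi, gtb in enumerate(batch_gt):
        assignments.extend(_assign_targets(levels, gtb, bi))

    # classification: balanced BCE-with-logits over every cell of every level
    cls_terms_pos, cls_terms_neg = [], []
    targets = []
    for li, lvl in enumerate(levels):
        t = np.zeros(lvl["cls"].shape, dtype=np.float32)
        targets.append(t)
    for li, bi, r, c, _ in assignments:
        targets[li][bi, 0, r, c] = 1.0
    cls_loss = None
    for lvl, t in zip(levels, targets):
        logit = lvl["cls"]
        # softplus(x) - t*x is BCE-with-logits
        per_cell = logit.softplus() - Tensor(t) * logit
        npos = max(t.sum(), 1.0)
        nneg = max(t.size - t.sum(), 1.0)
        pos = (per_cell * Tensor(t)).sum() * (1.0 / npos)
        neg = (per_cell * Tensor(1.0 - t)).sum() * (1.0 / nneg)
        term = pos + neg
        cls_loss = term if cls_loss is None else cls_loss + term

    if not assignments:
        zero = Tensor(np.zeros(()), requires_grad=False)
        return cls_loss, cls_loss, zero

    # box regression on positive cells
    pred_rows, gt_rows = {0: [], 1: []}, {0: [], 1: []}
    for li, bi, r, c, gt in assignments:
        gt_rows[li].append(gt)
        pred_rows[li].append((bi, r, c))
    box_loss = None
    n_levels_used = 0
    for li, lvl in enumerate(levels):
        if not gt_rows[li]:
            continue
        stride = lvl["stride"]
        idx = np.array(pred_rows[li])
        bi_idx, r_idx, c_idx = idx[:, 0], idx[:, 1], idx[:, 2]
        reg = lvl["reg"]
        sel = reg.transpose(0, 2, 3, 1)[bi_idx, r_idx, c_idx]    # (n, 4)
        ltrb = sel.softplus() * float(stride)
        ccx = ((c_idx + 0.5) * stride).astype(np.float32)
        ccy = ((r_idx + 0.5) * stride).astype(np.float32)
        cx_t, cy_t = Tensor(ccx), Tensor(ccy)
        x1 = cx_t - ltrb[:, 0]
        y1 = cy_t - ltrb[:, 1]
        x2 = cx_t + ltrb[:, 2]
        y2 = cy_t + ltrb[:, 3]
        from .nn.tensor import stack as _stack
        pred = _stack([x1, y1, x2, y2], axis=1)
        term = combined_box_loss_tensor(pred, np.stack(gt_rows[li]), mix, nwd_cfg)
        box_loss = term if box_loss is None else box_loss + term
        n_levels_used += 1
    box_loss = box_loss * (1.0 / n_levels_used)
    total = cls_loss + box_loss
    return total, cls_loss, box_loss


def train_detector(model: CmbDetector, dataset: Sequence[tuple[np.ndarray, Sequence[Box]]],
                   epochs: int, seed: int, batch_size: int = 8, lr: float = 2e-3,
                   max_steps: int | None = None) -> tuple[CmbDetector, list[dict]]:
    """Seeded training loop.

    ``dataset`` yields ``(image, gt_boxes)`` with image (3, H, W) float in [0, 1].
    Returns the model and a per-step loss trace with the box-regression
    component reported separately.
    """
    if epochs < 1:
        raise ValueError("epochs must be >= 1")
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    rng = np.random.default_rng(seed)
    opt = Adam(model.parameters(), lr=lr)
    mix = model.cfg.nwd_mix
    trace: list[dict] = []
    step = 0
    model.train()
    for epoch in range(epochs):
        order = rng.permutation(len(dataset))
        for lo in range(0, len(order), batch_size):
            idx = order[lo:lo + batch_size]
            imgs = np.stack([dataset[i][0] for i in idx]).astype(np.float32)
            gts = [dataset[i][1] for i in idx]
            levels = model(Tensor(imgs, requires_grad=False))
            total, cls_l, box_l = detection_loss(levels, gts, mix)
            opt.zero_grad()
            total.backward()
            clip_grad_norm(model.parameters(), 10.0)
            opt.step()
            trace.append({"step": step, "epoch": epoch, "total": float(total.data),
                          "cls": float(cls_l.data), "box": float(box_l.data)})
            step += 1
            if max_steps is not None and step >= max_steps:
                return model, trace
    return model, trace
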