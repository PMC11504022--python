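"""Multimodal candidate classifier: 3D image branch, text branch, fusion, transformer head.

A candidate region from the detector is classified using a 4-slice volume —
the SWI slices above/at/below the detection plus the matching phase slice —
optionally fused with encoded clinical text prompts (demographics, candidate
geometry, adjacent-slice detection status).

Image branch: two 3D convolution blocks with spatial stride 2 each (temporal
stride 1); batchnorm + GELU after the first, batchnorm only after the second;
an additive position embedding; then a reshape that merges channels x slices
into the token-channel axis and flattens space.  For a 64x64 crop the spatial
grid side falls 64 -> 16 and channels rise 3 -> 512.

Fusion: each 768-wide text statement vector is linearly projected to the
image token-channel width, aggregated over statements (mean — the output
shape is independent of the number of statements), broadcast along the token
axis, concatenated with the image tokens along the channel axis, and mixed by
a kernel-1 1-D convolution over tokens; the result is reshaped back to a
(B, C, T, H', W') volume.  With ``with_text=False`` fusion is bypassed
entirely and the image tokens flow straight to the head.

Head: a 3D convolution over the fused volume, flattening to a token sequence,
a class token + position encoding, a stack of transformer encoder blocks, and
a sigmoid readout of the class token.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .boxes import Box
from .nn import (Adam, BatchNorm2d, BatchNorm3d, Conv1d, Conv2d, Conv3d, LayerNorm, Linear, Module,
                 ModuleList, Tensor, TransformerBlock, clip_grad_norm, concatenate)
from .prompts import EMBED_DIM, TextEmbedding

__all__ = ["CandidateVolume", "CFConfig", "ClassificationResult", "CmbsClassifier",
           "extract_candidate_volume", "train_classifier"]

_VARIANTS = {"S": {"depth": 4, "d_model": 64}, "B": {"depth": 8, "d_model": 128}}
_CROP_SIDES = {"fixed32": 32, "fixed64": 64}


@dataclass(frozen=True)
class CFConfig:
    variant: str = "S"
    embed_channels: int = 512
    mid_channels: int = 128
    heads: int = 8
    depth: int | None = None
    d_model: int | None = None
    with_text: bool = True
    crop_mode: str = "fixed64"            # fixed32 | fixed64 | dynamic
    image_branch_mode: str = "volumetric"  # volumetric | averaged2d
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variant not in _VARIANTS:
            raise ValueError(f"variant must be one of {sorted(_VARIANTS)}")
        if self.crop_mode not in ("fixed32", "fixed64", "dynamic"):
            raise ValueError(f"bad crop_mode {self.crop_mode!r}")
        if self.image_branch_mode not in ("volumetric", "averaged2d"):
            raise ValueError(f"bad image_branch_mode {self.image_branch_mode!r}")
        d = self.resolved_d_model()
        if d % self.heads:
            raise ValueError(f"d_model {d} not divisible by heads {self.heads}")
        if self.embed_channels % self.heads:
            raise ValueError("embed_channels must be divisible by heads")

    def resolved_depth(self) -> int:
        return self.depth if self.depth is not None else _VARIANTS[self.variant]["depth"]

    def resolved_d_model(self) -> int:
        return self.d_model if self.d_model is not None else _VARIANTS[self.variant]["d_model"]

    @property
    def crop_side(self) -> int | None:
        return _CROP_SIDES.get(self.crop_mode)


@dataclass
class CandidateVolume:
    """(3, 4, H, W) float array in [0, 1]; slice order (S_{i-1}, S_i, S_{i+1}, P_i)."""

    values: np.ndarray
    prev_padded: bool = False
    next_padded: bool = False
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 4 or v.shape[0] != 3 or v.shape[1] != 4:
            raise ValueError(f"candidate volume must be (3, 4, H, W), got {v.shape}")
        if v.min() < -1e-6 or v.max() > 1.0 + 1e-6:
            raise ValueError("candidate volume values must lie in [0, 1]")


@dataclass(frozen=True)
class ClassificationResult:
    probability: float
    label: bool
    provenance: dict

    def __post_init__(self) -> None:
        if not np.isfinite(self.probability):
            raise ValueError("probability must be finite")


def _sinusoidal(n: int, d: int) -> np.ndarray:
    pos = np.arange(n)[:, None]
    i = np.arange(d)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / d)
    enc = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
    return enc.astype(np.float32)


class CmbsClassifier(Module):
    def __init__(self, cfg: CFConfig):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        mid, emb = cfg.mid_channels, cfg.embed_channels
        if cfg.image_branch_mode == "volumetric":
            self.conv1 = Conv3d(3, mid, 3, rng, stride=(1, 2, 2))
            self.conv2 = Conv3d(mid, emb, 3, rng, stride=(1, 2, 2))
            self.bn1 = BatchNorm3d(mid)
            self.bn2 = BatchNorm3d(emb)
        else:
            self.conv1 = Conv2d(3, mid, 3, rng, stride=2)
            self.conv2 = Conv2d(mid, emb, 3, rng, stride=2)
            self.bn1 = BatchNorm2d(mid)
            self.bn2 = BatchNorm2d(emb)
        self._pos_cache: dict[tuple, Tensor] = {}
        self.pos_embedding: Tensor | None = None
        if cfg.crop_side is not None:
            g = cfg.crop_side // 4
            t = 4 if cfg.image_branch_mode == "volumetric" else 1
            self.pos_embedding = Tensor(
                (rng.standard_normal((1, emb, t, g, g)) * 0.02).astype(np.float32),
                requires_grad=True)

        d = cfg.resolved_d_model()
        # LayerNorm after projection puts text features on the image-token
        # scale; without it the normalized hash embeddings are ~20x weaker
        # than the batchnormed image tokens and the fusion path starves
        self.text_proj = Linear(EMBED_DIM, self.token_channels, rng) if cfg.with_text else None
        self.text_norm = LayerNorm(self.token_channels) if cfg.with_text else None
        self.fuse_conv = (Conv1d(2 * self.token_channels, self.token_channels, 1, rng)
                          if cfg.with_text else None)
        self.head_conv = Conv3d(self.token_channels // self.t_slices, d, 3, rng,
                                stride=(1, 2, 2))
        self.cls_token = Tensor((rng.standard_normal((1, 1, d)) * 0.02).astype(np.float32),
                                requires_grad=True)
        self.blocks = ModuleList([TransformerBlock(d, cfg.heads, rng)
                                  for _ in range(cfg.resolved_depth())])
        self.head = Linear(d, 1, rng)

    # -- dimensions --------------------------------------------------------
    @property
    def t_slices(self) -> int:
        return 4 if self.cfg.image_branch_mode == "volumetric" else 1

    @property
    def token_channels(self) -> int:
        return self.cfg.embed_channels * self.t_slices

    # -- stages ------------------------------------------------------------
    def image_branch(self, v: Tensor) -> Tensor:
        """(B, 3, 4, H, W) -> (B, embed*T, (H/4)*(W/4)) token matrix."""
        cfg = self.cfg
        B = v.shape[0]
        H, W = v.shape[-2], v.shape[-1]
        if H % 4 or W % 4:
            raise ValueError(f"crop side must be divisible by 4, got ({H}, {W})")
        if cfg.image_branch_mode == "averaged2d":
            v = v.mean(axis=2)                       # collapse the slice axis
            x = self.bn1(self.conv1(v)).gelu()
            x = self.bn2(self.conv2(x))
            x = x.reshape(B, cfg.embed_channels, 1, H // 4, W // 4)
        else:
            x = self.bn1(self.conv1(v)).gelu()
            x = self.bn2(self.conv2(x))
        x = x + self._position_embedding(x.shape)
        B, C, T, Hq, Wq = x.shape
        return x.reshape(B, C * T, Hq * Wq)

    def _position_embedding(self, shape) -> Tensor:
        _, C, T, Hq, Wq = shape
        if self.pos_embedding is not None and self.pos_embedding.shape[1:] == (C, T, Hq, Wq):
            return self.pos_embedding
        key = (C, T, Hq, Wq)
        if key not in self._pos_cache:
            enc = _sinusoidal(T * Hq * Wq, C).T.reshape(1, C, T, Hq, Wq) * 0.02
            self._pos_cache[key] = Tensor(enc.astype(np.float32))
        return self._pos_cache[key]

    def fuse(self, image_tokens: Tensor, text: TextEmbedding | np.ndarray) -> Tensor:
        """Mix projected text into the token sequence; output shape equals input shape
        reinterpreted as a (B, C, T, H', W') volume and is independent of n."""
        if not self.cfg.with_text:
            raise ValueError("fuse requires with_text=True; use the image-only bypass")
        mat = text.matrix if isinstance(text, TextEmbedding) else np.asarray(text)
        if mat.ndim == 2:
            mat = mat[None]
        if mat.shape[1] != EMBED_DIM:
            raise ValueError(f"text width must be {EMBED_DIM}, got {mat.shape[1]}")
        B, Ctok, L = image_tokens.shape
        cols = Tensor(mat.astype(np.float32).transpose(0, 2, 1))   # (B, n, 768)
        proj = self.text_proj(cols)                                 # (B, n, Ctok)
        pooled = self.text_norm(proj.mean(axis=1)).reshape(B, Ctok, 1)  # statement-mean
        tiled = pooled * Tensor(np.ones((1, 1, L), dtype=np.float32))
        mixed = self.fuse_conv(concatenate([image_tokens, tiled], axis=1))
        return self._to_volume(mixed)

    def _to_volume(self, tokens: Tensor) -> Tensor:
        B, Ctok, L = tokens.shape
        T = self.t_slices
        side = int(round(np.sqrt(L)))
        return tokens.reshape(B, Ctok // T, T, side, side)

    def classify(self, fused: Tensor) -> Tensor:
        """(B, C, T, H', W') -> (B,) probability tensor."""
        x = self.head_conv(fused).gelu()             # (B, d, T, H'', W'')
        B, d, T, Hq, Wq = x.shape
        toks = x.reshape(B, d, T * Hq * Wq).transpose(0, 2, 1)     # (B, L, d)
        cls = self.cls_token * Tensor(np.ones((B, 1, 1), dtype=np.float32))
        seq = concatenate([cls, toks], axis=1)
        pe = Tensor(_sinusoidal(seq.shape[1], d)[None] * 0.1)
        seq = seq + pe
        for blk in self.blocks:
            seq = blk(seq)
        logit = self.head(seq[:, 0])
        return logit.sigmoid().reshape(B)

    def forward(self, volume: Tensor, text: TextEmbedding | np.ndarray | None = None) -> Tensor:
        tokens = self.image_branch(volume)
        if self.cfg.with_text and text is not None:
            vol = self.fuse(tokens, text)
        else:
            vol = self._to_volume(tokens)
        return self.classify(vol)

    def predict(self, volume: CandidateVolume, text: TextEmbedding | None = None,
                threshold: float = 0.5) -> ClassificationResult:
        self.eval()
        p = float(self.forward(Tensor(volume.values[None].astype(np.float32)), text).data[0])
        return ClassificationResult(probability=p, label=p >= threshold,
                                    provenance=dict(volume.provenance))


# --- crop extraction -------------------------------------------------------

def _resize2d(img: np.ndarray, side: int) -> np.ndarray:
    if img.shape == (side, side):
        return img
    return ndimage.zoom(img, (side / img.shape[0], side / img.shape[1]), order=1)


def extract_candidate_volume(swi_stack: np.ndarray, phase_stack: np.ndarray,
                             slice_index: int, box: Box, cfg: CFConfig) -> CandidateVolume:
    """Crop the (S_{i-1}, S_i, S_{i+1}, P_i) volume around a candidate box.

    The window is centered on the integer-rounded box center with side
    ``max(2 * max(w, h), 8)`` px; out-of-bounds regions and missing neighbour
    slices are zero-padded (and flagged).  Fixed crop modes resize the window
    bilinearly to the configured side; dynamic mode keeps the native window,
    padded up to a multiple of 4.
    """
    S, H, W = swi_stack.shape
    cx, cy = (int(round(c)) for c in box.center)
    win = int(max(2 * max(box.width, box.height), 8))
    if cfg.crop_side is not None:
        target = cfg.crop_side
    else:
        target = max(8, int(np.ceil(win / 4)) * 4)
    half = win // 2

    def crop(plane: np.ndarray | None) -> np.ndarray:
        out = np.zeros((win, win), dtype=np.float64)
        if plane is None:
            return out
        x0, y0 = cx - half, cy - half
        sx0, sy0 = max(0, x0), max(0, y0)
        sx1, sy1 = min(W, x0 + win), min(H, y0 + win)
        if sx1 > sx0 and sy1 > sy0:
            out[sy0 - y0:sy1 - y0, sx0 - x0:sx1 - x0] = plane[sy0:sy1, sx0:sx1]
        return out

    prev_plane = swi_stack[slice_index - 1] if slice_index - 1 >= 0 else None
    next_plane = swi_stack[slice_index + 1] if slice_index + 1 < S else None
    planes = [crop(prev_plane), crop(swi_stack[slice_index]),
              crop(next_plane), crop(phase_stack[slice_index])]
    planes = [_resize2d(p, target) for p in planes]
    vol = np.stack(planes, axis=0) / 255.0                      # (4, side, side)
    vol = np.repeat(vol[None], 3, axis=0).clip(0, 1)            # (3, 4, side, side)
    return CandidateVolume(values=vol.astype(np.float32),
                           prev_padded=prev_plane is None,
                           next_padded=next_plane is None,
                           provenance={"slice_index": slice_index, "box": box.as_tuple()})


# --- training --------------------------------------------------------------

def train_classifier(model: CmbsClassifier,
                     crops: Sequence[tuple[np.ndarray, TextEmbedding | None, int]],
                     epochs: int, seed: int, batch_size: int = 16, lr: float = 1e-3,
                     val_fraction: float = 0.25) -> tuple[CmbsClassifier, list[dict]]:
    """Seeded training with class-imbalance weighting.

    ``crops`` yields (volume (3, 4, H, W) float [0, 1], text or None, label in {0, 1}).
    Returns the model and a per-epoch trace with validation TPR/TNR/accuracy.
    """
    if epochs < 1:
        raise ValueError("epochs must be >= 1")
    labels = np.array([c[2] for c in crops])
    if len(np.unique(labels)) < 2:
        raise ValueError(
            "training set contains a single class; sample both true microbleeds "
            "and mimics before training")
    rng = np.random.default_rng(seed)
    # stratified split
    idx_pos = np.flatnonzero(labels == 1)
    idx_neg = np.flatnonzero(labels == 0)
    rng.shuffle(idx_pos)
    rng.shuffle(idx_neg)
    n_vp = max(1, int(len(idx_pos) * val_fraction))
    n_vn = max(1, int(len(idx_neg) * val_fraction))
    val_idx = np.concatenate([idx_pos[:n_vp], idx_neg[:n_vn]])
    train_idx = np.concatenate([idx_pos[n_vp:], idx_neg[n_vn:]])
    w_pos = len(train_idx) / (2.0 * max(1, (labels[train_idx] == 1).sum()))
    w_neg = len(train_idx) / (2.0 * max(1, (labels[train_idx] == 0).sum()))

    opt = Adam(model.parameters(), lr=lr)
    use_text = model.cfg.with_text
    trace: list[dict] = []

    def batch_forward(idxs, train: bool) -> np.ndarray:
        vols = np.stack([np.asarray(crops[i][0], dtype=np.float32) for i in idxs])
        text = None
        if use_text:
            mats = [crops[i][1].matrix if crops[i][1] is not None
                    else np.zeros((EMBED_DIM, 1)) for i in idxs]
            n_max = max(m.shape[1] for m in mats)
            text = np.stack([np.pad(m, ((0, 0), (0, n_max - m.shape[1]))) for m in mats])
        return model(Tensor(vols), text)

    for epoch in range(epochs):
        model.train()
        order = rng.permutation(train_idx)
        for lo in range(0, len(order), batch_size):
            idxs = order[lo:lo + batch_size]
            p = batch_forward(idxs, train=True)
            y = Tensor(labels[idxs].astype(np.float32))
            w = Tensor(np.where(labels[idxs] == 1, w_pos, w_neg).astype(np.float32))
            eps = 1e-7
            loss = -(w * (y * (p + eps).log() + (1.0 - y) * (1.0 - p + eps).log())).mean()
            opt.zero_grad()
            loss.backward()
            clip_grad_norm(model.parameters(), 10.0)
            opt.step()
        model.eval()
        preds = []
        for lo in range(0, len(val_idx), batch_size):
            idxs = val_idx[lo:lo + batch_size]
            preds.append(batch_forward(idxs, train=False).data)
        pv = np.concatenate(preds) >= 0.5
        yv = labels[val_idx] == 1
        tpr = float((pv & yv).sum() / max(1, yv.sum()))
        tnr = float((~pv & ~yv).sum() / max(1, (~yv).sum()))
        acc = float((pv == yv).mean())
        trace.append({"epoch": epoch, "val_tpr": tpr, "val_tnr": tnr, "val_acc": acc})
    return model, trace
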