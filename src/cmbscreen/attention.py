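"""Saliency multi-head attention block for convolutional detectors.

The block forms *query* tokens by adaptive max pooling of the feature map —
max pooling picks out salient (extreme) responses, such as the strongly
hypointense centers of microbleed candidates — and *key/value* tokens by
adaptive average pooling, a smoothed "background board" summarizing local
context.  Multi-head attention relates the salient queries to the background,
and the attended tokens are interpolated back onto the spatial grid and added
residually to the input, so the module is a same-shape endomorphism that can
be inserted at any backbone or fusion stage.

With the output projection zero-initialized the block is an exact identity,
making insertion into a pretrained backbone safe.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import (Module, MultiHeadAttention, Tensor, adaptive_avg_pool2d,
                 adaptive_max_pool2d, bilinear_resize)

__all__ = ["SaliencyAttentionConfig", "SaliencyAttention", "parameter_count"]


@dataclass(frozen=True)
class SaliencyAttentionConfig:
    channels: int
    heads: int = 4
    query_grid: int = 4
    key_grid: int = 8
    interpolation: str = "bilinear"  # or "nearest"
    zero_init_out: bool = True

    def __post_init__(self) -> None:
        if self.channels % self.heads:
            raise ValueError(f"channels {self.channels} not divisible by heads {self.heads}")
        if self.query_grid < 1 or self.key_grid < 1:
            raise ValueError("token grids must be >= 1")


def parameter_count(cfg: SaliencyAttentionConfig) -> int:
    """Exact learnable-parameter count of a block with this configuration.

    Four projection layers (query, key, value, output), each a C x C weight
    matrix plus a C bias.
    """
    c = cfg.channels
    return 4 * (c * c + c)


class SaliencyAttention(Module):
    def __init__(self, cfg: SaliencyAttentionConfig, rng: np.random.Generator) -> None:
        super().__init__()
        self.cfg = cfg
        self.mha = MultiHeadAttention(cfg.channels, cfg.heads, rng,
                                      zero_init_out=cfg.zero_init_out)

    def forward(self, x: Tensor) -> Tensor:
        cfg = self.cfg
        B, C, H, W = x.shape
        if C != cfg.channels:
            raise ValueError(f"feature map has {C} channels, config expects {cfg.channels}")
        if cfg.query_grid > min(H, W) or cfg.key_grid > min(H, W):
            raise ValueError(
                f"token grid ({cfg.query_grid}, {cfg.key_grid}) exceeds spatial extent ({H}, {W})"
            )
        qg, kg = cfg.query_grid, cfg.key_grid
        # (B, C, g, g) -> (B, g*g, C) token sequences
        q = adaptive_max_pool2d(x, qg).reshape(B, C, qg * qg).transpose(0, 2, 1)
        kv = adaptive_avg_pool2d(x, kg).reshape(B, C, kg * kg).transpose(0, 2, 1)
        attended = self.mha(q, kv)                      # (B, qg*qg, C)
        grid = attended.transpose(0, 2, 1).reshape(B, C, qg, qg)
        up = bilinear_resize(grid, (H, W), mode=cfg.interpolation)
        return x + up

    def num_parameters(self) -> int:  # matches parameter_count(cfg) by construction
        return super().num_parameters()
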