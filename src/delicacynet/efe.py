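"""Environment feature extraction (EFE) backbone.

Pipeline: HSI conversion -> per-pixel linear projection to an embedding
width -> parallel convolutions with different kernel sizes (same padding)
-> channel concatenation -> 1x1 convolution -> distribution-partition
normalization (MDN) -> 1x1 convolution.  All convolutions keep the spatial
dimensions, so the output grid equals the input grid.

The HSI planes are scaled to [0,1] (H/360, S/100, I/255) before entering
the network so the three channels are numerically comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concatenate, conv2d
from .hsi import rgb_to_hsi
from .mdn import MDNLayer
from .nn import Module, Parameter, uniform_init

__all__ = ["EFEConfig", "EFEModule", "efe_forward", "hsi_channels"]


@dataclass(frozen=True)
class EFEConfig:
    """Architecture of the EFE backbone.

    kernel_sizes: one parallel branch per (odd) kernel size.
    embed_dim: width of the per-pixel linear projection of the HSI input.
    channels_per_branch: output channels of each branch convolution.
    mid_channels: width after the first 1x1 convolution (MDN operates here).
    out_channels: width after the final 1x1 convolution.
    hsi_mode: 'replace' feeds HSI only; 'concat' feeds HSI stacked on RGB.
    mdn_partitions / mdn_bins: MDN layer settings.
    """

    kernel_sizes: tuple[int, ...] = (1, 3, 5, 7)
    embed_dim: int = 16
    channels_per_branch: int = 8
    mid_channels: int = 24
    out_channels: int = 24
    hsi_mode: str = "replace"
    mdn_partitions: int = 2
    mdn_bins: int = 32

    def __post_init__(self):
        if not self.kernel_sizes:
            raise ValueError("need at least one convolution branch")
        for k in self.kernel_sizes:
            if k % 2 == 0 or k < 1:
                raise ValueError(f"kernel sizes must be odd positive, got {k}")
        if self.hsi_mode not in ("replace", "concat"):
            raise ValueError(f"hsi_mode must be 'replace' or 'concat', got {self.hsi_mode!r}")
        for name in ("embed_dim", "channels_per_branch", "mid_channels", "out_channels"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")

    @property
    def in_channels(self) -> int:
        return 3 if self.hsi_mode == "replace" else 6


def hsi_channels(img: np.ndarray, mode: str = "replace") -> np.ndarray:
    """Front-end input planes for a (H,W,3) image in [0,1]: scaled HSI,
    optionally concatenated with the RGB planes.  Returns (C,H,W)."""
    hsi = rgb_to_hsi(img)
    scaled = np.stack(
        [hsi[..., 0] / 360.0, hsi[..., 1] / 100.0, hsi[..., 2] / 255.0], axis=0
    )
    if mode == "replace":
        return scaled
    rgb = np.moveaxis(np.asarray(img, dtype=np.float64), -1, 0)
    return np.concatenate([scaled, rgb], axis=0)


class EFEModule(Module):
    def __init__(self, cfg: EFEConfig, rng: np.random.Generator):
        self.cfg = cfg
        cin = cfg.in_channels
        # per-pixel linear projection implemented as a 1x1 convolution
        self.proj_w = Parameter(uniform_init(rng, (cfg.embed_dim, cin, 1, 1), cin))
        self.proj_b = Parameter(np.zeros(cfg.embed_dim))
        self.branch_w = [
            Parameter(uniform_init(rng, (cfg.channels_per_branch, cfg.embed_dim, k, k), cfg.embed_dim * k * k))
            for k in cfg.kernel_sizes
        ]
        self.branch_b = [Parameter(np.zeros(cfg.channels_per_branch)) for _ in cfg.kernel_sizes]
        cat = cfg.channels_per_branch * len(cfg.kernel_sizes)
        self.fuse1_w = Parameter(uniform_init(rng, (cfg.mid_channels, cat, 1, 1), cat))
        self.fuse1_b = Parameter(np.zeros(cfg.mid_channels))
        self.mdn = MDNLayer(cfg.mdn_partitions, cfg.mdn_bins)
        self.fuse2_w = Parameter(uniform_init(rng, (cfg.out_channels, cfg.mid_channels, 1, 1), cfg.mid_channels))
        self.fuse2_b = Parameter(np.zeros(cfg.out_channels))

    def __call__(self, x: Tensor) -> Tensor:
        """x: (N, C_in, H, W) HSI-space input planes -> (N, out_channels, H, W)."""
        if x.shape[1] != self.cfg.in_channels:
            raise ValueError(
                f"EFE expects {self.cfg.in_channels} input channels (hsi_mode="
                f"{self.cfg.hsi_mode!r}), got {x.shape[1]}"
            )
        h = conv2d(x, self.proj_w, self.proj_b)
        branches = [
            conv2d(h, w, b) for w, b in zip(self.branch_w, self.branch_b)
        ]
        h = concatenate(branches, axis=1)
        h = conv2d(h, self.fuse1_w, self.fuse1_b)
        h = self.mdn(h)
        h = conv2d(h, self.fuse2_w, self.fuse2_b)
        return h

    def forward_image(self, img: np.ndarray) -> np.ndarray:
        """Convenience single-image path: (H,W,3) in [0,1] -> (C,H,W)."""
        planes = hsi_channels(img, self.cfg.hsi_mode)
        return self(Tensor(planes[None])).data[0]


def efe_forward(img: np.ndarray, module: EFEModule) -> np.ndarray:
    """Run the EFE backbone on one preprocessed image; returns (C,H,W)."""
    return module.forward_image(img)
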