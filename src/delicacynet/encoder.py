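"""Dual-attention transformer encoder with ASPP and an image residual path.

Each layer projects the token matrix into a local (Q,K,V) triple and a
separately parameterized global (Qg,Kg,Vg) triple, computes two scaled
dot-product attention maps — the focused output C and the independent
output I — and fuses them as Wo (alpha*C + beta*I), followed by a GELU
feed-forward sublayer.  After the attention stack, an atrous spatial
pyramid pooling (ASPP) block aggregates multi-scale context and the
original image, resized to the encoder grid and 1x1-projected to the
feature width, is added as a residual.

Weight convention: tokens are rows, so a projection W acts on the feature
axis, Q = X @ Wq.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import softmax as _softmax
from skimage import transform as sktransform

from .autodiff import Tensor, concatenate, conv2d
from .nn import LayerNorm, Linear, Module, Parameter, gelu_t, softmax_t, uniform_init

__all__ = [
    "AttentionParams",
    "linear_projection",
    "focused_attention",
    "independent_attention",
    "mhsa_fuse",
    "aspp",
    "ASPPModule",
    "EncoderConfig",
    "Encoder",
    "encoder_forward",
]


# ---------------------------------------------------------------------------
# functional single-head API (numpy in, numpy out)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AttentionParams:
    """Single-head attention parameters: local and global projections,
    output projection, fusion scalars and the softmax temperature d_k."""

    Wq: np.ndarray
    Wk: np.ndarray
    Wv: np.ndarray
    Wq_global: np.ndarray
    Wk_global: np.ndarray
    Wv_global: np.ndarray
    Wo: np.ndarray
    alpha: float = 0.5
    beta: float = 0.5
    dk: int = 1

    def __post_init__(self):
        d = self.Wq.shape[0]
        for name in ("Wq", "Wk", "Wv", "Wq_global", "Wk_global", "Wv_global", "Wo"):
            m = getattr(self, name)
            if m.shape != (d, d):
                raise ValueError(f"{name} must be square {d}x{d}, got {m.shape}")
        if self.dk < 1:
            raise ValueError("dk must be >= 1")


def linear_projection(X: np.ndarray, p: AttentionParams):
    """Project tokens X (T,d) into (Q, K, V, Qg, Kg, Vg)."""
    X = np.asarray(X, dtype=np.float64)
    if X.shape[1] != p.Wq.shape[0]:
        raise ValueError(f"token width {X.shape[1]} does not match weights {p.Wq.shape[0]}")
    return (X @ p.Wq, X @ p.Wk, X @ p.Wv, X @ p.Wq_global, X @ p.Wk_global, X @ p.Wv_global)


def focused_attention(Q: np.ndarray, K: np.ndarray, V: np.ndarray, dk: int) -> np.ndarray:
    """softmax(Q K^T / sqrt(dk)) V, row-wise softmax."""
    Q, K, V = (np.asarray(m, dtype=np.float64) for m in (Q, K, V))
    scores = Q @ K.T / np.sqrt(dk)
    return _softmax(scores, axis=-1) @ V


def independent_attention(Qg: np.ndarray, Kg: np.ndarray, Vg: np.ndarray, dk: int) -> np.ndarray:
    """Same scaled-dot-product form as focused attention, on the global triple."""
    return focused_attention(Qg, Kg, Vg, dk)


def mhsa_fuse(C: np.ndarray, I: np.ndarray, p: AttentionParams) -> np.ndarray:
    """Wo applied to the weighted sum alpha*C + beta*I."""
    C = np.asarray(C, dtype=np.float64)
    I = np.asarray(I, dtype=np.float64)
    if C.shape != I.shape:
        raise ValueError(f"C and I shapes differ: {C.shape} vs {I.shape}")
    return (p.alpha * C + p.beta * I) @ p.Wo


def attention_t(Q: Tensor, K: Tensor, V: Tensor, dk: int) -> Tensor:
    """Differentiable scaled dot-product attention on (..., T, d) tensors."""
    scores = (Q @ K.transpose(*range(Q.ndim - 2), Q.ndim - 1, Q.ndim - 2)) * (1.0 / np.sqrt(dk))
    return softmax_t(scores, axis=-1) @ V


# ---------------------------------------------------------------------------
# ASPP
# ---------------------------------------------------------------------------

class ASPPModule(Module):
    """Parallel 3x3 dilated convolutions plus a 1x1 branch, fused by 1x1 conv."""

    def __init__(self, c_in: int, c_out: int, rates: tuple[int, ...], rng: np.random.Generator):
        if not rates:
            raise ValueError("ASPP needs at least one dilation rate")
        self.rates = tuple(rates)
        self.branch_w = [Parameter(uniform_init(rng, (c_out, c_in, 3, 3), c_in * 9)) for _ in self.rates]
        self.branch_b = [Parameter(np.zeros(c_out)) for _ in self.rates]
        self.point_w = Parameter(uniform_init(rng, (c_out, c_in, 1, 1), c_in))
        self.point_b = Parameter(np.zeros(c_out))
        cat = c_out * (len(self.rates) + 1)
        self.fuse_w = Parameter(uniform_init(rng, (c_out, cat, 1, 1), cat))
        self.fuse_b = Parameter(np.zeros(c_out))

    def __call__(self, x: Tensor) -> Tensor:
        outs = [conv2d(x, w, b, dilation=r) for r, w, b in zip(self.rates, self.branch_w, self.branch_b)]
        outs.append(conv2d(x, self.point_w, self.point_b))
        return conv2d(concatenate(outs, axis=1), self.fuse_w, self.fuse_b)


def aspp(t: np.ndarray, module: ASPPModule) -> np.ndarray:
    """Run ASPP on a single (C,H,W) tensor."""
    return module(Tensor(np.asarray(t, dtype=np.float64)[None])).data[0]


# ---------------------------------------------------------------------------
# encoder stack
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EncoderConfig:
    layers: int = 1
    width: int = 24
    n_heads: int = 4
    aspp_rates: tuple[int, ...] = (1, 6, 12, 18)
    token_pool: int = 4
    positional: bool = True
    ffn_mult: int = 4
    out_channels: int = 24

    def __post_init__(self):
        if self.layers < 0:
            raise ValueError("layers must be >= 0")
        if self.width < 1 or self.out_channels < 1:
            raise ValueError("widths must be positive")
        if self.n_heads < 1 or self.width % self.n_heads != 0:
            raise ValueError(f"width {self.width} must be divisible by n_heads {self.n_heads}")
        if self.token_pool < 1:
            raise ValueError("token_pool must be >= 1")


class EncoderLayer(Module):
    """One dual-attention layer: multi-head focused + independent attention,
    fused by Wo(alpha*C + beta*I), then a GELU feed-forward sublayer.
    Residual connections and layer normalization follow standard post-norm
    transformer practice; n_heads=1 reproduces the single-head formulas."""

    def __init__(self, d: int, n_heads: int, ffn_mult: int, rng: np.random.Generator):
        self.d = d
        self.n_heads = n_heads
        self.dh = d // n_heads
        def mat():
            return Parameter(uniform_init(rng, (d, d), d))
        self.Wq, self.Wk, self.Wv = mat(), mat(), mat()
        self.Wqg, self.Wkg, self.Wvg = mat(), mat(), mat()
        self.Wo = mat()
        self.alpha = Parameter(np.array(0.5))
        self.beta = Parameter(np.array(0.5))
        self.ln1 = LayerNorm(d)
        self.ff1 = Linear(d, ffn_mult * d, rng)
        self.ff2 = Linear(ffn_mult * d, d, rng)
        self.ln2 = LayerNorm(d)

    def _heads(self, x: Tensor) -> Tensor:
        # (N,T,d) -> (N,heads,T,dh)
        n, t, _ = x.shape
        return x.reshape(n, t, self.n_heads, self.dh).transpose(0, 2, 1, 3)

    def _merge(self, x: Tensor) -> Tensor:
        n, h, t, dh = x.shape
        return x.transpose(0, 2, 1, 3).reshape(n, t, h * dh)

    def __call__(self, x: Tensor) -> Tensor:
        q, k, v = x @ self.Wq, x @ self.Wk, x @ self.Wv
        qg, kg, vg = x @ self.Wqg, x @ self.Wkg, x @ self.Wvg
        C = self._merge(attention_t(self._heads(q), self._heads(k), self._heads(v), self.dh))
        I = self._merge(attention_t(self._heads(qg), self._heads(kg), self._heads(vg), self.dh))
        fused = (self.alpha * C + self.beta * I) @ self.Wo
        x = self.ln1(x + fused)
        x = self.ln2(x + self.ff2(gelu_t(self.ff1(x))))
        return x


class Encoder(Module):
    """Token-pooled dual-attention stack + ASPP + original-image residual."""

    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator, grid: tuple[int, int]):
        self.cfg = cfg
        h, w = grid
        p = cfg.token_pool
        if h % p or w % p:
            raise ValueError(f"grid {grid} not divisible by token_pool {p}")
        self.grid = (h // p, w // p)
        t = self.grid[0] * self.grid[1]
        self.pos = Parameter(0.02 * rng.standard_normal((t, cfg.width))) if cfg.positional else None
        self.layers = [EncoderLayer(cfg.width, cfg.n_heads, cfg.ffn_mult, rng) for _ in range(cfg.layers)]
        self.aspp = ASPPModule(cfg.width, cfg.out_channels, cfg.aspp_rates, rng)
        self.res_w = Parameter(uniform_init(rng, (cfg.out_channels, 3, 1, 1), 3))
        self.res_b = Parameter(np.zeros(cfg.out_channels))

    def _resize_original(self, original: np.ndarray) -> np.ndarray:
        """(N,h0,w0,3) in [0,1] -> (N,3,H',W') on the encoder grid."""
        hh, ww = self.grid
        out = np.empty((original.shape[0], 3, hh, ww), dtype=self.res_w.data.dtype)
        for i, img in enumerate(original):
            r = sktransform.resize(img, (hh, ww, 3), order=1, mode="reflect",
                                   anti_aliasing=False, preserve_range=True)
            out[i] = np.moveaxis(r, -1, 0)
        return out

    def __call__(self, x: Tensor, original: np.ndarray) -> Tensor:
        n, c, h, w = x.shape
        if c != self.cfg.width:
            raise ValueError(f"encoder width {self.cfg.width} != input channels {c}")
        p = self.cfg.token_pool
        if p > 1:
            x = x.reshape(n, c, h // p, p, w // p, p).mean(axis=(3, 5))
        hh, ww = self.grid
        tokens = x.reshape(n, c, hh * ww).transpose(0, 2, 1)
        if self.pos is not None:
            tokens = tokens + self.pos
        for layer in self.layers:
            tokens = layer(tokens)
        feat = tokens.transpose(0, 2, 1).reshape(n, c, hh, ww)
        feat = self.aspp(feat)
        residual = conv2d(Tensor(self._resize_original(original)), self.res_w, self.res_b)
        return feat + residual


def encoder_forward(efe_out: np.ndarray, original: np.ndarray, module: Encoder) -> np.ndarray:
    """Single-sample encoder pass: (C,H,W) features + (h,w,3) image -> (C',H',W')."""
    return module(Tensor(np.asarray(efe_out, dtype=np.float64)[None]), np.asarray(original)[None]).data[0]
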