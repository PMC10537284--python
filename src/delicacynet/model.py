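"""End-to-end model assembly and configuration.

The network composes four stages: the environment feature extraction (EFE)
backbone, the dual-attention encoder, the token-sleeping decoder and the
softmax nutrient head.  The model operates at a configurable working
resolution (the 224x224 preprocessed image is bilinearly resampled onto the
working grid before entering the EFE stage) so the attention token count
stays tractable on a CPU.

For ablation studies the EFE backbone can be swapped for a plain
convolutional stem of matched parameter budget (``use_efe=False``), which
consumes raw RGB planes with no HSI conversion and no MDN normalization.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np
from skimage import transform as sktransform

from .autodiff import Tensor, conv2d
from .decoder import Decoder, DecoderConfig, SleepState
from .efe import EFEConfig, EFEModule, hsi_channels
from .encoder import Encoder, EncoderConfig
from .head import HeadConfig, N_CLASSES, NutrientHead
from .nn import Module, Parameter, uniform_init

__all__ = ["ModelConfig", "PlainStem", "DelicacyNet", "model_forward", "prepare_image"]


@dataclass(frozen=True)
class ModelConfig:
    """All architecture hyperparameters, serializable round-trip."""

    efe: EFEConfig = field(default_factory=EFEConfig)
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    decoder: DecoderConfig = field(default_factory=DecoderConfig)
    head: HeadConfig = field(default_factory=HeadConfig)
    loss_weights: tuple[float, ...] = (1.0,) * N_CLASSES
    working_resolution: int = 32
    use_efe: bool = True
    dtype: str = "float32"
    seed: int = 0

    def __post_init__(self):
        if self.dtype not in ("float32", "float64"):
            raise ValueError(f"dtype must be float32 or float64, got {self.dtype!r}")
        if self.working_resolution < self.encoder.token_pool:
            raise ValueError("working_resolution smaller than token_pool")
        if self.working_resolution % self.encoder.token_pool:
            raise ValueError("working_resolution must be divisible by token_pool")
        if self.efe.out_channels != self.encoder.width:
            raise ValueError(
                f"EFE out_channels {self.efe.out_channels} must equal encoder width {self.encoder.width}"
            )
        if len(self.loss_weights) != self.head.n_classes:
            raise ValueError("loss_weights length must equal the number of nutrient classes")
        if any(w <= 0 for w in self.loss_weights):
            raise ValueError("loss weights must be strictly positive")

    # -- serialization -------------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        known = {"efe", "encoder", "decoder", "head", "loss_weights",
                 "working_resolution", "use_efe", "dtype", "seed"}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")

        def build(klass, sub):
            sub = dict(sub)
            names = {f for f in klass.__dataclass_fields__}
            bad = set(sub) - names
            if bad:
                raise ValueError(f"unknown {klass.__name__} keys: {sorted(bad)}")
            for k, v in sub.items():
                if isinstance(v, list):
                    sub[k] = tuple(v)
            return klass(**sub)

        kwargs = {}
        if "efe" in d:
            kwargs["efe"] = build(EFEConfig, d["efe"])
        if "encoder" in d:
            kwargs["encoder"] = build(EncoderConfig, d["encoder"])
        if "decoder" in d:
            kwargs["decoder"] = build(DecoderConfig, d["decoder"])
        if "head" in d:
            kwargs["head"] = build(HeadConfig, d["head"])
        for k in ("loss_weights", "working_resolution", "use_efe", "dtype", "seed"):
            if k in d:
                kwargs[k] = tuple(d[k]) if k == "loss_weights" else d[k]
        return cls(**kwargs)

    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]

    # -- canned sizes ---------------------------------------------------------
    @classmethod
    def small(cls, seed: int = 0, **overrides) -> "ModelConfig":
        """The CPU-scale configuration used throughout the test experiments:
        16x16 working grid, 8x8 token grid, ~6e4 parameters."""
        cfg = cls(
            efe=EFEConfig(kernel_sizes=(1, 3, 5), embed_dim=8, channels_per_branch=8,
                          mid_channels=24, out_channels=32),
            encoder=EncoderConfig(layers=1, width=32, n_heads=4, aspp_rates=(1, 2, 3),
                                  token_pool=2, out_channels=32),
            decoder=DecoderConfig(fc_layers=2, dropout=0.1, tau=1e-3, sleep_epochs=2,
                                  window=50, d_out=32),
            head=HeadConfig(hidden=64, dropout=0.3),
            working_resolution=16,
            seed=seed,
        )
        return replace(cfg, **overrides) if overrides else cfg


class PlainStem(Module):
    """Ablation stand-in for the EFE backbone: a plain convolutional stem
    (3x3 -> 3x3 -> 1x1 on raw RGB) sized to roughly the same parameter count,
    with no HSI front end and no MDN normalization."""

    def __init__(self, hidden: int, out_channels: int, rng: np.random.Generator):
        self.conv1_w = Parameter(uniform_init(rng, (hidden, 3, 3, 3), 27))
        self.conv1_b = Parameter(np.zeros(hidden))
        self.conv2_w = Parameter(uniform_init(rng, (hidden, hidden, 3, 3), hidden * 9))
        self.conv2_b = Parameter(np.zeros(hidden))
        self.conv3_w = Parameter(uniform_init(rng, (out_channels, hidden, 1, 1), hidden))
        self.conv3_b = Parameter(np.zeros(out_channels))

    def __call__(self, x: Tensor) -> Tensor:
        h = conv2d(x, self.conv1_w, self.conv1_b)
        h = conv2d(h, self.conv2_w, self.conv2_b)
        return conv2d(h, self.conv3_w, self.conv3_b)

    @staticmethod
    def matched_hidden(target_params: int, out_channels: int) -> int:
        """Hidden width whose stem parameter count best matches the target."""
        best, best_diff = 1, float("inf")
        for h in range(1, 257):
            n = (h * 27 + h) + (h * h * 9 + h) + (out_channels * h + out_channels)
            if abs(n - target_params) < best_diff:
                best, best_diff = h, abs(n - target_params)
        return best


def param_count(module: Module) -> int:
    return int(sum(p.data.size for p in module.parameters()))


def prepare_image(image: np.ndarray, working_resolution: int, use_efe: bool, hsi_mode: str):
    """One image (uint8 [0,255] or float [0,1], any size) -> model inputs.

    Returns (planes (C, R, R), original (R, R, 3)) at the working resolution.
    With the EFE backbone the planes are the scaled HSI channels (optionally
    stacked with RGB); the plain-stem ablation consumes raw RGB planes.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected H x W x 3 image, got shape {img.shape}")
    if not np.issubdtype(np.asarray(image).dtype, np.floating):
        img = img / 255.0
    r = working_resolution
    if img.shape[:2] != (r, r):
        img = sktransform.resize(img, (r, r, 3), order=1, mode="reflect",
                                 anti_aliasing=img.shape[0] > r, preserve_range=True)
    img = np.clip(img, 0.0, 1.0)
    if use_efe:
        planes = hsi_channels(img, hsi_mode)
    else:
        planes = np.moveaxis(img, -1, 0)
    return planes, img


class DelicacyNet(Module):
    """EFE (or plain stem) -> dual-attention encoder -> sleeping decoder ->
    softmax nutrient head."""

    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        if cfg.use_efe:
            self.stem = EFEModule(cfg.efe, rng)
        else:
            efe_params = param_count(EFEModule(cfg.efe, np.random.default_rng(cfg.seed)))
            hidden = PlainStem.matched_hidden(efe_params, cfg.efe.out_channels)
            self.stem = PlainStem(hidden, cfg.efe.out_channels, rng)
        r = cfg.working_resolution
        self.encoder = Encoder(cfg.encoder, rng, grid=(r, r))
        self.decoder = Decoder(cfg.decoder, cfg.encoder.out_channels, rng)
        self.head = NutrientHead(cfg.head, cfg.decoder.d_out, rng)
        self.astype(np.dtype(cfg.dtype))

    @property
    def n_tokens(self) -> int:
        g = self.cfg.working_resolution // self.cfg.encoder.token_pool
        return g * g

    def new_sleep_state(self) -> SleepState:
        return SleepState.awake(self.n_tokens, self.cfg.encoder.out_channels)

    def prepare(self, images) -> tuple[np.ndarray, np.ndarray]:
        """Batch of images -> (planes (N,C,R,R), originals (N,R,R,3))."""
        planes, originals = [], []
        for img in images:
            p, o = prepare_image(img, self.cfg.working_resolution, self.cfg.use_efe,
                                 self.cfg.efe.hsi_mode)
            planes.append(p)
            originals.append(o)
        dt = np.dtype(self.cfg.dtype)
        return np.stack(planes).astype(dt), np.stack(originals).astype(dt)

    def forward(
        self,
        planes: np.ndarray,
        originals: np.ndarray,
        train: bool = False,
        rng: np.random.Generator | None = None,
        sleep_state: SleepState | None = None,
    ) -> tuple[Tensor, np.ndarray, np.ndarray]:
        """Prepared inputs -> (simplex predictions (N,K), token stats)."""
        x = self.stem(Tensor(planes))
        x = self.encoder(x, originals)
        feat, token_abs, token_mean = self.decoder(x, sleep_state, train=train, rng=rng)
        out = self.head(feat, train=train, rng=rng)
        return out, token_abs, token_mean

    def predict(self, images) -> np.ndarray:
        """Eval-mode prediction: list/array of images -> (N, K) simplex rows."""
        planes, originals = self.prepare(images)
        out, _, _ = self.forward(planes, originals, train=False)
        return out.data


def model_forward(img: np.ndarray, model: DelicacyNet, mode: str = "eval",
                  rng: np.random.Generator | None = None,
                  sleep_state: SleepState | None = None) -> np.ndarray:
    """Single image -> nutrient fraction vector."""
    if mode not in ("train", "eval"):
        raise ValueError(f"mode must be 'train' or 'eval', got {mode!r}")
    train = mode == "train"
    if train and rng is None:
        rng = np.random.default_rng(0)
    planes, originals = model.prepare([img])
    out, _, _ = model.forward(planes, originals, train=train, rng=rng, sleep_state=sleep_state)
    return out.data[0]
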