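"""Decoder with supervised token sleeping (Sup-HeadAttention).

During training a supervision layer tracks each token's mean absolute
post-attention activation over a sliding window of steps.  Tokens whose
statistic falls below a threshold tau are put to sleep for a fixed number
of epochs: while asleep a token's output row is its frozen activation and
it is excluded from the attention computation, shrinking the matmul.
Sleeping is a training-time mechanism; evaluation uses all tokens.

The decoder body is attention -> dropout -> layer normalization -> a stack
of fully connected residual blocks -> mean pooling over awake tokens -> a
final linear map to the feature vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concatenate
from .encoder import attention_t, focused_attention
from .nn import Dropout, LayerNorm, Linear, Module, Parameter, gelu_t, uniform_init

__all__ = [
    "SleepState",
    "ActivationStats",
    "detect_inactive",
    "update_sleep",
    "sup_head_attention",
    "DecoderConfig",
    "Decoder",
    "decoder_forward",
]


@dataclass
class SleepState:
    """Per-token sleep bookkeeping: asleep mask, epochs of sleep remaining,
    and the activation row frozen when the token went to sleep.
    Invariant: asleep[i] iff remaining[i] > 0."""

    asleep: np.ndarray
    remaining: np.ndarray
    frozen_value: np.ndarray

    @classmethod
    def awake(cls, n_tokens: int, width: int) -> "SleepState":
        return cls(
            asleep=np.zeros(n_tokens, dtype=bool),
            remaining=np.zeros(n_tokens, dtype=np.int64),
            frozen_value=np.zeros((n_tokens, width)),
        )

    def validate(self) -> None:
        if not np.array_equal(self.asleep, self.remaining > 0):
            raise AssertionError("sleep-state invariant violated: asleep != (remaining > 0)")
        if (self.remaining < 0).any():
            raise AssertionError("negative remaining sleep counter")

    @property
    def n_awake(self) -> int:
        return int((~self.asleep).sum())


class ActivationStats:
    """Sliding-window running mean of per-token absolute activation."""

    def __init__(self, n_tokens: int, window: int):
        if window < 1:
            raise ValueError("window must be >= 1")
        self.window = window
        self.buffer = np.zeros((window, n_tokens))
        self.steps_seen = 0

    def update(self, abs_activation: np.ndarray) -> None:
        self.buffer[self.steps_seen % self.window] = abs_activation
        self.steps_seen += 1

    @property
    def ready(self) -> bool:
        return self.steps_seen >= self.window

    @property
    def mean_abs(self) -> np.ndarray:
        n = min(self.steps_seen, self.window)
        if n == 0:
            return np.zeros(self.buffer.shape[1])
        return self.buffer[:n].mean(axis=0)


def detect_inactive(stats: ActivationStats, tau: float) -> np.ndarray:
    """Tokens with windowed mean |activation| strictly below tau.

    The window must be filled; tau=0 never flags anything (strict inequality).
    """
    if tau < 0:
        raise ValueError("tau must be nonnegative")
    if not stats.ready:
        return np.zeros(stats.buffer.shape[1], dtype=bool)
    return stats.mean_abs < tau


def update_sleep(
    state: SleepState,
    flags: np.ndarray,
    sleep_epochs: int,
    epoch_boundary: bool,
    current_values: np.ndarray | None = None,
) -> SleepState:
    """Advance the sleep bookkeeping.

    At an epoch boundary every sleeping token's counter decrements and tokens
    reaching 0 wake up.  Then newly flagged *awake* tokens go to sleep with
    ``remaining = sleep_epochs`` and their current activation frozen;
    re-flagging an already-asleep token does not extend its sleep.
    """
    if sleep_epochs < 1:
        raise ValueError("sleep_epochs must be >= 1")
    flags = np.asarray(flags, dtype=bool)
    if flags.shape != state.asleep.shape:
        raise ValueError("flag mask size mismatch")
    remaining = state.remaining.copy()
    frozen = state.frozen_value.copy()

    if epoch_boundary:
        remaining = np.maximum(remaining - 1, 0)

    newly = flags & (remaining == 0)
    remaining[newly] = sleep_epochs
    if newly.any():
        if current_values is not None:
            frozen[newly] = np.asarray(current_values)[newly]
        else:
            frozen[newly] = 0.0

    new_state = SleepState(asleep=remaining > 0, remaining=remaining, frozen_value=frozen)
    new_state.validate()
    return new_state


def sup_head_attention(
    X: np.ndarray, state: SleepState, weights: tuple[np.ndarray, np.ndarray, np.ndarray], dk: int
) -> np.ndarray:
    """Attention restricted to awake tokens; asleep rows emit their frozen value.

    weights = (Wq, Wk, Wv); with an empty sleep mask this equals plain
    focused attention on (X Wq, X Wk, X Wv).
    """
    X = np.asarray(X, dtype=np.float64)
    wq, wk, wv = weights
    awake = ~state.asleep
    if not awake.any():
        raise ValueError("all tokens are asleep: attention is degenerate")
    xa = X[awake]
    att = focused_attention(xa @ wq, xa @ wk, xa @ wv, dk)
    out = np.empty((X.shape[0], att.shape[1]))
    out[awake] = att
    out[state.asleep] = state.frozen_value[state.asleep]
    return out


@dataclass(frozen=True)
class DecoderConfig:
    fc_layers: int = 2
    dropout: float = 0.1
    tau: float = 1e-3
    sleep_epochs: int = 2
    window: int = 50
    d_out: int = 32

    def __post_init__(self):
        if self.fc_layers < 0:
            raise ValueError("fc_layers must be >= 0")
        if self.sleep_epochs < 1:
            raise ValueError("sleep_epochs must be >= 1")
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.tau < 0:
            raise ValueError("tau must be >= 0")
        if self.d_out < 1:
            raise ValueError("d_out must be positive")


class Decoder(Module):
    """Sup-HeadAttention decoder producing a pooled feature vector."""

    def __init__(self, cfg: DecoderConfig, width: int, rng: np.random.Generator):
        self.cfg = cfg
        self.width = width
        self.Wq = Parameter(uniform_init(rng, (width, width), width))
        self.Wk = Parameter(uniform_init(rng, (width, width), width))
        self.Wv = Parameter(uniform_init(rng, (width, width), width))
        self.drop = Dropout(cfg.dropout)
        self.ln = LayerNorm(width)
        self.fc = [Linear(width, width, rng) for _ in range(cfg.fc_layers)]
        self.out = Linear(width, cfg.d_out, rng)

    def __call__(
        self,
        enc_out: Tensor,
        state: SleepState | None = None,
        train: bool = False,
        rng: np.random.Generator | None = None,
    ) -> tuple[Tensor, np.ndarray, np.ndarray]:
        """enc_out: (N,C,H,W) -> (feature (N,d_out), per-token mean |activation|,
        per-token batch-mean activation rows (T,d) used to freeze sleepers).

        ``state`` only takes effect in train mode; evaluation always uses the
        full token set.
        """
        n, c, h, w = enc_out.shape
        tokens = enc_out.reshape(n, c, h * w).transpose(0, 2, 1)  # (N,T,d)
        t = h * w

        use_sleep = train and state is not None and state.asleep.any()
        if use_sleep:
            state.validate()
            awake_idx = np.where(~state.asleep)[0]
            asleep_idx = np.where(state.asleep)[0]
            if awake_idx.size == 0:
                raise ValueError("all tokens are asleep: attention is degenerate")
            xa = tokens[:, awake_idx, :]
            att_awake = attention_t(xa @ self.Wq, xa @ self.Wk, xa @ self.Wv, self.width)
            frozen = Tensor(np.broadcast_to(state.frozen_value[asleep_idx], (n, asleep_idx.size, c))
                            .astype(enc_out.data.dtype))
            perm = np.concatenate([awake_idx, asleep_idx])
            inv = np.argsort(perm)
            att = concatenate([att_awake, frozen], axis=1)[:, inv, :]
        else:
            awake_idx = np.arange(t)
            att = attention_t(tokens @ self.Wq, tokens @ self.Wk, tokens @ self.Wv, self.width)

        token_abs = np.abs(att.data).mean(axis=(0, 2))  # per-token statistic
        token_mean = att.data.mean(axis=0)  # (T,d) rows frozen on sleep entry

        x = self.drop(att, train=train, rng=rng)
        x = self.ln(x)
        for layer in self.fc:
            x = x + gelu_t(layer(x))
        pooled = x[:, awake_idx, :].mean(axis=1)
        return self.out(pooled), token_abs, token_mean


def decoder_forward(
    enc_out: np.ndarray,
    state: SleepState | None,
    module: Decoder,
    mode: str = "eval",
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Single-sample decoder pass: (C,H,W) -> feature vector (d_out,)."""
    if mode not in ("train", "eval"):
        raise ValueError(f"mode must be 'train' or 'eval', got {mode!r}")
    train = mode == "train"
    if train and module.cfg.dropout > 0 and rng is None:
        rng = np.random.default_rng(0)
    feat, _, _ = module(Tensor(np.asarray(enc_out, dtype=np.float64)[None]), state, train=train, rng=rng)
    return feat.data[0]
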