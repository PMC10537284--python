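"""Training loop, evaluation and the ablation experiments.

Training minimizes the weighted mean absolute error (WMAE) between the
predicted and true nutrient fraction vectors with Adam.  The decoder's
supervision layer is driven from here: after every optimization step the
per-token activation statistics are updated, inactive tokens are put to
sleep, and at each epoch boundary the sleep counters are decremented.
Everything (data order, initialization, dropout, sleeping) is seeded, so a
run is reproducible bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .autodiff import Tensor
from .decoder import detect_inactive, update_sleep, ActivationStats
from .head import NUTRIENT_CLASSES
from .metrics import stability_variance, top1_from_vectors, top5_from_vectors, wmae
from .model import DelicacyNet, ModelConfig
from .nn import Adam

__all__ = [
    "RunRecord",
    "train",
    "evaluate",
    "ablate_efe",
    "ablate_depth",
    "save_checkpoint",
    "load_checkpoint",
    "wmae_loss",
]


def wmae_loss(weights: np.ndarray, pred: Tensor, true: np.ndarray) -> Tensor:
    """Batch-mean WMAE as a differentiable scalar."""
    w = np.asarray(weights, dtype=np.float64)
    diff = (pred - Tensor(np.asarray(true, dtype=np.float64))).abs()
    per_sample = (diff * Tensor(w)).sum(axis=-1) * (1.0 / w.sum())
    return per_sample.mean()


@dataclass
class RunRecord:
    """Per-epoch loss trace plus the sleep-event audit log."""

    seed: int
    config_hash: str
    epochs: list = field(default_factory=list)  # {"epoch", "train_wmae", "val_wmae"}
    sleep_events: list = field(default_factory=list)  # {"epoch", "step", "token", "stat"}

    def to_dict(self) -> dict:
        return {"seed": self.seed, "config_hash": self.config_hash,
                "epochs": self.epochs, "sleep_events": self.sleep_events}


def _as_images_targets(dataset) -> tuple[list, np.ndarray]:
    images, targets = [], []
    for item in dataset:
        if hasattr(item, "image"):
            images.append(item.image)
            targets.append(item.nutrients)
        else:
            img, tgt = item
            images.append(img)
            targets.append(tgt)
    return images, np.asarray(targets, dtype=np.float64)


def train(
    dataset,
    cfg: ModelConfig,
    epochs: int,
    seed: int,
    batch_size: int = 32,
    lr: float = 1e-3,
    val_frac: float = 0.2,
) -> tuple[DelicacyNet, RunRecord]:
    """Fit the model on (image, nutrient-vector) pairs.

    ``dataset`` is a sequence of objects with ``.image``/``.nutrients`` or of
    ``(image, target)`` tuples.  Returns the trained model and the run record.
    """
    images, targets = _as_images_targets(dataset)
    if len(images) == 0:
        raise ValueError("empty dataset")
    model = DelicacyNet(cfg)
    planes, originals = model.prepare(images)

    rng = np.random.default_rng([seed, 11])
    n = len(images)
    n_val = int(round(val_frac * n)) if n > 1 else 0
    perm = rng.permutation(n)
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    if train_idx.size == 0:
        train_idx, val_idx = perm, perm[:0]

    opt = Adam(model.parameters(), lr=lr)
    state = model.new_sleep_state()
    stats = ActivationStats(model.n_tokens, cfg.decoder.window)
    record = RunRecord(seed=seed, config_hash=cfg.config_hash())
    w = np.asarray(cfg.loss_weights)

    step = 0
    for epoch in range(epochs):
        order = rng.permutation(train_idx)
        epoch_loss, epoch_count = 0.0, 0
        for start in range(0, order.size, batch_size):
            idx = order[start : start + batch_size]
            pred, token_abs, token_mean = model.forward(
                planes[idx], originals[idx], train=True, rng=rng, sleep_state=state
            )
            loss = wmae_loss(w, pred, targets[idx])
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}, step {step}: {loss.data}"
                )
            model.zero_grad()
            loss.backward()
            opt.step()
            step += 1
            epoch_loss += float(loss.data) * idx.size
            epoch_count += idx.size

            stats.update(token_abs)
            if cfg.decoder.tau > 0 and stats.ready:
                flags = detect_inactive(stats, cfg.decoder.tau)
                newly = flags & ~state.asleep
                if newly.any():
                    for tok in np.where(newly)[0]:
                        record.sleep_events.append(
                            {"epoch": epoch, "step": step, "token": int(tok),
                             "stat": float(stats.mean_abs[tok])}
                        )
                state = update_sleep(state, flags, cfg.decoder.sleep_epochs,
                                     epoch_boundary=False, current_values=token_mean)
        # epoch boundary: decrement sleep counters
        state = update_sleep(state, np.zeros(model.n_tokens, dtype=bool),
                             cfg.decoder.sleep_epochs, epoch_boundary=True)

        # train WMAE = epoch mean of the minibatch losses (one pass, no re-eval)
        train_wmae = epoch_loss / max(epoch_count, 1)
        val_wmae = (
            _dataset_wmae(model, planes[val_idx], originals[val_idx], targets[val_idx], w)
            if val_idx.size else float("nan")
        )
        record.epochs.append({"epoch": epoch, "train_wmae": train_wmae, "val_wmae": val_wmae})
    return model, record


def _dataset_wmae(model, planes, originals, targets, w, batch_size: int = 64) -> float:
    vals = []
    for start in range(0, len(planes), batch_size):
        pred, _, _ = model.forward(planes[start : start + batch_size],
                                   originals[start : start + batch_size], train=False)
        for p, t in zip(pred.data, targets[start : start + batch_size]):
            vals.append(wmae(w, p, t))
    return float(np.mean(vals))


def evaluate(dataset, model: DelicacyNet | None = None, predict_fn=None,
             loss_weights=None) -> dict:
    """Mean Top-1/Top-5 regression accuracy, mean WMAE and a per-nutrient
    error breakdown over a dataset.

    ``predict_fn`` (images -> (N,K) array) overrides the model's predictor,
    which lets a reference predictor be scored with the same machinery.
    """
    images, targets = _as_images_targets(dataset)
    if len(images) == 0:
        raise ValueError("cannot evaluate on an empty dataset")
    if predict_fn is None:
        if model is None:
            raise ValueError("need a model or a predict_fn")
        predict_fn = model.predict
    preds = np.asarray(predict_fn(images), dtype=np.float64)
    if loss_weights is None:
        loss_weights = (model.cfg.loss_weights if model is not None
                        else np.ones(targets.shape[1]))
    w = np.asarray(loss_weights, dtype=np.float64)

    top1 = [top1_from_vectors(p, t) for p, t in zip(preds, targets)]
    top5 = [top5_from_vectors(p, t) for p, t in zip(preds, targets)]
    wm = [wmae(w, p, t) for p, t in zip(preds, targets)]
    per_nutrient = np.abs(preds - targets).mean(axis=0)
    return {
        "n": len(images),
        "top1": float(np.mean(top1)),
        "top5": float(np.mean(top5)),
        "wmae": float(np.mean(wm)),
        "per_nutrient_mae": {name: float(v) for name, v in zip(NUTRIENT_CLASSES, per_nutrient)},
    }


def _pair_stability(model: DelicacyNet, pairs) -> np.ndarray:
    """Per-nutrient stability variances, one row per background pair."""
    rows = []
    for a, b in pairs:
        preds = model.predict([a.image, b.image])
        rows.append(stability_variance(preds))
    return np.asarray(rows)


def ablate_efe(dataset, pairs, cfg: ModelConfig, seed: int, epochs: int = 10,
               batch_size: int = 32, lr: float = 1e-3) -> dict:
    """Train matched models with the EFE backbone and with a plain conv stem
    of equal parameter budget, then compare prediction stability across
    same-foreground/different-background pairs (smaller variance = more
    robust to background clutter)."""
    report = {"n_pairs": len(pairs), "seed": seed}
    for arm, use_efe in (("efe", True), ("no_efe", False)):
        from dataclasses import replace
        arm_cfg = replace(cfg, use_efe=use_efe)
        model, _ = train(dataset, arm_cfg, epochs=epochs, seed=seed,
                         batch_size=batch_size, lr=lr)
        var = _pair_stability(model, pairs)
        med = np.median(var, axis=0)
        report[arm] = {
            "per_nutrient_median_variance": {n: float(v) for n, v in zip(NUTRIENT_CLASSES, med)},
            "median_variance": float(np.median(var)),
        }
    return report


def ablate_depth(dataset, pairs, cfg: ModelConfig, depths, seed: int,
                 epochs: int = 10, batch_size: int = 32, lr: float = 1e-3) -> dict:
    """Train one model per decoder depth (number of fully connected residual
    blocks) and report per-depth predictions and stability variances."""
    depths = list(depths)
    if len(depths) < 2:
        raise ValueError("need at least two depths to compare")
    from dataclasses import replace as _replace
    report = {"seed": seed, "depths": {}}
    for depth in depths:
        arm_cfg = _replace(cfg, decoder=_replace(cfg.decoder, fc_layers=int(depth)))
        model, _ = train(dataset, arm_cfg, epochs=epochs, seed=seed,
                         batch_size=batch_size, lr=lr)
        metrics = evaluate(dataset, model)
        var = _pair_stability(model, pairs)
        med = np.median(var, axis=0)
        report["depths"][str(depth)] = {
            "wmae": metrics["wmae"],
            "top1": metrics["top1"],
            "per_nutrient_median_variance": {n: float(v) for n, v in zip(NUTRIENT_CLASSES, med)},
            "median_variance": float(np.median(var)),
        }
    return report


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(path: str | Path, model: DelicacyNet, record: RunRecord | None = None) -> None:
    """Single-archive checkpoint: weights named by module path + config + seed."""
    path = Path(path)
    state = model.named_state()
    meta = {"config": model.cfg.to_dict(), "record": record.to_dict() if record else None}
    np.savez(path, __meta__=json.dumps(meta), **state)


def load_checkpoint(path: str | Path) -> tuple[DelicacyNet, dict]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with np.load(path, allow_pickle=False) as archive:
        meta = json.loads(str(archive["__meta__"]))
        state = {k: archive[k] for k in archive.files if k != "__meta__"}
    cfg = ModelConfig.from_dict(meta["config"])
    model = DelicacyNet(cfg)
    model.load_state(state)
    return model, meta
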