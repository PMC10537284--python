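"""Semantic output head and the label -> nutrient-table mapping.

The head maps the decoder's feature vector through fully connected layers
with dropout to a softmax over nutrient classes, so every prediction is a
point on the simplex.  The tracked classes are protein, fat, fiber,
carbohydrate, minerals and water, expressed as fractions of a reference
intake (NRV%/100); because the tracked values of a real food do not sum to
100%, an explicit ``remainder`` class absorbs the shortfall so the simplex
representation is faithful.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .autodiff import Tensor
from .nn import Dropout, Linear, Module, gelu_t, softmax_t

__all__ = [
    "NUTRIENT_CLASSES",
    "TRACKED_NUTRIENTS",
    "NutrientTable",
    "HeadConfig",
    "NutrientHead",
    "semantic_output",
    "load_nutrient_table",
    "map_label",
    "validate_nutrient_vector",
]

TRACKED_NUTRIENTS = ("protein", "fat", "fiber", "carbohydrate", "minerals", "water")
NUTRIENT_CLASSES = TRACKED_NUTRIENTS + ("remainder",)
N_CLASSES = len(NUTRIENT_CLASSES)


def validate_nutrient_vector(v: np.ndarray, atol: float = 1e-6) -> np.ndarray:
    v = np.asarray(v, dtype=np.float64)
    if v.shape != (N_CLASSES,):
        raise ValueError(f"nutrient vector must have length {N_CLASSES}, got shape {v.shape}")
    if (v < -atol).any() or (v > 1 + atol).any():
        raise ValueError("nutrient fractions must lie in [0,1]")
    if abs(v.sum() - 1.0) > atol:
        raise ValueError(f"nutrient fractions must sum to 1, got {v.sum():.8f}")
    return v


@dataclass(frozen=True)
class NutrientTable:
    """Per-food nutrient fractions (rows on the simplex), keyed by food name."""

    rows: dict  # food name -> length-7 fraction vector
    provenance: str = ""

    def vector(self, food: str) -> np.ndarray:
        if food not in self.rows:
            raise KeyError(f"food {food!r} not in nutrient table")
        return self.rows[food]

    @property
    def foods(self) -> list[str]:
        return list(self.rows)


def _row_to_fractions(values: np.ndarray, food: str) -> np.ndarray:
    """Convert a row of tracked-nutrient percentages to a simplex vector.

    Values are NRV percentages; the remainder class absorbs the shortfall
    from 100%.  Rows summing to more than 100% are rescaled to sum exactly
    100% (remainder 0).
    """
    values = np.asarray(values, dtype=np.float64)
    if values.shape != (len(TRACKED_NUTRIENTS),):
        raise ValueError(f"row {food!r}: expected {len(TRACKED_NUTRIENTS)} nutrient values")
    if (values < 0).any():
        raise ValueError(f"row {food!r}: negative nutrient value")
    frac = values / 100.0
    total = frac.sum()
    if total > 1.0 + 1e-9:
        frac = frac / total
        total = 1.0
    remainder = max(0.0, 1.0 - total)
    return validate_nutrient_vector(np.concatenate([frac, [remainder]]))


def load_nutrient_table(path: str | Path) -> NutrientTable:
    """Read a nutrient table (CSV with columns food,protein,...,water in
    percent units, or the JSON equivalent {food: [values...]}).

    Every row is validated and renormalized onto the simplex; duplicate food
    names, negative values and malformed rows raise a validation error that
    names the offending row.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise ValueError(f"nutrient table {path} is empty")

    rows: dict[str, np.ndarray] = {}
    if path.suffix.lower() == ".json":
        data = json.loads(path.read_text())
        items = list(data.items())
    else:
        df = pd.read_csv(path)
        expected = ["food", *TRACKED_NUTRIENTS]
        if list(df.columns) != expected:
            raise ValueError(f"nutrient table {path}: expected columns {expected}, got {list(df.columns)}")
        if df.empty:
            raise ValueError(f"nutrient table {path} has no rows")
        items = [(r["food"], [r[n] for n in TRACKED_NUTRIENTS]) for _, r in df.iterrows()]

    for food, values in items:
        food = str(food)
        if food in rows:
            raise ValueError(f"duplicate food name {food!r} in nutrient table")
        try:
            values = np.asarray(values, dtype=np.float64)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"row {food!r}: unparseable values") from exc
        if np.isnan(values).any():
            raise ValueError(f"row {food!r}: missing or non-numeric values")
        rows[food] = _row_to_fractions(values, food)
    return NutrientTable(rows=rows, provenance=str(path))


def map_label(label, mapping: dict, table: NutrientTable) -> np.ndarray:
    """Resolve a class label through the label->food mapping to its vector.

    Missing labels or foods raise a KeyError rather than returning a silent
    zero vector.
    """
    if label not in mapping:
        raise KeyError(f"label {label!r} has no food mapping")
    food = mapping[label]
    if food not in table.rows:
        raise KeyError(f"label {label!r} maps to unknown food {food!r}")
    return table.rows[food]


@dataclass(frozen=True)
class HeadConfig:
    hidden: int = 32
    dropout: float = 0.3
    n_classes: int = N_CLASSES

    def __post_init__(self):
        if self.hidden < 1 or self.n_classes < 2:
            raise ValueError("head widths must be positive (n_classes >= 2)")


class NutrientHead(Module):
    """FC -> GELU -> dropout -> FC -> softmax over nutrient classes."""

    def __init__(self, cfg: HeadConfig, d_in: int, rng: np.random.Generator):
        self.cfg = cfg
        self.fc1 = Linear(d_in, cfg.hidden, rng)
        self.drop = Dropout(cfg.dropout)
        self.fc2 = Linear(cfg.hidden, cfg.n_classes, rng)

    def __call__(self, v: Tensor, train: bool = False, rng: np.random.Generator | None = None) -> Tensor:
        h = gelu_t(self.fc1(v))
        h = self.drop(h, train=train, rng=rng)
        return softmax_t(self.fc2(h), axis=-1)


def semantic_output(
    v: np.ndarray, module: NutrientHead, mode: str = "eval", rng: np.random.Generator | None = None
) -> np.ndarray:
    """Single feature vector -> nutrient fraction vector on the simplex."""
    if mode not in ("train", "eval"):
        raise ValueError(f"mode must be 'train' or 'eval', got {mode!r}")
    train = mode == "train"
    if train and module.cfg.dropout > 0 and rng is None:
        rng = np.random.default_rng(0)
    out = module(Tensor(np.asarray(v, dtype=np.float64)[None]), train=train, rng=rng)
    return out.data[0]
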