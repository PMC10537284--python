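"""Synthetic food images with known latent nutrient composition.

Each "food" is an elliptical dish whose appearance deterministically encodes
its nutrient vector: the dish hue is tied linearly to the carbohydrate
fraction and the sinusoidal texture frequency to the protein fraction, so a
model that reads appearance can in principle recover composition.  The dish
is composited over interchangeable background clutter (solid, gradient,
checkerboard or noise), which makes background-robustness experiments
possible: the foreground pixels depend only on (food, seed), never on the
background.

Everything is seeded and renders at a small native resolution (64x64 by
default); the preprocessing pipeline upsamples to the model input size.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from skimage import color as skcolor

from .head import TRACKED_NUTRIENTS, validate_nutrient_vector

__all__ = [
    "BACKGROUND_STYLES",
    "SyntheticSpec",
    "SyntheticSample",
    "food_nutrients",
    "food_appearance",
    "generate_sample",
    "generate_dataset",
    "generate_background_pairs",
    "write_nutrient_table",
]

BACKGROUND_STYLES = ("solid", "gradient", "checker", "noise")


def food_nutrients(food: int, n_foods: int) -> np.ndarray:
    """The published linear appearance->composition rule.

    With u = food/(n_foods-1):
      carbohydrate = 0.10 + 0.40 u   (encoded by dish hue)
      protein      = 0.30 - 0.22 u   (encoded by texture frequency)
      fat          = 0.04 + 0.06 u
      fiber        = 0.03, minerals = 0.02
      water/remainder split the rest 70/30.
    All seven fractions are strictly positive and the map is injective.
    """
    if not 0 <= food < n_foods:
        raise IndexError(f"food index {food} out of range [0,{n_foods})")
    u = food / max(n_foods - 1, 1)
    carb = 0.10 + 0.40 * u
    protein = 0.30 - 0.22 * u
    fat = 0.04 + 0.06 * u
    fiber, minerals = 0.03, 0.02
    rest = 1.0 - (carb + protein + fat + fiber + minerals)
    water, remainder = 0.7 * rest, 0.3 * rest
    return validate_nutrient_vector(
        np.array([protein, fat, fiber, carb, minerals, water, remainder])
    )


def food_appearance(food: int, n_foods: int) -> tuple[float, float]:
    """(hue in degrees, texture frequency in cycles across the dish)."""
    u = food / max(n_foods - 1, 1)
    return 300.0 * u, 2.0 + 3.0 * u


@dataclass(frozen=True)
class SyntheticSpec:
    n_foods: int = 6
    image_size: int = 64
    background_pool: tuple[str, ...] = BACKGROUND_STYLES
    seed: int = 0

    def __post_init__(self):
        if self.n_foods < 1:
            raise ValueError("need at least one food")
        if self.image_size < 8:
            raise ValueError("image_size must be >= 8")
        for style in self.background_pool:
            if style not in BACKGROUND_STYLES:
                raise ValueError(f"unknown background style {style!r}")

    @property
    def nutrient_map(self) -> np.ndarray:
        return np.stack([food_nutrients(i, self.n_foods) for i in range(self.n_foods)])


@dataclass
class SyntheticSample:
    image: np.ndarray  # H x W x 3 uint8
    label: int
    nutrients: np.ndarray
    background_id: int
    foreground_mask: np.ndarray | None = None


def _render_foreground(spec: SyntheticSpec, food: int, rng: np.random.Generator):
    """Dish pixels + mask; a deterministic function of (spec, food, seed)."""
    s = spec.image_size
    hue, freq = food_appearance(food, spec.n_foods)
    cy = s / 2 + rng.uniform(-0.1, 0.1) * s
    cx = s / 2 + rng.uniform(-0.1, 0.1) * s
    ay = s * (0.28 + rng.uniform(-0.05, 0.05))
    ax = s * (0.28 + rng.uniform(-0.05, 0.05))
    yy, xx = np.mgrid[0:s, 0:s]
    mask = ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0

    phase = rng.uniform(0, 2 * np.pi)
    val = 0.85 * (1.0 + 0.25 * np.sin(2 * np.pi * freq * xx / s + phase))
    hsv = np.stack(
        [np.full((s, s), hue / 360.0), np.full((s, s), 0.75), np.clip(val, 0.0, 1.0)],
        axis=-1,
    )
    return skcolor.hsv2rgb(hsv), mask


def _render_background(spec: SyntheticSpec, background_id: int, rng: np.random.Generator) -> np.ndarray:
    s = spec.image_size
    style = spec.background_pool[background_id]
    if style == "solid":
        return np.broadcast_to(rng.uniform(0.1, 0.9, size=3), (s, s, 3)).copy()
    if style == "gradient":
        c1, c2 = rng.uniform(0.1, 0.9, size=(2, 3))
        t = np.linspace(0, 1, s)[:, None, None]
        return np.broadcast_to((1 - t) * c1 + t * c2, (s, s, 3)).copy()
    if style == "checker":
        c1, c2 = rng.uniform(0.1, 0.9, size=(2, 3))
        block = max(s // 8, 1)
        yy, xx = np.mgrid[0:s, 0:s]
        parity = ((yy // block + xx // block) % 2).astype(bool)
        out = np.where(parity[..., None], c2, c1)
        return out
    if style == "noise":
        return rng.uniform(0.0, 1.0, size=(s, s, 3))
    raise ValueError(f"unknown background style {style!r}")


def generate_sample(spec: SyntheticSpec, food: int, background_id: int, seed: int) -> SyntheticSample:
    """Render one sample, deterministic per (spec, food, background_id, seed).

    The foreground is seeded by (spec.seed, food, seed) only, so changing the
    background never moves a foreground pixel.
    """
    if not 0 <= food < spec.n_foods:
        raise IndexError(f"food index {food} out of range [0,{spec.n_foods})")
    if not 0 <= background_id < len(spec.background_pool):
        raise IndexError(f"background_id {background_id} out of range [0,{len(spec.background_pool)})")
    fg_rng = np.random.default_rng([spec.seed, 1, food, seed])
    bg_rng = np.random.default_rng([spec.seed, 2, background_id, seed])
    fg, mask = _render_foreground(spec, food, fg_rng)
    bg = _render_background(spec, background_id, bg_rng)
    img = bg.copy()
    img[mask] = fg[mask]
    return SyntheticSample(
        image=np.round(img * 255.0).astype(np.uint8),
        label=food,
        nutrients=food_nutrients(food, spec.n_foods),
        background_id=background_id,
        foreground_mask=mask,
    )


def generate_dataset(
    spec: SyntheticSpec, n_samples: int, seed: int, out_dir: str | Path | None = None
) -> tuple[list[SyntheticSample], pd.DataFrame]:
    """Draw foods and backgrounds uniformly, render, optionally write to disk.

    Writes PNG images, a manifest CSV (image_path,label,background_id) and the
    nutrient table when ``out_dir`` is given.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng([seed, 3])
    foods = rng.integers(0, spec.n_foods, size=n_samples)
    bgs = rng.integers(0, len(spec.background_pool), size=n_samples)
    sample_seeds = rng.integers(0, 2**31 - 1, size=n_samples)

    samples = [
        generate_sample(spec, int(f), int(b), int(s))
        for f, b, s in zip(foods, bgs, sample_seeds)
    ]

    records = []
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
        (out_path / "images").mkdir(exist_ok=True)
    for i, smp in enumerate(samples):
        rel = f"images/sample_{i:05d}.png"
        if out_path is not None:
            Image.fromarray(smp.image).save(out_path / rel)
        records.append({"image_path": rel, "label": smp.label, "background_id": smp.background_id})
    manifest = pd.DataFrame.from_records(records)
    if out_path is not None:
        manifest.to_csv(out_path / "manifest.csv", index=False)
        write_nutrient_table(spec, out_path / "nutrient_table.csv")
    return samples, manifest


def generate_background_pairs(
    spec: SyntheticSpec, food: int, n_pairs: int, seed: int
) -> list[tuple[SyntheticSample, SyntheticSample]]:
    """Same-foreground, different-background sample pairs for the stability
    ablation: pair members share the foreground seed and differ only in
    background."""
    if len(spec.background_pool) < 2:
        raise ValueError("need at least two background styles for pairs")
    rng = np.random.default_rng([seed, 4, food])
    pairs = []
    for _ in range(n_pairs):
        fg_seed = int(rng.integers(0, 2**31 - 1))
        b1, b2 = rng.choice(len(spec.background_pool), size=2, replace=False)
        pairs.append(
            (
                generate_sample(spec, food, int(b1), fg_seed),
                generate_sample(spec, food, int(b2), fg_seed),
            )
        )
    return pairs


def write_nutrient_table(spec: SyntheticSpec, path: str | Path) -> None:
    """Write the spec's nutrient map in the standard table format
    (percent units; the remainder class is implied by the shortfall)."""
    rows = []
    for i in range(spec.n_foods):
        frac = food_nutrients(i, spec.n_foods)
        rows.append({"food": f"food_{i:02d}", **{n: 100.0 * frac[j] for j, n in enumerate(TRACKED_NUTRIENTS)}})
    pd.DataFrame(rows).to_csv(path, index=False)
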