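"""Image loading, resizing to the model input shape, and augmentation.

The model consumes 224x224x3 images with pixel values scaled to [0,1].
Augmentation (horizontal flip, rotation, random crop) is applied after
scaling and is fully seeded so a training run is reproducible end to end.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError
from skimage import transform as sktransform

__all__ = ["AugmentConfig", "ImageDecodeError", "INPUT_SIZE", "load_image", "preprocess", "augment"]

INPUT_SIZE = 224


class ImageDecodeError(ValueError):
    """Raised when a file cannot be decoded as a PNG/JPEG image."""


@dataclass(frozen=True)
class AugmentConfig:
    """Augmentation magnitudes: flip probability, max rotation (degrees),
    and the fraction of image area kept by the random crop."""

    p_flip: float = 0.5
    max_deg: float = 15.0
    crop_frac: float = 0.875

    def __post_init__(self):
        if not 0.0 <= self.p_flip <= 1.0:
            raise ValueError(f"p_flip must be in [0,1], got {self.p_flip}")
        if self.max_deg < 0:
            raise ValueError(f"max_deg must be >= 0, got {self.max_deg}")
        if not 0.0 < self.crop_frac <= 1.0:
            raise ValueError(f"crop_frac must be in (0,1], got {self.crop_frac}")


def load_image(path: str | Path) -> np.ndarray:
    """Decode a PNG/JPEG file to an H x W x 3 uint8 array.

    Grayscale inputs are replicated to three channels; palette and alpha
    images are converted to RGB.  Raises :class:`ImageDecodeError` on
    unreadable or truncated files.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        with Image.open(path) as im:
            im = im.convert("RGB")
            arr = np.asarray(im, dtype=np.uint8)
    except (UnidentifiedImageError, OSError, SyntaxError) as exc:
        raise ImageDecodeError(f"cannot decode image file {path}: {exc}") from exc
    return arr


def preprocess(img: np.ndarray) -> np.ndarray:
    """Bilinear-resize to 224x224 and scale pixel values to [0,1]."""
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected H x W x 3 image, got shape {img.shape}")
    out = sktransform.resize(
        img.astype(np.float64),
        (INPUT_SIZE, INPUT_SIZE, 3),
        order=1,
        mode="reflect",
        anti_aliasing=True,
        preserve_range=True,
    )
    return np.clip(out / 255.0, 0.0, 1.0)


def augment(img: np.ndarray, seed: int, params: AugmentConfig = AugmentConfig()) -> np.ndarray:
    """Seeded augmentation: horizontal flip, rotation, random crop + resize back.

    Applied in that order; out-of-frame pixels from rotation are filled by
    reflection so no artificial black background is introduced.
    """
    img = np.asarray(img, dtype=np.float64)
    if img.shape != (INPUT_SIZE, INPUT_SIZE, 3):
        raise ValueError(f"augment expects a preprocessed {INPUT_SIZE}x{INPUT_SIZE}x3 image, got {img.shape}")
    rng = np.random.default_rng(seed)

    if rng.random() < params.p_flip:
        img = img[:, ::-1, :].copy()

    if params.max_deg > 0:
        angle = rng.uniform(-params.max_deg, params.max_deg)
        img = sktransform.rotate(img, angle, order=1, mode="reflect", preserve_range=True)

    if params.crop_frac < 1.0:
        side = int(round(INPUT_SIZE * np.sqrt(params.crop_frac)))
        side = max(1, min(side, INPUT_SIZE))
        r0 = rng.integers(0, INPUT_SIZE - side + 1)
        c0 = rng.integers(0, INPUT_SIZE - side + 1)
        crop = img[r0 : r0 + side, c0 : c0 + side, :]
        img = sktransform.resize(
            crop, (INPUT_SIZE, INPUT_SIZE, 3), order=1, mode="reflect",
            anti_aliasing=False, preserve_range=True,
        )

    return np.clip(img, 0.0, 1.0)
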