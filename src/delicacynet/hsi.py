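"""RGB -> HSI (hue, saturation, intensity) conversion.

The conversion works on chromaticity coordinates r = R/(R+G+B) (and
likewise g, b).  Hue is the arccos of a normalized chroma expression with a
branch on b vs g, saturation is 1 - 3*min(r,g,b), and intensity is the
channel mean.  Outputs are scaled to the conventional ranges
H in [0,360) degrees, S in [0,100], I in [0,255].

Degenerate pixels are handled by convention: achromatic pixels (R=G=B)
have undefined hue (the arccos argument is 0/0) and get H=0 (S is already 0
there); the black pixel gets H=0, S=0, I=0.  The guard is applied only to
pixels whose hue denominator vanishes, so non-degenerate pixels are
computed exactly; the arccos argument is clamped to [-1,1] against
floating-point overshoot.
"""

from __future__ import annotations

import numpy as np

__all__ = ["rgb_to_hsi"]

_EPS = 1e-12


def rgb_to_hsi(img: np.ndarray) -> np.ndarray:
    """Convert an H x W x 3 RGB image (or a single pixel triple) to HSI.

    Accepts either integer images in [0,255] or scaled images in [0,1]
    (detected by dtype and range); the result is identical because hue and
    saturation are scale-invariant and intensity is defined on the [0,255]
    scale.
    """
    arr = np.asarray(img, dtype=np.float64)
    squeeze = arr.ndim == 1
    if squeeze:
        arr = arr[None, None, :]
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected H x W x 3 image, got shape {np.asarray(img).shape}")
    if np.issubdtype(np.asarray(img).dtype, np.floating) and arr.max() <= 1.0 + 1e-9:
        arr = arr * 255.0

    R, G, B = arr[..., 0], arr[..., 1], arr[..., 2]
    total = R + G + B
    black = total <= _EPS
    safe_total = np.where(black, 1.0, total)
    r, g, b = R / safe_total, G / safe_total, B / safe_total

    num = 0.5 * ((r - g) + (r - b))
    den2 = (r - g) ** 2 + (r - b) * (g - b)
    den = np.sqrt(np.maximum(den2, 0.0))
    # guard only truly degenerate pixels so exact values stay exact
    degenerate = den <= _EPS
    cos_arg = np.clip(num / np.where(degenerate, 1.0, den), -1.0, 1.0)
    cos_arg = np.where(degenerate, 1.0, cos_arg)  # arccos(1)=0 -> H=0
    h = np.arccos(cos_arg)
    h = np.where(b > g, 2.0 * np.pi - h, h)

    s = 1.0 - 3.0 * np.minimum(np.minimum(r, g), b)
    i = total / (3.0 * 255.0)

    H = np.mod(h * 180.0 / np.pi, 360.0)
    S = np.clip(s, 0.0, 1.0) * 100.0
    I = i * 255.0

    # hue is undefined for achromatic pixels; pin it to 0
    chroma = arr.max(axis=-1) - arr.min(axis=-1)
    achromatic = chroma <= _EPS
    H = np.where(achromatic, 0.0, H)
    S = np.where(black, 0.0, S)
    I = np.where(black, 0.0, I)

    out = np.stack([H, S, I], axis=-1)
    return out[0, 0] if squeeze else out
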