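"""Pseudo-color composites for the dynamic contrasts.

LIV composite: HSV image with hue = LIV (low -> red at 0 deg, high -> green
at 120 deg), saturation = 1 everywhere, value = windowed dB intensity, so
dark pixels stay black regardless of their dynamics. Fast-DOCT is displayed
as grayscale decorrelation gated by a validity mask (low-SNR pixels are
artifact, rendered black).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib.colors import hsv_to_rgb

__all__ = ["CompositeImage", "liv_composite", "fast_doct_display"]

GREEN_HUE = 1.0 / 3.0  # 120 degrees on the hexcone


@dataclass
class CompositeImage:
    rgb: np.ndarray  # (..., 3) in [0, 1]
    hue_range: tuple[float, float]
    value_window: tuple[float, float]


def _norm(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    if hi <= lo:
        raise ValueError("window must have hi > lo")
    return np.clip((x - lo) / (hi - lo), 0.0, 1.0)


def default_value_window(db_image: np.ndarray) -> tuple[float, float]:
    """Data-adaptive brightness window: [p1, p99] of the finite dB values."""
    finite = db_image[np.isfinite(db_image)]
    return (float(np.percentile(finite, 1)), float(np.percentile(finite, 99)))


def liv_composite(
    liv_image: np.ndarray,
    db_image: np.ndarray,
    hue_range: tuple[float, float] = (0.0, 10.0),
    value_window: tuple[float, float] | None = None,
    valid: np.ndarray | None = None,
) -> CompositeImage:
    """LIV/intensity HSV composite (hue = dynamics, brightness = dB signal).

    ``hue_range`` maps LIV (dB^2) onto red->green; ``value_window`` maps dB
    intensity onto brightness, defaulting to the [p1, p99] percentiles of
    the image. ``valid=False`` pixels (e.g. failed surface segmentation)
    render black.
    """
    liv_v = np.asarray(liv_image, dtype=float)
    db_v = np.asarray(db_image, dtype=float)
    if liv_v.shape != db_v.shape:
        raise ValueError(f"shape mismatch: LIV {liv_v.shape} vs dB {db_v.shape}")
    if value_window is None:
        value_window = default_value_window(db_v)
    bad = ~np.isfinite(liv_v) | ~np.isfinite(db_v)
    if valid is not None:
        bad |= ~np.asarray(valid, dtype=bool)
    h = _norm(np.where(bad, 0.0, liv_v), *hue_range) * GREEN_HUE
    v = _norm(np.where(bad, -np.inf, db_v), *value_window)
    s = np.ones_like(h)
    rgb = hsv_to_rgb(np.stack([h, s, v], axis=-1))
    return CompositeImage(rgb=rgb, hue_range=tuple(hue_range), value_window=tuple(value_window))


def fast_doct_display(
    fdoct_image: np.ndarray,
    validity: np.ndarray | None = None,
    db_image: np.ndarray | None = None,
    value_window: tuple[float, float] | None = None,
) -> np.ndarray:
    """Grayscale decorrelation display gated by validity (and optionally by
    a dB brightness window): invalid or dark pixels are black."""
    img = np.clip(np.nan_to_num(np.asarray(fdoct_image, dtype=float)), 0.0, 1.0)
    if validity is not None:
        img = np.where(np.asarray(validity, dtype=bool), img, 0.0)
    if db_image is not None:
        db_v = np.asarray(db_image, dtype=float)
        if value_window is None:
            value_window = default_value_window(db_v)
        img = img * (db_v >= value_window[0])
    return img


def to_uint8(img: np.ndarray) -> np.ndarray:
    """Quantize a [0, 1] image to 8 bits for PNG export."""
    return np.round(np.clip(img, 0.0, 1.0) * 255).astype(np.uint8)
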