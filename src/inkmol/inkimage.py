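"""Grayscale ink-image helpers.

An ink image is an ``(H, W)`` uint8 numpy array, ink dark on a light field.
PNG round-tripping goes through Pillow.
"""

from __future__ import annotations

import numpy as np
from PIL import Image

INK_THRESHOLD = 128


def as_ink_image(arr: np.ndarray) -> np.ndarray:
    arr = np.asarray(arr)
    if arr.ndim != 2:
        raise ValueError(f"ink image must be 2-D grayscale, got shape {arr.shape}")
    return arr.astype(np.uint8, copy=False)


def ink_fraction(img: np.ndarray, threshold: int = INK_THRESHOLD) -> float:
    """Fraction of pixels darker than ``threshold``."""
    img = as_ink_image(img)
    return float(np.count_nonzero(img < threshold)) / img.size


def save_png(img: np.ndarray, path) -> None:
    Image.fromarray(as_ink_image(img), mode="L").save(path, format="PNG")


def load_png(path) -> np.ndarray:
    with Image.open(path) as im:
        return np.asarray(im.convert("L"), dtype=np.uint8)
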