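"""Procedural paper backgrounds and ink compositing.

Backgrounds emulate the surfaces people draw on — plain paper, ruled and
grid notebook pages, noisy photocopies, stained sheets — and are generated
procedurally so the pipeline needs no downloads; user PNGs pass through the
same compositing interface. Backgrounds are augmented (rotation, crop-zoom,
brightness) before use so a model cannot latch onto one fixed texture.
Compositing is a per-pixel minimum: ink always stays at least as dark as
the paper beneath it.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.transform import resize, rotate

from .inkimage import as_ink_image

BACKGROUND_KINDS = ("plain", "ruled", "grid", "noise", "stained")


def make_background(kind: str, size: int, seed: int) -> np.ndarray:
    """Generate a ``size`` x ``size`` background of the given kind.

    Deterministic per ``(kind, size, seed)``; mean intensity stays >= 128
    (paper is lighter than ink).
    """
    if size < 64:
        raise ValueError("size must be >= 64")
    if kind not in BACKGROUND_KINDS:
        raise ValueError(f"unknown background kind {kind!r}; "
                         f"known: {BACKGROUND_KINDS}")
    kind_id = BACKGROUND_KINDS.index(kind)
    rng = np.random.default_rng(np.random.SeedSequence([kind_id, seed]))
    base = float(rng.uniform(232, 252))
    img = np.full((size, size), base)

    if kind in ("ruled", "grid"):
        spacing = int(rng.integers(size // 10, size // 6))
        offset = int(rng.integers(0, spacing))
        shade = float(rng.uniform(150, 200))
        for y in range(offset, size, spacing):
            img[y, :] = shade
        if kind == "grid":
            voff = int(rng.integers(0, spacing))
            for x in range(voff, size, spacing):
                img[:, x] = shade
    elif kind == "noise":
        img += rng.normal(0.0, rng.uniform(4, 12), img.shape)
    elif kind == "stained":
        for _ in range(int(rng.integers(2, 6))):
            cy, cx = rng.integers(0, size, 2)
            ry, rx = rng.integers(size // 12, size // 4, 2)
            yy, xx = np.mgrid[0:size, 0:size]
            blob = (((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2) <= 1.0
            depth = rng.uniform(15, 55)
            stain = np.where(blob, depth, 0.0)
            img -= ndimage.gaussian_filter(stain, size / 40)
    # plain: uniform near-white, nothing to add

    return as_ink_image(np.clip(img, 150, 255))


def augment_background(bg: np.ndarray, seed: int) -> np.ndarray:
    """Rotation / crop-zoom / brightness jitter on a background.

    Dimensions are preserved; deterministic per seed.
    """
    bg = as_ink_image(bg)
    rng = np.random.default_rng(seed)
    out = bg.astype(np.float64)
    h, w = out.shape

    ang = rng.uniform(-6.0, 6.0)
    out = rotate(out, ang, resize=False, mode="reflect", preserve_range=True,
                 order=1)

    frac = rng.uniform(0.75, 1.0)
    ch, cw = max(int(h * frac), 8), max(int(w * frac), 8)
    y0 = int(rng.integers(0, h - ch + 1))
    x0 = int(rng.integers(0, w - cw + 1))
    out = resize(out[y0:y0 + ch, x0:x0 + cw], (h, w), preserve_range=True,
                 order=1)

    out = 255.0 - rng.uniform(0.85, 1.1) * (255.0 - out)
    return as_ink_image(np.clip(out, 0, 255))


def composite(ink: np.ndarray, bg: np.ndarray) -> np.ndarray:
    """Per-pixel minimum blend of an ink image onto a background."""
    ink = as_ink_image(ink)
    bg = as_ink_image(bg)
    if ink.shape != bg.shape:
        raise ValueError(f"dimension mismatch: ink {ink.shape} vs bg {bg.shape}")
    return np.minimum(ink, bg)
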