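"""Probabilistic image corruption chains: augmentation and degradation.

A chain is an ordered list of named operations, each firing independently
with probability ``p``. Augmentation ops simulate variation in how people
draw (rotation, shear, elastic warp, stroke-width changes, sensor noise);
degradation ops simulate information loss in scans and photos (resolution
loss, compression blocking, stroke erasure, contrast fade, ink bleed).

Randomness is counter-based: each op in a chain gets its own child stream
derived from the chain seed, so whether one op fires never perturbs the
randomness of the ops after it, and datasets are reproducible when images
are generated in any order.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import ndimage
from scipy.fft import dctn, idctn
from skimage.transform import AffineTransform, resize, rotate, warp

from .inkimage import as_ink_image

_REGISTRY: dict[str, Callable] = {}


def register_op(name: str):
    def deco(fn):
        _REGISTRY[name] = fn
        return fn
    return deco


def registered_ops() -> tuple[str, ...]:
    return tuple(sorted(_REGISTRY))


@dataclass(frozen=True)
class OpSpec:
    """One corruption operation with its parameters and firing probability."""

    name: str
    params: dict = field(default_factory=dict)
    p: float = 0.5

    def __post_init__(self):
        if self.name not in _REGISTRY:
            raise KeyError(f"unregistered op {self.name!r}; "
                           f"known: {registered_ops()}")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"p={self.p} outside [0, 1]")


@dataclass(frozen=True)
class OpChain:
    """Ordered corruption chain; order is significant and preserved."""

    ops: tuple[OpSpec, ...]

    def __len__(self) -> int:
        return len(self.ops)

    def to_config(self) -> list[dict]:
        return [{"name": o.name, "params": o.params, "p": o.p} for o in self.ops]

    @classmethod
    def from_config(cls, cfg: list[dict]) -> "OpChain":
        return cls(tuple(OpSpec(c["name"], dict(c.get("params", {})),
                                float(c.get("p", 0.5))) for c in cfg))

    def hash(self) -> str:
        """Stable digest of the chain definition, recorded in manifests."""
        payload = json.dumps(self.to_config(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def apply_chain(img: np.ndarray, chain: OpChain, seed: int) -> np.ndarray:
    """Apply ``chain`` to ``img``; each op fires with its probability ``p``.

    Deterministic per ``(img, chain, seed)``; dimensions are preserved.
    """
    img = as_ink_image(img)
    out = img.astype(np.float64)
    children = np.random.SeedSequence(seed).spawn(len(chain.ops))
    for op, child in zip(chain.ops, children):
        rng = np.random.default_rng(child)
        if rng.random() < op.p:
            out = _REGISTRY[op.name](out, rng, **op.params)
            if out.shape != img.shape:
                raise RuntimeError(f"op {op.name!r} changed image shape")
    return as_ink_image(np.clip(out, 0, 255))


# ---------------------------------------------------------------------------
# augmentation ops (white fill keeps corners paper-colored)


@register_op("rotate")
def _op_rotate(img, rng, max_deg: float = 10.0):
    ang = rng.uniform(-max_deg, max_deg)
    return rotate(img, ang, resize=False, cval=255.0, preserve_range=True,
                  order=1)


@register_op("shear")
def _op_shear(img, rng, max_deg: float = 8.0):
    ang = np.deg2rad(rng.uniform(-max_deg, max_deg))
    h, w = img.shape
    tf = (AffineTransform(translation=(-w / 2, -h / 2))
          + AffineTransform(shear=ang)
          + AffineTransform(translation=(w / 2, h / 2)))
    return warp(img, tf.inverse, cval=255.0, preserve_range=True, order=1)


@register_op("elastic_warp")
def _op_elastic(img, rng, alpha: float = 12.0, sigma: float = 6.0):
    h, w = img.shape
    dx = ndimage.gaussian_filter(rng.standard_normal((h, w)), sigma) * alpha
    dy = ndimage.gaussian_filter(rng.standard_normal((h, w)), sigma) * alpha
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    return ndimage.map_coordinates(img, [yy + dy, xx + dx], order=1,
                                   mode="constant", cval=255.0)


@register_op("stroke_width")
def _op_stroke_width(img, rng, max_px: int = 2):
    # morphological: minimum filter thickens dark ink, maximum filter thins
    size = int(rng.integers(1, max_px + 1)) + 1
    if rng.random() < 0.5:
        return ndimage.minimum_filter(img, size=size)
    return ndimage.maximum_filter(img, size=size)


@register_op("gaussian_noise")
def _op_gauss_noise(img, rng, sigma: float = 10.0):
    return img + rng.normal(0.0, sigma, img.shape)


@register_op("salt_pepper")
def _op_salt_pepper(img, rng, amount: float = 0.01):
    out = img.copy()
    mask = rng.random(img.shape) < amount
    out[mask] = np.where(rng.random(np.count_nonzero(mask)) < 0.5, 0.0, 255.0)
    return out


@register_op("blur")
def _op_blur(img, rng, max_sigma: float = 1.2):
    return ndimage.gaussian_filter(img, rng.uniform(0.3, max_sigma))


# ---------------------------------------------------------------------------
# degradation ops


@register_op("resolution_loss")
def _op_resolution_loss(img, rng, max_factor: int = 4):
    f = int(rng.integers(2, max_factor + 1))
    h, w = img.shape
    small = resize(img, (max(h // f, 8), max(w // f, 8)),
                   preserve_range=True, anti_aliasing=True)
    return resize(small, (h, w), preserve_range=True, order=1)


@register_op("blocking")
def _op_blocking(img, rng, block: int = 8, keep: int = 3):
    """Compression-style artifacts: per-block 2D DCT truncated to the
    lowest ``keep`` x ``keep`` coefficients."""
    h, w = img.shape
    ph, pw = (-h) % block, (-w) % block
    padded = np.pad(img, ((0, ph), (0, pw)), mode="edge")
    hb, wb = padded.shape[0] // block, padded.shape[1] // block
    blocks = padded.reshape(hb, block, wb, block).transpose(0, 2, 1, 3)
    coef = dctn(blocks, axes=(2, 3), norm="ortho")
    coef[:, :, keep:, :] = 0.0
    coef[:, :, :, keep:] = 0.0
    rec = idctn(coef, axes=(2, 3), norm="ortho")
    out = rec.transpose(0, 2, 1, 3).reshape(padded.shape)
    return out[:h, :w]


@register_op("patch_erase")
def _op_patch_erase(img, rng, max_patches: int = 4, max_size: int = 18):
    out = img.copy()
    h, w = img.shape
    for _ in range(int(rng.integers(1, max_patches + 1))):
        sh = int(rng.integers(4, max_size + 1))
        sw = int(rng.integers(4, max_size + 1))
        y = int(rng.integers(0, max(h - sh, 1)))
        x = int(rng.integers(0, max(w - sw, 1)))
        out[y:y + sh, x:x + sw] = 255.0
    return out


@register_op("fade")
def _op_fade(img, rng, min_strength: float = 0.4, max_strength: float = 0.8):
    s = rng.uniform(min_strength, max_strength)
    return 255.0 - s * (255.0 - img)


@register_op("ink_bleed")
def _op_ink_bleed(img, rng, max_px: int = 2, sigma: float = 1.0):
    size = int(rng.integers(1, max_px + 1)) + 1
    return ndimage.gaussian_filter(ndimage.minimum_filter(img, size=size), sigma)


# ---------------------------------------------------------------------------
# default chains


def default_augment_chain(p: float = 0.5) -> OpChain:
    """The drawing-variation chain applied right after rendering."""
    names = ("rotate", "shear", "elastic_warp", "stroke_width",
             "gaussian_noise", "salt_pepper", "blur")
    return OpChain(tuple(OpSpec(n, p=p) for n in names))


def default_degrade_chain(p: float = 0.5) -> OpChain:
    """The information-loss chain simulating scans and photos."""
    names = ("resolution_loss", "blocking", "patch_erase", "fade", "ink_bleed")
    return OpChain(tuple(OpSpec(n, p=p) for n in names))
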