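"""Hand-drawn-style rendering of molecules to ink images.

The 2D atom layout comes from RDKit's standard depiction coordinates; the
hand-drawn look is produced by this module's own perturbation and
rasterization layer: per-bond endpoint and angle jitter, wavy (tremor)
strokes, randomized stroke widths and ink darkness, and parametric letter
glyphs (an ellipse for O, an open arc for C) whose size and orientation are
randomized per image. Everything random is driven by one seed, so a
``(molecule, params, seed)`` triple always produces byte-identical pixels,
and fully degenerate parameter ranges produce a clean, seed-independent
depiction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdDepictor

from .chem_core import MoleculeGraph, parse_smiles
from .inkimage import as_ink_image

MIN_BOND_PX = 6.0
MAX_BOND_PX = 70.0


class MoleculeTooLargeError(ValueError):
    """The molecule cannot fit on the canvas at the minimum legible scale."""


@dataclass(frozen=True)
class DepictionParams:
    """Randomization ranges for the hand-drawn renderer.

    Ranges are ``(low, high)`` tuples sampled uniformly per image or per
    stroke; a degenerate range ``(x, x)`` removes that source of
    randomness. Jitters are fractions of the bond length (endpoint) or
    degrees (angle); ``char_scale`` multiplies the base glyph radius.
    """

    canvas_px: int = 256
    bond_endpoint_jitter: tuple[float, float] = (0.0, 0.08)
    bond_angle_jitter_deg: tuple[float, float] = (0.0, 8.0)
    stroke_width_px: tuple[float, float] = (1.0, 4.0)
    char_scale: tuple[float, float] = (0.8, 1.3)
    char_rotation_deg: tuple[float, float] = (-12.0, 12.0)
    ink_darkness: tuple[float, float] = (0.0, 60.0)
    wavy_stroke: bool = True
    draw_carbon_labels: bool = False
    margin_frac: float = 0.08

    def __post_init__(self):
        if self.canvas_px < 64:
            raise ValueError("canvas_px must be >= 64")
        for name in ("bond_endpoint_jitter", "bond_angle_jitter_deg",
                     "stroke_width_px", "char_scale", "ink_darkness"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} range inverted: ({lo}, {hi})")

    @classmethod
    def clean(cls, canvas_px: int = 256) -> "DepictionParams":
        """Parameters with every randomized range degenerate: the clean,
        unperturbed depiction, identical across seeds."""
        return cls(canvas_px=canvas_px,
                   bond_endpoint_jitter=(0.0, 0.0),
                   bond_angle_jitter_deg=(0.0, 0.0),
                   stroke_width_px=(2.0, 2.0),
                   char_scale=(1.0, 1.0),
                   ink_darkness=(0.0, 0.0),
                   char_rotation_deg=(0.0, 0.0),
                   wavy_stroke=False)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "DepictionParams":
        d = dict(d)
        for name in ("bond_endpoint_jitter", "bond_angle_jitter_deg",
                     "stroke_width_px", "char_scale", "char_rotation_deg",
                     "ink_darkness"):
            if name in d:
                d[name] = tuple(d[name])
        return cls(**d)


def layout_2d(m: MoleculeGraph | str) -> np.ndarray:
    """Deterministic 2D coordinates for the heavy atoms, shape ``(n, 2)``.

    Bond lengths are approximately uniform (RDKit depiction units); a single
    atom sits at the origin.
    """
    if isinstance(m, str):
        m = parse_smiles(m)
    mol = Chem.Mol(m.to_rdkit())
    rdDepictor.Compute2DCoords(mol)
    conf = mol.GetConformer()
    return np.array([[conf.GetAtomPosition(i).x, conf.GetAtomPosition(i).y]
                     for i in range(mol.GetNumAtoms())], dtype=float)


def _uniform(rng: np.random.Generator, rng_range: tuple[float, float]) -> float:
    lo, hi = rng_range
    return lo + float(rng.random()) * (hi - lo)


def _draw_polyline(canvas: np.ndarray, pts: np.ndarray, width: float,
                   ink: float) -> None:
    """Stamp a dense polyline of disks onto ``canvas`` (min blend)."""
    h, w = canvas.shape
    r = max(width / 2.0, 0.5)
    # resample at ~0.5 px spacing
    seg = np.diff(pts, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    total = float(seglen.sum())
    n_samples = max(int(total / 0.5), 2)
    t = np.linspace(0.0, 1.0, n_samples)
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    if cum[-1] == 0:
        samples = np.repeat(pts[:1], n_samples, axis=0)
    else:
        xs = np.interp(t * cum[-1], cum, pts[:, 0])
        ys = np.interp(t * cum[-1], cum, pts[:, 1])
        samples = np.stack([xs, ys], axis=1)
    ri = int(math.ceil(r))
    yy, xx = np.mgrid[-ri:ri + 1, -ri:ri + 1]
    disk = (xx * xx + yy * yy) <= r * r
    for x, y in samples:
        cx, cy = int(round(x)), int(round(y))
        x0, x1 = max(cx - ri, 0), min(cx + ri + 1, w)
        y0, y1 = max(cy - ri, 0), min(cy + ri + 1, h)
        if x0 >= x1 or y0 >= y1:
            continue
        sub = disk[y0 - (cy - ri):y1 - (cy - ri), x0 - (cx - ri):x1 - (cx - ri)]
        region = canvas[y0:y1, x0:x1]
        region[sub] = np.minimum(region[sub], ink)


def _wavy(p0: np.ndarray, p1: np.ndarray, amplitude: float,
          rng: np.random.Generator) -> np.ndarray:
    """Sample a stroke from p0 to p1 with low-frequency sinusoidal tremor."""
    n = 24
    t = np.linspace(0.0, 1.0, n)
    base = np.outer(1 - t, p0) + np.outer(t, p1)
    if amplitude <= 0:
        return base
    d = p1 - p0
    length = float(np.hypot(*d))
    if length == 0:
        return base
    normal = np.array([-d[1], d[0]]) / length
    cycles = _uniform(rng, (0.8, 1.8))
    phase = _uniform(rng, (0.0, 2 * math.pi))
    # taper so stroke ends stay anchored
    env = np.sin(math.pi * t)
    disp = amplitude * env * np.sin(2 * math.pi * cycles * t + phase)
    return base + disp[:, None] * normal


def _glyph_strokes(symbol: str, center: np.ndarray, radius: float,
                   rotation_deg: float) -> list[np.ndarray]:
    """Parametric letter strokes: O is a closed ellipse, C an open arc."""
    rot = math.radians(rotation_deg)
    if symbol == "O":
        span = (0.0, 2 * math.pi)
    else:  # C: arc with an opening facing right
        span = (math.radians(40), math.radians(320))
    t = np.linspace(span[0], span[1], 32)
    # slight eccentricity so it reads as handwriting, not a compass circle
    xs = radius * np.cos(t)
    ys = radius * 1.1 * np.sin(t)
    cr, sr = math.cos(rot), math.sin(rot)
    pts = np.stack([xs * cr - ys * sr, xs * sr + ys * cr], axis=1)
    return [center + pts]


def render(m: MoleculeGraph | str, params: DepictionParams | None = None,
           seed: int = 0) -> np.ndarray:
    """Render a molecule as a hand-drawn-style grayscale ink image.

    Deterministic per ``(molecule, params, seed)``. Double and triple bonds
    are drawn as parallel strokes; carbons are skeletal (no glyph) unless
    ``draw_carbon_labels`` is set or the atom is isolated; oxygens always
    get a glyph. Raises :class:`MoleculeTooLargeError` when the drawing
    cannot fit with the required margin at minimum legible bond length.
    """
    if isinstance(m, str):
        m = parse_smiles(m)
    params = params or DepictionParams()
    rng = np.random.default_rng(seed)
    size = params.canvas_px

    mol = Chem.Mol(m.to_rdkit())
    Chem.Kekulize(mol, clearAromaticFlags=True)
    coords = layout_2d(m)
    n_atoms = coords.shape[0]

    bonds = [(b.GetBeginAtomIdx(), b.GetEndAtomIdx(),
              int(b.GetBondTypeAsDouble())) for b in mol.GetBonds()]

    # fit layout to canvas with margin
    margin = params.margin_frac * size
    avail = size - 2 * margin
    span = coords.max(axis=0) - coords.min(axis=0) if n_atoms > 1 else np.array([1.0, 1.0])
    span = np.maximum(span, 1e-6)
    unit_bond = 1.5  # RDKit depiction bond length in layout units
    scale = min(avail / span[0], avail / span[1], MAX_BOND_PX / unit_bond)
    if bonds and scale * unit_bond < MIN_BOND_PX:
        raise MoleculeTooLargeError(
            f"{n_atoms} atoms cannot fit on a {size}px canvas")
    center = (coords.max(axis=0) + coords.min(axis=0)) / 2 if n_atoms > 1 else coords[0]
    pix = (coords - center) * scale
    pix[:, 1] *= -1  # image y grows downward
    pix += size / 2.0
    bond_px = scale * unit_bond

    canvas = np.full((size, size), 255, dtype=np.float64)

    symbols = [a.GetSymbol() for a in mol.GetAtoms()]
    has_glyph = [
        sym == "O" or (sym == "C" and params.draw_carbon_labels) or
        mol.GetAtomWithIdx(i).GetDegree() == 0
        for i, sym in enumerate(symbols)
    ]
    glyph_radius = np.zeros(n_atoms)
    glyph_scale = [_uniform(rng, params.char_scale) for _ in range(n_atoms)]
    for i in range(n_atoms):
        if has_glyph[i]:
            glyph_radius[i] = 0.22 * bond_px * glyph_scale[i]

    ep_jit = _uniform(rng, params.bond_endpoint_jitter) * bond_px
    wave_amp = (params.bond_endpoint_jitter[1] * bond_px * 0.6
                if params.wavy_stroke else 0.0)

    for i, j, order in bonds:
        p0, p1 = pix[i].copy(), pix[j].copy()
        # trim at glyphs so bonds do not strike through letters
        for (a, b_) in ((i, j), (j, i)):
            if glyph_radius[a] > 0:
                d = pix[b_] - pix[a]
                norm = float(np.hypot(*d))
                if norm > 0:
                    trim = min(glyph_radius[a] * 1.4, 0.45 * norm)
                    if a == i:
                        p0 = pix[i] + d / norm * trim
                    else:
                        p1 = pix[j] + (pix[i] - pix[j]) / norm * trim
        # endpoint jitter
        p0 = p0 + rng.normal(0.0, 1.0, 2) * ep_jit * 0.5
        p1 = p1 + rng.normal(0.0, 1.0, 2) * ep_jit * 0.5
        # angle jitter: rotate about the midpoint
        ang = math.radians(_uniform(rng, params.bond_angle_jitter_deg))
        ang *= 1 if rng.random() < 0.5 else -1
        mid = (p0 + p1) / 2
        ca, sa = math.cos(ang), math.sin(ang)
        rot = np.array([[ca, -sa], [sa, ca]])
        p0 = mid + rot @ (p0 - mid)
        p1 = mid + rot @ (p1 - mid)

        d = p1 - p0
        norm = float(np.hypot(*d))
        if norm == 0:
            continue
        normal = np.array([-d[1], d[0]]) / norm
        offsets = {1: [0.0], 2: [-0.09, 0.09], 3: [-0.14, 0.0, 0.14]}[order]
        for off in offsets:
            shift = normal * off * bond_px
            width = _uniform(rng, params.stroke_width_px)
            ink = _uniform(rng, params.ink_darkness)
            pts = _wavy(p0 + shift, p1 + shift, wave_amp, rng)
            _draw_polyline(canvas, pts, width, ink)

    for idx in range(n_atoms):
        if not has_glyph[idx]:
            continue
        rot_deg = _uniform(rng, params.char_rotation_deg)
        width = _uniform(rng, params.stroke_width_px)
        ink = _uniform(rng, params.ink_darkness)
        radius = glyph_radius[idx] if glyph_radius[idx] > 0 else 0.22 * bond_px
        for stroke in _glyph_strokes(symbols[idx], pix[idx], radius, rot_deg):
            _draw_polyline(canvas, stroke, width, ink)

    return as_ink_image(np.clip(canvas, 0, 255))
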