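"""Dataset orchestration: variants, manifests, mixing, and splits.

Five generation variants reproduce the synthesis ablation arms:

====================  =================================================
tag                   stage sequence
====================  =================================================
``base``              render only
``aug``               render + augmentation chain
``aug_deg``           render + augmentation + degradation
``aug_bkg``           render + augmentation + background
``aug_bkg_deg``       render + augmentation + degradation + background
====================  =================================================

The default production recipe samples ``aug_deg`` and ``aug_bkg_deg``
with equal probability, the combination found to transfer best to real
hand-drawn images. A dataset is fully determined by its config and master
seed: per-image seeds are derived from the master seed and the record
index, so regeneration is byte-identical in any execution order.

Manifests are CSV (columns ``image_path, smiles, canonical_smiles,
variant, background, seed``); mixing uses largest-remainder rounding and
splits are molecule-level so no canonical SMILES leaks across train /
validation / test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import chem_core
from .background import BACKGROUND_KINDS, augment_background, composite, make_background
from .corruption import OpChain, apply_chain, default_augment_chain, default_degrade_chain
from .depiction import DepictionParams, render
from .inkimage import save_png

VARIANTS = ("base", "aug", "aug_deg", "aug_bkg", "aug_bkg_deg")

#: stage flags per variant: (augment, degrade, background)
_VARIANT_STAGES = {
    "base": (False, False, False),
    "aug": (True, False, False),
    "aug_deg": (True, True, False),
    "aug_bkg": (True, False, True),
    "aug_bkg_deg": (True, True, True),
}

MANIFEST_COLUMNS = ("image_path", "smiles", "canonical_smiles", "variant",
                    "background", "seed")


@dataclass(frozen=True)
class DatasetConfig:
    """Everything needed to (re)build a dataset deterministically."""

    smiles: tuple[str, ...]
    n_images: int
    output_dir: str
    variant_mix: dict = field(
        default_factory=lambda: {"aug_deg": 0.5, "aug_bkg_deg": 0.5})
    depiction: DepictionParams = field(default_factory=DepictionParams)
    augment_chain: OpChain = field(default_factory=default_augment_chain)
    degrade_chain: OpChain = field(default_factory=default_degrade_chain)
    background_kinds: tuple[str, ...] = BACKGROUND_KINDS
    master_seed: int = 0
    max_rings: int = 1
    max_len: int = 30

    def __post_init__(self):
        if self.n_images < 1:
            raise ValueError("n_images must be >= 1")
        total = sum(self.variant_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"variant mix fractions sum to {total}, not 1")
        for tag in self.variant_mix:
            if tag not in VARIANTS:
                raise ValueError(f"unknown variant {tag!r}")

    @classmethod
    def from_yaml(cls, path) -> "DatasetConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "smiles_file" in raw:
            smiles = tuple(chem_core.read_smiles_file(raw.pop("smiles_file")))
        elif "enumerate" in raw:
            spec = raw.pop("enumerate")
            smiles = tuple(chem_core.enumerate_cho(
                int(spec["max_heavy_atoms"]), int(spec.get("max_rings", 1))))
        else:
            smiles = tuple(raw.pop("smiles"))
        if "depiction" in raw:
            raw["depiction"] = DepictionParams.from_dict(raw["depiction"])
        for key in ("augment_chain", "degrade_chain"):
            if key in raw:
                raw[key] = OpChain.from_config(raw[key])
        if "background_kinds" in raw:
            raw["background_kinds"] = tuple(raw["background_kinds"])
        if "variant_mix" in raw:
            raw["variant_mix"] = dict(raw["variant_mix"])
        return cls(smiles=smiles, **raw)


def largest_remainder_counts(n_total: int, fractions) -> list[int]:
    """Integer counts per class summing to ``n_total``; fractional parts
    are awarded one by one to the largest remainders (ties to the earlier
    class)."""
    fractions = list(fractions)
    raw = [n_total * f for f in fractions]
    counts = [int(np.floor(r)) for r in raw]
    short = n_total - sum(counts)
    remainders = sorted(range(len(raw)), key=lambda i: (-(raw[i] - counts[i]), i))
    for i in remainders[:short]:
        counts[i] += 1
    return counts


def _image_seed(master_seed: int, index: int) -> int:
    """Stable per-record seed below 2**31."""
    ss = np.random.SeedSequence([master_seed, index])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def build_image(smiles: str, variant: str, config: DatasetConfig,
                seed: int) -> tuple[np.ndarray, str | None]:
    """Run one record through the variant's stage sequence.

    Returns the final image and the background kind used (or None). The
    four stages draw from independent child streams of ``seed``.
    """
    do_aug, do_deg, do_bkg = _VARIANT_STAGES[variant]
    kids = np.random.SeedSequence(seed).spawn(5)
    as_int = lambda ss: int(ss.generate_state(1)[0] & 0x7FFFFFFF)
    img = render(smiles, config.depiction, seed=as_int(kids[0]))
    if do_aug:
        img = apply_chain(img, config.augment_chain, seed=as_int(kids[1]))
    if do_deg:
        img = apply_chain(img, config.degrade_chain, seed=as_int(kids[2]))
    bg_kind = None
    if do_bkg:
        rng = np.random.default_rng(kids[3])
        bg_kind = config.background_kinds[int(rng.integers(len(config.background_kinds)))]
        bg = make_background(bg_kind, config.depiction.canvas_px, as_int(kids[3]))
        bg = augment_background(bg, as_int(kids[4]))
        img = composite(img, bg)
    return img, bg_kind


def generate_dataset(config: DatasetConfig) -> pd.DataFrame:
    """Generate images and return the manifest (also written to
    ``output_dir/manifest.csv``).

    Labels are drawn round-robin from the scope-filtered SMILES source;
    variant counts follow the requested mix under largest-remainder
    rounding, interleaved deterministically.
    """
    pool = [s for s in config.smiles
            if chem_core.passes_scope_filter(s, config.max_rings, config.max_len)]
    if not pool:
        raise ValueError("no SMILES pass the scope filter")

    out_dir = Path(config.output_dir)
    img_dir = out_dir / "images"
    img_dir.mkdir(parents=True, exist_ok=True)

    tags = sorted(config.variant_mix)
    counts = largest_remainder_counts(config.n_images,
                                      [config.variant_mix[t] for t in tags])
    variant_seq = [t for t, c in zip(tags, counts) for _ in range(c)]
    # deterministic interleave so consecutive records alternate variants
    order = np.random.default_rng(
        np.random.SeedSequence([config.master_seed, 0xA11CE])).permutation(len(variant_seq))
    variant_seq = [variant_seq[i] for i in order]

    records = []
    for idx in range(config.n_images):
        smiles = pool[idx % len(pool)]
        variant = variant_seq[idx]
        seed = _image_seed(config.master_seed, idx)
        img, bg_kind = build_image(smiles, variant, config, seed)
        rel = f"images/{idx:06d}.png"
        save_png(img, out_dir / rel)
        records.append({
            "image_path": rel,
            "smiles": smiles,
            "canonical_smiles": chem_core.canonicalize(smiles),
            "variant": variant,
            "background": bg_kind or "",
            "seed": seed,
        })
    manifest = pd.DataFrame.from_records(records, columns=list(MANIFEST_COLUMNS))
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    _write_provenance(out_dir, config)
    return manifest


def _write_provenance(out_dir: Path, config: DatasetConfig) -> None:
    meta = {
        "n_images": config.n_images,
        "master_seed": config.master_seed,
        "variant_mix": config.variant_mix,
        "depiction": config.depiction.to_dict(),
        "augment_chain_hash": config.augment_chain.hash(),
        "degrade_chain_hash": config.degrade_chain.hash(),
        "background_kinds": list(config.background_kinds),
    }
    with open(out_dir / "provenance.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)


def load_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns {sorted(missing)}")
    return df


@dataclass(frozen=True)
class MixSpec:
    """Synthetic : real mixing fractions (both in [0, 1], summing to 1)."""

    synthetic_fraction: float
    real_fraction: float

    def __post_init__(self):
        for f in (self.synthetic_fraction, self.real_fraction):
            if not 0.0 <= f <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if abs(self.synthetic_fraction + self.real_fraction - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")

    @classmethod
    def from_ratio(cls, ratio: str) -> "MixSpec":
        """Parse e.g. ``"90:10"`` into fractions."""
        syn, real = (float(x) for x in ratio.split(":"))
        total = syn + real
        return cls(syn / total, real / total)


def mix_datasets(synthetic: pd.DataFrame, real: pd.DataFrame, spec: MixSpec,
                 n_total: int, seed: int) -> pd.DataFrame:
    """Sample a training manifest mixing synthetic and real records.

    Counts per source follow largest-remainder rounding of the requested
    fractions; sampling is without replacement and seeded.
    """
    n_syn, n_real = largest_remainder_counts(
        n_total, [spec.synthetic_fraction, spec.real_fraction])
    for name, df, need in (("synthetic", synthetic, n_syn), ("real", real, n_real)):
        if len(df) < need:
            raise ValueError(
                f"{name} manifest has {len(df)} records, needs {need} "
                f"(short by {need - len(df)})")
    rng = np.random.default_rng(seed)
    parts = []
    for df, need, source in ((synthetic, n_syn, "synthetic"), (real, n_real, "real")):
        idx = rng.choice(len(df), size=need, replace=False)
        part = df.iloc[np.sort(idx)].copy()
        part["source"] = source
        parts.append(part)
    return pd.concat(parts, ignore_index=True)


def split_by_molecule(manifest: pd.DataFrame,
                      fractions: tuple[float, float, float],
                      seed: int) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Partition records into train/val/test with no molecule overlap.

    Molecules (canonical SMILES) are shuffled and allotted to splits by
    largest-remainder rounding of the molecule counts, so every record of
    a molecule lands in exactly one split.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    molecules = sorted(manifest["canonical_smiles"].unique())
    n_nonzero = sum(1 for f in fractions if f > 0)
    if len(molecules) < n_nonzero:
        raise ValueError(
            f"only {len(molecules)} distinct molecules for {n_nonzero} splits")
    rng = np.random.default_rng(seed)
    shuffled = [molecules[i] for i in rng.permutation(len(molecules))]
    counts = largest_remainder_counts(len(molecules), fractions)
    out = []
    start = 0
    for c in counts:
        chunk = set(shuffled[start:start + c])
        out.append(manifest[manifest["canonical_smiles"].isin(chunk)]
                   .reset_index(drop=True))
        start += c
    return tuple(out)
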