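"""Dataset generation, mixing, and molecule-level splitting."""

import numpy as np
import pandas as pd
import pytest

from inkmol import chem_core
from inkmol import dataset_builder as db
from inkmol.corruption import OpChain, OpSpec
from inkmol.depiction import DepictionParams


def small_config(tmp_path, **overrides):
    defaults = dict(
        smiles=tuple(chem_core.enumerate_cho(3, 1)),
        n_images=12,
        output_dir=str(tmp_path / "ds"),
        depiction=DepictionParams(canvas_px=96),
        master_seed=5,
    )
    defaults.update(overrides)
    return db.DatasetConfig(**defaults)


class TestLargestRemainder:
    @pytest.mark.parametrize("n,fracs,expected", [
        (1000, (0.9, 0.1), [900, 100]),
        (3, (0.5, 0.5), [2, 1]),
        (7, (0.5, 0.5), [4, 3]),
        (10, (0.5, 0.5), [5, 5]),
        (10, (0.8, 0.1, 0.1), [8, 1, 1]),
        (100, (1.0, 0.0), [100, 0]),
    ])
    def test_counts(self, n, fracs, expected):
        counts = db.largest_remainder_counts(n, fracs)
        assert counts == expected
        assert sum(counts) == n


class TestGenerate:
    def test_manifest_and_files(self, tmp_path):
        cfg = small_config(tmp_path)
        manifest = db.generate_dataset(cfg)
        assert len(manifest) == cfg.n_images
        root = tmp_path / "ds"
        for _, row in manifest.iterrows():
            assert (root / row.image_path).exists()
            assert row.canonical_smiles == chem_core.canonicalize(row.smiles)
            assert chem_core.passes_scope_filter(row.smiles)

    def test_run_twice_byte_identical(self, tmp_path):
        m1 = db.generate_dataset(small_config(tmp_path / "a"))
        m2 = db.generate_dataset(small_config(tmp_path / "b"))
        pd.testing.assert_frame_equal(m1, m2)
        for rel in m1.image_path:
            assert ((tmp_path / "a/ds" / rel).read_bytes()
                    == (tmp_path / "b/ds" / rel).read_bytes())

    def test_variant_counts_match_mix(self, tmp_path):
        cfg = small_config(tmp_path, n_images=100,
                           variant_mix={"aug_deg": 0.5, "aug_bkg_deg": 0.5})
        manifest = db.generate_dataset(cfg)
        counts = manifest["variant"].value_counts()
        assert counts["aug_deg"] == 50 and counts["aug_bkg_deg"] == 50

    def test_background_recorded_only_for_bkg_variants(self, tmp_path):
        cfg = small_config(tmp_path, n_images=20,
                           variant_mix={"aug_deg": 0.5, "aug_bkg_deg": 0.5})
        manifest = db.generate_dataset(cfg)
        with_bg = manifest[manifest.variant == "aug_bkg_deg"]
        without = manifest[manifest.variant == "aug_deg"]
        assert (with_bg.background != "").all()
        assert (without.background == "").all()

    def test_empty_filtered_source_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="scope"):
            db.generate_dataset(small_config(tmp_path, smiles=("CCN", "CCS")))

    def test_bad_mix_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            small_config(tmp_path, variant_mix={"aug_deg": 0.7})

    def test_yaml_config_round_trip(self, tmp_path):
        cfg_path = tmp_path / "cfg.yaml"
        cfg_path.write_text(
            "enumerate: {max_heavy_atoms: 3}\n"
            "n_images: 4\n"
            f"output_dir: {tmp_path / 'out'}\n"
            "master_seed: 2\n"
            "depiction: {canvas_px: 96}\n")
        cfg = db.DatasetConfig.from_yaml(cfg_path)
        assert cfg.n_images == 4
        assert cfg.depiction.canvas_px == 96
        assert set(cfg.smiles) == set(chem_core.enumerate_cho(3, 1))


class TestVariantSemantics:
    """The five stage sequences are distinguishable and collapse to the
    base rendering when every chain op has p=0."""

    def test_distinct_from_base_with_active_chains(self, tmp_path):
        cfg = small_config(tmp_path)
        seed = 123
        base, _ = db.build_image("CCO", "base", cfg, seed)
        for tag in ("aug", "aug_deg", "aug_bkg", "aug_bkg_deg"):
            img, _ = db.build_image("CCO", tag, cfg, seed)
            diff = np.abs(img.astype(float) - base.astype(float)).mean()
            assert diff > 0, tag

    def test_p_zero_chains_reproduce_base(self, tmp_path):
        dead_aug = OpChain(tuple(OpSpec(s.name, s.params, p=0.0)
                                 for s in db.default_augment_chain().ops))
        dead_deg = OpChain(tuple(OpSpec(s.name, s.params, p=0.0)
                                 for s in db.default_degrade_chain().ops))
        cfg = small_config(tmp_path, augment_chain=dead_aug,
                           degrade_chain=dead_deg)
        base, _ = db.build_image("CCO", "base", cfg, 7)
        aug, _ = db.build_image("CCO", "aug", cfg, 7)
        aug_deg, _ = db.build_image("CCO", "aug_deg", cfg, 7)
        assert (aug == base).all()
        assert (aug_deg == base).all()


class TestMixing:
    def _manifests(self, n_syn=1200, n_real=300):
        syn = pd.DataFrame({
            "image_path": [f"s{i}.png" for i in range(n_syn)],
            "smiles": "CCO", "canonical_smiles": "CCO",
            "variant": "aug_deg", "background": "", "seed": range(n_syn)})
        real = pd.DataFrame({
            "image_path": [f"r{i}.png" for i in range(n_real)],
            "smiles": "C=O", "canonical_smiles": "C=O",
            "variant": "base", "background": "", "seed": range(n_real)})
        return syn, real

    def test_90_10_exact_counts(self):
        syn, real = self._manifests()
        out = db.mix_datasets(syn, real, db.MixSpec.from_ratio("90:10"),
                              n_total=1000, seed=0)
        assert len(out) == 1000
        assert (out.source == "synthetic").sum() == 900
        assert (out.source == "real").sum() == 100

    def test_all_synthetic(self):
        syn, real = self._manifests()
        out = db.mix_datasets(syn, real, db.MixSpec.from_ratio("100:0"),
                              n_total=50, seed=1)
        assert (out.source == "synthetic").all()

    @pytest.mark.parametrize("n_total,expected", [(3, (2, 1)), (7, (4, 3)),
                                                  (10, (5, 5))])
    def test_50_50_largest_remainder(self, n_total, expected):
        syn, real = self._manifests()
        out = db.mix_datasets(syn, real, db.MixSpec.from_ratio("50:50"),
                              n_total=n_total, seed=2)
        assert ((out.source == "synthetic").sum(),
                (out.source == "real").sum()) == expected

    def test_deterministic_per_seed(self):
        syn, real = self._manifests()
        spec = db.MixSpec.from_ratio("50:50")
        a = db.mix_datasets(syn, real, spec, 100, seed=9)
        b = db.mix_datasets(syn, real, spec, 100, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_insufficient_records_reports_deficit(self):
        syn, real = self._manifests(n_real=5)
        with pytest.raises(ValueError, match="short by 95"):
            db.mix_datasets(syn, real, db.MixSpec.from_ratio("0:100"),
                            n_total=100, seed=0)

    def test_bad_spec_rejected(self):
        with pytest.raises(ValueError):
            db.MixSpec(0.7, 0.7)


class TestSplit:
    def _manifest(self, molecules=10, images_per=4):
        smiles = chem_core.enumerate_cho(4, 1)[:molecules]
        rows = [{"image_path": f"{s}_{k}.png", "smiles": s,
                 "canonical_smiles": s, "variant": "base", "background": "",
                 "seed": k}
                for s in smiles for k in range(images_per)]
        return pd.DataFrame(rows)

    def test_no_molecule_leaks_across_splits(self):
        manifest = self._manifest()
        tr, va, te = db.split_by_molecule(manifest, (0.8, 0.1, 0.1), seed=0)
        sets = [set(df.canonical_smiles) for df in (tr, va, te)]
        assert not (sets[0] & sets[1] or sets[0] & sets[2] or sets[1] & sets[2])

    def test_partition_preserves_records(self):
        manifest = self._manifest()
        parts = db.split_by_molecule(manifest, (0.8, 0.1, 0.1), seed=1)
        recovered = pd.concat(parts).sort_values("image_path")
        assert sorted(recovered.image_path) == sorted(manifest.image_path)

    def test_ten_molecules_8_1_1(self):
        parts = db.split_by_molecule(self._manifest(10), (0.8, 0.1, 0.1),
                                     seed=3)
        assert [df.canonical_smiles.nunique() for df in parts] == [8, 1, 1]

    def test_too_few_molecules_rejected(self):
        with pytest.raises(ValueError):
            db.split_by_molecule(self._manifest(2), (0.8, 0.1, 0.1), seed=0)
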