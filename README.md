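# inkmol

Synthetic hand-drawn chemical-structure images, and a desk-scale
image-to-SMILES recognizer, for small C/H/O molecules.

## The problem

Optical chemical structure recognition (OCSR) converts a drawing of a
molecule into a machine-readable encoding, usually a SMILES string. For
*hand-drawn* structures — the kind students write on exams and chemists
scribble in notebooks — almost no labeled training data exists, and
collecting it is slow: a volunteer needs 2–3 minutes per drawing. The
practical way forward is synthesis: render molecules with deliberately
sloppy, hand-writing-like geometry, then corrupt and composite the images
until they resemble photographed notebook pages, and train an
encoder-decoder on millions of such images mixed with a small amount of
real data.

`inkmol` implements that pipeline end to end for the chemistry scope of
carbon, hydrogen and oxygen with at most one ring:

- **chem_core** — SMILES parsing/canonicalization (via RDKit), a
  character-level tokenizer over the generation alphabet
  `# ( ) 1 = C O c o` with a 30-character length cap, the scope filter,
  and an exhaustive enumerator of C/H/O molecules up to 8 heavy atoms
  (so no database download is ever needed).
- **diversity** — Morgan fingerprints, the Tanimoto coefficient
  T(A,B) = |A∩B| / |A∪B|, and greedy MaxMin diverse-subset selection.
- **depiction** — a hand-drawn-style renderer: RDKit 2D layout plus this
  package's own perturbation layer (bond endpoint/angle jitter, wavy
  tremor strokes, random stroke widths, parametric O/C letter glyphs).
- **corruption** — probabilistic augmentation (rotate, shear, elastic
  warp, stroke width, noise, blur) and degradation (resolution loss,
  blocking artifacts, patch erasure, fade, ink bleed) chains; every op
  fires independently with probability *p*.
- **background** — procedural paper backgrounds (plain/ruled/grid/noise/
  stained), background augmentation, min-blend compositing.
- **dataset_builder** — the five generation variants (`base`, `aug`,
  `aug_deg`, `aug_bkg`, `aug_bkg_deg`), CSV manifests, synthetic:real
  mixing at ratios such as 90:10 with largest-remainder rounding, and
  molecule-level train/val/test splits.
- **metrics** — Exact Match on canonical SMILES, Levenshtein distance,
  Tanimoto similarity, and aggregate reports.
- **recognition** — a small CNN encoder + transformer decoder
  (numpy, with its own reverse-mode autograd) that trains in minutes on
  one CPU and demonstrates the full generate → train → evaluate loop.

## Worked example

```bash
# 1. build a corpus (all 529 C/H/O molecules up to 5 heavy atoms)
inkmol enumerate --max-heavy-atoms 5 --out corpus.smi

# 2. generate 200 labeled images with the production recipe
cat > cfg.yaml <<EOF
smiles_file: corpus.smi
n_images: 200
output_dir: unused
variant_mix: {aug_deg: 0.5, aug_bkg_deg: 0.5}
master_seed: 11
EOF
inkmol generate --config cfg.yaml --out ds
# -> wrote 200 images to ds

# 3. split with no molecule shared between subsets
inkmol split --manifest ds/manifest.csv --fractions 0.8,0.1,0.1 --seed 3 --out-prefix ds/part
# -> train: 160 records -> ds/part.train.csv ...

# 4. score predictions against ground truth
printf 'CCO\nC=O\nxx\nC\n'  > preds.txt
printf 'OCC\nC=O\nCC\nO\n' > truths.txt
inkmol evaluate --pred preds.txt --truth truths.txt --report report.json
```

The evaluation prints:

```json
{
  "n_pairs": 4,
  "exact_match_rate": 0.5,
  "mean_levenshtein": 1.25,
  "mean_tanimoto": 0.5,
  "n_invalid_predictions": 1
}
```

`CCO` matches `OCC` because Exact Match compares canonical SMILES — both
spell ethanol; `xx` does not parse, so it counts as an invalid
prediction with similarity 0.

Training the demo recognizer (`inkmol train-demo --train ... --val ...`)
on 10 molecules × 80 clean renderings each reaches ≥ 95 % held-out Exact
Match within a handful of epochs on one CPU; the equivalent library call
is shown in `tests/test_acceptance.py`.

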