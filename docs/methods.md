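# Methods

## Chemical scope and encodings

The pipeline covers molecules built from carbon, hydrogen and oxygen with
at most one ring and SMILES labels of at most 30 characters. The label
alphabet is the nine characters `# ( ) 1 = C O c o`: triple/double bond
symbols, branch parentheses, a single ring-closure digit (sufficient for
one ring), and aliphatic/aromatic C and O. Hydrogens are always implicit,
so `H` never appears in a label. Both Kekulé (`C1=CC=CC=C1`) and aromatic
(`c1ccccc1`) spellings are representable, since canonicalization of an
alternating six-ring naturally yields the aromatic form.

Parsing, valence checking, canonical atom ranking and 2D depiction
coordinates are delegated to RDKit; re-deriving Morgan canonical ranking
would add risk without adding science. The contracts we rely on —
idempotence of canonicalization and invariance under input atom
reordering — are what the tests pin down. Randomized SMILES spellings are
produced by renumbering atoms with a seeded permutation and writing
non-canonically, which makes them deterministic per seed (RDKit's own
`doRandom` writer has no seam for seeding).

### Exhaustive enumeration

Rather than downloading corpora, `enumerate_cho(n, r)` enumerates every
valence-valid connected C/O heavy-atom multigraph with ≤ n heavy atoms
and ≤ r rings: non-isomorphic tree skeletons (via networkx), plus one
extra edge for the unicyclic case, crossed with element assignments and
bond orders under valence pruning (C ≤ 4, O ≤ 2), sanitized by RDKit and
deduplicated by canonical SMILES. The enumeration is the package's own
brute force; the n = 1 (`C`, `O`) and n = 2 (9 molecules) outputs are
hand-verifiable against valence rules, and the n = 3 (34) and n = 4
(130) counts are pinned in tests as regression values. The guard at 8
heavy atoms keeps the combinatorics desk-sized. Note the enumeration is
deliberately valence-complete rather than stability-filtered: strained
species such as cyclopropyne count as molecules here.

## Hand-drawn rendering

The renderer separates *layout* (RDKit's deterministic 2D coordinates,
uniform bond length) from *perturbation and rasterization*, which are
owned by this package so the hand-drawn look is testable and independent
of toolkit internals:

- bond endpoint jitter (uniform fraction of bond length, default 0–0.08)
  and per-bond angle jitter (default 0–8°);
- wavy strokes: a sinusoidal displacement perpendicular to each stroke
  with 0.8–1.8 cycles, random phase, amplitude tied to the endpoint
  jitter setting and tapered to zero at the stroke ends (hand tremor);
- stroke width (default 1–4 px) and ink darkness (default 0–60 of 255)
  sampled per stroke;
- letter glyphs drawn parametrically — O as a slightly eccentric ellipse,
  C (only for isolated atoms, or when carbon labels are enabled) as an
  open arc — with per-image scale (0.8–1.3) and rotation (±12°); bonds
  are trimmed where they meet a glyph;
- double/triple bonds as parallel strokes offset ±0.09/±0.14 bond
  lengths; aromatic rings are Kekulized before drawing.

All ranges are uniform draws from a single `numpy` Generator seeded per
image, so a `(molecule, params, seed)` triple renders byte-identically,
and fully degenerate ranges (`DepictionParams.clean()`) give a
seed-independent clean depiction. Stroke rasterization stamps disks at
~0.5 px spacing along the (possibly wavy) polyline, which makes ink
coverage monotone in stroke width — a property the tests exercise. The
default canvas is 256×256 8-bit grayscale; rendering raises an error if
the molecule cannot fit with an 8 % margin at a minimum legible bond
length of 6 px. Magnitudes were chosen to visually match handwriting;
they are config-exposed, not claimed to be anyone's measured values.

## Corruption chains

Augmentation and degradation are ordered chains of registered ops, each
firing independently with probability p (default 0.5). Augmentation
models drawing variation: rotation ±10°, shear ±8°, elastic warp
(Gaussian-smoothed displacement field, α = 12, σ = 6), morphological
stroke thickening/thinning, Gaussian noise (σ = 10), salt-and-pepper
(1 %), mild blur. Degradation models capture loss: downscale–upscale by
2–4×, JPEG-like blocking (per-8×8-block DCT truncated to 3×3
coefficients), white-patch erasure, contrast fade, ink bleed
(dilate + blur). Exact parameters in the source of record are the
`corruption` module defaults; the registry is extensible without API
change.

Randomness is counter-based: op *i* of a chain draws from child stream
*i* of the chain seed (numpy `SeedSequence.spawn`), so whether one op
fires never perturbs later ops, firing events are independent across
ops, and datasets are reproducible regardless of generation order. The
empirical firing rate of a p = 0.5 op over 2 000 seeded trials is
0.489 in the test suite, within the expected binomial band.

## Backgrounds and compositing

Backgrounds are procedural (plain, ruled, grid, noise, stained) so the
package needs no image downloads; user PNGs enter through the same
compositing call. Every background is augmented (±6° rotation, 75–100 %
crop-zoom, brightness 0.85–1.1×) before use, because a model trained
against one fixed texture learns to subtract that texture and then fails
on new backgrounds. Compositing is the per-pixel minimum of ink and
paper: ink can only darken, so the set of ink pixels survives
compositing exactly — an invariant the tests check.

## Dataset builder

The five variants (`base`, `aug`, `aug_deg`, `aug_bkg`, `aug_bkg_deg`)
are stage sequences over render → augment → degrade → composite. The
default production mix draws `aug_deg` and `aug_bkg_deg` with equal
probability — the combination that transfers best to real hand-drawn
test images in the ablation this pipeline reproduces in miniature.
Mixing of synthetic with real manifests uses largest-remainder rounding
(90:10 of 1000 is exactly 900 + 100) and seeded sampling without
replacement. Splits are molecule-level: image-level splitting would put
renderings of the same molecule in both train and test, leaking labels.
Per-image seeds derive from `SeedSequence([master_seed, record_index])`,
making a dataset a pure function of its config.

## Metrics

Exact Match compares canonical SMILES (a raw-string mode exists behind a
flag): a prediction that spells the right molecule differently still
counts, and an unparseable prediction never counts. Levenshtein distance
is the unit-cost DP, written here because it is one of the three
reported measures and its correctness is pinned against an exhaustive
suffix-recursion oracle over the `{C, O, =}` alphabet (and against
`edlib` where available). Tanimoto similarity uses Morgan fingerprints
(radius 2, 2048 bits), the field's default substrate; invalid
predictions score 0 rather than being dropped, since dropping them would
inflate averages. MaxMin selection defines distance as 1 − Tanimoto,
starts from a seeded uniform pick and breaks ties toward the lowest
index, so selections are reproducible; the greedy step-optimality
condition is verified by brute force in the tests.

## Recognition model

The recognizer is the standard OCSR shape — a convolutional encoder
producing a spatial feature grid, and an autoregressive transformer
decoder attending over it — implemented in numpy on a minimal
reverse-mode autograd engine (`inkmol.nn`), sized to train in minutes on
one CPU. Encoder: images resized to 64×64, ink-positive in [0, 1];
three stride-2 3×3 convolutions (16, 32, 64 channels) giving an 8×8
grid, projected to d_model = 128 with a learned 2D positional embedding.
Decoder: 2 pre-norm transformer layers, 4 heads, feed-forward 256,
learned token and position embeddings, greedy decoding capped at 32
tokens (30-character labels plus start/end framing). Training is
teacher-forced cross entropy with Adam; initialization and batch order
derive from one seed. Gradient correctness is established by finite
difference checks in the test suite.

This is a contract-faithful demonstration, not a production OCSR engine:
the headline accuracies in this literature come from ImageNet-pretrained
backbones, ~10⁶ training images and GPU weeks, all outside desk scale.
The package's learnability experiment instead uses 10 molecules × 100
clean renderings split 80/20 by rendering seed (the model must
generalize across drawing jitter, not across chemistry); with learning
rate 10⁻³, batch 32 and early stopping once validation Exact Match
reaches 0.95 (cap 30 epochs), it reaches ≈ 0.95–0.96 held-out Exact
Match in about five epochs (~1 minute). Those problem sizes are the
package's chosen desk scale for a reproducible, minutes-long experiment.

## What the synthetic data does and does not show

The generator emulates geometric sloppiness, stroke variation, capture
degradation and paper backgrounds. It does not emulate personal
handwriting styles, letter-form idiosyncrasies, perspective distortion
of photographed pages, shadows, or ink chemistry; and the desk-scale
recognition experiment covers 10 molecules, not open-set chemistry.
Passing tests therefore demonstrate pipeline correctness and
trainability on synthetic distributions — they do not certify accuracy
on real hand-drawn images, which in the full-scale setting additionally
requires mixing ~10 % real drawings into training.

## Numerical and degenerate-input choices

- 0/0 Tanimoto (two empty fingerprints) is defined as 1.0: identical
  objects.
- Largest-remainder rounding breaks remainder ties toward the
  earlier-listed class.
- A single-atom molecule renders as its letter glyph (skeletal
  convention would otherwise draw nothing for methane).
- Images are uint8 throughout; chains compute in float64 and clip once
  at the end.
- Parse errors distinguish syntax failures (with the position of an
  unbalanced parenthesis when determinable) from valence violations.
- All derived seeds stay below 2³¹.
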