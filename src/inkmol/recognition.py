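"""Desk-scale image-to-SMILES encoder-decoder.

A convolutional encoder turns the ink image into a spatial grid of feature
vectors; an autoregressive transformer decoder attends over that grid and
emits SMILES tokens until the end symbol. The architecture mirrors the
CNN-encoder + transformer-decoder recipe standard in optical chemical
structure recognition, sized to train in minutes on one CPU: it is a
contract-faithful demonstration of the pipeline, not a production OCSR
engine (that takes millions of images, a pretrained backbone and GPUs).

Training uses teacher-forced cross entropy with the Adam optimizer;
greedy decoding is used at inference. All randomness (initialization,
batch order) is seeded.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from skimage.transform import resize

from .chem_core import Vocabulary, detokenize, tokenize
from .inkimage import as_ink_image
from .nn import (Adam, Conv2d, DecoderLayer, LayerNorm, Linear, Module,
                 Tensor, cross_entropy, embedding)


@dataclass(frozen=True)
class ModelConfig:
    """Architecture of the recognizer.

    ``input_px`` is the side length images are resized to before the
    encoder; ``encoder_channels`` lists the channel width of each stride-2
    convolution, so the feature grid is ``input_px / 2**len(channels)`` on
    a side. ``max_decode_len`` bounds the emitted token sequence including
    the start/end framing (30-character labels + 2).
    """

    encoder_family: str = "small_cnn"
    input_px: int = 64
    encoder_channels: tuple[int, ...] = (16, 32, 64)
    d_model: int = 128
    n_heads: int = 4
    n_layers: int = 2
    d_ff: int = 256
    max_decode_len: int = 32

    def __post_init__(self):
        if self.encoder_family != "small_cnn":
            raise ValueError(
                f"unsupported encoder family {self.encoder_family!r}; "
                "this build trains offline from scratch (small_cnn)")
        if self.d_model % self.n_heads:
            raise ValueError("n_heads must divide d_model")

    @property
    def grid_side(self) -> int:
        return self.input_px // (2 ** len(self.encoder_channels))


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings (Adam; defaults follow the standard recipe of
    lr 1e-4, 100 epochs, batch 32 — scale epochs down for desk runs)."""

    learning_rate: float = 1e-4
    epochs: int = 100
    batch_size: int = 32
    seed: int = 0
    early_stop_exact_match: float | None = None

    def __post_init__(self):
        if self.learning_rate <= 0 or self.epochs < 1 or self.batch_size < 1:
            raise ValueError("learning_rate, epochs, batch_size must be positive")


class Recognizer(Module):
    """CNN encoder + transformer decoder over a SMILES vocabulary."""

    def __init__(self, config: ModelConfig, vocab: Vocabulary, seed: int = 0):
        self.config = config
        self.vocab = vocab
        rng = np.random.default_rng(seed)
        chans = (1,) + tuple(config.encoder_channels)
        self.convs = [Conv2d(rng, chans[i], chans[i + 1], kernel=3, stride=2,
                             pad=1) for i in range(len(config.encoder_channels))]
        self.proj = Linear(rng, chans[-1], config.d_model)
        n_mem = config.grid_side ** 2
        self.pos_enc = Tensor(
            rng.normal(0, 0.02, (n_mem, config.d_model)).astype(np.float32),
            requires_grad=True)
        self.tok_emb = Tensor(
            rng.normal(0, 0.02, (len(vocab), config.d_model)).astype(np.float32),
            requires_grad=True)
        self.pos_dec = Tensor(
            rng.normal(0, 0.02, (config.max_decode_len, config.d_model)).astype(np.float32),
            requires_grad=True)
        self.layers = [DecoderLayer(rng, config.d_model, config.n_heads,
                                    config.d_ff)
                       for _ in range(config.n_layers)]
        self.ln_out = LayerNorm(config.d_model)
        self.head = Linear(rng, config.d_model, len(vocab))

    # -- encoder -----------------------------------------------------------

    def preprocess(self, imgs: Sequence[np.ndarray]) -> np.ndarray:
        """Resize to the model input size and map to [0, 1] ink-positive
        floats (ink bright, paper zero)."""
        s = self.config.input_px
        out = np.empty((len(imgs), 1, s, s), dtype=np.float32)
        for i, img in enumerate(imgs):
            img = as_ink_image(img).astype(np.float32) / 255.0
            if img.shape != (s, s):
                img = resize(img, (s, s), preserve_range=True,
                             anti_aliasing=True)
            out[i, 0] = 1.0 - img
        return out

    def encode(self, batch: np.ndarray) -> Tensor:
        """Feature grid for a preprocessed batch, shape (B, grid^2, d)."""
        x = Tensor(batch)
        for conv in self.convs:
            x = conv(x).relu()
        B, C, H, W = x.shape
        grid = x.reshape(B, C, H * W).transpose(0, 2, 1)
        return self.proj(grid) + self.pos_enc

    # -- decoder -----------------------------------------------------------

    def decode_logits(self, memory: Tensor, token_ids: np.ndarray) -> Tensor:
        """Teacher-forced logits, shape (B, L, V)."""
        L = token_ids.shape[1]
        x = embedding(self.tok_emb, token_ids) + Tensor(self.pos_dec.data[:L])
        for layer in self.layers:
            x = layer(x, memory)
        return self.head(self.ln_out(x))

    def greedy_decode(self, memory: Tensor,
                      max_len: int | None = None) -> list[list[int]]:
        """Batched greedy decoding; each row stops at EOS or ``max_len``."""
        max_len = max_len or self.config.max_decode_len
        B = memory.shape[0]
        ids = np.full((B, 1), self.vocab.bos_id, dtype=np.int64)
        done = np.zeros(B, dtype=bool)
        for _ in range(max_len - 1):
            logits = self.decode_logits(memory, ids)
            nxt = logits.data[:, -1, :].argmax(axis=-1)
            nxt[done] = self.vocab.pad_id
            ids = np.concatenate([ids, nxt[:, None]], axis=1)
            done |= nxt == self.vocab.eos_id
            if done.all():
                break
        return [row.tolist() for row in ids]

    def predict(self, imgs: Sequence[np.ndarray],
                batch_size: int = 64) -> list[str]:
        """SMILES strings for raw ink images (greedy decode, detokenized).

        Outputs may be chemically invalid; the metrics layer scores those
        as non-matches.
        """
        out = []
        for lo in range(0, len(imgs), batch_size):
            batch = self.preprocess(imgs[lo:lo + batch_size])
            memory = self.encode(batch)
            for seq in self.greedy_decode(memory):
                out.append(detokenize(seq, self.vocab))
        return out

    # -- persistence ---------------------------------------------------------

    def save(self, model_dir) -> None:
        model_dir = Path(model_dir)
        model_dir.mkdir(parents=True, exist_ok=True)
        arrays = {f"p{i}": p.data for i, p in enumerate(self.params())}
        np.savez(model_dir / "weights.npz", **arrays)
        meta = {"model": asdict(self.config),
                "vocab": json.loads(self.vocab.to_json())}
        (model_dir / "config.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, model_dir) -> "Recognizer":
        model_dir = Path(model_dir)
        meta = json.loads((model_dir / "config.json").read_text())
        mc = dict(meta["model"])
        mc["encoder_channels"] = tuple(mc["encoder_channels"])
        vocab = Vocabulary(tokens=tuple(meta["vocab"]["tokens"]),
                           max_len=int(meta["vocab"]["max_len"]))
        model = cls(ModelConfig(**mc), vocab)
        with np.load(model_dir / "weights.npz") as data:
            for i, p in enumerate(model.params()):
                p.data[...] = data[f"p{i}"]
        return model


def _batch_tokens(labels: Sequence[str], vocab: Vocabulary,
                  max_len: int) -> tuple[np.ndarray, np.ndarray]:
    """Right-padded token matrix and its validity mask."""
    ids = np.full((len(labels), max_len), vocab.pad_id, dtype=np.int64)
    mask = np.zeros((len(labels), max_len), dtype=bool)
    for i, text in enumerate(labels):
        toks = tokenize(text, vocab)
        if len(toks) > max_len:
            raise ValueError(
                f"label {text!r} needs {len(toks)} tokens, over the "
                f"decoder limit {max_len}")
        ids[i, :len(toks)] = toks
        mask[i, :len(toks)] = True
    return ids, mask


def exact_match_rate(model: Recognizer, imgs: Sequence[np.ndarray],
                     labels: Sequence[str]) -> float:
    from .metrics import exact_match
    preds = model.predict(imgs)
    return float(np.mean([exact_match(p, t) for p, t in zip(preds, labels)]))


def train(train_images: Sequence[np.ndarray], train_labels: Sequence[str],
          val_images: Sequence[np.ndarray], val_labels: Sequence[str],
          model_cfg: ModelConfig | None = None,
          train_cfg: TrainConfig | None = None,
          vocab: Vocabulary | None = None,
          verbose: bool = False) -> tuple[Recognizer, list[dict]]:
    """Train a recognizer with teacher forcing.

    Returns the model and a per-epoch history of mean training loss and
    validation Exact Match. Initialization and batch order derive from
    ``train_cfg.seed``. Training stops early once validation Exact Match
    reaches ``early_stop_exact_match`` (if set); the history then has
    fewer entries than requested epochs.
    """
    if not len(train_images):
        raise ValueError("empty training manifest")
    model_cfg = model_cfg or ModelConfig()
    train_cfg = train_cfg or TrainConfig()
    vocab = vocab or Vocabulary()

    model = Recognizer(model_cfg, vocab, seed=train_cfg.seed)
    ids, mask = _batch_tokens(train_labels, vocab, model_cfg.max_decode_len)
    x_all = model.preprocess(train_images)
    opt = Adam(model.params(), lr=train_cfg.learning_rate)
    rng = np.random.default_rng(np.random.SeedSequence([train_cfg.seed, 1]))

    history: list[dict] = []
    n = len(train_images)
    for epoch in range(train_cfg.epochs):
        order = rng.permutation(n)
        losses = []
        t0 = time.time()
        for lo in range(0, n, train_cfg.batch_size):
            sel = order[lo:lo + train_cfg.batch_size]
            memory = model.encode(x_all[sel])
            logits = model.decode_logits(memory, ids[sel][:, :-1])
            loss = cross_entropy(logits, ids[sel][:, 1:], mask[sel][:, 1:])
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        val_em = (exact_match_rate(model, val_images, val_labels)
                  if len(val_images) else float("nan"))
        history.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                        "val_exact_match": val_em,
                        "seconds": time.time() - t0})
        if verbose:
            h = history[-1]
            print(f"epoch {epoch:3d}  loss {h['train_loss']:.4f}  "
                  f"val EM {val_em:.3f}  ({h['seconds']:.1f}s)")
        if (train_cfg.early_stop_exact_match is not None
                and val_em >= train_cfg.early_stop_exact_match):
            break
    return model, history
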