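"""Molecular fingerprints, Tanimoto similarity, and MaxMin subset selection.

The MaxMin picker chooses a maximally diverse subset of a molecule pool:
starting from a seeded random pick, it repeatedly adds the candidate whose
minimum distance (1 - Tanimoto) to the already-selected set is largest.
The greedy condition at every step is the tested contract; ties break to
the lowest pool index so selections are reproducible.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from rdkit.Chem import rdFingerprintGenerator

from .chem_core import MoleculeGraph, parse_smiles

FP_RADIUS = 2
FP_BITS = 2048


def fingerprint(m: MoleculeGraph | str, radius: int = FP_RADIUS,
                n_bits: int = FP_BITS) -> np.ndarray:
    """Hashed circular (Morgan) fingerprint as a boolean numpy array.

    Deterministic; isomorphic graphs map to identical bitsets.
    """
    if isinstance(m, str):
        m = parse_smiles(m)
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    fp = gen.GetFingerprint(m.to_rdkit())
    arr = np.zeros(n_bits, dtype=bool)
    arr[list(fp.GetOnBits())] = True
    return arr


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto similarity |a AND b| / |a OR b| of two equal-length bitsets.

    Two all-zero bitsets are defined as identical (similarity 1.0).
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"fingerprint length mismatch: {a.shape} vs {b.shape}")
    union = np.count_nonzero(a | b)
    if union == 0:
        return 1.0
    return np.count_nonzero(a & b) / union


def maxmin_select(pool: Sequence[np.ndarray], k: int, seed: int) -> list[int]:
    """Greedy MaxMin diverse-subset selection over fingerprint bitsets.

    Returns ``k`` pool indices. The first is drawn uniformly with ``seed``;
    each later pick maximizes the minimum Tanimoto distance to everything
    selected so far, breaking ties toward the lowest index.
    """
    n = len(pool)
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range for pool of {n}")
    mat = np.stack([np.asarray(fp, dtype=bool) for fp in pool])
    rng = np.random.default_rng(seed)
    first = int(rng.integers(n))
    selected = [first]
    # min distance from every pool item to the selected set, updated greedily
    min_dist = _distances_to(mat, first)
    min_dist[first] = -1.0  # never re-pick
    for _ in range(k - 1):
        # argmax returns the first (lowest-index) maximizer: the tie rule
        nxt = int(np.argmax(min_dist))
        selected.append(nxt)
        d = _distances_to(mat, nxt)
        np.minimum(min_dist, d, out=min_dist)
        min_dist[nxt] = -1.0
    return selected


def _distances_to(mat: np.ndarray, idx: int) -> np.ndarray:
    """1 - Tanimoto from every row of ``mat`` to row ``idx``."""
    row = mat[idx]
    inter = np.count_nonzero(mat & row, axis=1)
    union = np.count_nonzero(mat | row, axis=1)
    sim = np.where(union == 0, 1.0, inter / np.maximum(union, 1))
    return 1.0 - sim
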