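"""Evaluation measures for image-to-SMILES predictions.

Three measures: Exact Match (canonical-SMILES equality — the strictest and
the headline criterion), Levenshtein edit distance between the predicted
and true strings, and the Tanimoto coefficient between the two molecules'
circular fingerprints. A prediction that fails to parse counts as a
non-match with similarity 0 rather than being dropped, so invalid outputs
cannot inflate averages.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np

from .chem_core import SmilesError, canonicalize
from .diversity import fingerprint, tanimoto


def levenshtein(a: str, b: str) -> int:
    """Minimal number of single-character insertions, deletions and
    substitutions (unit costs) transforming ``a`` into ``b``.

    Classic dynamic program, two-row formulation.
    """
    if a == b:
        return 0
    if not a:
        return len(b)
    if not b:
        return len(a)
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        cur = [i]
        append = cur.append
        for j, cb in enumerate(b, start=1):
            append(min(prev[j] + 1,                 # deletion
                       cur[j - 1] + 1,              # insertion
                       prev[j - 1] + (ca != cb)))   # substitution
        prev = cur
    return prev[-1]


def exact_match(pred: str, truth: str, canonical: bool = True) -> bool:
    """True iff prediction and truth denote the same molecule.

    By default both are canonicalized first, so any valid SMILES spelling
    of the right structure counts; ``canonical=False`` compares raw
    strings. An unparseable prediction is never a match.
    """
    if not canonical:
        return pred == truth
    try:
        return canonicalize(pred) == canonicalize(truth)
    except SmilesError:
        return False


def molecular_similarity(pred: str, truth: str) -> float:
    """Tanimoto coefficient between the fingerprints of the two molecules;
    0.0 when the prediction does not parse."""
    try:
        fp_pred = fingerprint(pred)
    except SmilesError:
        return 0.0
    return tanimoto(fp_pred, fingerprint(truth))


def is_valid_smiles(text: str) -> bool:
    try:
        canonicalize(text)
        return True
    except SmilesError:
        return False


@dataclass(frozen=True)
class EvalReport:
    """Aggregate evaluation over prediction/truth pairs."""

    n_pairs: int
    exact_match_rate: float
    mean_levenshtein: float
    mean_tanimoto: float
    n_invalid_predictions: int

    def to_dict(self) -> dict:
        return asdict(self)


def evaluate(pairs: Sequence[tuple[str, str]], canonical: bool = True) -> EvalReport:
    """Score a list of ``(prediction, truth)`` string pairs."""
    if not pairs:
        raise ValueError("no prediction/truth pairs to evaluate")
    n = len(pairs)
    matches = 0
    lev_total = 0
    tani_total = 0.0
    invalid = 0
    for pred, truth in pairs:
        ok = exact_match(pred, truth, canonical=canonical)
        matches += ok
        lev_total += levenshtein(pred, truth)
        tani_total += 1.0 if ok else molecular_similarity(pred, truth)
        invalid += not is_valid_smiles(pred)
    return EvalReport(
        n_pairs=n,
        exact_match_rate=matches / n,
        mean_levenshtein=lev_total / n,
        mean_tanimoto=tani_total / n,
        n_invalid_predictions=invalid,
    )
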