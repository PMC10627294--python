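"""Candidate pattern features of a binary token sequence.

Four integer-valued features, each a measure of a particular deviation
from Bernoulli(0.5) randomness:

* **F1** — length of the longest repeating subsequence: the maximal
  token count of a contiguous monochromatic block.
* **F2** — length of the longest alternating subsequence: the maximal
  token count of a contiguous strictly alternating block.  Larger values
  are evidence *for* randomness, so analyses store the feature negated
  (``f2_signed = -F2``) so that every stored feature points
  "larger = more patterned".
* **F3** — number of repetitions: count of adjacent equal token pairs.
  Its mirror, the number of alternations, satisfies
  ``F3 + alternations = n - 1``, a perfect negative correlation, so only
  F3 is kept.
* **F4** — predominance of colour: the absolute difference between the
  two colour counts, ``|n_blue - n_yellow|``.

Both "repeating subsequence" and "alternating subsequence" are read as
contiguous blocks measured in tokens; a single token is a block of
length 1 of either kind.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .generators import as_sequence

FEATURE_IDS = (1, 2, 3, 4)
FEATURE_NAMES = {1: "f1", 2: "f2_signed", 3: "f3", 4: "f4"}
FEATURE_LABELS = {
    1: "F1 longest repeating subsequence",
    2: "F2 longest alternating subsequence (negated)",
    3: "F3 number of repetitions",
    4: "F4 predominance of colour",
}


def _as_batch(seqs) -> np.ndarray:
    arr = np.asarray(seqs)
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.ndim != 2 or arr.shape[1] == 0:
        raise ValueError("expected a (n_sequences, n_tokens) array with n_tokens >= 1")
    return arr.astype(np.uint8)


def _longest_true_run(mask: np.ndarray) -> np.ndarray:
    """Row-wise longest run of True in a boolean matrix (0 if none)."""
    n_rows, n_cols = mask.shape
    best = np.zeros(n_rows, dtype=np.int64)
    cur = np.zeros(n_rows, dtype=np.int64)
    for t in range(n_cols):
        cur = np.where(mask[:, t], cur + 1, 0)
        best = np.maximum(best, cur)
    return best


def f1_batch(seqs) -> np.ndarray:
    """F1 for each row of a sequence batch."""
    arr = _as_batch(seqs)
    if arr.shape[1] == 1:
        return np.ones(arr.shape[0], dtype=np.int64)
    eq = arr[:, 1:] == arr[:, :-1]
    return _longest_true_run(eq) + 1


def f2_batch(seqs) -> np.ndarray:
    """Raw (positive) F2 for each row of a sequence batch."""
    arr = _as_batch(seqs)
    if arr.shape[1] == 1:
        return np.ones(arr.shape[0], dtype=np.int64)
    neq = arr[:, 1:] != arr[:, :-1]
    return _longest_true_run(neq) + 1


def f3_batch(seqs) -> np.ndarray:
    """F3 (repetition count) for each row; requires n >= 2."""
    arr = _as_batch(seqs)
    if arr.shape[1] < 2:
        raise ValueError("F3 needs at least 2 tokens")
    return (arr[:, 1:] == arr[:, :-1]).sum(axis=1).astype(np.int64)


def f4_batch(seqs) -> np.ndarray:
    """F4 (colour predominance) for each row."""
    arr = _as_batch(seqs)
    n = arr.shape[1]
    return np.abs(2 * arr.sum(axis=1).astype(np.int64) - n)


def f1_longest_run(seq) -> int:
    """Length (in tokens) of the longest contiguous monochromatic block."""
    return int(f1_batch(as_sequence(seq))[0])


def f2_longest_alternation(seq) -> int:
    """Length (in tokens) of the longest contiguous strictly alternating block.

    Returns the raw positive value; ``feature_vector`` stores its negation.
    """
    return int(f2_batch(as_sequence(seq))[0])


def f3_repetitions(seq) -> int:
    """Number of adjacent equal token pairs (positions t with s_t = s_{t-1})."""
    return int(f3_batch(as_sequence(seq))[0])


def f4_color_predominance(seq) -> int:
    """Absolute difference between the counts of the two colours."""
    return int(f4_batch(as_sequence(seq))[0])


_SIGNED_BATCH = {
    1: f1_batch,
    2: lambda s: -f2_batch(s),
    3: f3_batch,
    4: f4_batch,
}


def signed_feature_batch(feature_id: int, seqs) -> np.ndarray:
    """Signed feature values (F2 negated) for each row of a batch."""
    if feature_id not in FEATURE_IDS:
        raise ValueError(f"unknown feature id {feature_id}; expected 1..4")
    return _SIGNED_BATCH[feature_id](seqs)


@dataclass(frozen=True)
class FeatureVector:
    """Signed feature values of one sequence; unrequested features are None."""

    f1: int | None = None
    f2_signed: int | None = None
    f3: int | None = None
    f4: int | None = None

    @property
    def K(self) -> int:
        return sum(v is not None for v in (self.f1, self.f2_signed, self.f3, self.f4))

    def as_dict(self) -> dict[str, int]:
        d = {"f1": self.f1, "f2_signed": self.f2_signed, "f3": self.f3, "f4": self.f4}
        return {k: v for k, v in d.items() if v is not None}


def feature_vector(seq, subset=FEATURE_IDS) -> FeatureVector:
    """Compute the requested features of one sequence (F2 stored negated)."""
    subset = tuple(sorted(set(subset)))
    if not subset:
        raise ValueError("feature subset must be non-empty")
    if not set(subset) <= set(FEATURE_IDS):
        raise ValueError(f"feature ids must be within {FEATURE_IDS}, got {subset}")
    s = as_sequence(seq)
    values = {
        FEATURE_NAMES[fid]: int(signed_feature_batch(fid, s)[0]) for fid in subset
    }
    return FeatureVector(**values)


def feature_matrix(seqs, subset=FEATURE_IDS) -> pd.DataFrame:
    """Signed feature values for a batch of sequences.

    Returns a DataFrame with one row per sequence and one column per
    requested feature (``f1``, ``f2_signed``, ``f3``, ``f4``).
    """
    subset = tuple(sorted(set(subset)))
    if not subset:
        raise ValueError("feature subset must be non-empty")
    arr = _as_batch(seqs)
    return pd.DataFrame(
        {FEATURE_NAMES[fid]: signed_feature_batch(fid, arr) for fid in subset}
    )
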