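"""Numeric sequence representations.

Two encodings are provided: the order-preserving one-hot 4xL matrix fed to
the convolutional model (row order A, U, C, G; one unit entry per column),
and the order-free normalized k-mer composition vector used by conventional
baseline classifiers (4^k entries, lexicographic over A, C, G, U).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from circrbp.sequence_io import SequenceRecord

#: row order of the one-hot matrix
ONEHOT_ORDER = "AUCG"
_ROW = {c: i for i, c in enumerate(ONEHOT_ORDER)}

#: symbol order used for k-mer indexing (lexicographic)
KMER_ORDER = "ACGU"
_KIDX = {c: i for i, c in enumerate(KMER_ORDER)}


def one_hot_encode(seq: str) -> np.ndarray:
    """Encode an RNA string as a 4xL binary matrix (rows A, U, C, G)."""
    if len(seq) == 0:
        raise ValueError("cannot encode empty sequence")
    M = np.zeros((4, len(seq)), dtype=np.uint8)
    for j, c in enumerate(seq):
        i = _ROW.get(c)
        if i is None:
            raise ValueError(f"invalid character {c!r} at position {j}")
        M[i, j] = 1
    return M


def decode(M: np.ndarray) -> str:
    """Inverse of one_hot_encode; validates the one-unit-per-column invariant."""
    M = np.asarray(M)
    if M.ndim != 2 or M.shape[0] != 4:
        raise ValueError(f"expected a 4xL matrix, got shape {M.shape}")
    colsums = M.sum(axis=0)
    if not np.all(colsums == 1):
        bad = int(np.flatnonzero(colsums != 1)[0])
        raise ValueError(f"column {bad} does not sum to 1")
    return "".join(ONEHOT_ORDER[i] for i in M.argmax(axis=0))


def kmer_features(seq: str, k: int = 3) -> np.ndarray:
    """Normalized overlapping k-mer frequencies: a 4^k vector summing to 1.

    Entry order is lexicographic over A, C, G, U; counts use stride-1
    windows, divided by the number of windows (L - k + 1).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(seq) < k:
        raise ValueError(f"sequence length {len(seq)} < k={k}")
    v = np.zeros(4**k, dtype=float)
    for j in range(len(seq) - k + 1):
        idx = 0
        for c in seq[j : j + k]:
            idx = idx * 4 + _KIDX[c]
        v[idx] += 1
    return v / (len(seq) - k + 1)


def encode_records(records: Sequence[SequenceRecord]) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Batch-encode records: (N,4,L) float32 array, 0/1 label vector, ids.

    All records must share one length. Labels map positive->1, negative->0;
    unlabeled records raise.
    """
    if not records:
        raise ValueError("no records to encode")
    L = len(records[0])
    X = np.zeros((len(records), 4, L), dtype=np.float32)
    y = np.zeros(len(records), dtype=np.int64)
    ids = []
    for n, r in enumerate(records):
        if len(r) != L:
            raise ValueError(f"record {r.id!r} has length {len(r)}, expected {L}")
        X[n] = one_hot_encode(r.seq)
        if r.label is None:
            raise ValueError(f"record {r.id!r} is unlabeled")
        y[n] = 1 if r.label == "positive" else 0
        ids.append(r.id)
    return X, y, ids


def encode_unlabeled(records: Sequence[SequenceRecord]) -> tuple[np.ndarray, list[str]]:
    """Batch-encode without labels: (N,4,L) array and ids."""
    if not records:
        raise ValueError("no records to encode")
    L = len(records[0])
    X = np.zeros((len(records), 4, L), dtype=np.float32)
    ids = []
    for n, r in enumerate(records):
        if len(r) != L:
            raise ValueError(f"record {r.id!r} has length {len(r)}, expected {L}")
        X[n] = one_hot_encode(r.seq)
        ids.append(r.id)
    return X, ids
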