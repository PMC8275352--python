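"""Sequence normalization and k-mer encoding.

Sequences are plain Python strings over the RNA alphabet ``{A, C, G, U}``.
DNA input is accepted everywhere: ``T`` is silently mapped to ``U`` and case
is folded.  Ambiguity codes (``N`` etc.) survive normalization; the
thermodynamic layer assigns zero statistical weight to any k-length window
that contains one.

k-mers are indexed lexicographically with A < C < G < U, i.e. base-4 with
A=0, C=1, G=2, U=3.  This ordering is part of the model-file format and must
stay stable.
"""

from __future__ import annotations

import numpy as np

ALPHABET = "ACGU"

_BASE_INDEX = {base: i for i, base in enumerate(ALPHABET)}

# str.translate table: fold case, map T/t -> U.
_NORMALIZE = str.maketrans(
    "acgutT" + ALPHABET.lower(),
    "ACGUUU" + ALPHABET,
)


def normalize_sequence(seq: str) -> str:
    """Uppercase ``seq`` and map T to U. Other letters pass through."""
    return seq.upper().translate(str.maketrans("T", "U"))


def kmer_to_index(kmer: str) -> int:
    """Lexicographic index (A<C<G<U, base 4) of a k-mer."""
    idx = 0
    for pos, base in enumerate(kmer):
        if base not in _BASE_INDEX:
            raise ValueError(
                f"invalid character {base!r} at position {pos} of k-mer {kmer!r}"
            )
        idx = idx * 4 + _BASE_INDEX[base]
    return idx


def index_to_kmer(index: int, k: int) -> str:
    """Inverse of :func:`kmer_to_index`."""
    if not 0 <= index < 4**k:
        raise ValueError(f"index {index} out of range for k={k}")
    bases = []
    for _ in range(k):
        bases.append(ALPHABET[index % 4])
        index //= 4
    return "".join(reversed(bases))


def all_kmers(k: int) -> list[str]:
    """All 4^k k-mers in lexicographic order."""
    return [index_to_kmer(i, k) for i in range(4**k)]


def _digit_array(seq: str) -> np.ndarray:
    """Per-position base-4 digits; -1 marks a non-ACGU character."""
    out = np.full(len(seq), -1, dtype=np.int64)
    for i, base in enumerate(seq):
        out[i] = _BASE_INDEX.get(base, -1)
    return out


def encode_sequence(seq: str, k: int) -> np.ndarray:
    """k-mer indices of all windows of ``seq``, strict alphabet.

    Returns, for each window end i in [k-1, L-1], the lexicographic index of
    ``seq[i-k+1 : i+1]``; the empty array when L < k.  Raises on any
    character outside {A,C,G,U}, naming its position.
    """
    if k < 1:
        raise ValueError("k must be a positive integer")
    digits = _digit_array(seq)
    bad = np.nonzero(digits < 0)[0]
    if bad.size:
        pos = int(bad[0])
        raise ValueError(
            f"invalid character {seq[pos]!r} at position {pos}: "
            "sequences must contain only A, C, G, U after normalization"
        )
    return _window_indices(digits, k)


def encode_windows(seq: str, k: int) -> np.ndarray:
    """Like :func:`encode_sequence` but windows containing a non-ACGU
    character get index -1 instead of raising (zero statistical weight
    downstream)."""
    if k < 1:
        raise ValueError("k must be a positive integer")
    return _window_indices(_digit_array(seq), k)


def _window_indices(digits: np.ndarray, k: int) -> np.ndarray:
    L = digits.shape[0]
    if L < k:
        return np.empty(0, dtype=np.int64)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(digits, k)
    idx = windows @ powers
    idx[(windows < 0).any(axis=1)] = -1
    return idx
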