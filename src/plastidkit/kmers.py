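"""Kmer extraction and counting.

Two representations coexist:

* :class:`KmerCountVector` — a sparse kmer -> count mapping with source
  metadata (length, base composition), the container consumed by the
  alignment-free D2/D2* statistics.  Practical for small k (the phylogeny
  uses k = 8).
* packed kmers — 2-bit-encoded kmers as ``uint64`` numpy arrays
  (A=0, C=1, G=2, T=3, most significant base first, valid for k <= 31),
  used by the reference database and the read classifier where millions of
  kmers must be matched quickly.  The 2-bit packing preserves lexicographic
  order, so the canonical form (minimum of a kmer and its reverse
  complement) is simply the elementwise minimum of the two encodings.

Windows containing any character outside ``{A, C, G, T}`` are skipped
entirely; this is the only ambiguity rule in the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

__all__ = [
    "KmerCountVector",
    "extract_kmers",
    "extract_kmers_circular",
    "reverse_complement",
    "encode_sequence",
    "packed_kmers",
    "packed_kmers_matrix",
    "decode_kmer",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

# byte -> 2-bit code lookup; 255 marks an invalid (non-ACGT) byte
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class KmerCountVector:
    """Sparse kmer counts plus source-sequence metadata.

    ``base_freqs`` are the (A, C, G, T) frequencies of the source sequence
    (ambiguous bases excluded), used as the zeroth-order background model
    by the centered D2* statistic.
    """

    k: int
    counts: dict[str, int]
    n_kmers_total: int
    source_len: int
    base_freqs: tuple[float, float, float, float]
    canonical: bool = False

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        s = sum(self.base_freqs)
        if self.counts and abs(s - 1.0) > 1e-9:
            raise ValueError(f"base_freqs sum {s} != 1")


def _base_freqs(codes: np.ndarray) -> tuple[float, float, float, float]:
    valid = codes[codes != 255]
    if valid.size == 0:
        return (0.25, 0.25, 0.25, 0.25)
    counts = np.bincount(valid, minlength=4)[:4]
    freqs = counts / counts.sum()
    return tuple(float(f) for f in freqs)


def encode_sequence(seq: str) -> np.ndarray:
    """2-bit-encode a DNA string; non-ACGT bytes become 255."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _CODE[raw]


def _roll_pack(codes: np.ndarray, k: int, canonical: bool) -> tuple[np.ndarray, np.ndarray]:
    """Packed kmers of every window (valid or not) plus a validity mask.

    Rolling bit updates over length-n slices; never materializes an
    (n, k) window matrix, so memory stays linear in the sequence length.
    """
    n = codes.size - k + 1
    vals = (codes & np.uint8(3)).astype(np.uint64)
    invalid = codes == 255
    fwd = np.zeros(n, dtype=np.uint64)
    bad = np.zeros(n, dtype=bool)
    for j in range(k):
        fwd <<= np.uint64(2)
        fwd |= vals[j : j + n]
        bad |= invalid[j : j + n]
    if not canonical:
        return fwd, ~bad
    comp = np.uint64(3) - vals
    rev = np.zeros(n, dtype=np.uint64)
    for j in range(k - 1, -1, -1):
        rev <<= np.uint64(2)
        rev |= comp[j : j + n]
    np.minimum(fwd, rev, out=fwd)
    return fwd, ~bad


def _packed_from_codes(codes: np.ndarray, k: int, canonical: bool) -> np.ndarray:
    """Packed kmers of every valid window of a code array, in window order."""
    if codes.size - k + 1 <= 0:
        return np.empty(0, dtype=np.uint64)
    packed, valid = _roll_pack(codes, k, canonical)
    return packed[valid]


def decode_kmer(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append("ACGT"[code & 3])
        code >>= 2
    return "".join(reversed(out))


def packed_kmers(seq: str, k: int, canonical: bool = True, circular: bool = False) -> np.ndarray:
    """All valid-window packed kmers of ``seq``, in window order (k <= 31)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > 31:
        raise ValueError("packed kmers support k <= 31")
    if circular:
        if len(seq) < k:
            raise ValueError("circular extraction requires len(seq) >= k")
        seq = seq + seq[: k - 1]
    return _packed_from_codes(encode_sequence(seq), k, canonical)


def packed_kmers_matrix(seqs: list[str], k: int, canonical: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Packed kmers of many sequences at once.

    Returns ``(kmers, owner)`` where ``owner[i]`` is the index of the
    sequence that contributed ``kmers[i]``.  Windows spanning two
    sequences are excluded by a one-byte separator between them.
    """
    if k > 31:
        raise ValueError("packed kmers support k <= 31")
    if not seqs:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=np.int64)
    joined = "\x00".join(seqs)
    codes = encode_sequence(joined)
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=np.int64)
    packed, valid = _roll_pack(codes, k, canonical)
    # window start -> owning sequence index
    lengths = np.fromiter((len(s) for s in seqs), dtype=np.int64, count=len(seqs))
    starts = np.concatenate(([0], np.cumsum(lengths + 1)))[:-1]
    owner_of_pos = (np.searchsorted(starts, np.arange(n), side="right") - 1).astype(np.int64)
    return packed[valid], owner_of_pos[valid]


def _vector_from_codes(
    codes: np.ndarray, k: int, canonical: bool, source_len: int
) -> KmerCountVector:
    if k < 1:
        raise ValueError("k must be >= 1")
    if k <= 31:
        packed = _packed_from_codes(codes, k, canonical)
        uniq, cnt = np.unique(packed, return_counts=True)
        counts = {decode_kmer(int(u), k): int(c) for u, c in zip(uniq, cnt)}
        total = int(cnt.sum()) if cnt.size else 0
    else:  # very large k: direct string windows (rarely used)
        seq = "".join("ACGTN"[min(c, 4)] for c in codes)
        counts = {}
        total = 0
        for i in range(len(seq) - k + 1):
            w = seq[i : i + k]
            if any(c not in "ACGT" for c in w):
                continue
            if canonical:
                w = min(w, reverse_complement(w))
            counts[w] = counts.get(w, 0) + 1
            total += 1
    return KmerCountVector(
        k=k,
        counts=counts,
        n_kmers_total=total,
        source_len=source_len,
        base_freqs=_base_freqs(codes[: source_len]),
        canonical=canonical,
    )


def extract_kmers(seq: str, k: int, canonical: bool = False) -> KmerCountVector:
    """Count kmers of every valid window of a linear sequence.

    Windows containing a non-ACGT character are skipped.  With
    ``canonical=True`` each kmer is replaced by the lexicographic minimum
    of itself and its reverse complement before counting.  Sequences
    shorter than ``k`` yield an empty vector.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    seq = seq.upper()
    return _vector_from_codes(encode_sequence(seq), k, canonical, len(seq))


def extract_kmers_circular(seq: str, k: int, canonical: bool = False) -> KmerCountVector:
    """Count kmers of a circular sequence (adds the k-1 wrap-around windows).

    Equivalent to linear extraction of ``seq + seq[:k-1]``; for an N-free
    circular sequence the total kmer count equals ``len(seq)``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(seq) < k:
        raise ValueError("circular extraction requires len(seq) >= k")
    seq = seq.upper()
    return _vector_from_codes(encode_sequence(seq + seq[: k - 1]), k, canonical, len(seq))
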