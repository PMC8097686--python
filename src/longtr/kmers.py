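"""Sliding-window k-mer frequency profiles and window similarity.

A read position is inter-base: position ``i`` is the point between the
``i``-th and ``i+1``-th character, so the substring ``R[a, b]`` (0-based,
half-open) has length ``b - a``.  A window of size ``w`` at position ``i``
is ``R[i, i+w]`` and its k-mer frequency vector counts all ``w - k + 1``
k-mers inside it.  Two normalized similarity measures between equal-shape
frequency vectors are supported:

* ``manhattan``: ``1 - ||f - h||_1 / (2 w)``
* ``pearson``:   ``(rho(f, h) + 1) / 2``

Both map into [0, 1].  The Manhattan variant is normalized by ``2w`` (not
``2(w - k + 1)``), which is slightly loose for ``k > 1`` but keeps the
measure monotone in the raw L1 distance.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BASES",
    "Read",
    "KmerProfile",
    "SimilarityMeasure",
    "encode_kmer",
    "decode_kmer",
    "seq_to_digits",
    "kmer_codes",
    "window_profile",
    "slide_profile",
    "similarity",
    "error_free_kmer_prob",
]

BASES = "ACGT"
_BASE_TO_DIGIT = {b: i for i, b in enumerate(BASES)}


@dataclass(frozen=True)
class Read:
    """A named nucleotide sequence over the alphabet {A, C, G, T}."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"read {self.id!r}: empty sequence")
        bad = set(self.seq) - set(BASES)
        if bad:
            pos = next(i for i, c in enumerate(self.seq) if c in bad)
            raise ValueError(
                f"read {self.id!r}: non-ACGT character {self.seq[pos]!r} "
                f"at offset {pos} (sanitize input first)"
            )

    def __len__(self) -> int:
        return len(self.seq)


class SimilarityMeasure(str, enum.Enum):
    MANHATTAN = "manhattan"
    PEARSON = "pearson"


@dataclass
class KmerProfile:
    """k-mer frequency vector of the window ``R[start, start + w]``."""

    k: int
    w: int
    start: int
    counts: np.ndarray = field(repr=False)

    def copy(self) -> "KmerProfile":
        return KmerProfile(self.k, self.w, self.start, self.counts.copy())


def encode_kmer(s: str) -> int:
    """Encode a k-mer as a k-digit quaternary number (A=0, C=1, G=2, T=3).

    The leftmost character is the most significant digit.
    """
    if not s:
        raise ValueError("empty k-mer")
    code = 0
    for i, c in enumerate(s):
        d = _BASE_TO_DIGIT.get(c)
        if d is None:
            raise ValueError(f"non-ACGT character {c!r} at offset {i}")
        code = code * 4 + d
    return code


def decode_kmer(code: int, k: int) -> str:
    """Inverse of :func:`encode_kmer`."""
    if not 0 <= code < 4**k:
        raise ValueError(f"code {code} out of range for k={k}")
    out = []
    for _ in range(k):
        out.append(BASES[code % 4])
        code //= 4
    return "".join(reversed(out))


def seq_to_digits(seq: str) -> np.ndarray:
    """Map a sequence string to an int8 array of base digits."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int8)
    for i, b in enumerate(BASES):
        out[arr == ord(b)] = i
    if (out < 0).any():
        pos = int(np.argmax(out < 0))
        raise ValueError(f"non-ACGT character {seq[pos]!r} at offset {pos}")
    return out


def kmer_codes(digits: np.ndarray, k: int) -> np.ndarray:
    """Codes of all k-mers of a digit array, vectorized.

    ``codes[i]`` is the code of the k-mer starting at inter-base position i;
    the result has length ``len(digits) - k + 1``.
    """
    n = len(digits)
    if k < 1 or k > n:
        raise ValueError(f"k={k} out of range for sequence of length {n}")
    codes = digits[: n - k + 1].astype(np.int64)
    for j in range(1, k):
        codes = codes * 4 + digits[j : n - k + 1 + j]
    return codes


def window_profile(read: Read, i: int, w: int, k: int) -> KmerProfile:
    """k-mer frequency vector of the window ``R[i, i + w]``."""
    n = len(read)
    if k < 1 or k > w:
        raise ValueError(f"need 1 <= k <= w, got k={k}, w={w}")
    if i < 0 or i + w > n:
        raise ValueError(f"window [{i}, {i + w}) outside read of length {n}")
    digits = seq_to_digits(read.seq[i : i + w])
    counts = np.bincount(kmer_codes(digits, k), minlength=4**k)
    return KmerProfile(k=k, w=w, start=i, counts=counts.astype(np.int64))


def slide_profile(p: KmerProfile, read: Read) -> KmerProfile:
    """Profile at ``start + 1``, updated incrementally in O(k).

    Decrements the count of the k-mer leaving on the left
    (``R[i, i+k]``) and increments the one entering on the right
    (``R[i+1+w-k, i+1+w]``).
    """
    i, w, k = p.start, p.w, p.k
    if i + 1 + w > len(read):
        raise ValueError("cannot slide past the end of the read")
    counts = p.counts.copy()
    counts[encode_kmer(read.seq[i : i + k])] -= 1
    counts[encode_kmer(read.seq[i + 1 + w - k : i + 1 + w])] += 1
    return KmerProfile(k=k, w=w, start=i + 1, counts=counts)


def similarity(
    p: KmerProfile, q: KmerProfile, measure: SimilarityMeasure | str = SimilarityMeasure.MANHATTAN
) -> float:
    """Normalized similarity of two equal-shape k-mer frequency vectors.

    A zero-variance vector under the Pearson measure (e.g. a homopolymer
    window) yields the "no correlation" midpoint 0.5 rather than an error.
    """
    if p.k != q.k or p.w != q.w:
        raise ValueError("profiles must share k and w")
    measure = SimilarityMeasure(measure)
    f = p.counts.astype(np.float64)
    h = q.counts.astype(np.float64)
    if measure is SimilarityMeasure.MANHATTAN:
        return float(1.0 - np.abs(f - h).sum() / (2.0 * p.w))
    fc = f - f.mean()
    hc = h - h.mean()
    denom = np.sqrt((fc * fc).sum() * (hc * hc).sum())
    if denom == 0.0:
        return 0.5
    rho = float((fc * hc).sum() / denom)
    return (rho + 1.0) / 2.0


def error_free_kmer_prob(eps: float, k: int) -> float:
    """Probability that a k-mer carries no sequencing error, ``(1 - eps)^k``,
    under i.i.d. per-base errors at rate ``eps``."""
    if not 0.0 <= eps < 1.0:
        raise ValueError("eps must be in [0, 1)")
    return (1.0 - eps) ** k
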