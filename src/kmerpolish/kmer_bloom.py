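"""Canonical k-mer hashing and Bloom filter membership.

The polishing pipeline never compares k-mer strings directly: every k-mer is
reduced to a strand-symmetric pair of 64-bit hashes, so that a k-mer and its
reverse complement always map to the same pair.  All windows of a sequence are
hashed at once with a prefix-sum rolling scheme (vectorized in numpy), which a
unit-tested property keeps equal to a straightforward per-window re-hash.

The Bloom filter stores canonical k-mer presence with double hashing
(index_i = h1 + i*h2 mod m), sized from the standard formulas

    m = ceil(-n ln p / (ln 2)^2),    h = max(1, round((m/n) ln 2))

for ``n`` expected distinct k-mers at target false-positive rate ``p``.
"""

from __future__ import annotations

import math
import struct
from dataclasses import dataclass
from typing import Iterable, Iterator, NamedTuple

import numpy as np

__all__ = [
    "KmerSpec",
    "KmerBloomFilter",
    "ExactKmerIndex",
    "KmerWindow",
    "canonical",
    "reverse_complement",
    "iter_kmers",
    "size_filter",
    "hash_kmer",
    "window_hashes",
    "encode",
    "decode",
    "save_filter",
    "load_filter",
]

_MASK64 = (1 << 64) - 1
# Odd multipliers so they are invertible mod 2^64 (rolling hash bases).
_B1 = 0x9E3779B97F4A7C15
_B2 = 0xC2B2AE3D27D4EB4F
_B1_INV = pow(_B1, -1, 1 << 64)
_B2_INV = pow(_B2, -1, 1 << 64)
_H2_SALT = 0xFF51AFD7ED558CCD
_MIX_C1 = 0xBF58476D1CE4E5B9
_MIX_C2 = 0x94D049BB133111EB

_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate(b"ACGT"):
    _ENCODE[_c] = _i
for _i, _c in enumerate(b"acgt"):
    _ENCODE[_c] = _i
_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)

_RC_TABLE = str.maketrans("ACGTacgt", "TGCAtgca")

_MAGIC = b"KMBF"
_FORMAT_VERSION = 1


class FilterFormatError(ValueError):
    """Raised when a serialized filter file is malformed."""


@dataclass(frozen=True)
class KmerSpec:
    """k-mer length and the canonicalization convention shared pipeline-wide.

    Canonical form is the lexicographically smaller of a k-mer and its
    reverse complement; 4 <= k <= 255.
    """

    k: int

    def __post_init__(self) -> None:
        if not (4 <= self.k <= 255):
            raise ValueError(f"k must be in [4, 255], got {self.k}")


def encode(seq: str) -> np.ndarray:
    """Map a DNA string to uint8 codes A,C,G,T -> 0..3; anything else -> 255."""
    raw = np.frombuffer(seq.encode("latin-1", errors="replace"), dtype=np.uint8)
    return _ENCODE[raw]


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode` for valid codes (0..3)."""
    return _DECODE[codes].tobytes().decode("ascii")


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC_TABLE)[::-1]


def canonical(seq: str) -> str:
    """Lexicographically smaller of ``seq`` (uppercased) and its reverse complement.

    Raises ValueError on non-ACGT characters; the caller decides whether to
    skip the offending window.
    """
    s = seq.upper()
    if any(c not in "ACGT" for c in s):
        raise ValueError(f"non-ACGT character in k-mer {seq!r}")
    rc = reverse_complement(s)
    return s if s <= rc else rc


def _mix64_arr(x: np.ndarray) -> np.ndarray:
    # splitmix64 finalizer, vectorized; uint64 arithmetic wraps mod 2^64.
    x = x.copy()
    x ^= x >> np.uint64(30)
    x *= np.uint64(_MIX_C1)
    x ^= x >> np.uint64(27)
    x *= np.uint64(_MIX_C2)
    x ^= x >> np.uint64(31)
    return x


def _mix64_int(x: int) -> int:
    x &= _MASK64
    x ^= x >> 30
    x = (x * _MIX_C1) & _MASK64
    x ^= x >> 27
    x = (x * _MIX_C2) & _MASK64
    x ^= x >> 31
    return x


def _powers(base: int, n: int) -> np.ndarray:
    out = np.full(n, np.uint64(base & _MASK64), dtype=np.uint64)
    if n:
        out[0] = 1
    np.multiply.accumulate(out, out=out)
    return out


def window_hashes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Strand-symmetric hash pair for every length-``k`` window of ``codes``.

    Returns ``(h1, h2, valid)`` arrays of length ``len(codes) - k + 1`` (empty
    when the sequence is shorter than k).  ``valid[i]`` is False when window i
    overlaps a non-ACGT code; h1/h2 at invalid windows are meaningless.

    This is the rolling path: per-window values are obtained from modular
    prefix sums, and are identical to :func:`hash_kmer` on the window string.
    """
    L = int(len(codes))
    n = L - k + 1
    if n <= 0:
        e = np.empty(0, dtype=np.uint64)
        return e, e.copy(), np.empty(0, dtype=bool)

    good = codes < 4
    bad_prefix = np.zeros(L + 1, dtype=np.int64)
    np.cumsum(~good, out=bad_prefix[1:])
    valid = (bad_prefix[k:] - bad_prefix[:n]) == 0

    c = np.where(good, codes, 0).astype(np.uint64)
    cc = np.uint64(3) - c

    def _strand(base: int, base_inv: int) -> tuple[np.ndarray, np.ndarray]:
        pb = _powers(base, L)
        pi = _powers(base_inv, L)
        S = np.zeros(L + 1, dtype=np.uint64)
        np.cumsum(c * pb, out=S[1:])
        T = np.zeros(L + 1, dtype=np.uint64)
        np.cumsum(cc * pi, out=T[1:])
        bk1 = np.uint64(pow(base, k - 1, 1 << 64))
        # forward: sum_t code[i+t] * b^t ; reverse-complement hash likewise on
        # the complemented, reversed window.
        f = (S[k:] - S[:n]) * pi[:n]
        r = (T[k:] - T[:n]) * pb[:n] * bk1
        return f, r

    f1, r1 = _strand(_B1, _B1_INV)
    f2, r2 = _strand(_B2, _B2_INV)
    use_fwd = (f1 < r1) | ((f1 == r1) & (f2 <= r2))
    u1 = np.where(use_fwd, f1, r1)
    u2 = np.where(use_fwd, f2, r2)
    return _mix64_arr(u1), _mix64_arr(u2 ^ np.uint64(_H2_SALT)), valid


def hash_kmer(kmer: str) -> tuple[int, int]:
    """Direct (non-rolling) strand-symmetric hash pair of a single k-mer.

    Independent scalar re-computation of what :func:`window_hashes` produces;
    the two are held equal by a test property.
    """
    s = kmer.upper()
    k = len(s)
    f1 = r1 = f2 = r2 = 0
    p1 = p2 = 1
    q1 = pow(_B1, k - 1, 1 << 64)
    q2 = pow(_B2, k - 1, 1 << 64)
    for ch in s:
        c = "ACGT".find(ch)
        if c < 0:
            raise ValueError(f"non-ACGT character in k-mer {kmer!r}")
        cc = 3 - c
        f1 = (f1 + c * p1) & _MASK64
        f2 = (f2 + c * p2) & _MASK64
        r1 = (r1 + cc * q1) & _MASK64
        r2 = (r2 + cc * q2) & _MASK64
        p1 = (p1 * _B1) & _MASK64
        p2 = (p2 * _B2) & _MASK64
        q1 = (q1 * _B1_INV) & _MASK64
        q2 = (q2 * _B2_INV) & _MASK64
    if (f1 < r1) or (f1 == r1 and f2 <= r2):
        u1, u2 = f1, f2
    else:
        u1, u2 = r1, r2
    return _mix64_int(u1), _mix64_int(u2 ^ _H2_SALT)


class KmerWindow(NamedTuple):
    pos: int
    kmer: str | None
    valid: bool


def iter_kmers(seq: str, spec: KmerSpec) -> Iterator[KmerWindow]:
    """Yield one entry per window start 0..len(seq)-k (5'→3').

    Windows overlapping a non-ACGT character are yielded with ``kmer=None``
    and ``valid=False`` so a consumer can skip them without losing positions.
    Sequences shorter than k yield nothing.
    """
    k = spec.k
    s = seq.upper()
    codes = encode(s)
    n = len(s) - k + 1
    if n <= 0:
        return
    good = codes < 4
    bad_prefix = np.zeros(len(s) + 1, dtype=np.int64)
    np.cumsum(~good, out=bad_prefix[1:])
    for i in range(n):
        if bad_prefix[i + k] - bad_prefix[i]:
            yield KmerWindow(i, None, False)
        else:
            yield KmerWindow(i, canonical(s[i : i + k]), True)


def size_filter(n_expected: int, p_target: float) -> tuple[int, int]:
    """Bloom sizing: bit-array length m and hash count h for n k-mers at FPR p."""
    if n_expected < 1:
        raise ValueError("n_expected must be >= 1")
    if not (0.0 < p_target < 1.0):
        raise ValueError(f"p_target must be in (0, 1), got {p_target}")
    m = math.ceil(-n_expected * math.log(p_target) / (math.log(2) ** 2))
    h = max(1, round((m / n_expected) * math.log(2)))
    return m, h


class KmerBloomFilter:
    """Bloom filter over canonical k-mers.

    Presence bits live in a numpy bool array of length ``m`` (one byte per
    bit in memory; packed on disk).  Probe indices come from double hashing
    of the strand-symmetric hash pair, so ``contains`` is automatically
    identical for a k-mer and its reverse complement, and an inserted k-mer
    can never query absent.
    """

    def __init__(self, k: int, m: int, num_hashes: int, p_target: float | None = None):
        KmerSpec(k)  # validate range
        if m < 1 or num_hashes < 1:
            raise ValueError("m and num_hashes must be >= 1")
        self.k = int(k)
        self.m = int(m)
        self.num_hashes = int(num_hashes)
        self.p_target = p_target
        self.n_inserted = 0
        self._bits = np.zeros(self.m, dtype=bool)

    @classmethod
    def from_params(cls, k: int, n_expected: int, p_target: float) -> "KmerBloomFilter":
        m, h = size_filter(n_expected, p_target)
        return cls(k, m, h, p_target)

    # -- hash-level interface (shared with ExactKmerIndex) -------------------

    def insert_hashes(self, h1: np.ndarray, h2: np.ndarray) -> None:
        h1 = np.asarray(h1, dtype=np.uint64)
        h2 = np.asarray(h2, dtype=np.uint64)
        m = np.uint64(self.m)
        for i in range(self.num_hashes):
            idx = ((h1 + np.uint64(i) * h2) % m).astype(np.intp)
            self._bits[idx] = True
        self.n_inserted += int(len(h1))

    def contains_hashes(self, h1: np.ndarray, h2: np.ndarray) -> np.ndarray:
        h1 = np.asarray(h1, dtype=np.uint64)
        h2 = np.asarray(h2, dtype=np.uint64)
        m = np.uint64(self.m)
        out = np.ones(len(h1), dtype=bool)
        for i in range(self.num_hashes):
            if not out.any():
                break
            alive = np.flatnonzero(out)
            idx = ((h1[alive] + np.uint64(i) * h2[alive]) % m).astype(np.intp)
            out[alive[~self._bits[idx]]] = False
        return out

    # -- string-level interface ----------------------------------------------

    def _check_kmer(self, kmer: str) -> tuple[int, int]:
        if len(kmer) != self.k:
            raise ValueError(
                f"k-mer length {len(kmer)} does not match filter k={self.k}"
            )
        return hash_kmer(kmer)

    def insert(self, kmer: str) -> None:
        h1, h2 = self._check_kmer(kmer)
        self.insert_hashes(np.array([h1], dtype=np.uint64), np.array([h2], dtype=np.uint64))

    def contains(self, kmer: str) -> bool:
        h1, h2 = self._check_kmer(kmer)
        m = self.m
        for i in range(self.num_hashes):
            # match the vectorized path: probe arithmetic wraps mod 2^64
            if not self._bits[((h1 + i * h2) & _MASK64) % m]:
                return False
        return True

    __contains__ = contains

    # -- serialization --------------------------------------------------------
    #
    # Byte layout (little-endian):
    #   bytes 0-3   magic "KMBF"
    #   bytes 4-5   format version (uint16)
    #   byte  6     k (uint8)
    #   bytes 7-14  m, bit count (uint64)
    #   bytes 15-22 num_hashes (uint64)
    #   bytes 23-30 n_inserted (uint64)
    #   bytes 31-38 p_target (float64; NaN when unset)
    #   bytes 39-   ceil(m/8) bytes of packed presence bits (MSB-first)

    _HEADER = struct.Struct("<4sHBQQQd")

    def save(self, path) -> None:
        p_t = float("nan") if self.p_target is None else float(self.p_target)
        header = self._HEADER.pack(
            _MAGIC, _FORMAT_VERSION, self.k, self.m, self.num_hashes, self.n_inserted, p_t
        )
        with open(path, "wb") as fh:
            fh.write(header)
            fh.write(np.packbits(self._bits).tobytes())

    @classmethod
    def load(cls, path, expected_k: int | None = None) -> "KmerBloomFilter":
        with open(path, "rb") as fh:
            header = fh.read(cls._HEADER.size)
            if len(header) < cls._HEADER.size:
                raise FilterFormatError(f"{path}: truncated header")
            magic, version, k, m, h, n_ins, p_t = cls._HEADER.unpack(header)
            if magic != _MAGIC:
                raise FilterFormatError(f"{path}: bad magic {magic!r}, not a k-mer filter file")
            if version != _FORMAT_VERSION:
                raise FilterFormatError(f"{path}: unsupported format version {version}")
            payload = fh.read()
        n_bytes = (m + 7) // 8
        if len(payload) != n_bytes:
            raise FilterFormatError(
                f"{path}: bit array truncated ({len(payload)} bytes, expected {n_bytes})"
            )
        if expected_k is not None and k != expected_k:
            raise ValueError(f"{path}: filter k={k} does not match requested k={expected_k}")
        bf = cls(k, m, h, None if math.isnan(p_t) else p_t)
        bf.n_inserted = n_ins
        bf._bits = np.unpackbits(np.frombuffer(payload, dtype=np.uint8), count=m).astype(bool)
        return bf


def save_filter(bf: KmerBloomFilter, path) -> None:
    bf.save(path)


def load_filter(path, expected_k: int | None = None) -> KmerBloomFilter:
    return KmerBloomFilter.load(path, expected_k=expected_k)


class ExactKmerIndex:
    """Exact canonical k-mer membership — the zero-FPR stand-in for a Bloom
    filter, used as the editing oracle in tests and available to users who
    can afford exact sets.

    Implements the same hash-level protocol as :class:`KmerBloomFilter`
    (``k``, ``contains_hashes``, ``contains``) so the editor accepts either.
    """

    def __init__(self, k: int, h1: np.ndarray | None = None, h2: np.ndarray | None = None):
        KmerSpec(k)
        self.k = int(k)
        if h1 is None:
            h1 = np.empty(0, dtype=np.uint64)
            h2 = np.empty(0, dtype=np.uint64)
        order = np.argsort(h1, kind="stable")
        self._h1 = np.asarray(h1, dtype=np.uint64)[order]
        self._h2 = np.asarray(h2, dtype=np.uint64)[order]
        self.n_inserted = int(len(self._h1))

    @classmethod
    def from_sequences(cls, seqs: Iterable[str], k: int) -> "ExactKmerIndex":
        parts_h1, parts_h2 = [], []
        for seq in seqs:
            h1, h2, valid = window_hashes(encode(seq.upper()), k)
            parts_h1.append(h1[valid])
            parts_h2.append(h2[valid])
        if parts_h1:
            h1 = np.concatenate(parts_h1)
            h2 = np.concatenate(parts_h2)
            uh1, idx = np.unique(h1, return_index=True)
            return cls(k, uh1, h2[idx])
        return cls(k)

    @classmethod
    def from_kmers(cls, kmers: Iterable[str], k: int) -> "ExactKmerIndex":
        pairs = sorted({hash_kmer(km) for km in kmers})
        if pairs:
            h1 = np.array([p[0] for p in pairs], dtype=np.uint64)
            h2 = np.array([p[1] for p in pairs], dtype=np.uint64)
            return cls(k, h1, h2)
        return cls(k)

    def contains_hashes(self, h1: np.ndarray, h2: np.ndarray) -> np.ndarray:
        h1 = np.asarray(h1, dtype=np.uint64)
        h2 = np.asarray(h2, dtype=np.uint64)
        if len(self._h1) == 0:
            return np.zeros(len(h1), dtype=bool)
        pos = np.searchsorted(self._h1, h1)
        pos_c = np.minimum(pos, len(self._h1) - 1)
        return (self._h1[pos_c] == h1) & (self._h2[pos_c] == h2)

    def contains(self, kmer: str) -> bool:
        if len(kmer) != self.k:
            raise ValueError(f"k-mer length {len(kmer)} does not match index k={self.k}")
        h1, h2 = hash_kmer(kmer)
        return bool(
            self.contains_hashes(
                np.array([h1], dtype=np.uint64), np.array([h2], dtype=np.uint64)
            )[0]
        )

    __contains__ = contains
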