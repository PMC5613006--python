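"""Shared low-level helpers: sequence encoding, k-mer codes, intervals, RNG streams."""

from __future__ import annotations

import zlib

import numpy as np

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: A,C,G,T -> 0,1,2,3 lookup for byte-encoded sequences.
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def seq_to_codes(seq: str) -> np.ndarray:
    """Encode a DNA string as a uint8 array over {0,1,2,3}; other bytes become 255."""
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def codes_to_seq(codes: np.ndarray) -> str:
    return BASES[codes].tobytes().decode()


def kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Pack every k-mer of a 2-bit-encoded sequence into a uint64 (k <= 31).

    Positions whose window contains a non-ACGT byte get the sentinel 2**63.
    """
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    acc = np.zeros(n, dtype=np.uint64)
    bad = np.zeros(n, dtype=bool)
    for i in range(k):
        w = codes[i : i + n]
        bad |= w == 255
        acc = (acc << np.uint64(2)) | w.astype(np.uint64)
    acc[bad] = np.uint64(1) << np.uint64(63)
    return acc


def rc_kmer_codes(fwd: np.ndarray, k: int) -> np.ndarray:
    """Reverse-complement packed k-mer codes (elementwise)."""
    out = np.zeros_like(fwd)
    x = fwd.copy()
    for _ in range(k):
        out = (out << np.uint64(2)) | (np.uint64(3) - (x & np.uint64(3)))
        x >>= np.uint64(2)
    sentinel = np.uint64(1) << np.uint64(63)
    out[fwd == sentinel] = sentinel
    return out


def merge_intervals(iv: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals, sorted, abutting intervals merged."""
    if not iv:
        return []
    iv = sorted(iv)
    out = [list(iv[0])]
    for s, e in iv[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def complement_intervals(iv: list[tuple[int, int]], length: int) -> list[tuple[int, int]]:
    """Gaps of a merged interval set inside [0, length)."""
    out = []
    prev = 0
    for s, e in merge_intervals(iv):
        if s > prev:
            out.append((prev, s))
        prev = max(prev, e)
    if prev < length:
        out.append((prev, length))
    return out


def overlap_len(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    """min(overlap/|a|, overlap/|b|) for half-open intervals; 0 for empty input."""
    la, lb = a[1] - a[0], b[1] - b[0]
    if la <= 0 or lb <= 0:
        return 0.0
    ov = overlap_len(a, b)
    return min(ov / la, ov / lb)


def substream(seed: int, *salts) -> np.random.Generator:
    """Deterministic child RNG derived from a base seed and string/int salts.

    Keeps derived seeds below 2**31 so they stay portable.
    """
    h = zlib.crc32(repr((int(seed), salts)).encode()) & 0x7FFFFFFF
    return np.random.default_rng(h)
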