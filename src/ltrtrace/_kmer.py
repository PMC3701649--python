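"""Sorted-array k-mer index over a chromosome sequence.

Used for seeding direct-repeat discovery (intact element mining), homology
scans against family consensus sequences, and junction-marker lookups.
k-mers containing non-ACGT characters are skipped. Encoding is 2 bits/base,
so k must be <= 31.
"""

from __future__ import annotations

import numpy as np

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


def encode_kmers(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Return (codes, positions) for every valid k-mer of ``seq``."""
    if k > 31:
        raise ValueError("k must be <= 31")
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _CODE[raw]
    n = len(seq) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    kv = np.zeros(n, dtype=np.int64)
    bad = np.zeros(n, dtype=bool)
    for j in range(k):
        window = codes[j : j + n]
        kv = (kv << 2) | np.where(window == 255, 0, window).astype(np.int64)
        bad |= window == 255
    pos = np.nonzero(~bad)[0].astype(np.int64)
    return kv[~bad], pos


def encode_one(kmer: str) -> int | None:
    """Encode a single k-mer; None if it contains non-ACGT characters."""
    v = 0
    for c in kmer:
        code = _CODE[ord(c)]
        if code == 255:
            return None
        v = (v << 2) | int(code)
    return v


class KmerIndex:
    """Query-by-k-mer index of one sequence (sorted-code representation)."""

    def __init__(self, seq: str, k: int):
        self.k = k
        self.length = len(seq)
        kv, pos = encode_kmers(seq, k)
        order = np.argsort(kv, kind="stable")
        self._codes = kv[order]
        self._pos = pos[order]

    def lookup(self, kmer_code: int) -> np.ndarray:
        """Positions (ascending) at which the k-mer occurs."""
        lo = np.searchsorted(self._codes, kmer_code, side="left")
        hi = np.searchsorted(self._codes, kmer_code, side="right")
        return np.sort(self._pos[lo:hi])

    def duplicate_groups(self, max_occurrences: int = 2000):
        """Yield position arrays for every k-mer occurring 2..max_occurrences times."""
        codes = self._codes
        if len(codes) == 0:
            return
        # boundaries of runs of equal codes
        change = np.nonzero(codes[1:] != codes[:-1])[0] + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [len(codes)]))
        sizes = ends - starts
        for s, e, sz in zip(starts, ends, sizes):
            if 2 <= sz <= max_occurrences:
                yield np.sort(self._pos[s:e])
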