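"""Shared low-level sequence primitives: complementation and Hamming matching.

Everything here operates on plain uppercase DNA strings or their uint8 byte
views. Matching is ungapped (Hamming); positions are 0-based half-open on the
forward strand of the subject sequence.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# byte-level complement table for vectorised work on uint8 arrays
_COMP_BYTES = np.arange(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTNacgtn", b"TGCANtgcan"):
    _COMP_BYTES[_a] = _b


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N, case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """DNA string as a read-only uint8 view (ASCII codes)."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def revcomp_bytes(arr: np.ndarray) -> np.ndarray:
    return _COMP_BYTES[arr][::-1]


def hamming_offsets(subject: np.ndarray, pattern: np.ndarray, max_mismatches: int) -> np.ndarray:
    """All offsets where ``pattern`` matches ``subject`` within the budget.

    Returns a sorted int array of start offsets ``o`` with
    ``hamming(subject[o:o+len(pattern)], pattern) <= max_mismatches``.
    Empty when the subject is shorter than the pattern.
    """
    m = len(pattern)
    if len(subject) < m:
        return np.empty(0, dtype=np.int64)
    windows = sliding_window_view(subject, m)
    mm = (windows != pattern).sum(axis=1)
    return np.nonzero(mm <= max_mismatches)[0]


def hamming_hits(subject: str, query: str, max_mismatches: int) -> list[tuple[int, str, int]]:
    """Ungapped two-strand search of ``query`` against ``subject``.

    A plus-strand hit means ``query`` matches the subject forward sequence at
    that offset; a minus-strand hit means the reverse complement of ``query``
    does (i.e. the query matches the bottom strand). Returns
    ``(start, strand, mismatches)`` tuples sorted by (mismatches, start,
    strand) with strand in {"plus", "minus"}.
    """
    sub = encode(subject)
    hits: list[tuple[int, str, int]] = []
    for strand, q in (("plus", query), ("minus", revcomp(query))):
        pat = encode(q)
        if len(sub) < len(pat):
            continue
        windows = sliding_window_view(sub, len(pat))
        mm = (windows != pat).sum(axis=1)
        for o in np.nonzero(mm <= max_mismatches)[0]:
            hits.append((int(o), strand, int(mm[o])))
    hits.sort(key=lambda h: (h[2], h[0], h[1]))
    return hits


class ExactIndex:
    """Exact k-mer lookup over both strands of a subject sequence.

    Used as the fast path for mismatch-free spacer localisation; equivalent to
    ``hamming_hits(..., max_mismatches=0)`` for fixed-length queries.
    """

    def __init__(self, subject: str, k: int):
        self.k = k
        index: dict[str, list[int]] = {}
        for i in range(len(subject) - k + 1):
            index.setdefault(subject[i : i + k], []).append(i)
        self._index = index

    def lookup(self, query: str) -> list[tuple[int, str, int]]:
        hits = [(pos, "plus", 0) for pos in self._index.get(query, ())]
        # a palindromic query legitimately hits both strands at the same offset
        hits += [(pos, "minus", 0) for pos in self._index.get(revcomp(query), ())]
        hits.sort(key=lambda h: (h[2], h[0], h[1]))
        return hits
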