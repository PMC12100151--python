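"""Vectorized k-mer encoding and seed matching shared by the anchor and unit scanners.

Sequences are 2-bit encoded with numpy; k-mer codes are computed with a
sliding-window dot product, so seeding a 10 kb read costs a handful of numpy
calls rather than a Python loop per base.
"""

from __future__ import annotations

import numpy as np

_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
    _ENCODE[_b + 32] = _i  # lowercase

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """2-bit codes; 255 marks any non-ACGT character."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Integer code of every k-mer; -1 where the window contains a non-ACGT base.

    Codes fit in int64 for k <= 31.
    """
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = ~np.any(windows == 255, axis=1)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    vals = windows.astype(np.int64) @ powers
    vals[~valid] = -1
    return vals


def build_index(query: str, k: int) -> dict[int, list[int]]:
    """Map k-mer code -> sorted positions in the query."""
    idx: dict[int, list[int]] = {}
    for pos, code in enumerate(kmer_codes(encode(query), k)):
        if code >= 0:
            idx.setdefault(int(code), []).append(pos)
    return idx


def seed_matches(read_codes: np.ndarray, index: dict[int, list[int]]) -> np.ndarray:
    """(read_pos, query_pos) pairs for every shared k-mer, sorted by read_pos.

    Returns an (n, 2) int64 array.
    """
    if read_codes.size == 0 or not index:
        return np.empty((0, 2), dtype=np.int64)
    keys = np.fromiter(index.keys(), dtype=np.int64, count=len(index))
    keys.sort()
    candidate = np.nonzero(np.isin(read_codes, keys))[0]
    pairs: list[tuple[int, int]] = []
    for r in candidate:
        for q in index[int(read_codes[r])]:
            pairs.append((int(r), q))
    return np.asarray(pairs, dtype=np.int64).reshape(-1, 2)


def cluster_by_offset(pairs: np.ndarray, gap: int) -> list[dict]:
    """Group seed pairs into colinear clusters by diagonal (read_pos - query_pos).

    Pairs whose offsets differ by more than ``gap`` fall into separate
    clusters. Each cluster dict reports the median offset and the seed extents
    on read and query; clusters come back sorted by offset (read order).
    """
    if pairs.shape[0] == 0:
        return []
    offsets = pairs[:, 0] - pairs[:, 1]
    order = np.argsort(offsets, kind="stable")
    offsets = offsets[order]
    pairs = pairs[order]
    breaks = np.nonzero(np.diff(offsets) > gap)[0] + 1
    clusters = []
    for chunk, opart in zip(
        np.split(pairs, breaks), np.split(offsets, breaks)
    ):
        clusters.append(
            {
                "offset": int(np.median(opart)),
                "n_seeds": int(chunk.shape[0]),
                "read_min": int(chunk[:, 0].min()),
                "read_max": int(chunk[:, 0].max()),
                "query_min": int(chunk[:, 1].min()),
                "query_max": int(chunk[:, 1].max()),
            }
        )
    return clusters
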