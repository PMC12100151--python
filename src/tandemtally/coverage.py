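"""Per-base coverage of the plasmid reference, normalized, as bedGraph.

The reference is a chosen linear template (the two-unit template by
default), not a whole genome: read placements are projected from the anchor
and unit hits already computed, so no external mapper is involved.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .count import CopyCall
from .plasmid import LinearTemplate
from .select import ReadClass

__all__ = [
    "CoverageTrack",
    "accumulate_coverage",
    "normalize_coverage",
    "write_bedgraph",
    "read_bedgraph",
    "reference_intervals",
]


@dataclass
class CoverageTrack:
    reference_name: str
    raw: np.ndarray
    normalized: np.ndarray

    def __post_init__(self) -> None:
        if len(self.raw) != len(self.normalized):
            raise ValueError("raw and normalized tracks differ in length")


def accumulate_coverage(intervals: list[tuple[int, int]], ref_len: int) -> np.ndarray:
    """Per-base counts: value at i = number of intervals covering i."""
    raw = np.zeros(ref_len + 1, dtype=np.int64)
    for start, end in intervals:
        if not (0 <= start <= end <= ref_len):
            raise ValueError(f"interval ({start}, {end}) outside [0, {ref_len})")
        raw[start] += 1
        raw[end] -= 1
    return np.cumsum(raw[:-1])


def normalize_coverage(raw: np.ndarray, mode: str = "mean") -> np.ndarray:
    """Divide by the mean per-base count (``mean``) or by the total number of
    aligned bases (``total``)."""
    raw = np.asarray(raw, dtype=float)
    if mode == "mean":
        norm = raw.mean()
        if norm == 0:
            raise ValueError("all-zero coverage track cannot be mean-normalized")
    elif mode == "total":
        norm = raw.sum()
        if norm == 0:
            raise ValueError("all-zero coverage track cannot be total-normalized")
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    return raw / norm


def write_bedgraph(track: CoverageTrack, path, header_lines: list[str] | None = None) -> None:
    """bedGraph with 0-based half-open intervals; runs of equal value merged."""
    vals = track.normalized
    path = Path(path)
    try:
        with path.open("w") as fh:
            for line in header_lines or []:
                fh.write(f"# {line}\n")
            if len(vals):
                change = np.nonzero(np.diff(vals))[0] + 1
                starts = np.concatenate([[0], change])
                ends = np.concatenate([change, [len(vals)]])
                for s, e in zip(starts, ends):
                    # shortest round-trippable decimal, so write->read is exact
                    fh.write(f"{track.reference_name}\t{s}\t{e}\t{float(vals[s])!r}\n")
    except OSError as exc:
        raise OSError(f"failed writing bedGraph to {path}: {exc}") from exc


def read_bedgraph(path) -> tuple[str, np.ndarray]:
    """Parse a single-reference bedGraph back into a dense value array."""
    name = None
    chunks: list[tuple[int, int, float]] = []
    with Path(path).open() as fh:
        for line in fh:
            if line.startswith(("#", "track")) or not line.strip():
                continue
            ref, s, e, v = line.rstrip("\n").split("\t")
            if name is None:
                name = ref
            elif ref != name:
                raise ValueError("multi-reference bedGraph not supported")
            chunks.append((int(s), int(e), float(v)))
    if name is None:
        return "", np.empty(0)
    vals = np.zeros(max(e for _, e, _ in chunks))
    for s, e, v in chunks:
        vals[s:e] = v
    return name, vals


def reference_intervals(
    classes: list[ReadClass],
    calls: dict[str, CopyCall],
    template: LinearTemplate,
    anchor_len: int,
) -> list[tuple[int, int]]:
    """Approximate reference placement of each target read.

    Each target read contributes one interval spanning from the start of its
    left anchor through its counted units to the end of its right anchor,
    with copy numbers beyond the reference's clamped to the reference array
    length. This is a projection of existing hits, not an independent
    alignment, and is intended for coverage sanity plots.
    """
    lf = len(template.left_flank)
    ulen = len(template.repeat_unit_seq)
    ref_len = len(template)
    out = []
    for rc in classes:
        if rc.call != "target" or rc.read_id not in calls:
            continue
        k = min(calls[rc.read_id].copy_number, template.copy_number)
        start = max(0, lf - anchor_len)
        end = min(ref_len, lf + k * ulen + anchor_len)
        out.append((start, end))
    return out
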