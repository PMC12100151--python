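"""Target-read selection: anchor both vector arms on each read.

A read is *target* only if it contains both vector flanks, on the same
strand, in the order the linear template dictates. Requiring both anchors
guarantees the read traversed the whole array, so end-clipping cannot bias
the downstream unit count — clipped molecules simply fail selection.

Anchors are located by exact k-mer seeding, colinear (diagonal) clustering,
and verification with a bounded-edit-distance alignment (edlib) inside the
seeded window. Identity is matches / alignment columns, indels counted as
non-matches. All tie-breaks are deterministic (best score, then leftmost,
then forward strand).
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib

from . import _kmer
from .plasmid import ConfigurationError, PlasmidMap, build_template

__all__ = [
    "AnchorParams",
    "AnchorHit",
    "ReadClass",
    "SelectionSummary",
    "find_anchor",
    "classify_read",
    "summarize_selection",
]

# cap on seed clusters verified by alignment per (arm, strand); spurious
# clusters are rare on random background, so this only bounds worst cases
_MAX_CLUSTERS = 8


@dataclass(frozen=True)
class AnchorParams:
    """Anchor detection parameters.

    ``anchor_len`` bases are taken from each flank immediately adjacent to
    the array, so the inter-anchor interval tightly bounds the array region.
    """

    anchor_len: int = 500
    kmer_size: int = 15
    min_identity: float = 0.80
    band_width: int = 100

    def __post_init__(self) -> None:
        if self.kmer_size > self.anchor_len:
            raise ConfigurationError("kmer_size must be <= anchor_len")
        if not 0 < self.min_identity <= 1:
            raise ConfigurationError("min_identity must be in (0, 1]")


@dataclass(frozen=True)
class AnchorHit:
    arm: str                      # "left" | "right"
    read_start: int
    read_end: int                 # half-open on the read as given
    strand: str                   # "+" | "-"
    identity: float
    score: int                    # matches - edits

    @property
    def interval(self) -> tuple[int, int]:
        return (self.read_start, self.read_end)


@dataclass
class ReadClass:
    """Per-read classification with its anchor evidence."""

    read_id: str
    call: str                     # "target" | "non_target" | "ambiguous"
    left_hit: AnchorHit | None = None
    right_hit: AnchorHit | None = None
    inter_anchor_interval: tuple[int, int] | None = None

    @property
    def strand(self) -> str | None:
        return self.left_hit.strand if self.call == "target" else None


def _align_identity(query: str, window: str) -> tuple[int, int, float, int] | None:
    """Best placement of query inside window: (start, end, identity, score)."""
    res = edlib.align(query, window, mode="HW", task="path")
    if res["editDistance"] < 0 or not res["locations"]:
        return None
    dist = res["editDistance"]
    cols = sum(int(n) for n in _cigar_lengths(res["cigar"]))
    start, end_incl = min(res["locations"], key=lambda x: x[0])
    identity = (cols - dist) / cols if cols else 0.0
    return int(start), int(end_incl) + 1, identity, cols - 2 * dist


def _cigar_lengths(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield int(num)
            num = ""


def find_anchor(
    read_seq: str, arm_seq: str, params: AnchorParams, arm: str = "left"
) -> AnchorHit | None:
    """Locate one vector arm on a read (either strand); best hit or None.

    Reads shorter than the k-mer size simply yield no hit.
    """
    k = params.kmer_size
    if len(read_seq) < k:
        return None
    read_codes = _kmer.kmer_codes(_kmer.encode(read_seq), k)
    best: AnchorHit | None = None
    for strand in "+-":
        query = arm_seq if strand == "+" else _kmer.revcomp(arm_seq)
        index = _kmer.build_index(query, k)
        pairs = _kmer.seed_matches(read_codes, index)
        clusters = _kmer.cluster_by_offset(pairs, gap=params.band_width)
        clusters.sort(key=lambda c: (-c["n_seeds"], c["offset"]))
        for cl in clusters[:_MAX_CLUSTERS]:
            ws = max(0, cl["offset"] - params.band_width)
            we = min(len(read_seq), cl["offset"] + len(query) + params.band_width)
            hit = _align_identity(query, read_seq[ws:we])
            if hit is None:
                continue
            s, e, ident, score = hit
            if ident < params.min_identity:
                continue
            cand = AnchorHit(arm, ws + s, ws + e, strand, ident, score)
            if (
                best is None
                or cand.score > best.score
                or (cand.score == best.score and cand.read_start < best.read_start)
            ):
                best = cand
    return best


def arm_sequences(pmap: PlasmidMap, params: AnchorParams) -> tuple[str, str]:
    """Innermost ``anchor_len`` bases of each flank (adjacent to the array)."""
    tmpl = build_template(pmap, 0)
    left = tmpl.left_flank[-params.anchor_len:]
    right = tmpl.right_flank[: params.anchor_len]
    return left, right


def classify_read(
    read_id: str,
    read_seq: str,
    pmap: PlasmidMap,
    params: AnchorParams | None = None,
    arms: tuple[str, str] | None = None,
) -> ReadClass:
    """Fig-style target/non-target call for one read.

    Target requires both anchors on one strand with left-before-right
    ordering after strand canonicalization; a single anchor or inconsistent
    geometry is non-target; overlapping anchors are ambiguous.
    """
    params = params or AnchorParams()
    left_arm, right_arm = arms if arms is not None else arm_sequences(pmap, params)
    lh = find_anchor(read_seq, left_arm, params, arm="left")
    rh = find_anchor(read_seq, right_arm, params, arm="right")
    if lh is None or rh is None or lh.strand != rh.strand:
        return ReadClass(read_id, "non_target", lh, rh)
    if lh.strand == "+":
        first, second = lh, rh
    else:  # on a reverse-strand read the right arm appears first
        first, second = rh, lh
    if first.read_end <= second.read_start:
        return ReadClass(
            read_id, "target", lh, rh,
            inter_anchor_interval=(first.read_end, second.read_start),
        )
    if first.read_start < second.read_end:  # anchors overlap on the read
        return ReadClass(read_id, "ambiguous", lh, rh)
    return ReadClass(read_id, "non_target", lh, rh)


@dataclass
class SelectionSummary:
    n_total: int
    n_target: int
    n_non_target: int
    n_ambiguous: int

    @property
    def target_fraction(self) -> float:
        return self.n_target / self.n_total

    def as_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_target": self.n_target,
            "n_non_target": self.n_non_target,
            "n_ambiguous": self.n_ambiguous,
            "target_fraction": self.target_fraction,
        }


def summarize_selection(classes: list[ReadClass]) -> SelectionSummary:
    if not classes:
        raise ValueError("no reads to summarize")
    calls = [c.call for c in classes]
    return SelectionSummary(
        n_total=len(calls),
        n_target=calls.count("target"),
        n_non_target=calls.count("non_target"),
        n_ambiguous=calls.count("ambiguous"),
    )
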