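"""Repeat-unit counting inside the inter-anchor region of a target read.

The per-read copy number is the number of accepted, non-overlapping unit
placements between the two vector anchors — the in-silico analogue of
counting BLAST hits of the repeat unit against each target read. Restricting
hits to the inter-anchor region (plus one band width of slack) is what makes
the count immune to read clipping: bases outside the anchors cannot
contribute placements.

Placement candidates come from k-mer seeding and diagonal clustering with an
expected period of one unit length; each candidate is verified by edlib
alignment. Hits spanning less than ``min_span_frac`` of the unit are flagged
``partial`` rather than counted, and reads carrying any partial hit are
marked ``has_partial`` so the reporting layer can exclude them (the default)
or keep them.

``oracle_scan`` is a deliberately slow, seeding-free reference: iterated
best local alignment (Biopython PairwiseAligner) with masking. It exists so
tests can cross-check the fast path against an independent algorithm.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib

from . import _kmer
from .plasmid import ConfigurationError
from .select import _align_identity

__all__ = [
    "UnitParams",
    "UnitHit",
    "CopyCall",
    "scan_units",
    "count_copies",
    "oracle_scan",
]

_MIN_SUBQUERY = 20  # shortest unit fragment worth aligning, bases


@dataclass(frozen=True)
class UnitParams:
    kmer_size: int = 15
    min_identity: float = 0.80
    min_span_frac: float = 0.90
    partial_span_frac: float = 0.30
    band_width: int = 150

    def __post_init__(self) -> None:
        if not 0 < self.partial_span_frac < self.min_span_frac <= 1:
            raise ConfigurationError(
                "need 0 < partial_span_frac < min_span_frac <= 1"
            )
        if not 0 < self.min_identity <= 1:
            raise ConfigurationError("min_identity must be in (0, 1]")


@dataclass(frozen=True)
class UnitHit:
    read_start: int
    read_end: int          # half-open, on the read as given
    strand: str
    identity: float
    span_frac: float       # fraction of the unit covered by the placement
    status: str            # "accepted" | "partial"
    score: int

    @property
    def interval(self) -> tuple[int, int]:
        return (self.read_start, self.read_end)


@dataclass
class CopyCall:
    read_id: str
    copy_number: int
    partial_count: int
    qc: str                # "clean" | "has_partial"
    hits: list[UnitHit]


def scan_units(
    read_seq: str,
    region: tuple[int, int],
    unit_seq: str,
    params: UnitParams | None = None,
    strand: str = "+",
) -> list[UnitHit]:
    """All unit placements (accepted and partial) within ``region``, sorted
    by read position.

    ``region`` is a 0-based half-open interval on the read (normally the
    inter-anchor interval); ``strand`` selects the unit orientation expected
    on this read. One ``band_width`` of slack is allowed on either side.
    """
    params = params or UnitParams()
    ulen = len(unit_seq)
    if ulen < params.kmer_size:
        raise ValueError("unit shorter than kmer_size")
    rs, re_ = region
    if not (0 <= rs <= re_ <= len(read_seq)):
        raise ValueError("region outside read")
    band = params.band_width
    lo = max(0, rs - band)
    hi = min(len(read_seq), re_ + band)
    sub = read_seq[lo:hi]
    if len(sub) < params.kmer_size:
        return []
    query = unit_seq if strand == "+" else _kmer.revcomp(unit_seq)
    index = _kmer.build_index(query, params.kmer_size)
    pairs = _kmer.seed_matches(_kmer.kmer_codes(_kmer.encode(sub), params.kmer_size), index)
    clusters = _kmer.cluster_by_offset(pairs, gap=band)
    hits: list[UnitHit] = []
    prev_end = 0
    for cl in clusters:  # offset order == read order
        hit = _verify_cluster(sub, cl, query, params, floor=prev_end)
        if hit is None:
            continue
        s, e, ident, span, score = hit
        status = "accepted" if span >= params.min_span_frac else "partial"
        hits.append(UnitHit(lo + s, lo + e, strand, ident, span, status, score))
        prev_end = e
    hits.sort(key=lambda h: (h.read_start, -h.score))
    return hits


def _verify_cluster(sub, cl, query, params, floor: int = 0):
    """Align the expected portion of the unit at one seeded placement.

    The placement may run off the region edge (a clipped/partial copy); then
    only the overlapping unit fragment is aligned and span_frac records the
    fraction attempted. Interior partial copies (broken units) fail the
    full-unit alignment and are salvaged from their seed extent. ``floor``
    (the previous hit's end) bounds the alignment window on the left so that
    abutting template copies cannot produce overlapping hits through
    boundary jitter.
    """
    ulen = len(query)
    off = cl["offset"]
    qa = max(0, -off)
    qb = min(ulen, len(sub) - off)
    if qb - qa < max(_MIN_SUBQUERY, params.kmer_size):
        return None
    res = _try_align(sub, query, qa, qb, off, params, floor)
    if res is not None:
        return res
    # salvage: align only the seed-supported fragment of the unit
    qa2 = max(qa, cl["query_min"])
    qb2 = min(qb, cl["query_max"] + params.kmer_size)
    if (qa2, qb2) == (qa, qb) or qb2 - qa2 < max(_MIN_SUBQUERY, params.kmer_size):
        return None
    return _try_align(sub, query, qa2, qb2, off, params, floor)


def _try_align(sub, query, qa, qb, off, params, floor: int = 0):
    band = params.band_width
    ws = max(0, off + qa - band, floor)
    we = min(len(sub), off + qb + band)
    if we - ws < qb - qa - band:
        return None
    hit = _align_identity(query[qa:qb], sub[ws:we])
    if hit is None:
        return None
    s, e, ident, score = hit
    if ident < params.min_identity:
        return None
    span = (qb - qa) / len(query)
    return ws + s, ws + e, ident, span, score


def count_copies(read_id: str, hits: list[UnitHit]) -> CopyCall:
    """Resolve hits into a copy-number call.

    The copy number is the size of the largest set of pairwise
    non-overlapping accepted hits (overlap = any shared read base), found by
    exact interval scheduling; ties in count are broken by total score, then
    leftmost placement. Reads carry at most a handful of hits, so the exact
    DP costs nothing and always matches an exhaustive enumeration. Any
    partial hit marks the read ``has_partial``.
    """
    accepted = sorted(
        (h for h in hits if h.status == "accepted"),
        key=lambda h: (h.read_end, h.read_start, -h.score),
    )
    # DP over hits sorted by end: best[i] = optimum using the first i hits,
    # valued lexicographically as (count, total score, -start positions)
    n = len(accepted)
    best: list[tuple] = [(0, 0, (), ())]  # (count, score, starts_key, chosen_idx)
    for i, h in enumerate(accepted):
        # last hit ending at or before h.read_start
        j = 0
        for j_cand in range(i, 0, -1):
            if accepted[j_cand - 1].read_end <= h.read_start:
                j = j_cand
                break
        take_cnt, take_score, _, take_idx = best[j]
        take = (
            take_cnt + 1,
            take_score + h.score,
            tuple(-accepted[t].read_start for t in take_idx + (i,)),
            take_idx + (i,),
        )
        skip = best[i]
        best.append(max(take, skip, key=lambda v: v[:3]))
    chosen = sorted((accepted[i] for i in best[n][3]), key=lambda h: h.read_start)
    n_partial = sum(1 for h in hits if h.status == "partial")
    return CopyCall(
        read_id=read_id,
        copy_number=len(chosen),
        partial_count=n_partial,
        qc="has_partial" if n_partial else "clean",
        hits=sorted(hits, key=lambda h: h.read_start),
    )


def oracle_scan(
    read_seq: str,
    region: tuple[int, int],
    unit_seq: str,
    min_identity: float = 0.80,
    min_span_frac: float = 0.90,
    both_strands: bool = True,
) -> int:
    """Reference unit count by iterated local alignment with masking.

    Finds the best local alignment of the unit in the region (both
    orientations unless disabled), accepts it when identity and unit span
    clear the thresholds, masks the matched bases, and repeats until no
    acceptable hit remains. Exhaustive and quadratic — intended for small
    inputs and test cross-checks only, independent of the seeded scanner.
    """
    from Bio import Align

    aligner = Align.PairwiseAligner(
        mode="local",
        match_score=2,
        mismatch_score=-3,
        open_gap_score=-5,
        extend_gap_score=-2,
    )
    rs, re_ = region
    target = list(read_seq[rs:re_])
    if not target or not unit_seq:
        return 0
    queries = [unit_seq] + ([_kmer.revcomp(unit_seq)] if both_strands else [])
    count = 0
    for _ in range(len(target) // max(1, len(unit_seq)) + 5):
        best = None
        for q in queries:
            alns = aligner.align("".join(target), q)
            if len(alns) == 0 or alns.score <= 0:
                continue
            aln = alns[0]
            if best is None or aln.score > best.score:
                best = aln
        if best is None:
            break
        c = best.counts()
        cols = c.identities + c.mismatches + c.gaps
        identity = c.identities / cols if cols else 0.0
        qcoords = best.aligned[1]
        span = (qcoords[-1][1] - qcoords[0][0]) / len(unit_seq)
        tcoords = best.aligned[0]
        t0, t1 = int(tcoords[0][0]), int(tcoords[-1][1])
        if identity >= min_identity and span >= min_span_frac:
            count += 1
            target[t0:t1] = ["#"] * (t1 - t0)
        else:
            break
    return count
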