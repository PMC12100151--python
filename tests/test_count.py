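"""Unit scanning, copy-number calling, and the iterated-alignment oracle."""

from itertools import combinations

import numpy as np
import pytest

from tandemtally import (
    ClipModel,
    ErrorModel,
    MixtureSpec,
    UnitParams,
    build_template,
    count_copies,
    mutate,
    oracle_scan,
    scan_units,
    simulate_sample,
)
from tandemtally._kmer import revcomp
from tandemtally.constructs import random_dna
from tandemtally.count import UnitHit
from tandemtally.pipeline import profile_reads

NO_ERROR = ErrorModel(0.0, 0.0, 0.0, 30)
NO_CLIP = ClipModel(0.0, 0.0)


def _hit(start, end, score, status="accepted"):
    return UnitHit(start, end, "+", 1.0, 1.0 if status == "accepted" else 0.5,
                   status, score)


class TestScanUnits:
    def test_exact_three_unit_region(self, small_map):
        t = build_template(small_map, 3)
        region = (len(t.left_flank), len(t.left_flank) + 3 * small_map.unit_length)
        hits = scan_units(t.full_seq, region, small_map.repeat_unit_seq)
        assert [h.status for h in hits] == ["accepted"] * 3
        assert all(h.identity == 1.0 for h in hits)

    def test_partial_trailing_copy_flagged(self, small_map):
        u = small_map.repeat_unit_seq
        lead = build_template(small_map, 0).left_flank[-300:]
        read = lead + u + u[: int(0.4 * len(u))] + random_dna(np.random.default_rng(1), 80)
        region = (len(lead), len(lead) + len(u) + int(0.4 * len(u)))
        hits = scan_units(read, region, u)
        assert [h.status for h in hits] == ["accepted", "partial"]
        assert hits[1].span_frac == pytest.approx(0.4, abs=0.02)

    def test_unit_absent_yields_nothing(self, small_map):
        read = random_dna(np.random.default_rng(2), 2000)
        assert scan_units(read, (0, 2000), small_map.repeat_unit_seq) == []

    def test_region_bounds_validated(self, small_map):
        with pytest.raises(ValueError):
            scan_units("ACGT" * 100, (0, 1000), small_map.repeat_unit_seq)

    def test_strand_invariance_of_count(self, small_map):
        t = build_template(small_map, 3)
        seq = mutate(t.full_seq, ErrorModel(), 17)
        fwd_hits = scan_units(seq, (0, len(seq)), small_map.repeat_unit_seq)
        rev = revcomp(seq)
        rev_hits = scan_units(rev, (0, len(rev)), small_map.repeat_unit_seq, strand="-")
        assert (
            count_copies("r", fwd_hits).copy_number
            == count_copies("r", rev_hits).copy_number
            == 3
        )

    def test_translation_invariance(self, small_map):
        """Prepending non-unit sequence outside the region shifts nothing."""
        t = build_template(small_map, 2)
        region = (len(t.left_flank), len(t.left_flank) + 2 * small_map.unit_length)
        base = count_copies(
            "r", scan_units(t.full_seq, region, small_map.repeat_unit_seq)
        )
        pad = random_dna(np.random.default_rng(3), 500)
        shifted_region = (region[0] + 500, region[1] + 500)
        shifted = count_copies(
            "r", scan_units(pad + t.full_seq, shifted_region, small_map.repeat_unit_seq)
        )
        assert shifted.copy_number == base.copy_number
        assert shifted.qc == base.qc


class TestCountCopies:
    def test_empty_hits(self):
        call = count_copies("r", [])
        assert (call.copy_number, call.qc) == (0, "clean")

    def test_two_disjoint_hits(self):
        call = count_copies("r", [_hit(0, 100, 90), _hit(100, 200, 85)])
        assert call.copy_number == 2

    def test_partial_hits_flag_but_do_not_count(self):
        call = count_copies("r", [_hit(0, 100, 90), _hit(100, 140, 30, "partial")])
        assert call.copy_number == 1
        assert call.qc == "has_partial"
        assert call.partial_count == 1

    def test_conflict_resolution_matches_exhaustive(self):
        """Middle hit overlaps both neighbours and scores highest: the
        largest non-overlapping subset is the two flanking hits, and an
        exhaustive search over subsets agrees with the call."""
        hits = [_hit(0, 100, 80), _hit(50, 150, 95), _hit(140, 240, 70)]
        call = count_copies("r", hits)

        def disjoint(sub):
            return all(
                a.read_end <= b.read_start or b.read_end <= a.read_start
                for a, b in combinations(sub, 2)
            )

        best = max(
            (len(sub) for n in range(len(hits) + 1)
             for sub in combinations(hits, n) if disjoint(sub)),
        )
        assert call.copy_number == best == 2


class TestOracle:
    def test_oracle_matches_scan_on_constructed_examples(self, small_map):
        u = small_map.repeat_unit_seq
        t3 = build_template(small_map, 3)
        region3 = (len(t3.left_flank), len(t3.left_flank) + 3 * len(u))
        lead = build_template(small_map, 0).left_flank[-300:]
        partial_read = lead + u + u[: int(0.4 * len(u))]
        cases = [
            (t3.full_seq, region3),
            (partial_read, (len(lead), len(partial_read))),
            (random_dna(np.random.default_rng(4), 1500), (0, 1500)),
        ]
        for read, region in cases:
            fast = count_copies("r", scan_units(read, region, u)).copy_number
            assert oracle_scan(read, region, u) == fast

    @pytest.mark.parametrize("k", range(6))
    def test_zero_error_templates(self, small_map, k):
        t = build_template(small_map, k)
        region = (len(t.left_flank), len(t.left_flank) + k * small_map.unit_length)
        assert oracle_scan(t.full_seq, region, small_map.repeat_unit_seq) == k

    def test_unit_absent(self, small_map):
        read = random_dna(np.random.default_rng(5), 1200)
        assert oracle_scan(read, (0, 1200), small_map.repeat_unit_seq) == 0


class TestSimulatedAccuracy:
    def test_two_copy_reads_counted_exactly(self, default_map):
        """Simulated two-copy reads at ~2.5% total error: the accepted-hit
        count equals truth for >= 99% of reads."""
        n = 300
        batch = simulate_sample(
            default_map, MixtureSpec({2: 1.0}), ErrorModel(), NO_CLIP, n, 13
        )
        res = profile_reads([(r.read_id, r.sequence) for r in batch.reads], default_map)
        correct = sum(1 for c in res.calls.values() if c.copy_number == 2)
        assert len(res.calls) == n
        assert correct >= 0.99 * n

    def test_zero_error_exact_for_all_copy_numbers(self, default_map):
        """Error-free reads of k-unit templates yield copy_number k for all
        reads, k in 0..5."""
        props = {k: 1 / 6 for k in range(6)}
        batch = simulate_sample(
            default_map, MixtureSpec(props), NO_ERROR, NO_CLIP, 120, 14
        )
        res = profile_reads([(r.read_id, r.sequence) for r in batch.reads], default_map)
        assert len(res.calls) == 120
        for rid, call in res.calls.items():
            assert call.copy_number == batch.truth.loc[rid, "copy_number"]
            assert call.qc == "clean"
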