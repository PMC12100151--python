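"""Error model, clipping, mixture sampling, and simulator determinism."""

import edlib
import numpy as np
import pytest

from tandemtally import (
    ClipModel,
    ConfigurationError,
    ErrorModel,
    MixtureSpec,
    build_template,
    mutate,
    simulate_sample,
)
from tandemtally._kmer import revcomp
from tandemtally.constructs import DEFAULT_MIXTURE_PROPORTIONS, random_dna
from tandemtally.seqio import write_fastq, write_truth
from tandemtally.simulate import TARGET_LABEL

NO_ERROR = ErrorModel(0.0, 0.0, 0.0, 30)
NO_CLIP = ClipModel(0.0, 0.0)


class TestMutate:
    def test_zero_rates_identity(self):
        seq = random_dna(np.random.default_rng(0), 500)
        assert mutate(seq, NO_ERROR, 1) == seq

    def test_empty_sequence(self):
        assert mutate("", ErrorModel(), 1) == ""

    def test_deterministic_for_fixed_seed(self):
        seq = random_dna(np.random.default_rng(1), 2000)
        model = ErrorModel()
        assert mutate(seq, model, 42) == mutate(seq, model, 42)
        assert mutate(seq, model, 42) != mutate(seq, model, 43)

    def test_substitution_count_matches_binomial(self):
        """Substitution-only errors: mismatch count within 3 sigma of n*p,
        checked over several seeds (binomial oracle)."""
        seq = random_dna(np.random.default_rng(2), 10_000)
        model = ErrorModel(sub_rate=0.01, ins_rate=0.0, del_rate=0.0)
        n, p = len(seq), 0.01
        sigma = np.sqrt(n * p * (1 - p))
        for seed in range(5):
            mutated = mutate(seq, model, seed)
            assert len(mutated) == n
            mismatches = sum(a != b for a, b in zip(seq, mutated))
            assert abs(mismatches - n * p) <= 3 * sigma

    def test_edit_distance_tracks_total_rate(self):
        """Expected edit distance ~ total error rate times length."""
        seq = random_dna(np.random.default_rng(3), 10_000)
        model = ErrorModel(0.01, 0.005, 0.01)
        dists = [
            edlib.align(mutate(seq, model, seed), seq, mode="NW")["editDistance"]
            for seed in range(5)
        ]
        expected = model.total_rate * len(seq)
        # alignment can explain some events more cheaply, so allow 15% slack
        assert expected * 0.85 <= np.mean(dists) <= expected * 1.05

    def test_rate_validation(self):
        with pytest.raises(ConfigurationError):
            ErrorModel(sub_rate=0.6)
        with pytest.raises(ConfigurationError):
            ErrorModel(0.4, 0.4, 0.4)


class TestMixtureSpec:
    def test_proportions_must_sum_to_one(self):
        with pytest.raises(ConfigurationError):
            MixtureSpec({1: 0.5, 2: 0.4})

    def test_background_requires_pool(self):
        with pytest.raises(ConfigurationError):
            MixtureSpec({2: 1.0}, background_fraction=0.3, background_pool=[])

    def test_exonuclease_filters_linear_molecules(self, background_pool):
        mix = MixtureSpec({2: 1.0}, 0.5, background_pool)
        filtered = mix.without_linear_background()
        assert all(m.circular for m in filtered.background_pool)
        assert len(filtered.background_pool) == 1


class TestSimulateSample:
    def test_no_background_all_target(self, default_map):
        batch = simulate_sample(
            default_map, MixtureSpec({2: 1.0}), NO_ERROR, NO_CLIP, 50, 3
        )
        assert (batch.truth["origin"] == TARGET_LABEL).all()

    def test_clean_reads_equal_template_or_revcomp(self, default_map):
        batch = simulate_sample(
            default_map, MixtureSpec({1: 0.5, 2: 0.5}), NO_ERROR, NO_CLIP, 40, 4
        )
        templates = {k: build_template(default_map, k).full_seq for k in (1, 2)}
        for read in batch.reads:
            row = batch.truth.loc[read.read_id]
            expected = templates[int(row.copy_number)]
            if row.strand == "-":
                expected = revcomp(expected)
            assert read.sequence == expected

    def test_mixture_proportions_recovered(self, default_map):
        """Observed one-copy fraction within 3 binomial SE of 0.25."""
        n = 5000
        batch = simulate_sample(
            default_map, MixtureSpec({1: 0.25, 2: 0.75}), NO_ERROR, NO_CLIP, n, 5
        )
        frac = (batch.truth["copy_number"] == 1).mean()
        se = np.sqrt(0.25 * 0.75 / n)
        assert abs(frac - 0.25) <= 3 * se

    def test_clipping_recorded_in_truth(self, default_map):
        batch = simulate_sample(
            default_map, MixtureSpec({2: 1.0}), NO_ERROR,
            ClipModel(1.0, 200.0), 50, 6,
        )
        clips = batch.truth[["left_clip", "right_clip"]].to_numpy()
        assert (clips >= 0).all() and clips.sum() > 0
        tlen = len(build_template(default_map, 2))
        for read in batch.reads:
            row = batch.truth.loc[read.read_id]
            assert len(read.sequence) == tlen - row.left_clip - row.right_clip

    def test_background_draws_from_pool(self, default_map, background_pool):
        batch = simulate_sample(
            default_map,
            MixtureSpec({2: 1.0}, 0.5, background_pool),
            NO_ERROR, NO_CLIP, 400, 7,
        )
        labels = set(batch.truth["origin"])
        assert TARGET_LABEL in labels
        assert {m.label for m in background_pool} & labels

    def test_same_seed_byte_identical_outputs(self, default_map, tmp_path):
        """Full determinism: FASTQ and truth TSV are byte-identical for a
        fixed seed."""
        mix = MixtureSpec(DEFAULT_MIXTURE_PROPORTIONS)
        paths = []
        for tag in ("a", "b"):
            batch = simulate_sample(
                default_map, mix, ErrorModel(), ClipModel(0.3, 300), 100, 99
            )
            fq, tsv = tmp_path / f"{tag}.fastq", tmp_path / f"{tag}.tsv"
            write_fastq(batch, fq)
            write_truth(batch, tsv)
            paths.append((fq, tsv))
        assert paths[0][0].read_bytes() == paths[1][0].read_bytes()
        assert paths[0][1].read_bytes() == paths[1][1].read_bytes()

    def test_read_streams_stable_under_n_reads(self, default_map):
        """Read i is identical no matter how many reads follow it."""
        mix = MixtureSpec(DEFAULT_MIXTURE_PROPORTIONS)
        small = simulate_sample(default_map, mix, ErrorModel(), NO_CLIP, 5, 21)
        large = simulate_sample(default_map, mix, ErrorModel(), NO_CLIP, 30, 21)
        for a, b in zip(small.reads, large.reads[:5]):
            assert a.sequence == b.sequence

    def test_n_reads_validation(self, default_map):
        with pytest.raises(ValueError):
            simulate_sample(default_map, MixtureSpec({2: 1.0}), NO_ERROR, NO_CLIP, 0, 1)
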