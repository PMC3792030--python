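import numpy as np
import pytest
from hypothesis import given, strategies as st

from decayscan.coverage import (
    N_BINS,
    PositionalProfile,
    TooShortError,
    ZeroCoverageError,
    bin_profile,
    bin_profiles,
    compute_depth,
    condition_binned_profiles,
    count_reads,
    depth_profiles,
    genome_depth,
    pool_profiles,
)
from decayscan.io import TranscriptAnnotation

from conftest import make_reads


def brute_force_depth(tx, intervals):
    """Independent per-base interval-stabbing oracle."""
    depth = [
        sum(1 for s, e in intervals if s <= p < e) for p in range(tx.start, tx.end)
    ]
    if tx.strand == "-":
        depth = depth[::-1]
    return np.array(depth, dtype=float)


def brute_force_bins(depth):
    """Independent base-to-bin assignment oracle (explicit loop)."""
    length = len(depth)
    total = sum(depth)
    bins = [0.0] * N_BINS
    for p, d in enumerate(depth):
        bins[(N_BINS * p) // length] += d / total
    return np.array(bins)


class TestComputeDepth:
    def test_no_overlap_gives_zeros(self, toy_tx):
        reads = make_reads([("chr1", 0, 36, "+"), ("chr2", 100, 136, "+")])
        profile = compute_depth(reads, toy_tx)
        assert profile.n_overlapping_reads == 0
        assert not profile.depth.any()

    def test_interval_stabbing_example(self):
        tx = TranscriptAnnotation("txA", "chr1", 100, 110, "+")
        reads = make_reads([("chr1", 95, 105, "+"), ("chr1", 104, 112, "+")])
        profile = compute_depth(reads, tx)
        assert profile.n_overlapping_reads == 2
        assert profile.depth.tolist() == [1, 1, 1, 1, 2, 1, 1, 1, 1, 1]

    def test_minus_strand_reverses_profile(self):
        tx = TranscriptAnnotation("txA", "chr1", 100, 110, "-")
        reads = make_reads([("chr1", 95, 105, "-"), ("chr1", 104, 112, "-")])
        profile = compute_depth(reads, tx)
        assert profile.depth.tolist() == [1, 1, 1, 1, 1, 2, 1, 1, 1, 1]

    def test_spanning_read_on_minus_strand(self):
        tx = TranscriptAnnotation("txA", "chr1", 100, 110, "-")
        profile = compute_depth(make_reads([("chr1", 90, 120, "-")]), tx)
        assert profile.depth.tolist() == [1.0] * 10
        assert profile.n_overlapping_reads == 1

    def test_strandedness_flag(self, toy_tx):
        reads = make_reads([("chr1", 100, 110, "-")])
        assert compute_depth(reads, toy_tx, stranded=True).n_overlapping_reads == 0
        assert compute_depth(reads, toy_tx, stranded=False).n_overlapping_reads == 1

    def test_matches_brute_force_on_random_layouts(self, rng):
        for _ in range(30):
            start = int(rng.integers(0, 50))
            length = int(rng.integers(5, 60))
            strand = rng.choice(["+", "-"])
            tx = TranscriptAnnotation("t", "c", start, start + length, strand)
            n = int(rng.integers(0, 15))
            ivals = []
            for _ in range(n):
                s = int(rng.integers(0, start + length + 20))
                ivals.append((s, s + int(rng.integers(1, 30))))
            reads = make_reads([("c", s, e, strand) for s, e in ivals])
            got = compute_depth(reads, tx)
            np.testing.assert_array_equal(got.depth, brute_force_depth(tx, ivals))

    def test_depth_profiles_agree_with_per_transcript_calls(self, small_dataset):
        subset = small_dataset.reads[small_dataset.reads["sample_id"] == "WT_log_1"]
        batch = depth_profiles(subset, small_dataset.annotations)
        for tx in small_dataset.annotations[:10]:
            single = compute_depth(subset, tx)
            np.testing.assert_array_equal(batch[tx.transcript_id].depth, single.depth)
            assert batch[tx.transcript_id].n_overlapping_reads == single.n_overlapping_reads


class TestBinProfile:
    def test_uniform_depth_gives_uniform_bins(self):
        profile = PositionalProfile("t", np.full(1000, 3.0), 30)
        np.testing.assert_allclose(bin_profile(profile).bins, 0.01)

    def test_point_mass_lands_in_first_bin(self):
        depth = np.zeros(500)
        depth[0] = 7
        bins = bin_profile(PositionalProfile("t", depth, 7)).bins
        assert bins[0] == 1.0 and not bins[1:].any()

    def test_length_not_divisible_matches_brute_force(self):
        depth = np.ones(250)
        bins = bin_profile(PositionalProfile("t", depth, 10)).bins
        expected = brute_force_bins(depth)
        np.testing.assert_allclose(bins, expected, atol=1e-15)
        assert set(np.round(expected * 250).astype(int)) == {2, 3}
        assert bins.sum() == pytest.approx(1.0, abs=1e-12)

    def test_too_short_and_zero_coverage_flagged(self):
        with pytest.raises(TooShortError):
            bin_profile(PositionalProfile("t", np.ones(99), 5))
        with pytest.raises(ZeroCoverageError):
            bin_profile(PositionalProfile("t", np.zeros(200), 0))

    @given(scale=st.floats(min_value=1e-3, max_value=1e6), seed=st.integers(0, 10_000))
    def test_scale_invariance(self, scale, seed):
        rng = np.random.default_rng(seed)
        depth = rng.random(int(rng.integers(100, 400))) + 1e-9
        base = bin_profile(PositionalProfile("t", depth, 1)).bins
        scaled = bin_profile(PositionalProfile("t", depth * scale, 1)).bins
        np.testing.assert_allclose(base, scaled, rtol=1e-9)

    def test_matches_brute_force_on_random_profiles(self, rng):
        for _ in range(100):
            length = int(rng.integers(100, 1000))
            depth = rng.poisson(5, size=length).astype(float)
            if depth.sum() == 0:
                depth[0] = 1
            got = bin_profile(PositionalProfile("t", depth, 1)).bins
            np.testing.assert_allclose(got, brute_force_bins(depth), atol=1e-12)

    def test_strand_mirror_symmetry(self, rng):
        """A transcript and its reverse-complement layout bin identically."""
        tx_fwd = TranscriptAnnotation("t", "c", 300, 900, "+")
        tx_rev = TranscriptAnnotation("t", "c", 300, 900, "-")
        fwd = []
        for _ in range(200):
            s = int(rng.integers(250, 900))
            fwd.append((s, s + 40))
        # mirror every read through the transcript's own midline
        rev = [(300 + (900 - e), 300 + (900 - s)) for s, e in fwd]
        p_fwd = bin_profile(compute_depth(make_reads([("c", s, e, "+") for s, e in fwd]), tx_fwd))
        p_rev = bin_profile(compute_depth(make_reads([("c", s, e, "-") for s, e in rev]), tx_rev))
        np.testing.assert_allclose(p_fwd.bins, p_rev.bins, atol=1e-12)


class TestBatchAndCounting:
    def test_bin_profiles_tracks_exclusion_reasons(self):
        profiles = {
            "ok": PositionalProfile("ok", np.ones(200), 60),
            "short": PositionalProfile("short", np.ones(50), 60),
            "silent": PositionalProfile("silent", np.zeros(200), 0),
            "sparse": PositionalProfile("sparse", np.ones(200), 3),
        }
        binned, excluded = bin_profiles(profiles, min_reads=50)
        assert set(binned) == {"ok"}
        assert excluded == {"short": "too_short", "silent": "unquantifiable", "sparse": "low_coverage"}

    def test_pool_profiles_sums_depth(self):
        a = PositionalProfile("t", np.ones(120), 4)
        b = PositionalProfile("t", np.full(120, 2.0), 8)
        pooled = pool_profiles([a, b])
        assert pooled.n_overlapping_reads == 12
        np.testing.assert_array_equal(pooled.depth, np.full(120, 3.0))
        with pytest.raises(ValueError):
            pool_profiles([a, PositionalProfile("u", np.ones(120), 1)])

    def test_pool_and_average_replicates_agree_at_equal_depth(self, small_dataset):
        samples = ["WT_log_1", "WT_log_2"]
        pooled, _ = condition_binned_profiles(
            small_dataset.reads, small_dataset.annotations, samples, min_reads=1
        )
        averaged, _ = condition_binned_profiles(
            small_dataset.reads, small_dataset.annotations, samples,
            min_reads=1, replicate_handling="average",
        )
        assert set(pooled) == set(averaged)
        tid = next(iter(pooled))
        assert averaged[tid].bins.sum() == pytest.approx(1.0, abs=1e-9)

    def test_one_nt_overlap_counting_rule(self):
        tx = TranscriptAnnotation("t", "c", 100, 200, "+")
        reads = make_reads(
            [
                ("c", 64, 100, "+"),   # ends where tx starts: no overlap
                ("c", 65, 101, "+"),   # 1 nt overlap: counted
                ("c", 199, 235, "+"),  # 1 nt at the other end: counted
                ("c", 200, 236, "+"),  # starts at tx end: no overlap
            ]
        )
        counts = count_reads(reads, [tx])
        assert counts.loc["t", "s1"] == 2

    def test_genome_depth_runs(self):
        reads = make_reads([("c", 0, 10, "+"), ("c", 5, 15, "+"), ("c", 30, 40, "-")])
        depth = genome_depth(reads, "+")
        assert depth["c"][:5].tolist() == [1] * 5
        assert depth["c"][5:10].tolist() == [2] * 5
        assert depth["c"][30:40].sum() == 0
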