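"""Interval merging, background shuffling, midpoint counting and RPKM."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cadchart.quant import (
    GenomicInterval,
    InfeasiblePlacementError,
    PeakSet,
    compute_rpkm,
    count_reads_in_intervals,
    merge_replicate_peaks,
    shuffle_background,
)


def ps(*intervals):
    return PeakSet(pd.DataFrame(intervals, columns=["chrom", "start", "end"]))


def brute_force_support_merge(replicates, min_support, genome_end=5000):
    """Per-base support counting on a dense array (independent oracle)."""
    chroms = sorted({iv.chrom for r in replicates for iv in r})
    out = []
    for chrom in chroms:
        support = np.zeros(genome_end, dtype=int)
        for rep in replicates:
            covered = np.zeros(genome_end, dtype=bool)
            for iv in rep:
                if iv.chrom == chrom:
                    covered[iv.start : iv.end] = True
            support += covered
        mask = support >= min_support
        diffs = np.flatnonzero(np.diff(np.concatenate([[0], mask.view(np.int8), [0]])))
        for s, e in zip(diffs[::2], diffs[1::2]):
            out.append((chrom, int(s), int(e)))
    return out


class TestGenomicInterval:
    def test_rejects_invalid(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 100, 100)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -1, 100)


class TestMergeReplicatePeaks:
    def test_single_replicate_identity(self):
        reps = [ps(("chr1", 100, 200), ("chr1", 300, 400))]
        merged = merge_replicate_peaks(reps, min_support=1)
        assert merged.df[["chrom", "start", "end"]].values.tolist() == [
            ["chr1", 100, 200],
            ["chr1", 300, 400],
        ]

    def test_disjoint_replicates_give_empty_set(self):
        merged = merge_replicate_peaks(
            [ps(("chr1", 0, 100)), ps(("chr1", 200, 300))], min_support=2
        )
        assert len(merged) == 0

    def test_three_replicate_partial_overlap(self):
        # supported-by->=2 positions of {[100,200), [150,250), [160,180)} are [150,200)
        merged = merge_replicate_peaks(
            [ps(("chr1", 100, 200)), ps(("chr1", 150, 250)), ps(("chr1", 160, 180))],
            min_support=2,
        )
        assert merged.df[["start", "end"]].values.tolist() == [[150, 200]]

    def test_empty_replicate_list_raises(self):
        with pytest.raises(ValueError):
            merge_replicate_peaks([], 1)

    @pytest.mark.parametrize("min_support", [1, 2, 3])
    def test_matches_per_base_oracle(self, min_support):
        rng = np.random.default_rng(42)
        replicates = []
        for _ in range(3):
            starts = np.sort(rng.integers(0, 4000, size=12))
            replicates.append(
                ps(*[("chr1", int(s), int(s + rng.integers(50, 400))) for s in starts])
            )
        merged = merge_replicate_peaks(replicates, min_support)
        expected = brute_force_support_merge(replicates, min_support)
        assert merged.df[["chrom", "start", "end"]].apply(tuple, axis=1).tolist() == expected

    def test_replicate_order_invariance(self):
        rng = np.random.default_rng(3)
        reps = [
            ps(*[("chr1", int(s), int(s) + 100) for s in rng.integers(0, 3000, 8)])
            for _ in range(3)
        ]
        a = merge_replicate_peaks(reps, 2).df
        b = merge_replicate_peaks(reps[::-1], 2).df
        pd.testing.assert_frame_equal(a, b)


class TestShuffleBackground:
    def test_empty_peaks(self):
        out = shuffle_background(PeakSet.empty(), {"chr1": 1000}, PeakSet.empty(), seed=0)
        assert len(out) == 0

    def test_unique_legal_placement_is_found(self):
        peaks = ps(("chr1", 0, 1000))
        exclusion = ps(("chr1", 0, 9000))
        out = shuffle_background(peaks, {"chr1": 10000}, exclusion, seed=1)
        assert out.df[["start", "end"]].values.tolist() == [[9000, 10000]]

    def test_no_legal_placement_raises(self):
        with pytest.raises(InfeasiblePlacementError):
            shuffle_background(
                ps(("chr1", 0, 1000)), {"chr1": 10000}, ps(("chr1", 0, 9500)), seed=1
            )

    def test_conservation_and_exclusion_on_large_genome(self):
        rng = np.random.default_rng(11)
        starts = np.sort(rng.choice(np.arange(0, 9_900_000, 2000), 500, replace=False))
        lengths = rng.integers(200, 1500, size=500)
        peaks = ps(*[("chr1", int(s), int(s + l)) for s, l in zip(starts, lengths)])
        sizes = {"chr1": 10_000_000}
        out = shuffle_background(peaks, sizes, peaks, seed=5)
        again = shuffle_background(peaks, sizes, peaks, seed=5)
        pd.testing.assert_frame_equal(out.df, again.df)  # seeded reproducibility
        assert len(out) == len(peaks)
        assert sorted(out.lengths) == sorted(peaks.lengths)  # length multiset
        excluded = np.zeros(10_000_000, dtype=bool)
        for iv in peaks:
            excluded[iv.start : iv.end] = True
        for iv in out:  # interval-intersection oracle: zero overlap
            assert not excluded[iv.start : iv.end].any()
            assert 0 <= iv.start and iv.end <= 10_000_000

    def test_different_seeds_differ(self):
        peaks = ps(*[("chr1", i * 1000, i * 1000 + 300) for i in range(20)])
        a = shuffle_background(peaks, {"chr1": 1_000_000}, peaks, seed=1)
        b = shuffle_background(peaks, {"chr1": 1_000_000}, peaks, seed=2)
        assert not a.df[["start"]].equals(b.df[["start"]])


class TestCountReads:
    def frag(self, *rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end"])

    def test_no_fragments_all_zero(self):
        counts = count_reads_in_intervals(self.frag(), ps(("chr1", 0, 100)))
        assert counts.tolist() == [0]

    def test_midpoint_assignment(self):
        # fragment [100,200) has midpoint 150, inside [140,160)
        counts = count_reads_in_intervals(
            self.frag(("chr1", 100, 200)), ps(("chr1", 140, 160))
        )
        assert counts.tolist() == [1]

    def test_midpoint_outside_interval_not_counted(self):
        counts = count_reads_in_intervals(
            self.frag(("chr1", 100, 200)), ps(("chr1", 100, 149))
        )
        assert counts.tolist() == [0]

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(0)
        starts = rng.integers(0, 10_000, size=1000)
        frags = self.frag(*[("chr1", int(s), int(s + 80)) for s in starts])
        tiles = ps(*[("chr1", i * 500, (i + 1) * 500) for i in range(20)])
        counts = count_reads_in_intervals(frags, tiles)
        mids = starts + 40
        expected = [
            int(((mids >= iv.start) & (mids < iv.end)).sum()) for iv in tiles
        ]
        assert counts.tolist() == expected
        assert counts.sum() <= len(frags)


class TestComputeRpkm:
    def test_zero_count_gives_zero(self):
        assert compute_rpkm([0], [500], 1e6).tolist() == [0.0]

    def test_unit_case(self):
        assert compute_rpkm([1000], [1000], 1e6)[0] == pytest.approx(1000.0)

    def test_formula(self):
        # 250 / ((500/1e3) * (2e7/1e6)) = 25.0
        assert compute_rpkm([250], [500], 2e7)[0] == pytest.approx(25.0)

    @given(
        count=st.integers(0, 10_000),
        length=st.integers(1, 100_000),
        library=st.integers(1, 10**9),
        factor=st.floats(0.01, 1000),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_scale_invariance(self, count, length, library, factor):
        base = compute_rpkm([count], [length], library)[0]
        scaled = compute_rpkm([count * factor], [length], library * factor)[0]
        assert scaled == pytest.approx(base, rel=1e-9)

    @pytest.mark.parametrize("lengths,library", [([0], 1e6), ([100], 0), ([-5], 1e6)])
    def test_invalid_normalization_basis(self, lengths, library):
        with pytest.raises(ValueError):
            compute_rpkm([1], lengths, library)
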