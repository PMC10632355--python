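"""Profile matrices, pileups, k-means clustering and mark comparison."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import silhouette_score

from cadchart.profiles import (
    ProfileMatrix,
    build_profile_matrix,
    cluster_profiles,
    compare_marks,
    pileup,
)
from cadchart.quant import PeakSet


def bedgraph(chrom_len=100_000, bin_width=50, value=0.0, chrom="chr1"):
    starts = np.arange(0, chrom_len, bin_width)
    return pd.DataFrame(
        {"chrom": chrom, "start": starts, "end": starts + bin_width,
         "value": np.full(len(starts), value, dtype=float)}
    )


def peak_set(*rows):
    return PeakSet(pd.DataFrame(rows, columns=["chrom", "start", "end"]))


class TestBuildProfileMatrix:
    def test_zero_signal_gives_zero_matrix(self):
        pm = build_profile_matrix(bedgraph(), peak_set(("chr1", 40_000, 40_500)))
        assert pm.values.shape == (1, 120)
        assert not pm.values.any()

    def test_delta_signal_hits_only_central_bin(self):
        track = bedgraph()
        center = (40_000 + 40_500) // 2  # 40,250: inside bin [40250, 40300)
        track.loc[track["start"] == 40_250, "value"] = 7.0
        pm = build_profile_matrix(track, peak_set(("chr1", 40_000, 40_500)))
        nz = np.flatnonzero(pm.values[0])
        assert nz.tolist() == [60]  # first bin right of the anchor
        assert pm.values[0, 60] == pytest.approx(7.0)

    def test_uniform_signal_gives_constant_profile_both_anchors(self):
        track = bedgraph(value=1.0)
        pm = build_profile_matrix(track, peak_set(("chr1", 40_000, 40_500)))
        assert np.allclose(pm.values, 1.0)
        genes = pd.DataFrame(
            {"gene_id": ["g1"], "chrom": ["chr1"], "strand": ["-"],
             "tss": [42_000], "span_start": [40_000], "span_end": [42_000]}
        )
        pm_body = build_profile_matrix(track, genes, anchor_mode="scaled_body")
        assert pm_body.values.shape == (1, 220)
        assert np.allclose(pm_body.values, 1.0)

    def test_out_of_chromosome_bins_zero_filled(self):
        pm = build_profile_matrix(
            bedgraph(value=2.0), peak_set(("chr1", 0, 500))
        )  # window extends 3 kb left of the chromosome start
        left = pm.values[0, :50]
        assert not left.any()
        assert np.allclose(pm.values[0, 70:], 2.0)

    def test_signal_conservation_for_in_bounds_loci(self):
        rng = np.random.default_rng(8)
        track = bedgraph()
        track["value"] = rng.lognormal(0, 1, size=len(track))
        loci = peak_set(("chr1", 50_000, 50_400))
        pm = build_profile_matrix(track, loci)
        center = (50_000 + 50_400) // 2
        window_mask = (track["start"] >= center - 3000) & (track["start"] < center + 3000)
        integral = (track.loc[window_mask, "value"] * 50).sum()
        assert (pm.values[0] * 50).sum() == pytest.approx(integral, rel=1e-9)

    def test_bad_bin_width_raises(self):
        with pytest.raises(ValueError):
            build_profile_matrix(bedgraph(), peak_set(("chr1", 0, 100)), bin_width=0)
        with pytest.raises(ValueError):
            build_profile_matrix(bedgraph(), peak_set(("chr1", 0, 100)), bin_width=70)


def toy_profile(rows, ids=None):
    rows = np.asarray(rows, dtype=float)
    ids = ids or [f"L{i}" for i in range(len(rows))]
    positions = (np.arange(rows.shape[1]) - rows.shape[1] // 2) * 50 + 25.0
    return ProfileMatrix(ids, positions, rows, "peak_center", 50, rows.shape[1] * 25)


class TestPileup:
    def test_single_locus_identity(self):
        pm = toy_profile([[1.0, 2.0, 3.0, 4.0]])
        assert pileup(pm, ["L0"]).tolist() == [1.0, 2.0, 3.0, 4.0]

    def test_two_row_mean(self):
        pm = toy_profile([[1.0, 2.0], [3.0, 6.0]])
        assert pileup(pm).tolist() == [2.0, 4.0]

    def test_matches_mean_oracle(self):
        rng = np.random.default_rng(1)
        rows = rng.random((100, 24))
        pm = toy_profile(rows)
        np.testing.assert_allclose(pileup(pm), rows.mean(axis=0), atol=1e-12)

    def test_empty_subset_raises(self):
        with pytest.raises(ValueError):
            pileup(toy_profile([[1.0]]), [])


class TestClusterProfiles:
    def two_group_profile(self, rng, n=40):
        x = np.linspace(-3, 3, 60)
        shape = np.exp(-(x**2) / 2)
        high = 10 * shape + rng.normal(0, 0.2, size=(n, 60))
        low = 1 * shape + rng.normal(0, 0.2, size=(n, 60))
        return toy_profile(np.vstack([high, low]).clip(min=0))

    def test_k1_single_cluster(self):
        pm = toy_profile([[1.0, 2.0], [3.0, 4.0]])
        cl = cluster_profiles(pm, k=1, seed=0)
        assert set(cl.cluster_labels) == {1}

    def test_two_group_recovery_and_ordering(self):
        rng = np.random.default_rng(4)
        pm = self.two_group_profile(rng)
        cl = cluster_profiles(pm, k=2, seed=0)
        assert (cl.cluster_labels[:40] == 1).all()  # cluster 1 = strong group
        assert (cl.cluster_labels[40:] == 2).all()
        sil = silhouette_score(pm.values, cl.cluster_labels)
        assert sil > 0.8

    def test_row_permutation_invariance_after_relabeling(self):
        rng = np.random.default_rng(4)
        pm = self.two_group_profile(rng)
        perm = rng.permutation(len(pm.locus_ids))
        pm_perm = ProfileMatrix(
            [pm.locus_ids[i] for i in perm], pm.bin_positions, pm.values[perm],
            pm.anchor_mode, pm.bin_width, pm.window,
        )
        cl = cluster_profiles(pm, k=2, seed=0)
        cl_perm = cluster_profiles(pm_perm, k=2, seed=0)
        by_id = dict(zip(cl.locus_ids, cl.cluster_labels))
        by_id_perm = dict(zip(cl_perm.locus_ids, cl_perm.cluster_labels))
        assert by_id == by_id_perm

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(4)
        pm = self.two_group_profile(rng)
        a = cluster_profiles(pm, k=3, seed=9).cluster_labels
        b = cluster_profiles(pm, k=3, seed=9).cluster_labels
        assert (a == b).all()

    def test_k_above_locus_count_raises(self):
        with pytest.raises(ValueError):
            cluster_profiles(toy_profile([[1.0, 2.0]]), k=2, seed=0)


class TestCompareMarks:
    def profiles_for(self, diffs_log2, n=30, seed=0):
        """One profile pair per mark with a given window-mean log2 offset."""
        rng = np.random.default_rng(seed)
        base = rng.lognormal(2, 0.3, size=(n, 40))
        out = {}
        for mark, d in diffs_log2.items():
            out[(mark, "pos")] = toy_profile(base * (2.0**d))
            out[(mark, "neg")] = toy_profile(base)
        return out

    def test_identical_populations_zero_diff(self):
        pm = self.profiles_for({"H3K27ac": 0.0, "H3K4me3": 0.0})
        comp = compare_marks(pm, "pos", "neg")
        assert np.allclose(comp.per_locus.to_numpy(), 0.0)

    def test_effect_ordering_recovered(self):
        pm = self.profiles_for({"H3K27ac": 2.0, "H3K4me3": 0.5})
        comp = compare_marks(pm, "pos", "neg")
        assert comp.summary["H3K27ac"] > comp.summary["H3K4me3"]
        assert comp.strongest_mark == "H3K27ac"

    def test_antisymmetry_under_population_swap(self):
        pm = self.profiles_for({"H3K27ac": 1.0, "H3K4me3": 0.3})
        fwd = compare_marks(pm, "pos", "neg").per_locus
        rev = compare_marks(pm, "neg", "pos").per_locus
        np.testing.assert_allclose(fwd.to_numpy(), -rev.to_numpy(), atol=1e-12)

    def test_pseudocount_shrinks_diffs(self):
        pm = self.profiles_for({"H3K27ac": 1.5})
        small = compare_marks(pm, "pos", "neg", pseudocount=1.0).per_locus.abs()
        large = compare_marks(pm, "pos", "neg", pseudocount=2.0).per_locus.abs()
        assert (large.to_numpy() <= small.to_numpy() + 1e-12).all()

    def test_binning_mismatch_raises(self):
        pm = self.profiles_for({"H3K27ac": 1.0})
        other = toy_profile(np.ones((30, 20)))
        pm[("H3K4me3", "pos")] = other
        pm[("H3K4me3", "neg")] = other
        with pytest.raises(ValueError):
            compare_marks(pm, "pos", "neg")
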