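"""Tests for SNP-index computation, filtering, and the window scan."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import bulkseg as bs

import oracles


def make_counts(rows):
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "sb_ref", "sb_alt", "hb_ref", "hb_alt"]
    )


class TestSnpIndex:
    @pytest.mark.parametrize(
        "ref,alt,expected", [(12, 0, 0.0), (0, 12, 1.0), (6, 6, 0.5), (9, 3, 0.25)]
    )
    def test_fraction_of_nonreference_reads(self, ref, alt, expected):
        assert bs.snp_index(ref, alt) == pytest.approx(expected)

    def test_zero_depth_is_uncovered_not_zero(self):
        with pytest.raises(ValueError, match="uncovered"):
            bs.snp_index(0, 0)

    def test_delta_is_sb_minus_hb(self):
        assert bs.delta_index(0.9, 0.1) == pytest.approx(0.8)
        assert bs.delta_index(0.44, 0.44) == 0.0

    def test_dominant_class_bulk_delta_two_thirds(self):
        # SB of pure F_ plants is a 1:2 FF:Ff mix -> allele frequency
        # (1*2 + 2*1) / (3*2) = 2/3; HB of ff plants has frequency 0
        ff_mix_freq = (1 * 2 + 2 * 1) / 6
        assert bs.delta_index(ff_mix_freq, 0.0) == pytest.approx(2 / 3)


class TestFilter:
    def test_both_bulk_low_index_dropped(self):
        counts = make_counts(
            [
                ("c1", 100, "A", "T", 17, 3, 18, 2),  # 0.15 / 0.10 -> dropped
                ("c1", 200, "A", "T", 4, 8, 99, 1),  # 0.67 / 0.01 -> kept
                ("c1", 300, "A", "T", 10, 10, 0, 0),  # hb uncovered -> dropped
            ]
        )
        kept = bs.filter_snps(counts, bs.ScanConfig())
        assert list(kept["pos"]) == [200]

    def test_either_mode_drops_one_sided_low(self):
        counts = make_counts([("c1", 200, "A", "T", 4, 8, 99, 1)])
        kept = bs.filter_snps(counts, bs.ScanConfig(filter_mode="either"))
        assert kept.empty

    def test_min_depth_applies_per_bulk(self):
        counts = make_counts([("c1", 100, "A", "T", 30, 30, 2, 2)])
        assert bs.filter_snps(counts, bs.ScanConfig(min_depth=5)).empty
        assert len(bs.filter_snps(counts, bs.ScanConfig(min_depth=2))) == 1

    def test_order_preserved(self):
        counts = make_counts(
            [("c1", p, "A", "T", 5, 7, 6, 6) for p in (500, 100, 900)]
        )
        kept = bs.filter_snps(counts, bs.ScanConfig())
        assert list(kept["pos"]) == [500, 100, 900]


class TestSwapReference:
    def test_index_complement_and_involution(self):
        counts = make_counts(
            [("c1", 100, "A", "T", 7, 3, 2, 8), ("c1", 200, "G", "C", 1, 9, 5, 5)]
        )
        idx = bs.compute_snp_indices(counts)
        swapped = bs.compute_snp_indices(bs.swap_reference(counts))
        assert np.allclose(idx["sb_index"] + swapped["sb_index"], 1.0)
        assert np.allclose(idx["hb_index"] + swapped["hb_index"], 1.0)
        back = bs.swap_reference(bs.swap_reference(counts))
        pd.testing.assert_frame_equal(back, counts)

    def test_filter_asymmetry_after_swap(self):
        # one SNP is dropped in exactly one orientation: indices 0.85/0.9
        # pass the both-<0.2 filter, the complement 0.15/0.1 does not
        counts = make_counts([("c1", 100, "A", "T", 3, 17, 1, 9)])
        assert len(bs.filter_snps(counts)) == 1
        assert bs.filter_snps(bs.swap_reference(counts)).empty


class TestSlidingWindows:
    def test_simple_window_mean(self):
        counts = make_counts(
            [
                ("c1", 1_000, "A", "T", 8, 2, 4, 8),
                ("c1", 2_000, "A", "T", 6, 4, 2, 10),
                ("c1", 3_000, "A", "T", 4, 6, 6, 6),
            ]
        )
        track = bs.sliding_windows(
            counts, {"c1": 10_000}, bs.ScanConfig(window=10_000, step=10_000)
        )
        w = track.iloc[0]
        assert w["n_snps"] == 3
        assert w["sb_index"] == pytest.approx((0.2 + 0.4 + 0.6) / 3)

    def test_grid_membership_of_single_snp(self):
        # a SNP at 2,050,000 with a 2 Mb window on a 50 kb grid belongs to
        # windows starting 50,001 .. 2,000,001 (brute-force enumeration)
        cfg = bs.ScanConfig(window=2_000_000, step=50_000, min_snps=1)
        counts = make_counts([("c1", 2_050_000, "A", "T", 5, 5, 5, 5)])
        track = bs.sliding_windows(counts, {"c1": 5_000_000}, cfg)
        hit = track[track["n_snps"] == 1]
        starts = set()
        s = 1
        while s <= 5_000_000:
            if s <= 2_050_000 < s + cfg.window:
                starts.add(s)
            s += cfg.step
        assert set(hit["start"]) == starts
        assert hit["start"].min() == 50_001 and hit["start"].max() == 2_000_001

    def test_windows_below_min_snps_flagged_missing(self):
        counts = make_counts([("c1", 100, "A", "T", 5, 5, 5, 5)])
        track = bs.sliding_windows(
            counts, {"c1": 1_000}, bs.ScanConfig(window=1_000, step=1_000, min_snps=3)
        )
        assert track.iloc[0]["n_snps"] == 1
        assert np.isnan(track.iloc[0]["delta"])

    def test_unsorted_input_rejected(self):
        counts = make_counts(
            [("c1", 500, "A", "T", 5, 5, 5, 5), ("c1", 100, "A", "T", 5, 5, 5, 5)]
        )
        with pytest.raises(ValueError, match="sorted"):
            bs.sliding_windows(
                counts, {"c1": 1_000}, bs.ScanConfig(window=1_000, step=1_000), prefiltered=True
            )

    @given(
        data=st.lists(
            st.tuples(
                st.integers(1, 9_999),  # position
                st.integers(0, 20),
                st.integers(0, 20),
                st.integers(0, 20),
                st.integers(0, 20),
            ),
            min_size=1,
            max_size=40,
            unique_by=lambda t: t[0],
        ),
        window=st.integers(500, 5_000),
    )
    def test_window_means_match_brute_force(self, data, window):
        data = sorted(data)
        counts = make_counts(
            [("c1", p, "A", "T", a, b, c, d) for p, a, b, c, d in data]
        )
        cfg = bs.ScanConfig(window=window, step=max(window // 3, 1), min_snps=1)
        retained = bs.filter_snps(counts, cfg)
        track = bs.sliding_windows(counts, {"c1": 10_000}, cfg)
        expected = oracles.brute_force_windows(
            10_000,
            cfg.window,
            cfg.step,
            retained["pos"].tolist(),
            retained["delta"].tolist(),
            cfg.min_snps,
        )
        assert len(track) == len(expected)
        for (_, row), (start, n, mean) in zip(track.iterrows(), expected):
            assert row["start"] == start
            assert row["n_snps"] == n
            if np.isnan(mean):
                assert np.isnan(row["delta"])
            else:
                assert row["delta"] == pytest.approx(mean, abs=1e-12)

    def test_row_order_invariance_after_sorting(self, mini_genome):
        study = bs.simulate_study(genome=mini_genome, seed=40)
        counts = study.counts
        shuffled = counts.sample(frac=1.0, random_state=0)
        shuffled = shuffled.sort_values(["chrom", "pos"]).reset_index(drop=True)
        a = bs.sliding_windows(counts, mini_genome)
        b = bs.sliding_windows(shuffled, mini_genome)
        pd.testing.assert_frame_equal(a, b)

    def test_window_mean_between_extremes(self, mini_genome):
        study = bs.simulate_study(genome=mini_genome, seed=41)
        idx = bs.filter_snps(study.counts)
        track = bs.sliding_windows(study.counts, mini_genome)
        ok = track.dropna(subset=["delta"])
        assert ok["delta"].between(-1, 1).all()


class TestAverageDepth:
    @pytest.mark.parametrize(
        "n,l,g,expected",
        [(100, 90, 9_000, 1.0), (2, 50, 100, 1.0), (22e6, 90, 7.8e8, 2.5384615)],
    )
    def test_fold_coverage(self, n, l, g, expected):
        assert bs.average_depth(n, l, g) == pytest.approx(expected)

    def test_zero_genome_rejected(self):
        with pytest.raises(ValueError):
            bs.average_depth(10, 10, 0)
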