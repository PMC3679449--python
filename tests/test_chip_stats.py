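"""ChIP fold enrichment, tracks, peak calling, ratio regression, count assays."""

import math

import numpy as np
import pandas as pd
import pytest

from centrorep.chip_stats import (
    MeasurementError,
    enrichment_track,
    find_peaks,
    fold_enrichment,
    loss_rate,
    peak_ratio_regression,
    two_dot_fraction,
)
from centrorep.genome import GenomeLayout, ParameterError
from centrorep.synthetic_data import chip_expected_enrichment
from centrorep.tracks import EnrichmentTrack, ReadCounts


def qpcr_panel(rows):
    return pd.DataFrame(rows, columns=["locus", "condition", "ip", "wce"])


class TestFoldEnrichment:
    def test_reference_control_is_exactly_one(self):
        panel = qpcr_panel([
            ("CEN6", "WT", 0.20, 1.0),
            ("CEN6", "mut", 0.10, 1.0),
            ("PHO4", "WT", 0.05, 1.0),
            ("PHO4", "mut", 0.05, 1.0),
        ])
        out = fold_enrichment(panel, control_locus="PHO4", reference_condition="WT")
        ref = out[(out.locus == "PHO4") & (out.condition == "WT")]
        assert ref["fold"].iloc[0] == 1.0

    def test_fourfold_arithmetic(self):
        panel = qpcr_panel([("CEN6", "WT", 0.20, 1.0), ("ctrl", "WT", 0.05, 1.0)])
        out = fold_enrichment(panel, "ctrl", "WT")
        assert out[out.locus == "CEN6"]["fold"].iloc[0] == pytest.approx(4.0)

    def test_uniform_panel_all_ones(self):
        panel = qpcr_panel(
            [(f"L{i}", c, 0.4, 2.0) for i in range(4) for c in ("WT", "mut")]
        )
        out = fold_enrichment(panel, "L0", "WT")
        assert np.allclose(out["fold"], 1.0)

    def test_zero_wce_rejected(self):
        panel = qpcr_panel([("CEN6", "WT", 0.2, 0.0), ("ctrl", "WT", 0.05, 1.0)])
        with pytest.raises(MeasurementError):
            fold_enrichment(panel, "ctrl", "WT")

    def test_missing_reference_rejected(self):
        panel = qpcr_panel([("CEN6", "WT", 0.2, 1.0)])
        with pytest.raises(ParameterError):
            fold_enrichment(panel, "ctrl", "WT")


class TestEnrichmentTrack:
    def test_ip_equal_input_gives_unit_ratio(self):
        ip = ReadCounts(1000, {"chr1": np.full(200, 40, dtype=np.int64)})
        inp = ReadCounts(1000, {"chr1": np.full(200, 40, dtype=np.int64)})
        assert np.allclose(enrichment_track(ip, inp).data["chr1"], 1.0)

    def test_single_peak_apex_ratio_equals_one_plus_amplitude(self, single_chrom_layout):
        # noise-free integer counts straight from the generator expectation
        e = chip_expected_enrichment(single_chrom_layout, [("chr1", 200_000)], amplitude=5.0)
        depth = 1000
        ip = ReadCounts(1000, {"chr1": (depth * e["chr1"]).round().astype(np.int64)})
        inp = ReadCounts(1000, {"chr1": np.full(400, depth, dtype=np.int64)})
        track = enrichment_track(ip, inp)
        apex = track.data["chr1"][200]
        background = np.nanmedian(track.data["chr1"])
        assert apex / background == pytest.approx(6.0, rel=0.01)

    def test_low_input_bins_missing(self):
        ip = ReadCounts(1000, {"chr1": np.full(100, 40, dtype=np.int64)})
        vals = np.full(100, 40, dtype=np.int64)
        vals[7] = 3
        inp = ReadCounts(1000, {"chr1": vals})
        track = enrichment_track(ip, inp, min_input=10)
        assert np.isnan(track.data["chr1"][7])


class TestFindPeaks:
    def layout(self, n=400_000):
        return GenomeLayout((("chr1", n),), {"chr1": n // 2})

    def track(self, vals):
        return EnrichmentTrack(1000, {"chr1": np.asarray(vals, dtype=float)})

    def test_flat_track_has_no_peaks(self):
        peaks = find_peaks(self.track(np.ones(100)), self.layout(100_000), threshold=1.5)
        assert len(peaks) == 0

    def test_single_bump_called_at_apex(self):
        vals = np.ones(100)
        vals[48:53] = [2, 3, 5, 3, 2]
        peaks = find_peaks(self.track(vals), self.layout(100_000), threshold=1.5)
        assert list(peaks.table["pos"]) == [50_000]
        assert peaks.table["height"].iloc[0] == 5.0
        assert peaks.table["cen_dist_kb"].iloc[0] == pytest.approx(0.0)

    def test_close_maxima_keep_only_higher(self):
        # 500-bp bins: maxima at 50.0 and 51.0 kb are 1 kb apart
        vals = np.ones(200)
        vals[100], vals[101], vals[102] = 4.0, 1.2, 5.0
        track = EnrichmentTrack(500, {"chr1": vals})
        # brute force: both are strict local maxima over threshold
        strict = [i for i in range(1, 199) if vals[i] > vals[i - 1] and vals[i] > vals[i + 1]]
        assert [i for i in strict if vals[i] >= 1.5] == [100, 102]
        peaks = find_peaks(track, self.layout(100_000), threshold=1.5, min_separation_kb=2.0)
        assert list(peaks.table["pos"]) == [51_000]

    def test_equal_close_maxima_keep_leftmost(self):
        vals = np.ones(100)
        vals[50], vals[51], vals[52] = 5.0, 2.0, 5.0  # equal maxima 2 kb apart
        peaks = find_peaks(
            self.track(vals), self.layout(100_000), threshold=1.5, min_separation_kb=3.0
        )
        assert list(peaks.table["pos"]) == [50_000]

    def test_default_threshold_from_median(self):
        vals = np.ones(200)
        vals[100] = 1.4  # below 1.5 x median
        vals[150] = 2.0
        peaks = find_peaks(self.track(vals), self.layout(200_000))
        assert list(peaks.table["pos"]) == [150_000]


class TestPeakRatioRegression:
    def make_tracks(self, amplitude, rho, lam_c):
        layout = GenomeLayout((("chr1", 400_000),), {"chr1": 200_000})
        peak_pos = [("chr1", 200_000 + off) for off in range(0, 150_000, 3000)]
        wt = EnrichmentTrack(1000, chip_expected_enrichment(layout, peak_pos, amplitude))
        mut = EnrichmentTrack(
            1000,
            chip_expected_enrichment(layout, peak_pos, amplitude, (rho, lam_c)),
        )
        return layout, wt, mut

    def test_identical_tracks_fit_flat(self):
        layout, wt, _ = self.make_tracks(5.0, 0.5, 8.0)
        peaks = find_peaks(wt, layout)
        table, fit = peak_ratio_regression(peaks, wt, wt)
        assert np.allclose(table["ratio"], 1.0)
        assert abs(fit.a) < 1e-6

    def test_decay_length_recovered_within_twenty_percent(self):
        # moderate peaks keep the ratio statistic near-exponential in distance
        layout, wt, mut = self.make_tracks(1.0, 0.5, 8.0)
        peaks = find_peaks(wt, layout)
        _, fit = peak_ratio_regression(peaks, wt, mut)
        assert abs(fit.lam - 8.0) / 8.0 <= 0.2

    def test_arm_peaks_unreduced(self):
        layout, wt, mut = self.make_tracks(5.0, 0.5, 8.0)
        peaks = find_peaks(wt, layout)
        table, _ = peak_ratio_regression(peaks, wt, mut)
        arm = table[table["cen_dist_kb"] > 80.0]
        assert np.allclose(arm["ratio"], 1.0, atol=0.01)

    def test_apex_missing_in_b_dropped(self):
        layout, wt, mut = self.make_tracks(5.0, 0.5, 8.0)
        peaks = find_peaks(wt, layout)
        first = peaks.table.iloc[0]
        mut.data[first.chrom][mut.bin_index(first.pos)] = np.nan
        table, _ = peak_ratio_regression(peaks, wt, mut)
        assert len(table) == len(peaks) - 1


# --- exact-count statistics ------------------------------------------------


def fisher_two_sided_oracle(a, b, c, d):
    """Two-sided Fisher exact p by full hypergeometric enumeration."""
    row1, col1, n = a + b, a + c, a + b + c + d

    def pmf(k):
        return (
            math.comb(col1, k)
            * math.comb(n - col1, row1 - k)
            / math.comb(n, row1)
        )

    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    p_obs = pmf(a)
    return sum(pmf(k) for k in range(lo, hi + 1) if pmf(k) <= p_obs * (1 + 1e-9))


class TestTwoDotFraction:
    def counts(self, rows):
        return pd.DataFrame(rows, columns=["condition", "two_dot", "total"])

    def test_zero_events_zero_proportion_with_zero_lower_bound(self):
        summary, _ = two_dot_fraction(self.counts([("WT", 0, 300)]))
        assert summary["proportion"].iloc[0] == 0.0
        assert summary["ci_low"].iloc[0] == 0.0

    def test_simple_percentage(self):
        summary, _ = two_dot_fraction(self.counts([("mut", 75, 300)]))
        assert summary["proportion"].iloc[0] == pytest.approx(0.25)
        lo, hi = summary["ci_low"].iloc[0], summary["ci_high"].iloc[0]
        assert lo < 0.25 < hi

    def test_fisher_matches_enumeration_oracle(self):
        summary, pairs = two_dot_fraction(
            self.counts([("WT", 30, 300), ("mut", 60, 300)])
        )
        expected = fisher_two_sided_oracle(30, 270, 60, 240)
        assert pairs["p_fisher"].iloc[0] == pytest.approx(expected, rel=1e-9)

    def test_zero_total_rejected(self):
        with pytest.raises(ParameterError):
            two_dot_fraction(self.counts([("WT", 0, 0)]))


class TestLossRate:
    def counts(self, rows):
        return pd.DataFrame(rows, columns=["strain", "sectored", "total"])

    def test_zero_and_simple_rates(self):
        summary, _, _ = loss_rate(self.counts([("WT", 0, 500), ("mut", 6, 1000)]))
        assert summary.set_index("strain")["rate"]["WT"] == 0.0
        assert summary.set_index("strain")["rate"]["mut"] == pytest.approx(0.006)

    def test_fisher_matches_enumeration_oracle(self):
        _, pairs, _ = loss_rate(self.counts([("WT", 6, 1000), ("mut", 30, 1000)]))
        expected = fisher_two_sided_oracle(6, 994, 30, 970)
        assert pairs["p_fisher"].iloc[0] == pytest.approx(expected, rel=1e-9)

    def test_synergy_flagged_on_super_additive_double(self):
        rows = [("WT", 2, 1000), ("A", 10, 1000), ("B", 6, 1000), ("AB", 40, 1000)]
        _, _, syn = loss_rate(self.counts(rows), "WT", "A", "B", "AB")
        assert syn["synergistic"] is True
        assert syn["additive_expectation"] == pytest.approx(0.012)

    def test_additive_double_not_flagged(self):
        rows = [("WT", 2, 1000), ("A", 10, 1000), ("B", 6, 1000), ("AB", 14, 1000)]
        _, _, syn = loss_rate(self.counts(rows), "WT", "A", "B", "AB")
        assert syn["synergistic"] is False
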