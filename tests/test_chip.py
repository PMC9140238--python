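"""Coverage normalisation, telomere/core partition, peak calling, assignment."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from histolife import (
    CoverageTrack,
    call_peaks,
    compare_groups,
    enrichment_ratio,
    normalize_pair,
    partition_telomere_core,
    peaks_to_genes,
    read_bedgraph,
    write_bedgraph,
    write_wiggle,
)


def track(data, bin_size=50, lengths=None):
    return CoverageTrack(
        data={c: np.asarray(v, dtype=float) for c, v in data.items()},
        bin_size=bin_size,
        lengths=lengths or {},
    )


class TestNormalizePair:
    def test_already_at_target_unchanged(self):
        a = track({"c1": np.full(20, 5.0)})  # sum 100
        b = track({"c1": np.full(20, 5.0)})
        an, bn = normalize_pair(a, b, target_sum=100.0)
        np.testing.assert_allclose(an.data["c1"], a.data["c1"], rtol=1e-12)
        np.testing.assert_allclose(bn.data["c1"], b.data["c1"], rtol=1e-12)

    def test_double_total_halves_scale(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(1, 5, 40)
        ip, inp = track({"c1": 2 * base}), track({"c1": base})
        ip_n, in_n = normalize_pair(ip, inp, target_sum=1e6)
        assert ip_n.total() == pytest.approx(1e6, rel=1e-12)
        assert in_n.total() == pytest.approx(1e6, rel=1e-12)
        # the IP scale factor is half the input's (sums recomputed directly)
        assert (ip_n.data["c1"] / ip.data["c1"])[0] == pytest.approx(
            (in_n.data["c1"] / inp.data["c1"])[0] / 2
        )

    def test_preserves_pairwise_bin_ratios(self):
        rng = np.random.default_rng(3)
        v = rng.uniform(0.5, 9, 30)
        a, _ = normalize_pair(track({"c1": v}), track({"c1": v * 3}), 1e6)
        np.testing.assert_allclose(
            a.data["c1"][1:] / a.data["c1"][:-1], v[1:] / v[:-1], rtol=1e-12
        )

    def test_zero_track_rejected(self):
        with pytest.raises(ValueError):
            normalize_pair(track({"c1": np.zeros(5)}), track({"c1": np.ones(5)}), 1e6)


class TestEnrichmentRatio:
    def test_identical_tracks_give_unity(self):
        v = np.arange(1.0, 11.0)
        r = enrichment_ratio(track({"c1": v}), track({"c1": v}), pseudo=0.0)
        np.testing.assert_allclose(r.data["c1"], 1.0)

    def test_planted_window_recovered(self):
        inp = np.ones(100)
        ip = np.ones(100)
        ip[40:60] = 3.0
        r = enrichment_ratio(track({"c1": ip}), track({"c1": inp}), pseudo=0.0)
        np.testing.assert_allclose(r.data["c1"][40:60], 3.0)
        np.testing.assert_allclose(r.data["c1"][:40], 1.0)

    def test_pseudocount_keeps_ratio_finite(self):
        r = enrichment_ratio(track({"c1": np.ones(4)}), track({"c1": np.zeros(4)}),
                             pseudo=0.5)
        assert np.all(np.isfinite(r.data["c1"]))


class TestPartition:
    def test_uniform_track_is_unity_everywhere(self):
        t = track({f"c{i}": np.full(2000, 7.0) for i in range(3)})  # 100 kb each
        part = partition_telomere_core(t, telomere_window=20_000)
        np.testing.assert_allclose(part["tel"], 1.0, atol=1e-12)
        np.testing.assert_allclose(part["core"], 1.0, atol=1e-12)

    def test_hand_computed_terminal_enrichment(self):
        # 100 kb chromosome, signal 2 in both 20 kb ends, 1 in the middle:
        # genome mean 1.4 -> tel 2/1.4, core 1/1.4
        v = np.ones(2000)
        v[:400] = 2.0
        v[-400:] = 2.0
        part = partition_telomere_core(track({"c1": v}), telomere_window=20_000)
        assert part.loc[0, "tel"] == pytest.approx(2 / 1.4)
        assert part.loc[0, "core"] == pytest.approx(1 / 1.4)

    def test_short_chromosome_has_no_core(self):
        t = track({"c1": np.full(600, 1.0), "c2": np.full(2000, 1.0)})  # 30kb, 100kb
        with pytest.warns(UserWarning, match="no core region"):
            part = partition_telomere_core(t, telomere_window=20_000)
        row = part[part["chrom"] == "c1"].iloc[0]
        assert not row["has_core"] and math.isnan(row["core"])

    def test_weighted_mean_identity(self):
        # (tel*tel_bp + core*core_bp) summed over chromosomes equals genome bp
        rng = np.random.default_rng(8)
        lengths = [120_000, 250_000, 90_000]
        t = track(
            {f"c{i}": rng.uniform(0.1, 4.0, l // 50) for i, l in enumerate(lengths)},
            lengths={f"c{i}": l for i, l in enumerate(lengths)},
        )
        w = 20_000
        part = partition_telomere_core(t, telomere_window=w)
        acc = 0.0
        for _, row in part.iterrows():
            l = lengths[int(row["chrom"][1])]
            acc += row["tel"] * 2 * w + row["core"] * (l - 2 * w)
        assert acc / sum(lengths) == pytest.approx(1.0, abs=1e-9)

    def test_partial_bin_weighting(self):
        # 100,025 bp chromosome: last bin covers 25 bp and must weigh half a bin
        v = np.full(2001, 3.0)
        t = track({"c1": v}, lengths={"c1": 100_025})
        part = partition_telomere_core(t, telomere_window=20_000)
        assert part.loc[0, "tel"] == pytest.approx(1.0, abs=1e-12)


class TestCompareGroups:
    def test_identical_groups(self):
        res = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == pytest.approx(0.0) and res.p == pytest.approx(1.0)
        assert not res.significant

    def test_matches_hand_welch_formula(self):
        a, b = [1.0, 2.0, 3.0, 4.0], [2.0, 3.0, 4.0, 5.0]
        # sample variances 5/3 each; se = sqrt(2*(5/3)/4); Welch df = 6
        se = math.sqrt(2 * (5 / 3) / 4)
        t_hand = (2.5 - 3.5) / se
        df = 6.0
        p_hand = 2 * stats.t.sf(abs(t_hand), df)
        res = compare_groups(a, b)
        assert res.t == pytest.approx(t_hand, rel=1e-12)
        assert res.p == pytest.approx(p_hand, rel=1e-12)

    def test_strong_separation(self):
        rng = np.random.default_rng(5)
        a = rng.normal(1, 0.1, 16)
        b = rng.normal(10, 0.1, 16)
        res = compare_groups(a, b)
        assert res.p < 1e-6 and res.significant

    def test_degenerate_equal_constant_groups(self):
        res = compare_groups([2.0, 2.0], [2.0, 2.0])
        assert res.t == 0.0 and res.p == 1.0


class TestCallPeaks:
    def test_flat_track_yields_no_peaks(self):
        assert call_peaks(track({"c1": np.ones(100)}), threshold=2.0).empty

    def test_planted_region_recovered_within_one_bin(self):
        v = np.ones(2000)
        v[400:440] = 3.0  # 2 kb region at 20,000-22,000
        peaks = call_peaks(track({"c1": v}), threshold=2.0, min_len=500)
        assert len(peaks) == 1
        assert abs(peaks.loc[0, "start"] - 20_000) <= 50
        assert abs(peaks.loc[0, "end"] - 22_000) <= 50
        assert peaks.loc[0, "max_ratio"] == 3.0

    def test_merge_gap_rule(self):
        v = np.ones(1000)
        v[100:110] = 3.0
        v[114:124] = 3.0  # 200 bp gap
        two = call_peaks(track({"c1": v}), threshold=2.0, merge_gap=100)
        one = call_peaks(track({"c1": v}), threshold=2.0, merge_gap=200)
        assert len(two) == 2 and len(one) == 1

    def test_min_len_filter(self):
        v = np.ones(1000)
        v[100:102] = 3.0
        assert call_peaks(track({"c1": v}), threshold=2.0, min_len=500).empty

    def test_masking_called_peaks_leaves_nothing_to_call(self):
        # the caller is exhaustive: blank out every called peak and no signal
        # above threshold remains
        rng = np.random.default_rng(9)
        v = 1.0 + rng.exponential(0.6, 3000)
        v[500:550] = 5.0
        first = call_peaks(track({"c1": v}), threshold=3.0, merge_gap=100)
        assert len(first) >= 1
        masked = v.copy()
        for _, pk in first.iterrows():
            masked[pk["start"] // 50 : pk["end"] // 50] = 1.0
        assert call_peaks(track({"c1": masked}), threshold=3.0, merge_gap=100).empty


class TestPeaksToGenes:
    def genes(self):
        return pd.DataFrame(
            [
                {"chrom": "c1", "start": 10_000, "end": 12_000, "name": "gP",
                 "score": 0, "strand": "+"},
                {"chrom": "c1", "start": 30_000, "end": 32_000, "name": "gM",
                 "score": 0, "strand": "-"},
            ]
        )

    def peak(self, start, end):
        return pd.DataFrame(
            [{"chrom": "c1", "start": start, "end": end, "mean_ratio": 2.0,
              "max_ratio": 2.0}]
        )

    def test_peak_inside_gene_body(self):
        out = peaks_to_genes(self.peak(10_500, 10_600), self.genes())
        assert list(out["gene"]) == ["gP"]

    def test_upstream_boundary_exhaustive(self):
        # + strand: search window starts at 10_000-500 = 9_500 (half-open)
        for end, hit in [(9_500, False), (9_501, True)]:
            out = peaks_to_genes(self.peak(9_000, end), self.genes(), upstream=500)
            assert ("gP" in set(out["gene"])) is hit, (end, hit)
        # - strand mirror: window extends to 32_000+500 = 32_500
        for start, hit in [(32_500, False), (32_499, True)]:
            out = peaks_to_genes(self.peak(start, 33_000), self.genes(), upstream=500)
            assert ("gM" in set(out["gene"])) is hit, (start, hit)

    def test_brute_force_random_instances(self):
        rng = np.random.default_rng(42)
        genes = self.genes()
        for _ in range(200):
            s = int(rng.integers(0, 40_000))
            e = s + int(rng.integers(1, 5_000))
            out = set(peaks_to_genes(self.peak(s, e), genes)["gene"])
            expected = set()
            for _, g in genes.iterrows():
                lo = g["start"] - 500 if g["strand"] == "+" else g["start"]
                hi = g["end"] if g["strand"] == "+" else g["end"] + 500
                if s < hi and lo < e:
                    expected.add(g["name"])
            assert out == expected

    def test_empty_peakset(self):
        empty = pd.DataFrame(columns=["chrom", "start", "end", "mean_ratio", "max_ratio"])
        assert peaks_to_genes(empty, self.genes()).empty


class TestRoundTrip:
    def test_bedgraph_round_trip_bit_exact(self, tmp_path):
        rng = np.random.default_rng(12)
        t = track({"c1": np.round(rng.uniform(0, 9, 40), 3),
                   "c2": np.round(rng.uniform(0, 9, 25), 3)})
        path = tmp_path / "t.bedgraph"
        write_bedgraph(t, path)
        back = read_bedgraph(path, bin_size=50, lengths=t.lengths)
        for c in t.data:
            np.testing.assert_allclose(back.data[c], t.data[c], rtol=1e-9)

    def test_wiggle_fixedstep_one_based(self, tmp_path):
        t = track({"c1": np.array([1.0, 2.0])})
        path = tmp_path / "t.wig"
        write_wiggle(t, path)
        lines = path.read_text().splitlines()
        assert lines[1] == "fixedStep chrom=c1 start=1 step=50 span=50"
        assert lines[2:] == ["1", "2"]
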