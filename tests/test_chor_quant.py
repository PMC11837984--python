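import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scarchor.chor_quant import (
    SpikeCounts,
    consensus_peaks,
    efficiency_change,
    global_spike_ratio,
    quantify_peak_windows,
    rrpm_track,
    spike_scale_factor,
)
from scarchor.genomic_io import GenomeLayout, IntervalSet, make_read_frame


def intervals(rows):
    return IntervalSet(pd.DataFrame(rows, columns=["chrom", "start", "end"]))


class TestSpikeScaling:
    def test_identical_composition_gives_unit_alpha(self):
        c = SpikeCounts(1_000_000, 1000, 1_000_000, 1000)
        assert spike_scale_factor(c) == pytest.approx(1.0)
        assert global_spike_ratio(c) == pytest.approx(1.0)

    def test_doubled_ip_spike_fraction_halves_alpha(self):
        # IP spike fraction 0.002 vs input 0.001
        c = SpikeCounts(998_000, 2000, 999_000, 1000)
        assert spike_scale_factor(c) == pytest.approx(0.5, rel=1e-3)
        assert global_spike_ratio(c) == pytest.approx(0.5, rel=2e-3)

    def test_zero_spike_reads_is_error(self):
        with pytest.raises(ValueError, match="spike"):
            spike_scale_factor(SpikeCounts(100, 0, 100, 10))

    def test_rrpm_invariant_to_spike_preserving_input_depth(self):
        """Adding input reads at the same spike fraction leaves alpha
        unchanged."""
        c1 = SpikeCounts(1_000_000, 5000, 500_000, 250)
        c2 = SpikeCounts(1_000_000, 5000, 2_000_000, 1000)
        assert spike_scale_factor(c1) == pytest.approx(spike_scale_factor(c2))


class TestRrpmTrack:
    @pytest.fixture
    def layout(self):
        return GenomeLayout({"chr1": 10_000})

    def test_rpm_times_alpha(self, layout):
        reads = make_read_frame(["chr1"] * 10, [1100] * 10, [1200] * 10,
                                ["+"] * 10, ["target"] * 10)
        counts = SpikeCounts(1_000_000, 1000, 1_000_000, 1000)  # alpha = 1
        track = rrpm_track(reads, layout, counts, bin_width=1000)
        assert track.data["chr1"][1] == pytest.approx(10.0)
        counts2 = SpikeCounts(1_000_000, 1000, 799_360, 1000)  # alpha ~ 0.8
        track2 = rrpm_track(reads, layout, counts2, bin_width=1000)
        assert track2.data["chr1"][1] == pytest.approx(
            10.0 * track2.scale_factor
        )
        assert (track2.data["chr1"][2:] == 0).all()


def brute_force_consensus(replicates, merge_dist):
    """O(n^2) oracle: transitive gap-clustering of the pooled intervals,
    then all-replicate support filtering by pairwise overlap scans."""
    pooled = [
        (r.chrom, r.start, r.end, i)
        for i, rep in enumerate(replicates)
        for r in rep.df.itertuples(index=False)
    ]
    n = len(pooled)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            ci, si, ei, _ = pooled[i]
            cj, sj, ej, _ = pooled[j]
            if ci == cj and max(si, sj) - min(ei, ej) <= merge_dist:
                parent[find(i)] = find(j)
    clusters = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(pooled[i])
    out = []
    n_reps = len(replicates)
    for members in clusters.values():
        chrom = members[0][0]
        start = min(m[1] for m in members)
        end = max(m[2] for m in members)
        support = set()
        for rep_i, rep in enumerate(replicates):
            for r in rep.df.itertuples(index=False):
                if r.chrom == chrom and r.start < end and r.end > start:
                    support.add(rep_i)
        if len(support) == n_reps:
            out.append((chrom, start, end))
    return sorted(out)


class TestConsensusPeaks:
    def test_merge_within_distance_and_keep(self):
        a = intervals([("chr1", 0, 100)])
        b = intervals([("chr1", 550, 650)])
        cons = consensus_peaks([a, b], merge_dist=500)
        assert [(r.chrom, r.start, r.end) for r in cons.intervals] == [
            ("chr1", 0, 650)
        ]

    def test_unsupported_merged_intervals_dropped(self):
        a = intervals([("chr1", 0, 100)])
        b = intervals([("chr1", 700, 800)])
        cons = consensus_peaks([a, b], merge_dist=500)
        assert len(cons.intervals) == 0

    def test_single_replicate_degenerates_to_merge(self):
        a = intervals([("chr1", 0, 100), ("chr1", 150, 300)])
        cons = consensus_peaks([a], merge_dist=500)
        assert [(r.start, r.end) for r in cons.intervals] == [(0, 300)]

    def test_empty_replicate_warns_empty_consensus(self):
        with pytest.warns(UserWarning):
            cons = consensus_peaks([intervals([("chr1", 0, 10)]), IntervalSet()])
        assert len(cons.intervals) == 0

    @given(st.integers(0, 2**32 - 1), st.sampled_from([0, 1, 500]))
    @settings(max_examples=25, deadline=None)
    def test_matches_quadratic_oracle(self, seed, merge_dist):
        rng = np.random.default_rng(seed)
        n_reps = rng.integers(1, 5)
        reps = []
        for _ in range(n_reps):
            k = rng.integers(1, 40)
            start = rng.integers(0, 20_000, k)
            length = rng.integers(1, 800, k)
            chrom = rng.choice(["chr1", "chr2"], k)
            reps.append(intervals(list(zip(chrom, start, start + length))))
        cons = consensus_peaks(reps, merge_dist=merge_dist)
        got = sorted(
            (r.chrom, r.start, r.end) for r in cons.intervals
        )
        assert got == brute_force_consensus(reps, merge_dist)


class TestQuantifyPeakWindows:
    def test_overlap_rule_selects_bins(self):
        layout = GenomeLayout({"chr1": 10_000})
        from scarchor.chor_quant import QuantTrack

        track = QuantTrack(1000, {"chr1": np.arange(10, dtype=float)}, 1.0)
        sel = quantify_peak_windows(track, intervals([("chr1", 1500, 2500)]))
        assert list(sel.index.get_level_values("bin_start")) == [1000, 2000]
        assert list(sel.values) == [1.0, 2.0]

    def test_no_peaks_gives_empty_vector(self):
        from scarchor.chor_quant import QuantTrack

        track = QuantTrack(1000, {"chr1": np.ones(5)}, 1.0)
        assert len(quantify_peak_windows(track, IntervalSet())) == 0


class TestEfficiencyChange:
    def test_no_change(self):
        v = np.array([1.0, 2.0, 3.0])
        assert efficiency_change(v, v, "genome_wide") == pytest.approx(0.0)

    def test_uniform_twenty_percent_loss(self):
        v = np.array([1.0, 2.0, 3.0])
        assert efficiency_change(0.8 * v, v, "genome_wide") == pytest.approx(20.0)

    def test_zero_control_is_error(self):
        with pytest.raises(ValueError):
            efficiency_change(np.ones(3), np.zeros(3), "genome_wide")

    def test_mismatched_bin_universe_is_error(self):
        a = pd.Series([1.0], index=pd.MultiIndex.from_tuples(
            [("chr1", 0)], names=["chrom", "bin_start"]))
        b = pd.Series([1.0], index=pd.MultiIndex.from_tuples(
            [("chr1", 1000)], names=["chrom", "bin_start"]))
        with pytest.raises(ValueError, match="bin universe"):
            efficiency_change(a, b, "in_domain")
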