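"""Spike-in-calibrated quantification of nascent-chromatin occupancy.

ChOR-seq libraries carry a constant small proportion of exogenous
(Drosophila) spike-in chromatin. Scaling read-per-million (RPM) tracks by
the spike recovery of the IP relative to its matched input yields
reference-adjusted RPM (RRPM), which is comparable between conditions.
Occupancy is quantified over consensus peaks (merged peaks supported by
every replicate) in fixed 1-kb windows, and recycling-efficiency changes
between conditions are the percentage loss of summed RRPM signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genomic_io import FORWARD, GenomeLayout, IntervalSet, ReadTally


@dataclass(frozen=True)
class SpikeCounts:
    """Target/spike read tallies for an IP library and its matched input."""

    ip_target: int
    ip_spike: int
    input_target: int
    input_spike: int

    @classmethod
    def from_tallies(cls, ip: ReadTally, inp: ReadTally) -> "SpikeCounts":
        return cls(ip.target, ip.spike, inp.target, inp.spike)


@dataclass
class QuantTrack:
    """Per-chromosome RRPM arrays in fixed bins."""

    bin_width: int
    data: dict[str, np.ndarray]
    scale_factor: float

    def total(self) -> float:
        return float(sum(a.sum() for a in self.data.values()))

    def to_series(self) -> pd.Series:
        """All bins as a Series indexed by (chrom, bin_start)."""
        frames = []
        for chrom in sorted(self.data):
            arr = self.data[chrom]
            idx = pd.MultiIndex.from_arrays(
                [np.repeat(chrom, len(arr)),
                 np.arange(len(arr), dtype=np.int64) * self.bin_width],
                names=["chrom", "bin_start"],
            )
            frames.append(pd.Series(arr, index=idx))
        return pd.concat(frames)


@dataclass
class ConsensusPeakSet:
    """Merged peaks supported by at least one peak from every replicate."""

    intervals: IntervalSet
    n_replicates: int
    merge_dist: int


def spike_scale_factor(counts: SpikeCounts) -> float:
    """RRPM scale factor alpha = input spike fraction / IP spike fraction.

    Equals 1 when IP and input have identical spike composition; under a
    genome-wide loss of target signal in the IP, alpha drops in proportion,
    which is what makes RRPM tracks comparable between conditions.
    """
    if counts.ip_spike <= 0 or counts.input_spike <= 0:
        raise ValueError(
            "zero spike-in reads; sequence (or simulate) deeper to estimate alpha"
        )
    ip_frac = counts.ip_spike / (counts.ip_spike + counts.ip_target)
    input_frac = counts.input_spike / (counts.input_spike + counts.input_target)
    return input_frac / ip_frac


def global_spike_ratio(counts: SpikeCounts) -> float:
    """Target-per-spike reads in the IP, normalized to the input.

    The bar-plot statistic (ip_target/ip_spike)/(input_target/input_spike);
    proportional to total genome-wide RRPM mass.
    """
    if counts.ip_spike <= 0 or counts.input_spike <= 0 or counts.input_target <= 0:
        raise ValueError("zero denominator in spike ratio")
    return (counts.ip_target / counts.ip_spike) / (
        counts.input_target / counts.input_spike
    )


def rrpm_track(
    reads: pd.DataFrame,
    layout: GenomeLayout,
    counts: SpikeCounts,
    bin_width: int = 1000,
) -> QuantTrack:
    """Strand-blind per-bin RPM x alpha over the target genome.

    Reads are assigned to bins by fragment midpoint; RPM uses the IP's
    retained target-read total from ``counts``.
    """
    alpha = spike_scale_factor(counts)
    scale = alpha * 1e6 / counts.ip_target
    data = {
        chrom: np.zeros(layout.n_bins(chrom, bin_width))
        for chrom in layout.chrom_sizes
    }
    target = reads.loc[reads["origin"] == "target"]
    mid = (target["start"].to_numpy() + target["end"].to_numpy()) // 2
    bins = mid // bin_width
    chroms = target["chrom"].to_numpy()
    for chrom in np.unique(chroms):
        sel = chroms == chrom
        b = bins[sel]
        b = b[b < len(data[chrom])]
        np.add.at(data[chrom], b, scale)
    return QuantTrack(bin_width, data, alpha)


def consensus_peaks(
    replicate_peaks: list[IntervalSet], merge_dist: int = 500
) -> ConsensusPeakSet:
    """Concatenate, sort and merge replicate peaks; keep merged intervals
    overlapping (>=1 bp) at least one peak from every replicate."""
    if not replicate_peaks:
        raise ValueError("need at least one replicate peak set")
    if any(len(r) == 0 for r in replicate_peaks):
        warnings.warn("a replicate has no peaks; consensus is empty", stacklevel=2)
        return ConsensusPeakSet(IntervalSet(), len(replicate_peaks), merge_dist)
    pooled = IntervalSet(
        pd.concat([r.df for r in replicate_peaks], ignore_index=True)
    )
    merged = pooled.merged(merge_dist)
    keep = []
    for iv in merged.df.itertuples(index=False):
        supported = all(
            _overlaps_any(iv, rep) for rep in replicate_peaks
        )
        if supported:
            keep.append((iv.chrom, iv.start, iv.end))
    ivs = (
        IntervalSet(pd.DataFrame(keep, columns=["chrom", "start", "end"]))
        if keep
        else IntervalSet()
    )
    return ConsensusPeakSet(ivs, len(replicate_peaks), merge_dist)


def _overlaps_any(iv, peaks: IntervalSet) -> bool:
    df = peaks.df
    sub = df[df["chrom"] == iv.chrom]
    return bool(((sub["start"] < iv.end) & (sub["end"] > iv.start)).any())


def peak_window_index(
    peaks: IntervalSet, bin_width: int
) -> pd.MultiIndex:
    """(chrom, bin_start) index of every bin overlapping >=1 bp of a peak."""
    chroms, starts = [], []
    for iv in peaks.df.itertuples(index=False):
        first = iv.start // bin_width
        last = (iv.end - 1) // bin_width
        b = np.arange(first, last + 1, dtype=np.int64) * bin_width
        chroms.extend([iv.chrom] * len(b))
        starts.extend(b.tolist())
    idx = pd.MultiIndex.from_arrays(
        [chroms, np.asarray(starts, dtype=np.int64)], names=["chrom", "bin_start"]
    )
    return idx.drop_duplicates()


def quantify_peak_windows(
    track: QuantTrack, peaks: ConsensusPeakSet | IntervalSet
) -> pd.Series:
    """RRPM of every fixed-width bin overlapping any consensus peak.

    The bin set depends only on the peaks, never on the signal, so vectors
    from different conditions over the same peak set align bin-for-bin.
    """
    ivs = peaks.intervals if isinstance(peaks, ConsensusPeakSet) else peaks
    idx = peak_window_index(ivs, track.bin_width)
    values = np.zeros(len(idx))
    for i, (chrom, start) in enumerate(idx):
        arr = track.data.get(chrom)
        if arr is None:
            continue
        b = start // track.bin_width
        if 0 <= b < len(arr):
            values[i] = arr[b]
    return pd.Series(values, index=idx)


def efficiency_change(
    treated: pd.Series | np.ndarray,
    control: pd.Series | np.ndarray,
    scope: str = "in_domain",
) -> float:
    """Percent loss of summed RRPM signal, treated relative to control.

    Positive values mean loss. For ``scope='in_domain'`` the two vectors
    must cover the same bin universe (align them with
    :func:`quantify_peak_windows` over a shared peak set); for
    ``scope='genome_wide'`` pass full-genome bin vectors or totals.
    """
    if scope not in ("in_domain", "genome_wide"):
        raise ValueError("scope must be 'in_domain' or 'genome_wide'")
    if isinstance(treated, pd.Series) and isinstance(control, pd.Series):
        if scope == "in_domain" and not treated.index.equals(control.index):
            raise ValueError("treated and control cover different bin universes")
        t_sum, c_sum = float(treated.sum()), float(control.sum())
    else:
        t_sum = float(np.sum(treated))
        c_sum = float(np.sum(control))
    if c_sum == 0:
        raise ValueError("control signal sums to zero")
    return 100.0 * (1.0 - t_sum / c_sum)
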