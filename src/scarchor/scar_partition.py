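"""SCAR-seq partition statistic.

Strand-resolved nascent ChIP reads are counted in fixed-width genomic bins
(default 1 kb), normalized to counts per million (CPM), smoothed with a
uniform (moving-average) blur, corrected by subtracting the matched input
processed identically, filtered for low coverage, and reduced to the
partition score

    partition = (F - R) / (F + R)

per bin, where F and R are the normalized, input-corrected forward- and
reverse-strand signals. Partition is +1 when all nascent reads map to the
forward strand and -1 when all map to the reverse strand.

Stages are tracked explicitly and must advance in the fixed order
raw_counts -> cpm -> smoothed -> input_corrected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genomic_io import FORWARD, GenomeLayout

STAGES = ("raw_counts", "cpm", "smoothed", "input_corrected")


@dataclass
class StrandArrays:
    F: np.ndarray
    R: np.ndarray


@dataclass
class BinnedStrandTrack:
    """Per-chromosome forward/reverse signal in fixed-width bins."""

    bin_width: int
    data: dict[str, StrandArrays]
    stage: str
    library_size: int = 0

    def copy_with(self, data: dict[str, StrandArrays], stage: str) -> "BinnedStrandTrack":
        if STAGES.index(stage) != STAGES.index(self.stage) + 1:
            raise ValueError(f"illegal stage transition {self.stage} -> {stage}")
        return BinnedStrandTrack(self.bin_width, data, stage, self.library_size)


@dataclass
class PartitionArrays:
    partition: np.ndarray  # NaN where masked
    coverage: np.ndarray   # F + R
    valid: np.ndarray      # boolean


@dataclass
class PartitionTrack:
    """Per-bin partition score in [-1, 1] with a validity mask."""

    bin_width: int
    data: dict[str, PartitionArrays] = field(default_factory=dict)


def bin_stranded_reads(
    reads: pd.DataFrame, layout: GenomeLayout, bin_width: int = 1000
) -> BinnedStrandTrack:
    """Count target reads per strand in fixed bins by fragment midpoint.

    Each read increments exactly one bin on its strand's array: the bin
    containing floor((start+end)/2). Reads whose midpoint falls beyond the
    recorded chromosome length are dropped.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    data = {
        chrom: StrandArrays(
            np.zeros(layout.n_bins(chrom, bin_width)),
            np.zeros(layout.n_bins(chrom, bin_width)),
        )
        for chrom in layout.chrom_sizes
    }
    n_used = 0
    if len(reads):
        target = reads.loc[reads["origin"] == "target"]
        mid = (target["start"].to_numpy() + target["end"].to_numpy()) // 2
        bins = mid // bin_width
        fwd = (target["strand"] == FORWARD).to_numpy()
        chroms = target["chrom"].to_numpy()
        for chrom in np.unique(chroms):
            sel = chroms == chrom
            n = data[chrom].F.shape[0]
            for arr, mask in ((data[chrom].F, fwd), (data[chrom].R, ~fwd)):
                b = bins[sel & mask]
                b = b[b < n]
                np.add.at(arr, b, 1.0)
                n_used += len(b)
    return BinnedStrandTrack(bin_width, data, "raw_counts", library_size=n_used)


def cpm_normalize(track: BinnedStrandTrack, library_size: int) -> BinnedStrandTrack:
    """Scale both strand arrays to counts per million of the library.

    ``library_size`` is the library's total retained target reads (both
    strands combined); per-bin F:R ratios are unchanged.
    """
    if track.stage != "raw_counts":
        raise ValueError("cpm_normalize expects a raw_counts track")
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    scale = 1e6 / library_size
    data = {
        c: StrandArrays(a.F * scale, a.R * scale) for c, a in track.data.items()
    }
    out = track.copy_with(data, "cpm")
    out.library_size = library_size
    return out


def moving_average(x: np.ndarray, half_width: int) -> np.ndarray:
    """Truncated-window moving average over (2*half_width+1) bins.

    At array edges the window shrinks to the bins actually present and the
    mean is renormalized, so constant arrays are exact fixed points.
    """
    if half_width == 0:
        return x.astype(float).copy()
    kernel = np.ones(2 * half_width + 1)
    sums = np.convolve(x, kernel, mode="same")
    counts = np.convolve(np.ones_like(x, dtype=float), kernel, mode="same")
    return sums / counts


def uniform_blur(track: BinnedStrandTrack, half_width_bins: int = 30) -> BinnedStrandTrack:
    """Smooth each strand array with a uniform blur per chromosome."""
    if track.stage != "cpm":
        raise ValueError("uniform_blur expects a cpm track")
    if half_width_bins < 0:
        raise ValueError("half_width_bins must be >= 0")
    data = {
        c: StrandArrays(
            moving_average(a.F, half_width_bins),
            moving_average(a.R, half_width_bins),
        )
        for c, a in track.data.items()
    }
    return track.copy_with(data, "smoothed")


def input_correct_and_filter(
    ip: BinnedStrandTrack, input_track: BinnedStrandTrack, min_cpm: float = 0.3
) -> tuple[BinnedStrandTrack, dict[str, np.ndarray]]:
    """Subtract the matched input per strand, clip at zero, flag weak bins.

    The input must have been processed through the identical CPM and blur
    stages. A bin is masked iff both corrected strands fall below
    ``min_cpm``; masked bins are excluded from all downstream statistics.
    Returns the corrected track and a per-chromosome boolean mask that is
    True where the bin is KEPT.
    """
    if ip.stage != "smoothed" or input_track.stage != "smoothed":
        raise ValueError("both tracks must be at the smoothed stage")
    if ip.bin_width != input_track.bin_width or set(ip.data) != set(input_track.data):
        raise ValueError("IP and input tracks have mismatched binning")
    data, keep = {}, {}
    for chrom, arrs in ip.data.items():
        inp = input_track.data[chrom]
        if arrs.F.shape != inp.F.shape:
            raise ValueError(f"bin count mismatch on {chrom}")
        F = np.maximum(arrs.F - inp.F, 0.0)
        R = np.maximum(arrs.R - inp.R, 0.0)
        data[chrom] = StrandArrays(F, R)
        keep[chrom] = ~((F < min_cpm) & (R < min_cpm))
    return ip.copy_with(data, "input_corrected"), keep


def compute_partition(
    track: BinnedStrandTrack,
    keep: dict[str, np.ndarray] | None = None,
    flip: bool = False,
) -> PartitionTrack:
    """Per-bin partition (F-R)/(F+R) with validity mask.

    ``flip`` multiplies the score by -1 for libraries whose sequenced strand
    is the complement of the nascent strand (xGen UMI-adapter chemistry).
    Bins with zero total coverage are masked regardless of ``keep``.
    """
    if track.stage != "input_corrected":
        raise ValueError("compute_partition expects an input_corrected track")
    sign = -1.0 if flip else 1.0
    out = PartitionTrack(track.bin_width)
    for chrom, arrs in track.data.items():
        cov = arrs.F + arrs.R
        valid = cov > 0
        if keep is not None:
            valid = valid & keep[chrom]
        part = np.full(cov.shape, np.nan)
        with np.errstate(invalid="ignore", divide="ignore"):
            part[valid] = sign * (arrs.F[valid] - arrs.R[valid]) / cov[valid]
        out.data[chrom] = PartitionArrays(part, cov, valid)
    return out


def partition_pipeline(
    ip_reads: pd.DataFrame,
    input_reads: pd.DataFrame,
    layout: GenomeLayout,
    bin_width: int = 1000,
    blur_half_width: int = 30,
    min_cpm: float = 0.3,
    flip: bool = False,
) -> PartitionTrack:
    """Full stage pipeline: bin -> CPM -> blur -> input-correct -> partition."""
    ip = bin_stranded_reads(ip_reads, layout, bin_width)
    inp = bin_stranded_reads(input_reads, layout, bin_width)
    ip = uniform_blur(cpm_normalize(ip, ip.library_size), blur_half_width)
    inp = uniform_blur(cpm_normalize(inp, inp.library_size), blur_half_width)
    corrected, keep = input_correct_and_filter(ip, inp, min_cpm)
    return compute_partition(corrected, keep, flip=flip)
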