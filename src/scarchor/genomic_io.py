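"""Genomics file I/O with origin-genome tagging.

Reads stranded alignments (BAM/SAM or BED6) into a compact tabular form,
classifying every read as coming from the target genome or from exogenous
spike-in chromatin by a chromosome-name prefix, and reads/writes the interval
and bedGraph formats used elsewhere in the pipeline.

Coordinates are 0-based half-open everywhere (BED/BAM native).
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
import pysam

FORWARD = "+"
REVERSE = "-"

#: columns of the canonical read frame
READ_COLUMNS = ["chrom", "start", "end", "strand", "origin"]


class ReadRecord(NamedTuple):
    """A single stranded read: half-open interval plus origin genome."""

    chrom: str
    start: int
    end: int
    strand: str  # "+" (forward) or "-" (reverse)
    origin: str  # "target" or "spike"


@dataclass(frozen=True)
class GenomeLayout:
    """Target-genome chromosome sizes plus the spike-in contig prefix.

    Contigs whose name starts with ``spike_prefix`` are classified as
    spike-in; contigs present in ``chrom_sizes`` are target; anything else
    is discarded (with a tally).
    """

    chrom_sizes: dict[str, int]
    spike_prefix: str = "dm6_"

    def __post_init__(self) -> None:
        for chrom, size in self.chrom_sizes.items():
            if size <= 0:
                raise ValueError(f"chromosome {chrom!r} has non-positive length {size}")
            if chrom.startswith(self.spike_prefix):
                raise ValueError(
                    f"spike-prefixed contig {chrom!r} must not appear in chrom_sizes"
                )

    def origin_of(self, chrom: str) -> str | None:
        """Classify a contig: 'target', 'spike', or None (unknown)."""
        if chrom.startswith(self.spike_prefix):
            return "spike"
        if chrom in self.chrom_sizes:
            return "target"
        return None

    def n_bins(self, chrom: str, bin_width: int) -> int:
        return -(-self.chrom_sizes[chrom] // bin_width)


@dataclass
class ReadTally:
    """Per-origin read counts for one parsed file."""

    target: int = 0
    spike: int = 0
    discarded: int = 0

    @property
    def total(self) -> int:
        return self.target + self.spike + self.discarded


@dataclass
class IntervalSet:
    """Sorted genomic intervals (chrom, start, end[, name]).

    Stored as a pandas DataFrame sorted by (chrom, start); every record
    satisfies start < end.
    """

    df: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["chrom", "start", "end", "name"]))

    def __post_init__(self) -> None:
        df = self.df.copy()
        if "name" not in df.columns:
            df["name"] = "."
        df = df[["chrom", "start", "end", "name"]]
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if (df["start"] >= df["end"]).any():
            bad = df.index[(df["start"] >= df["end"])][0]
            raise ValueError(f"interval with start >= end at record {bad}")
        df = df.sort_values(["chrom", "start", "end"], kind="mergesort")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self):
        return self.df.itertuples(index=False)

    def merged(self, merge_dist: int = 0) -> "IntervalSet":
        """Merge intervals whose gap (end-to-start) is <= merge_dist."""
        if len(self.df) == 0:
            return IntervalSet(self.df.copy())
        rows = []
        for chrom, sub in self.df.groupby("chrom", sort=True):
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            cur_s, cur_e = starts[0], ends[0]
            for s, e in zip(starts[1:], ends[1:]):
                if s - cur_e <= merge_dist:
                    cur_e = max(cur_e, e)
                else:
                    rows.append((chrom, cur_s, cur_e))
                    cur_s, cur_e = s, e
            rows.append((chrom, cur_s, cur_e))
        return IntervalSet(pd.DataFrame(rows, columns=["chrom", "start", "end"]))


def make_read_frame(chrom, start, end, strand, origin) -> pd.DataFrame:
    """Assemble a canonical read frame from columnar data.

    Scalar ``chrom``/``strand``/``origin`` values are broadcast to the
    length of ``start``.
    """
    start = np.asarray(start, dtype=np.int64)
    n = len(start)

    def col(v):
        if np.ndim(v) == 0:
            return np.repeat(v, n)
        return np.asarray(v, dtype=object)

    return pd.DataFrame(
        {
            "chrom": pd.Series(col(chrom), dtype="object"),
            "start": pd.Series(start, dtype=np.int64),
            "end": pd.Series(np.asarray(end, dtype=np.int64), dtype=np.int64),
            "strand": pd.Series(col(strand), dtype="object"),
            "origin": pd.Series(col(origin), dtype="object"),
        }
    )


def _classify_frame(df: pd.DataFrame, layout: GenomeLayout) -> tuple[pd.DataFrame, ReadTally]:
    chroms = df["chrom"]
    is_spike = chroms.str.startswith(layout.spike_prefix)
    is_target = chroms.isin(layout.chrom_sizes.keys()) & ~is_spike
    tally = ReadTally(
        target=int(is_target.sum()),
        spike=int(is_spike.sum()),
        discarded=int((~is_target & ~is_spike).sum()),
    )
    if tally.discarded:
        unknown = sorted(chroms[~is_target & ~is_spike].unique())
        warnings.warn(
            f"discarded {tally.discarded} reads on unknown contigs {unknown[:5]}",
            stacklevel=3,
        )
    out = df.loc[is_target | is_spike].copy()
    out["origin"] = np.where(out["chrom"].str.startswith(layout.spike_prefix),
                             "spike", "target")
    return out.reset_index(drop=True), tally


def _read_bed6(path: str) -> pd.DataFrame:
    if os.path.getsize(path) == 0:
        return pd.DataFrame(columns=["chrom", "start", "end", "strand"])
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        usecols=[0, 1, 2, 5],
        names=["chrom", "start", "end", "strand"],
        dtype={0: str, 1: np.int64, 2: np.int64, 5: str},
    )
    bad = ~df["strand"].isin([FORWARD, REVERSE])
    if bad.any():
        line = int(df.index[bad][0]) + 1
        raise ValueError(f"unstranded or malformed strand field at line {line} of {path}")
    return df


def _read_alignments(path: str, min_mapq: int) -> pd.DataFrame:
    mode = "rb" if path.endswith(".bam") else "r"
    chroms, starts, ends, strands = [], [], [], []
    with pysam.AlignmentFile(path, mode, check_sq=False) as fh:
        for aln in fh.fetch(until_eof=True):
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            if aln.mapping_quality < min_mapq:
                continue
            chroms.append(aln.reference_name)
            starts.append(aln.reference_start)
            ends.append(aln.reference_end)
            strands.append(REVERSE if aln.is_reverse else FORWARD)
    return make_read_frame(chroms, starts, ends, strands, "target")[
        ["chrom", "start", "end", "strand"]
    ]


def read_stranded_alignments(
    path: str, layout: GenomeLayout, min_mapq: int = 30
) -> tuple[pd.DataFrame, ReadTally]:
    """Parse stranded reads from BAM/SAM or BED6 into a read frame.

    Returns a DataFrame with columns chrom/start/end/strand/origin (target
    and spike reads only) and a :class:`ReadTally` with per-origin totals.
    ``min_mapq`` applies to alignment files only; BED records carry no
    mapping quality.
    """
    ext = os.path.splitext(path)[1].lower()
    if ext in (".bam", ".sam"):
        df = _read_alignments(path, min_mapq)
    else:
        df = _read_bed6(path)
    if len(df) == 0:
        empty = make_read_frame([], [], [], [], [])
        return empty, ReadTally()
    return _classify_frame(df, layout)


def iter_read_records(df: pd.DataFrame) -> Iterable[ReadRecord]:
    """Yield ReadRecord tuples from a read frame (convenience view)."""
    for row in df.itertuples(index=False):
        yield ReadRecord(row.chrom, row.start, row.end, row.strand, row.origin)


def read_intervals(path: str) -> IntervalSet:
    """Read BED3+/broadPeak intervals; sorted, zero-length records rejected."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 tab-separated columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise ValueError(
                    f"{path}:{lineno}: start >= end ({start} >= {end})"
                )
            name = parts[3] if len(parts) > 3 else "."
            rows.append((chrom, start, end, name))
    if not rows:
        return IntervalSet()
    return IntervalSet(pd.DataFrame(rows, columns=["chrom", "start", "end", "name"]))


def write_intervals(ivs: IntervalSet, path: str) -> None:
    ivs.df[["chrom", "start", "end", "name"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def write_reads_bed6(df: pd.DataFrame, path: str) -> None:
    """Write a read frame as BED6 (name column carries the origin tag)."""
    out = df[["chrom", "start", "end"]].copy()
    out["name"] = df["origin"]
    out["score"] = 0
    out["strand"] = df["strand"]
    out.to_csv(path, sep="\t", header=False, index=False)


def write_bedgraph(track, path: str, which: str) -> None:
    """Write one channel of a binned track as bedGraph.

    ``which`` is 'forward' or 'reverse' for a :class:`BinnedStrandTrack`,
    or 'partition' for a :class:`PartitionTrack` (masked bins omitted).
    Values are written with 6 decimal places, so a write-then-read round
    trip recovers them to 1e-6.
    """
    bw = track.bin_width
    with open(path, "w") as fh:
        for chrom in sorted(track.data):
            if which == "partition":
                values = track.data[chrom].partition
                keep = track.data[chrom].valid
            else:
                arrs = track.data[chrom]
                values = arrs.F if which == "forward" else arrs.R
                keep = np.ones(len(values), dtype=bool)
            idx = np.nonzero(keep)[0]
            for i in idx:
                start = int(i) * bw
                fh.write(f"{chrom}\t{start}\t{start + bw}\t{values[i]:.6f}\n")


def read_bedgraph(path: str, bin_width: int) -> dict[str, np.ndarray]:
    """Read a fixed-width bedGraph back into per-chromosome arrays.

    Bins absent from the file are NaN. Array length is inferred from the
    largest end coordinate per chromosome.
    """
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "value"],
                     dtype={0: str, 1: np.int64, 2: np.int64, 3: float})
    out: dict[str, np.ndarray] = {}
    for chrom, sub in df.groupby("chrom", sort=True):
        n = int(-(-sub["end"].max() // bin_width))
        arr = np.full(n, np.nan)
        arr[(sub["start"] // bin_width).to_numpy()] = sub["value"].to_numpy()
        out[chrom] = arr
    return out
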