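"""Read filtering, position merging, and the inter-position distance track.

The detection signal of isolated-chromosome sequencing lives in the spacing
of *merged read positions*: maximal runs of overlapping (or book-ended)
filtered alignments collapsed into single intervals. Inside a genomic region
that is physically present on the sampled chromosome, consecutive positions
are densely spaced; in the contamination background they are sparse. This
module turns raw mapped-read records into that spacing ("rainfall") track.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .intervals import ContractError, GenomicInterval, ReferenceIndex


@dataclass(frozen=True)
class ReadRecord:
    """One filtered-alignment candidate: a mapped read with its QC fields."""

    interval: GenomicInterval
    mapping_quality: int = 60
    aligned_length: int | None = None
    contaminant_flag: bool = False

    def __post_init__(self) -> None:
        if self.aligned_length is None:
            object.__setattr__(self, "aligned_length", self.interval.length())
        if self.aligned_length > self.interval.length():
            raise ValueError("aligned_length exceeds interval length")


@dataclass(frozen=True)
class MergedPosition:
    """A maximal run of overlapping reads with its supporting read count."""

    interval: GenomicInterval
    read_count: int = 1


def filter_reads(
    records: Iterable[ReadRecord],
    min_mapq: int = 20,
    min_len: int = 20,
    reference: ReferenceIndex | None = None,
) -> list[ReadRecord]:
    """Keep reads passing mapping-quality, length and contamination filters.

    Thresholds are inclusive (``>= min_mapq``, ``>= min_len``). A read whose
    midpoint falls inside a reference exclusion mask (telomeric/centromeric
    repeat stretches) is discarded, as such repeats generate false-positive
    region signals in cross-species mapping.
    """
    if min_mapq < 0 or min_len < 0:
        raise ValueError("thresholds must be >= 0")
    kept = []
    for r in records:
        if r.contaminant_flag:
            continue
        if r.mapping_quality < min_mapq or r.aligned_length < min_len:
            continue
        if reference is not None:
            mid = (r.interval.start + r.interval.end) // 2
            if reference.is_masked(r.interval.chrom, mid):
                continue
        kept.append(r)
    return kept


def merge_reads(records: Iterable[ReadRecord]) -> list[MergedPosition]:
    """Collapse overlapping-or-book-ended reads into merged positions.

    Merging uses join gap 0, so all downstream inter-position gaps are
    strictly positive and the log transform of the rainfall track is safe.
    ``read_count`` is the number of reads in the run.
    """
    ivs = sorted(((r.interval, 1) for r in records), key=lambda t: t[0])
    out: list[MergedPosition] = []
    for iv, _ in ivs:
        if (
            out
            and out[-1].interval.chrom == iv.chrom
            and iv.start <= out[-1].interval.end
        ):
            prev = out[-1]
            out[-1] = MergedPosition(
                GenomicInterval(
                    iv.chrom, prev.interval.start, max(prev.interval.end, iv.end)
                ),
                prev.read_count + 1,
            )
        else:
            out.append(MergedPosition(iv, 1))
    return out


@dataclass
class DistanceTrack:
    """Per-chromosome position coordinates and the gaps between them.

    For each chromosome: ``starts``/``ends`` are the sorted merged-position
    coordinates; ``gaps()[i] = starts[i+1] - ends[i]`` and its anchor is
    ``ends[i]`` (the right edge of the left position). A chromosome with k
    positions contributes k-1 gaps.
    """

    starts: dict[str, np.ndarray] = field(default_factory=dict)
    ends: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def chroms(self) -> list[str]:
        return list(self.starts)

    def n_positions(self, chrom: str) -> int:
        return len(self.starts[chrom])

    def gaps(self, chrom: str) -> np.ndarray:
        return self.starts[chrom][1:] - self.ends[chrom][:-1]

    def anchors(self, chrom: str) -> np.ndarray:
        return self.ends[chrom][:-1]

    def all_gaps(self) -> np.ndarray:
        parts = [self.gaps(c) for c in self.chroms]
        return np.concatenate(parts) if parts else np.array([], dtype=int)


def distance_track(positions: Sequence[MergedPosition]) -> DistanceTrack:
    """Build the inter-position distance track from merged positions.

    Positions must be sorted and pairwise non-overlapping per chromosome
    (the contract of :func:`merge_reads` output).
    """
    track = DistanceTrack()
    by_chrom: dict[str, list[MergedPosition]] = {}
    for p in positions:
        by_chrom.setdefault(p.interval.chrom, []).append(p)
    for chrom, plist in by_chrom.items():
        starts = np.array([p.interval.start for p in plist], dtype=np.int64)
        ends = np.array([p.interval.end for p in plist], dtype=np.int64)
        if np.any(np.diff(starts) <= 0) or np.any(starts[1:] < ends[:-1]):
            raise ContractError(f"positions on {chrom} unsorted or overlapping")
        track.starts[chrom] = starts
        track.ends[chrom] = ends
    return track


def rainfall_export(track: DistanceTrack) -> pd.DataFrame:
    """Tabular rainfall-plot data: (chrom, anchor, log10(gap+1)) per gap."""
    rows = []
    for chrom in track.chroms:
        gaps = track.gaps(chrom)
        anchors = track.anchors(chrom)
        for a, g in zip(anchors, gaps):
            rows.append((chrom, int(a), math.log10(int(g) + 1)))
    return pd.DataFrame(rows, columns=["chrom", "anchor", "log10_gap"])


def rainfall_to_track_gaps(df: pd.DataFrame) -> dict[str, np.ndarray]:
    """Recover per-chromosome gap arrays from an exported rainfall table."""
    out = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        out[str(chrom)] = np.round(10.0 ** sub["log10_gap"].to_numpy() - 1).astype(
            np.int64
        )
    return out


# --- BED6 I/O ---------------------------------------------------------------


def write_positions_bed(
    positions: Iterable[MergedPosition], path: str | Path, name: str = "pos"
) -> None:
    """BED6 with score = supporting read count."""
    lines = [
        f"{p.interval.chrom}\t{p.interval.start}\t{p.interval.end}"
        f"\t{name}\t{p.read_count}\t+\n"
        for p in positions
    ]
    Path(path).write_text("".join(lines))


def read_positions_bed(path: str | Path) -> list[MergedPosition]:
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("track", "#")):
            continue
        f = line.split("\t")
        count = int(f[4]) if len(f) > 4 else 1
        out.append(MergedPosition(GenomicInterval(f[0], int(f[1]), int(f[2])), count))
    return out


def read_reads_bed(path: str | Path) -> list[ReadRecord]:
    """BED6+2 read records: name ignored, score = mapq, then strand;
    optional columns 7-8 are aligned length and contaminant flag (0/1)."""
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("track", "#")):
            continue
        f = line.split("\t")
        iv = GenomicInterval(f[0], int(f[1]), int(f[2]))
        mapq = int(f[4]) if len(f) > 4 else 60
        alen = int(f[6]) if len(f) > 6 else iv.length()
        contam = bool(int(f[7])) if len(f) > 7 else False
        out.append(ReadRecord(iv, mapq, alen, contam))
    return out
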