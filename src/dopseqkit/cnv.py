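"""Windowed WGS read-depth analysis: normalization, segmentation, per-B copies.

Depth is summarized in fixed windows (default 1000 bp). Normalized depth 1.0
corresponds to the diploid baseline, so integer copy number is
``round(2 × normalized_depth)`` and extra copies = copy number − 2. Dividing
the excess by the number of B chromosomes in the individual gives per-B
copies — a value below 1 means the region is missing from some of the Bs.

The genome baseline is the *median* window count, robust to the amplified
B-chromosomal regions themselves. Windows below 500 bp are warned against:
at that scale uneven cross-species mapping produces spurious deletions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter

from .detect import RegionCall
from .intervals import GenomicInterval, merge_intervals

MIN_SAFE_WINDOW = 500  # bp; smaller windows inflate false-positive deletions


class DegenerateInputError(ValueError):
    """Depth track unusable (e.g. zero genome-wide median)."""


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass
class DepthTrack:
    """Per-chromosome window read counts at a fixed window size."""

    window_size: int
    counts: dict[str, np.ndarray]
    mask: dict[str, np.ndarray] | None = None  # True = window excluded
    normalized: dict[str, np.ndarray] | None = None
    genome_median: float | None = None

    def __post_init__(self) -> None:
        if self.window_size < MIN_SAFE_WINDOW:
            warnings.warn(
                f"window size {self.window_size} bp < {MIN_SAFE_WINDOW} bp: "
                "expect spurious deletion calls from uneven coverage",
                stacklevel=2,
            )
        for c, v in self.counts.items():
            if np.any(v < 0):
                raise ValueError(f"negative window counts on {c}")

    @property
    def chroms(self) -> list[str]:
        return list(self.counts)

    def n_windows(self) -> int:
        return sum(len(v) for v in self.counts.values())


def normalize_depth(track: DepthTrack) -> DepthTrack:
    """Divide every window by the genome-wide median of unmasked windows.

    Masked windows are excluded from the median but still normalized, so
    downstream consumers see a complete track. Requires >= 100 windows.
    """
    if track.n_windows() < 100:
        raise ValueError(f"need >= 100 windows, got {track.n_windows()}")
    pooled = []
    for chrom, v in track.counts.items():
        if track.mask is not None and chrom in track.mask:
            pooled.append(v[~track.mask[chrom]])
        else:
            pooled.append(v)
    med = float(np.median(np.concatenate(pooled)))
    if med <= 0:
        raise DegenerateInputError("genome-wide median window count is 0")
    track.genome_median = med
    track.normalized = {c: v / med for c, v in track.counts.items()}
    return track


@dataclass(frozen=True)
class DepthSegment:
    """A maximal constant-copy-number stretch of the depth track."""

    interval: GenomicInterval
    normalized_depth: float
    copy_number: int

    @property
    def extra_copies(self) -> int:
        return self.copy_number - 2

    def __post_init__(self) -> None:
        if self.copy_number < 0:
            raise ValueError("copy_number must be >= 0")


def segment_depth(track: DepthTrack, smooth_span: int = 5) -> list[DepthSegment]:
    """Median-smooth the normalized track and split it into constant-CN runs.

    Window-wise integer copy number is ``round(2 × smoothed depth)``; maximal
    runs of an identical value become segments aligned to window boundaries.
    A segment's reported ``normalized_depth`` is the mean of its *raw*
    normalized windows. Deterministic.
    """
    if track.normalized is None:
        raise ValueError("normalize_depth() must run first")
    w = track.window_size
    segments: list[DepthSegment] = []
    for chrom, nd in track.normalized.items():
        if len(nd) == 0:
            continue
        smoothed = median_filter(nd, size=smooth_span, mode="nearest")
        cn = np.floor(2.0 * smoothed + 0.5).astype(int)  # round half up, nd >= 0
        change = np.flatnonzero(np.diff(cn)) + 1
        bounds = np.concatenate([[0], change, [len(cn)]])
        for a, b in zip(bounds[:-1], bounds[1:]):
            segments.append(
                DepthSegment(
                    GenomicInterval(chrom, int(a) * w, int(b) * w),
                    float(nd[a:b].mean()),
                    int(cn[a]),
                )
            )
    return segments


def per_b_copies(segment: DepthSegment, n_b: int) -> tuple[float, int]:
    """Per-B-chromosome copy excess: exact value and reported integer.

    The integer is rounded half away from zero (e.g. 20 extra copies over 3
    Bs → 6.67 → 7). Values below 1 are reported, not suppressed: they mean
    the region is absent from some of the individual's Bs.
    """
    if n_b < 1:
        raise ValueError("n_b must be >= 1")
    exact = segment.extra_copies / n_b
    return exact, _round_half_away(exact)


def amplified_runs(
    segments: Sequence[DepthSegment], merge_gap: int | None = None, window_size: int = 1000
) -> list[GenomicInterval]:
    """Coalesce amplified segments (CN > 2) into maximal amplified regions.

    Book-ended amplified segments and those separated by ≤ ``merge_gap``
    (default 5 windows) are unioned; this is the region-level object whose
    breakpoints are compared across detection methods.
    """
    if merge_gap is None:
        merge_gap = 5 * window_size
    amp = [s.interval for s in segments if s.copy_number > 2]
    return merge_intervals(amp, join_gap=merge_gap)


@dataclass
class ConcordanceReport:
    pairs: pd.DataFrame  # one row per matched region pair
    median_breakpoint_diff: float
    recovered_fraction_a: float
    only_a: list[GenomicInterval]
    only_b: list[GenomicInterval]


def _best_reciprocal_pairs(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval], min_overlap: float
) -> list[tuple[GenomicInterval, GenomicInterval]]:
    best_for_a: dict[int, int] = {}
    best_for_b: dict[int, int] = {}
    ov = np.zeros((len(a), len(b)), dtype=np.int64)
    for i, x in enumerate(a):
        for j, y in enumerate(b):
            ov[i, j] = x.overlap(y)
    for i in range(len(a)):
        if ov.shape[1] and ov[i].max() > 0:
            best_for_a[i] = int(ov[i].argmax())
    for j in range(len(b)):
        if ov.shape[0] and ov[:, j].max() > 0:
            best_for_b[j] = int(ov[:, j].argmax())
    pairs = []
    for i, j in best_for_a.items():
        if best_for_b.get(j) != i:
            continue
        o = ov[i, j]
        if o >= min_overlap * a[i].length() and o >= min_overlap * b[j].length():
            pairs.append((a[i], b[j]))
    return pairs


def concordance(
    regions_a: Sequence[RegionCall] | Sequence[GenomicInterval],
    segments_b: Sequence[DepthSegment],
    min_overlap: float = 0.5,
    merge_gap: int | None = None,
) -> ConcordanceReport:
    """Breakpoint agreement between spacing-based calls and depth segments.

    Amplified depth segments are coalesced into amplified regions, then
    matched to the calls by best reciprocal overlap ≥ ``min_overlap``. Per
    matched pair, both |start − start| and |end − end| enter the pooled
    median breakpoint difference. Unmatched regions on either side are
    reported as detected by one method only.
    """
    a = [c.interval if isinstance(c, RegionCall) else c for c in regions_a]
    b = amplified_runs(segments_b, merge_gap=merge_gap, window_size=1000)
    pairs = _best_reciprocal_pairs(a, b, min_overlap)
    rows = []
    diffs = []
    for x, y in pairs:
        ds, de = abs(x.start - y.start), abs(x.end - y.end)
        diffs.extend([ds, de])
        rows.append(
            {
                "region_a": str(x),
                "region_b": str(y),
                "overlap_bp": x.overlap(y),
                "start_diff": ds,
                "end_diff": de,
            }
        )
    matched_a = {str(x) for x, _ in pairs}
    matched_b = {str(y) for _, y in pairs}
    return ConcordanceReport(
        pairs=pd.DataFrame(
            rows, columns=["region_a", "region_b", "overlap_bp", "start_diff", "end_diff"]
        ),
        median_breakpoint_diff=float(np.median(diffs)) if diffs else float("nan"),
        recovered_fraction_a=(len(matched_a) / len(a)) if a else float("nan"),
        only_a=[x for x in a if str(x) not in matched_a],
        only_b=[y for y in b if str(y) not in matched_b],
    )


def copy_spectrum(
    segments: Sequence[DepthSegment],
    regions: Sequence[RegionCall] | Sequence[GenomicInterval],
) -> pd.DataFrame:
    """Histogram of extra-copy values over segments overlapping the regions.

    Region parts with different copy numbers count separately: each depth
    segment that overlaps any region contributes one unit at its
    extra-copies value.
    """
    ivs = [c.interval if isinstance(c, RegionCall) else c for c in regions]
    counts: dict[int, int] = {}
    for s in segments:
        if any(s.interval.overlap(iv) > 0 for iv in ivs):
            counts[s.extra_copies] = counts.get(s.extra_copies, 0) + 1
    return pd.DataFrame(
        sorted(counts.items()), columns=["extra_copies", "n_segments"]
    )


# --- bedGraph I/O -----------------------------------------------------------


def write_bedgraph(track: DepthTrack, path: str | Path) -> None:
    lines = []
    w = track.window_size
    for chrom, v in track.counts.items():
        for i, c in enumerate(v):
            lines.append(f"{chrom}\t{i * w}\t{(i + 1) * w}\t{int(c)}\n")
    Path(path).write_text("".join(lines))


def read_bedgraph(path: str | Path, window_size: int | None = None) -> DepthTrack:
    """Read a fixed-window bedGraph into a :class:`DepthTrack`."""
    per_chrom: dict[str, list[tuple[int, int]]] = {}
    widths = set()
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("track", "#")):
            continue
        chrom, start, end, value = line.split("\t")[:4]
        per_chrom.setdefault(chrom, []).append((int(start), int(float(value))))
        widths.add(int(end) - int(start))
    if window_size is None:
        window_size = max(widths) if widths else 1000
    counts = {}
    for chrom, rows in per_chrom.items():
        rows.sort()
        counts[chrom] = np.array([v for _, v in rows], dtype=np.int64)
    return DepthTrack(window_size=window_size, counts=counts)


def segments_table(segments: Sequence[DepthSegment], n_b: int) -> pd.DataFrame:
    rows = []
    for s in segments:
        exact, rounded = per_b_copies(s, n_b)
        rows.append(
            {
                "chrom": s.interval.chrom,
                "start": s.interval.start,
                "end": s.interval.end,
                "normalized_depth": s.normalized_depth,
                "copy_number": s.copy_number,
                "extra_copies": s.extra_copies,
                "per_b_copies": exact,
                "per_b_reported": rounded,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "start", "end", "normalized_depth", "copy_number",
            "extra_copies", "per_b_copies", "per_b_reported",
        ],
    )
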