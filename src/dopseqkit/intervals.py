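"""Genomic interval algebra and reference metadata.

Coordinates are 0-based half-open throughout: an interval ``(chrom, start,
end)`` covers base pairs ``start .. end-1`` and has length ``end - start``.
Printed region strings such as ``"CFA13:47122582-47327423"`` are ingested
verbatim as ``(start, end)`` so that their lengths sum to published region-set
totals without any ±1 adjustment.

Chromosome names are matched by exact string equality; no "chr"-prefix
normalization is applied.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence


class ContractError(ValueError):
    """An operation's input contract was violated (e.g. overlapping set)."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open coordinate span ``[start, end)`` on a named chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got {self.chrom}:{self.start}-{self.end}"
            )

    def length(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        """Overlap in bp with ``other`` (0 if disjoint or other chromosome)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def gap_to(self, other: "GenomicInterval") -> int | None:
        """Gap in bp between two disjoint same-chromosome intervals.

        Returns ``None`` for different chromosomes, 0 for book-ended, and a
        negative number when the intervals overlap.
        """
        if self.chrom != other.chrom:
            return None
        return max(self.start, other.start) - min(self.end, other.end)

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


_REGION_RE = re.compile(r"^(?P<chrom>[^:]+):(?P<start>\d+)-(?P<end>\d+)$")


def parse_region(text: str) -> GenomicInterval:
    """Parse ``"chrom:start-end"`` verbatim into a :class:`GenomicInterval`."""
    m = _REGION_RE.match(text.strip())
    if m is None:
        raise ValueError(f"cannot parse region string {text!r}")
    return GenomicInterval(m["chrom"], int(m["start"]), int(m["end"]))


@dataclass
class ReferenceIndex:
    """Ordered chromosome name → length map, plus optional exclusion masks.

    The exclusion set holds intervals (telomeric/centromeric repeat stretches
    and similar) whose reads should be discarded upstream; such repeats are a
    known source of false-positive region calls in cross-species mapping.
    """

    lengths: dict[str, int]
    exclusions: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.lengths) == 0:
            raise ValueError("reference must contain at least one chromosome")
        for name, n in self.lengths.items():
            if n <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {n}")
        for iv in self.exclusions:
            if iv.chrom not in self.lengths:
                raise ValueError(f"exclusion {iv} on unknown chromosome")
            if iv.end > self.lengths[iv.chrom]:
                raise ValueError(f"exclusion {iv} extends past chromosome end")

    @property
    def chroms(self) -> list[str]:
        return list(self.lengths)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths

    def check_interval(self, iv: GenomicInterval) -> None:
        if iv.chrom not in self.lengths:
            raise ValueError(f"interval {iv} on unknown chromosome {iv.chrom!r}")
        if iv.end > self.lengths[iv.chrom]:
            raise ValueError(f"interval {iv} extends past chromosome end")

    def is_masked(self, chrom: str, pos: int) -> bool:
        """True if the single base ``pos`` falls inside an exclusion interval."""
        return any(
            iv.chrom == chrom and iv.start <= pos < iv.end for iv in self.exclusions
        )

    @classmethod
    def from_chrom_sizes(cls, path: str | Path) -> "ReferenceIndex":
        lengths: dict[str, int] = {}
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            name, size = line.split("\t")[:2]
            lengths[name] = int(size)
        return cls(lengths)

    def to_chrom_sizes(self, path: str | Path) -> None:
        Path(path).write_text(
            "".join(f"{name}\t{size}\n" for name, size in self.lengths.items())
        )


def _check_nonoverlapping(intervals: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    ivs = sorted(intervals)
    for a, b in zip(ivs, ivs[1:]):
        if a.chrom == b.chrom and b.start < a.end:
            raise ContractError(f"intervals overlap: {a} and {b}")
    return ivs


def merge_intervals(
    intervals: Iterable[GenomicInterval], join_gap: int = 0
) -> list[GenomicInterval]:
    """Union-merge intervals, bridging same-chromosome gaps ≤ ``join_gap``.

    Book-ended intervals (gap exactly ``join_gap``) merge; the output is
    sorted and pairwise non-overlapping. Idempotent.
    """
    if join_gap < 0:
        raise ValueError(f"join_gap must be >= 0, got {join_gap}")
    ivs = sorted(intervals)
    out: list[GenomicInterval] = []
    for iv in ivs:
        if out and out[-1].chrom == iv.chrom and iv.start - out[-1].end <= join_gap:
            if iv.end > out[-1].end:
                out[-1] = GenomicInterval(iv.chrom, out[-1].start, iv.end)
        else:
            out.append(iv)
    return out


def intersect_sets(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> list[tuple[GenomicInterval, GenomicInterval, int]]:
    """All overlapping pairs between two non-overlapping interval sets.

    Returns ``(interval_a, interval_b, overlap_bp)`` triples with
    ``overlap_bp >= 1``, sorted by coordinate. Symmetric: swapping the inputs
    swaps the pair members but preserves count and overlap sizes.
    """
    sa = _check_nonoverlapping(a)
    sb = _check_nonoverlapping(b)
    out: list[tuple[GenomicInterval, GenomicInterval, int]] = []
    i = j = 0
    while i < len(sa) and j < len(sb):
        x, y = sa[i], sb[j]
        if x.chrom != y.chrom:
            if x.chrom < y.chrom:
                i += 1
            else:
                j += 1
            continue
        ov = x.overlap(y)
        if ov > 0:
            out.append((x, y, ov))
        if x.end <= y.end:
            i += 1
        else:
            j += 1
    return out


def total_size(intervals: Sequence[GenomicInterval]) -> int:
    """Total bp covered by a non-overlapping interval set."""
    return sum(iv.length() for iv in _check_nonoverlapping(intervals))


def subtract(
    minuend: GenomicInterval, holes: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """Interval minus a set of holes, as a sorted list of remaining pieces."""
    pieces: list[GenomicInterval] = []
    cursor = minuend.start
    for h in merge_intervals([h for h in holes if h.overlap(minuend) > 0]):
        if h.start > cursor:
            pieces.append(GenomicInterval(minuend.chrom, cursor, h.start))
        cursor = max(cursor, h.end)
    if cursor < minuend.end:
        pieces.append(GenomicInterval(minuend.chrom, cursor, minuend.end))
    return pieces


# --- BED3 I/O ---------------------------------------------------------------


def read_bed3(path: str | Path) -> list[GenomicInterval]:
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("track", "#")):
            continue
        fields = line.split("\t")
        out.append(GenomicInterval(fields[0], int(fields[1]), int(fields[2])))
    return out


def write_bed3(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    Path(path).write_text(
        "".join(f"{iv.chrom}\t{iv.start}\t{iv.end}\n" for iv in intervals)
    )
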