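"""Multi-sample and cross-species synthesis of region calls.

Consensus rows come from union-merging the *strong* calls of all samples of
one species; each sample's cell is then "+" (a strong call overlaps the
row), "~" (no strong call, but at least two merged positions fall inside —
the manual-rescue tier), or absent. Shared regions between species are exact
interval overlaps; proximal pairs are same-chromosome neighbours within a
configurable distance, the pattern of repeated reuse of nearby donor regions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .detect import RegionCall
from .intervals import (
    GenomicInterval,
    ReferenceIndex,
    intersect_sets,
    merge_intervals,
    parse_region,
)
from .positions import MergedPosition

STRONG, WEAK, ABSENT = "+", "~", ""


@dataclass
class PresenceMatrix:
    """Consensus regions × samples table of presence states.

    ``df`` is indexed by region string ("chrom:start-end"), one column per
    sample with values "+", "~" or ""; ``evidence`` optionally holds an
    external-evidence column (e.g. BAC clone mapping) keyed the same way.
    """

    df: pd.DataFrame
    evidence: pd.Series | None = None

    @property
    def regions(self) -> list[GenomicInterval]:
        return [parse_region(r) for r in self.df.index]

    @property
    def samples(self) -> list[str]:
        return list(self.df.columns)

    def to_tsv(self, path: str | Path) -> None:
        out = self.df.copy()
        if self.evidence is not None:
            out["evidence"] = self.evidence
        out.to_csv(path, sep="\t", index_label="region")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PresenceMatrix":
        df = pd.read_csv(path, sep="\t", index_col="region", dtype=str).fillna("")
        evidence = None
        if "evidence" in df.columns:
            evidence = df.pop("evidence")
        return cls(df=df, evidence=evidence)


def build_consensus(
    calls_by_sample: Mapping[str, Sequence[RegionCall]],
    join_gap: int = 10_000,
    reference: ReferenceIndex | None = None,
) -> list[GenomicInterval]:
    """Union-merge strong calls across samples into the consensus row set.

    Weak calls never create rows — they can only rescue a sample's presence
    in a row established by another sample's strong call.
    """
    strong = []
    for calls in calls_by_sample.values():
        for c in calls:
            if reference is not None and c.interval.chrom not in reference:
                raise ValueError(
                    f"call {c.interval} not on the shared reference "
                    f"(unknown chromosome {c.interval.chrom!r})"
                )
            if c.tier == "strong":
                strong.append(c.interval)
    return merge_intervals(strong, join_gap=join_gap)


def fill_matrix(
    consensus: Sequence[GenomicInterval],
    calls_by_sample: Mapping[str, Sequence[RegionCall]],
    positions_by_sample: Mapping[str, Sequence[MergedPosition]] | None = None,
    weak_min_positions: int = 2,
) -> PresenceMatrix:
    """Fill the presence matrix over a built consensus.

    A cell is strong if the sample has a strong call overlapping the row;
    weak if not, but at least ``weak_min_positions`` merged positions of the
    sample fall inside the row (single positions are treated as noise);
    absent otherwise.
    """
    index = [str(iv) for iv in sorted(consensus)]
    data: dict[str, list[str]] = {}
    for sample, calls in calls_by_sample.items():
        strong_ivs = [c.interval for c in calls if c.tier == "strong"]
        positions = (
            positions_by_sample.get(sample, []) if positions_by_sample else []
        )
        col = []
        for iv in sorted(consensus):
            if any(iv.overlap(s) > 0 for s in strong_ivs):
                col.append(STRONG)
                continue
            n_inside = sum(
                1
                for p in positions
                if iv.contains(p.interval)
            )
            col.append(WEAK if n_inside >= weak_min_positions else ABSENT)
        data[sample] = col
    df = pd.DataFrame(data, index=index)
    keep = (df != ABSENT).any(axis=1)
    return PresenceMatrix(df=df[keep])


def sample_agreement(matrix: PresenceMatrix) -> list[list[str]]:
    """Partition samples into groups with exactly identical presence columns.

    Strong and weak are *not* collapsed: columns must agree cell by cell.
    Groups are sorted by decreasing size, then by first sample name.
    """
    if len(matrix.samples) < 2:
        raise ValueError("need >= 2 samples")
    groups: dict[tuple, list[str]] = {}
    for s in matrix.samples:
        groups.setdefault(tuple(matrix.df[s]), []).append(s)
    return sorted(groups.values(), key=lambda g: (-len(g), g[0]))


def cross_species_overlap(
    consensus_a: Sequence[GenomicInterval],
    consensus_b: Sequence[GenomicInterval],
    prox_max: int = 5_000_000,
) -> tuple[
    list[tuple[GenomicInterval, GenomicInterval, int]],
    list[tuple[GenomicInterval, GenomicInterval, int]],
]:
    """Shared (overlapping) and proximal region pairs between two species.

    Shared pairs overlap by >= 1 bp on the common reference; proximal pairs
    sit on the same chromosome within ``prox_max`` bp without overlapping
    (the two sets are disjoint by construction). Proximal gap is returned
    as the third element.
    """
    shared = intersect_sets(consensus_a, consensus_b)
    proximal = []
    for x in sorted(consensus_a):
        for y in sorted(consensus_b):
            g = x.gap_to(y)
            if g is not None and 0 < g <= prox_max:
                proximal.append((x, y, g))
    return shared, proximal


def external_evidence_check(
    matrix: PresenceMatrix | Sequence[GenomicInterval],
    evidence: Sequence[GenomicInterval],
) -> tuple[list[GenomicInterval], list[GenomicInterval]]:
    """Split prior-evidence intervals into recovered vs missed.

    An evidence interval (e.g. a BAC clone mapping position) is recovered
    iff it overlaps any consensus row by >= 1 bp.
    """
    rows = matrix.regions if isinstance(matrix, PresenceMatrix) else list(matrix)
    recovered, missed = [], []
    for ev in evidence:
        (recovered if any(ev.overlap(r) > 0 for r in rows) else missed).append(ev)
    return recovered, missed


def pairs_table(
    shared: Sequence[tuple[GenomicInterval, GenomicInterval, int]],
    proximal: Sequence[tuple[GenomicInterval, GenomicInterval, int]],
) -> pd.DataFrame:
    rows = [
        {"kind": "shared", "region_a": str(a), "region_b": str(b), "bp": n}
        for a, b, n in shared
    ] + [
        {"kind": "proximal", "region_a": str(a), "region_b": str(b), "bp": n}
        for a, b, n in proximal
    ]
    return pd.DataFrame(rows, columns=["kind", "region_a", "region_b", "bp"])
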