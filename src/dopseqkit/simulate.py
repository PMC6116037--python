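"""Synthetic isolated-chromosome positions and WGS depth with known truth.

The generator emulates the two data types the pipeline consumes, with a
ground-truth manifest so every downstream stage is testable offline:

* *Merged read positions*: inside planted regions (minus their internal
  deletions) successive position starts are spaced Exponential with mean
  ``target_spacing_mean``; everywhere else (the amplification/contamination
  background) Exponential with mean ``background_spacing_mean``. Position
  widths are Exponential(``position_width_mean``) plus a 36 bp read-length
  floor — only the spacing matters downstream. Each raw position is retained
  with probability ``1 - dropout_rate``, a stand-in for the coverage dropout
  of whole-chromosome amplification (DOP-PCR/WGA).

* *Windowed WGS depth*: per-window counts are Poisson(baseline × CN/2) where
  CN = 2 + extra_copies inside planted regions, 0 inside planted homozygous
  deletions, and 2 elsewhere. 1.0× baseline is the diploid state.

One master seed drives everything; per-track generators use fixed offsets
(0 = positions, 1 = depth), so adding one track never perturbs the other.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import yaml

from .intervals import GenomicInterval, ReferenceIndex, parse_region, subtract
from .positions import MergedPosition, merge_reads, ReadRecord

_READ_FLOOR = 36  # bp: minimal position width, read-length-like

_POSITIONS_STREAM = 0
_DEPTH_STREAM = 1


@dataclass(frozen=True)
class PlantedRegion:
    """A ground-truth target region with its copy excess and deletions."""

    interval: GenomicInterval
    extra_copies: int = 0
    deletions: tuple[GenomicInterval, ...] = ()

    def __post_init__(self) -> None:
        if self.extra_copies < 0:
            raise ValueError("extra_copies must be >= 0")
        for d in self.deletions:
            if not (
                d.chrom == self.interval.chrom
                and self.interval.start < d.start
                and d.end < self.interval.end
            ):
                raise ValueError(f"deletion {d} not strictly inside {self.interval}")


@dataclass
class SimulationScenario:
    """Study conditions for one simulated individual.

    Defaults mirror the canid B-chromosome setting: three B chromosomes per
    individual, 1000 bp depth windows, dense target spacing (200 bp mean)
    against a sparse 50 kb background, and ~30 reads per diploid window.
    """

    reference: ReferenceIndex
    planted_regions: list[PlantedRegion] = field(default_factory=list)
    n_b: int = 3
    target_spacing_mean: float = 200.0
    background_spacing_mean: float = 50_000.0
    position_width_mean: float = 50.0
    wgs_baseline_depth: float = 30.0
    window_size: int = 1000
    dropout_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target_spacing_mean <= 0 or self.background_spacing_mean <= 0:
            raise ValueError("spacing means must be > 0")
        if self.wgs_baseline_depth <= 0:
            raise ValueError("wgs_baseline_depth must be > 0")
        if not (0 <= self.dropout_rate < 1):
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.n_b < 1:
            raise ValueError("n_b must be >= 1")
        for pr in self.planted_regions:
            self.reference.check_interval(pr.interval)
        ratio = self.background_spacing_mean / self.target_spacing_mean
        if ratio < 10:
            warnings.warn(
                f"background/target spacing ratio {ratio:.1f} < 10: "
                "the spacing contrast carrying the detection signal is weak",
                stacklevel=2,
            )

    def _rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stream)])

    # --- manifest / config round-trip ---------------------------------

    def manifest(self) -> dict:
        return {
            "seed": int(self.seed),
            "n_b": int(self.n_b),
            "window_size": int(self.window_size),
            "target_spacing_mean": float(self.target_spacing_mean),
            "background_spacing_mean": float(self.background_spacing_mean),
            "position_width_mean": float(self.position_width_mean),
            "wgs_baseline_depth": float(self.wgs_baseline_depth),
            "dropout_rate": float(self.dropout_rate),
            "chromosomes": {c: int(n) for c, n in self.reference.lengths.items()},
            "planted_regions": [
                {
                    "region": str(pr.interval),
                    "extra_copies": int(pr.extra_copies),
                    "deletions": [str(d) for d in pr.deletions],
                }
                for pr in self.planted_regions
            ],
        }

    @classmethod
    def from_manifest(cls, data: dict) -> "SimulationScenario":
        ref = ReferenceIndex({c: int(n) for c, n in data["chromosomes"].items()})
        planted = [
            PlantedRegion(
                parse_region(p["region"]),
                int(p["extra_copies"]),
                tuple(parse_region(d) for d in p["deletions"]),
            )
            for p in data["planted_regions"]
        ]
        return cls(
            reference=ref,
            planted_regions=planted,
            n_b=int(data["n_b"]),
            target_spacing_mean=float(data["target_spacing_mean"]),
            background_spacing_mean=float(data["background_spacing_mean"]),
            position_width_mean=float(data["position_width_mean"]),
            wgs_baseline_depth=float(data["wgs_baseline_depth"]),
            window_size=int(data["window_size"]),
            dropout_rate=float(data["dropout_rate"]),
            seed=int(data["seed"]),
        )

    def write_manifest(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.manifest(), indent=1) + "\n")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationScenario":
        return cls.from_manifest(yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.manifest(), sort_keys=False))


def _target_pieces(scenario: SimulationScenario) -> list[GenomicInterval]:
    """Planted regions minus their deletions: where dense spacing applies."""
    pieces = []
    for pr in scenario.planted_regions:
        pieces.extend(subtract(pr.interval, list(pr.deletions)))
    return sorted(pieces)


def _draw_positions_in(
    rng: np.random.Generator,
    span: GenomicInterval,
    spacing_mean: float,
    width_mean: float,
) -> list[GenomicInterval]:
    out = []
    cursor = span.start + rng.exponential(spacing_mean)
    while cursor < span.end:
        width = _READ_FLOOR + rng.exponential(width_mean)
        end = min(int(cursor + width), span.end)
        start = int(cursor)
        if end > start:
            out.append(GenomicInterval(span.chrom, start, end))
        cursor += rng.exponential(spacing_mean)
    return out


def simulate_positions(
    scenario: SimulationScenario,
) -> tuple[list[MergedPosition], dict]:
    """Generate merged read positions plus the ground-truth manifest.

    Background positions (contamination and amplification noise) cover every
    chromosome end to end; dense target positions are laid down inside each
    planted region minus its deletions. Deterministic for a fixed seed.
    """
    rng = scenario._rng(_POSITIONS_STREAM)
    raw: list[GenomicInterval] = []
    for chrom, length in scenario.reference.lengths.items():
        span = GenomicInterval(chrom, 0, length)
        raw.extend(
            _draw_positions_in(
                rng, span, scenario.background_spacing_mean, scenario.position_width_mean
            )
        )
    for piece in _target_pieces(scenario):
        raw.extend(
            _draw_positions_in(
                rng, piece, scenario.target_spacing_mean, scenario.position_width_mean
            )
        )
    if scenario.dropout_rate > 0:
        keep = rng.random(len(raw)) >= scenario.dropout_rate
        raw = [iv for iv, k in zip(raw, keep) if k]
    positions = merge_reads(ReadRecord(iv) for iv in raw)
    return positions, scenario.manifest()


def simulate_depth(scenario: SimulationScenario) -> tuple["DepthTrack", dict]:
    """Generate the windowed WGS depth track plus the ground-truth manifest.

    The copy number of a window is decided at its midpoint: 0 inside a
    planted homozygous deletion, 2 + extra_copies inside a planted region,
    2 elsewhere; counts are Poisson(baseline × CN / 2).
    """
    from .cnv import DepthTrack  # local import to avoid a cycle

    rng = scenario._rng(_DEPTH_STREAM)
    w = scenario.window_size
    counts: dict[str, np.ndarray] = {}
    for chrom, length in scenario.reference.lengths.items():
        n_win = -(-length // w)  # ceil
        mids = np.arange(n_win, dtype=np.int64) * w + w // 2
        cn = np.full(n_win, 2.0)
        for pr in scenario.planted_regions:
            if pr.interval.chrom != chrom:
                continue
            inside = (mids >= pr.interval.start) & (mids < pr.interval.end)
            cn[inside] = 2.0 + pr.extra_copies
            for d in pr.deletions:
                cn[(mids >= d.start) & (mids < d.end)] = 0.0
        counts[chrom] = rng.poisson(scenario.wgs_baseline_depth * cn / 2.0)
    track = DepthTrack(window_size=w, counts=counts)
    return track, scenario.manifest()


def write_bedgraph(track: "DepthTrack", path: str | Path) -> None:
    from .cnv import write_bedgraph as _w

    _w(track, path)


def planted_truth(scenario: SimulationScenario) -> dict[str, list[GenomicInterval]]:
    """Convenience view of ground truth for tests and recovery metrics."""
    return {
        "regions": [pr.interval for pr in scenario.planted_regions],
        "deletions": [d for pr in scenario.planted_regions for d in pr.deletions],
    }


def positions_to_bed(positions: Iterable[MergedPosition], path: str | Path) -> None:
    from .positions import write_positions_bed

    write_positions_bed(positions, path)
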