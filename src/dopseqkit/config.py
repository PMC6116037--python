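"""Pipeline configuration with field-standard defaults.

Defaults follow the canid B-chromosome study conditions: alignment filter
min_mapq 20 / min_len 20, 1000 bp depth windows, three B chromosomes per
individual.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class FilterConfig:
    min_mapq: int = 20
    min_len: int = 20


@dataclass
class DetectorConfig:
    switch_penalty: float = 1e-3
    strong_min: int = 5
    min_del: int = 10_000
    del_quantile: float = 0.999
    max_iter: int = 500
    tol: float = 1e-8


@dataclass
class CnvConfig:
    window_size: int = 1000
    n_b: int = 3
    smooth_span: int = 5
    min_overlap: float = 0.5


@dataclass
class CompareConfig:
    join_gap: int = 10_000
    prox_max: int = 5_000_000
    weak_min_positions: int = 2


@dataclass
class PipelineConfig:
    filter: FilterConfig = field(default_factory=FilterConfig)
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    cnv: CnvConfig = field(default_factory=CnvConfig)
    compare: CompareConfig = field(default_factory=CompareConfig)
    seed: int = 0
    scenario: str | None = None  # YAML scenario path for the simulate stage
    positions: dict[str, str] = field(default_factory=dict)  # sample -> BED
    depth: str | None = None  # bedGraph path
    chrom_sizes: str | None = None
    annotation: str | None = None  # genes BED/GFF3
    homology: str | None = None  # homology TSV
    evidence: str | None = None  # external-evidence BED

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(
            filter=FilterConfig(**raw.get("filter", {})),
            detector=DetectorConfig(**raw.get("detector", {})),
            cnv=CnvConfig(**raw.get("cnv", {})),
            compare=CompareConfig(**raw.get("compare", {})),
            seed=int(raw.get("seed", 0)),
            scenario=raw.get("scenario"),
            positions=dict(raw.get("positions", {})),
            depth=raw.get("depth"),
            chrom_sizes=raw.get("chrom_sizes"),
            annotation=raw.get("annotation"),
            homology=raw.get("homology"),
            evidence=raw.get("evidence"),
        )
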