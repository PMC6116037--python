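"""Stage orchestration with explicit file handoffs and provenance logging.

Stages run in a fixed order — simulate (optional) → filter/merge → detect →
cnv → compare → genes — each reading only files produced by earlier stages
or listed in the config, and each writing its outputs plus one provenance
line (stage, inputs, parameters, package version, seed) to ``run.log``.
Reruns with the same config are bit-identical: the only randomness is the
scenario seed.
"""

from __future__ import annotations

import json
import sys
from pathlib import Path

from . import __version__
from .cnv import (
    concordance,
    copy_spectrum,
    normalize_depth,
    read_bedgraph,
    segment_depth,
    segments_table,
)
from .compare import build_consensus, fill_matrix, external_evidence_check, pairs_table
from .config import PipelineConfig
from .detect import detect_regions, region_report
from .intervals import ReferenceIndex, read_bed3, write_bed3
from .positions import distance_track, read_positions_bed, write_positions_bed
from .simulate import SimulationScenario, simulate_depth, simulate_positions


class StageError(RuntimeError):
    """A stage could not run; names the stage and the offending file."""


def _provenance(outdir: Path, stage: str, inputs: list[str], params: dict, seed: int) -> None:
    line = json.dumps(
        {
            "stage": stage,
            "inputs": inputs,
            "params": params,
            "version": __version__,
            "seed": seed,
        },
        sort_keys=True,
    )
    with open(outdir / "run.log", "a") as fh:
        fh.write(line + "\n")
    print(f"[dopseqkit] {stage}: done", file=sys.stderr)


def _require(path: str | None, stage: str, what: str) -> Path:
    if path is None:
        raise StageError(f"stage {stage!r}: missing config entry for {what}")
    p = Path(path)
    if not p.exists():
        raise StageError(f"stage {stage!r}: {what} file not found: {p}")
    return p


def run_simulate(scenario: SimulationScenario, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    positions, manifest = simulate_positions(scenario)
    track, _ = simulate_depth(scenario)
    pos_path = outdir / "positions.bed"
    depth_path = outdir / "depth.bedgraph"
    manifest_path = outdir / "truth.json"
    sizes_path = outdir / "reference.sizes"
    write_positions_bed(positions, pos_path)
    from .cnv import write_bedgraph

    write_bedgraph(track, depth_path)
    Path(manifest_path).write_text(json.dumps(manifest, indent=1) + "\n")
    scenario.reference.to_chrom_sizes(sizes_path)
    _provenance(outdir, "simulate", [], manifest, scenario.seed)
    return {
        "positions": pos_path,
        "depth": depth_path,
        "truth": manifest_path,
        "chrom_sizes": sizes_path,
    }


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict[str, Path]:
    """Run every configured stage; returns the map of produced files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    produced: dict[str, Path] = {}

    positions_files = dict(config.positions)
    depth_file = config.depth

    if config.scenario is not None:
        scen_path = _require(config.scenario, "simulate", "scenario")
        scenario = SimulationScenario.from_yaml(scen_path)
        if config.seed:
            scenario.seed = config.seed
        sim = run_simulate(scenario, outdir / "simulate")
        positions_files.setdefault("sim", str(sim["positions"]))
        depth_file = depth_file or str(sim["depth"])
        produced.update({f"simulate_{k}": v for k, v in sim.items()})

    reference = None
    if config.chrom_sizes:
        reference = ReferenceIndex.from_chrom_sizes(
            _require(config.chrom_sizes, "detect", "chrom_sizes")
        )

    # detect: per-sample region calls from merged positions
    calls_by_sample = {}
    positions_by_sample = {}
    for sample, path in positions_files.items():
        pos = read_positions_bed(_require(path, "detect", f"positions[{sample}]"))
        positions_by_sample[sample] = pos
        if not pos:
            calls_by_sample[sample] = []
            continue
        track = distance_track(pos)
        try:
            calls, _model = detect_regions(
                track,
                switch_penalty=config.detector.switch_penalty,
                strong_min=config.detector.strong_min,
                min_del=config.detector.min_del,
                del_quantile=config.detector.del_quantile,
                max_iter=config.detector.max_iter,
                tol=config.detector.tol,
                sample_id=sample,
            )
        except ValueError:
            calls = []
        calls_by_sample[sample] = calls
    all_calls = [c for calls in calls_by_sample.values() for c in calls]
    report = region_report(all_calls)
    report_path = outdir / "region_calls.tsv"
    report.to_csv(report_path, sep="\t", index=False)
    produced["region_calls"] = report_path
    _provenance(
        outdir, "detect", sorted(positions_files.values()),
        vars(config.detector), config.seed,
    )

    # cnv: depth normalization, segmentation, concordance, spectrum
    if depth_file is not None:
        track = read_bedgraph(
            _require(depth_file, "cnv", "depth"), window_size=config.cnv.window_size
        )
        track = normalize_depth(track)
        segments = segment_depth(track, smooth_span=config.cnv.smooth_span)
        seg_path = outdir / "depth_segments.tsv"
        segments_table(segments, config.cnv.n_b).to_csv(seg_path, sep="\t", index=False)
        produced["depth_segments"] = seg_path
        if all_calls:
            rep = concordance(all_calls, segments, min_overlap=config.cnv.min_overlap)
            conc_path = outdir / "concordance.tsv"
            rep.pairs.to_csv(conc_path, sep="\t", index=False)
            (outdir / "concordance_summary.json").write_text(
                json.dumps(
                    {
                        "median_breakpoint_diff": rep.median_breakpoint_diff,
                        "recovered_fraction": rep.recovered_fraction_a,
                        "only_distance": [str(x) for x in rep.only_a],
                        "only_depth": [str(x) for x in rep.only_b],
                    },
                    indent=1,
                )
                + "\n"
            )
            produced["concordance"] = conc_path
            spectrum = copy_spectrum(segments, all_calls)
            spec_path = outdir / "copy_spectrum.tsv"
            spectrum.to_csv(spec_path, sep="\t", index=False)
            produced["copy_spectrum"] = spec_path
        _provenance(outdir, "cnv", [str(depth_file)], vars(config.cnv), config.seed)

    # compare: consensus, presence matrix, external evidence
    if len(calls_by_sample) >= 1:
        consensus = build_consensus(
            calls_by_sample, join_gap=config.compare.join_gap, reference=reference
        )
        write_bed3(consensus, outdir / "consensus.bed")
        matrix = fill_matrix(
            consensus, calls_by_sample, positions_by_sample,
            weak_min_positions=config.compare.weak_min_positions,
        )
        matrix_path = outdir / "presence_matrix.tsv"
        matrix.to_tsv(matrix_path)
        produced["presence_matrix"] = matrix_path
        if config.evidence:
            evidence = read_bed3(_require(config.evidence, "compare", "evidence"))
            recovered, missed = external_evidence_check(consensus, evidence)
            (outdir / "evidence_check.json").write_text(
                json.dumps(
                    {
                        "recovered": [str(x) for x in recovered],
                        "missed": [str(x) for x in missed],
                    },
                    indent=1,
                )
                + "\n"
            )
        _provenance(outdir, "compare", [], vars(config.compare), config.seed)

        # genes: overlay annotation on the consensus
        if config.annotation:
            from .genes import (
                gene_content_table,
                genes_in_regions,
                read_genes_bed,
                read_genes_gff3,
                read_homology_tsv,
            )

            ann_path = _require(config.annotation, "genes", "annotation")
            if ann_path.suffix in {".gff", ".gff3"}:
                annotation = read_genes_gff3(ann_path)
            else:
                annotation = read_genes_bed(ann_path)
            genes = genes_in_regions(annotation, consensus)
            homology = (
                read_homology_tsv(_require(config.homology, "genes", "homology"))
                if config.homology
                else None
            )
            table = gene_content_table(
                {"consensus": ("reference", consensus, genes)}, homology
            )
            genes_path = outdir / "gene_content.tsv"
            table.to_csv(genes_path, sep="\t", index=False)
            produced["gene_content"] = genes_path
            _provenance(outdir, "genes", [str(ann_path)], {}, config.seed)

    return produced
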