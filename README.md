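# dopseqkit

Analysis toolkit for **isolated-chromosome sequencing** (flow-sorted or
microdissected chromosomes amplified by DOP-PCR/WGA and sequenced), built for
the study of **B chromosomes** — supernumerary, dispensable chromosomes that
arise as segmental duplications of ordinary genomic regions. Given reads from
an isolated chromosome mapped to a reference genome, the central question is:
*which reference regions are actually present on the sampled chromosome?*

## The method

Mapped reads are filtered (`mapping quality ≥ 20`, `aligned length ≥ 20 bp`)
and collapsed into **merged read positions** (maximal runs of overlapping
alignments). Regions present on the sampled chromosome produce densely spaced
positions; the amplification/contamination background produces sparse ones.
dopseqkit models the inter-position gaps *g* as a two-component exponential
mixture

> p(g) = w λ_t e^(−λ_t g) + (1 − w) λ_b e^(−λ_b g),  λ_t > λ_b

fitted by EM (deterministic median-split initialization), then decodes the
most probable target/background state path along each chromosome with a
two-state Viterbi smoother (symmetric switch probability, default 10⁻³).
Maximal target-state runs become region calls, tiered **strong** (">5 merged
positions, recovered automatically) or **weak** ("~", 2–5 positions, kept
only when another sample supports the region); unusually long internal gaps
become deletion calls.

Independently, whole-genome sequencing depth in 1 kb windows is normalized so
that 1.0 = diploid baseline (genome-wide median), median-smoothed, and
segmented into constant-copy-number stretches with
`copy number = round(2 × normalized depth)`. For an individual carrying *n_B*
B chromosomes, `per-B copies = (copy number − 2) / n_B`; e.g. 6 extra copies
with n_B = 3 means two copies per B. A concordance report matches the two
methods' regions by best reciprocal overlap and measures their breakpoint
agreement.

Comparative layers build multi-sample consensus region sets, strong/weak
presence matrices, sample-agreement partitions, cross-species shared and
proximal region pairs, and gene/homolog content tables. The shipped data
fixtures include the published B-chromosome region catalogues of the red fox
(VVUB2/3/5/6) and Chinese raccoon dog (NPPB1–8) on the dog CanFam3.1
assembly, with BAC-clone evidence flags.

A seeded synthetic-data generator (`dopseqkit.simulate`) produces both data
types with known ground truth — planted regions, internal deletions, extra
copies — so the whole pipeline is testable without any sequencing download.

## Worked example

```python
from dopseqkit import (
    GenomicInterval, ReferenceIndex, SimulationScenario,
    simulate_positions, simulate_depth, distance_track, detect_regions,
    normalize_depth, segment_depth, concordance,
)
from dopseqkit.simulate import PlantedRegion

ref = ReferenceIndex({"chr1": 10_000_000})
scenario = SimulationScenario(
    reference=ref,
    planted_regions=[PlantedRegion(
        GenomicInterval("chr1", 4_000_000, 5_000_000), extra_copies=4)],
    seed=11,
)
positions, _ = simulate_positions(scenario)
calls, model = detect_regions(distance_track(positions))
print(f"spacing model: target mean {model.mean_target:.0f} bp, "
      f"background mean {model.mean_background:.0f} bp")
for c in calls:
    print(f"call: {c.interval}  tier={c.tier}  positions={c.n_positions}")

depth, _ = simulate_depth(scenario)
segments = segment_depth(normalize_depth(depth))
report = concordance(calls, segments)
print(f"median breakpoint difference: {report.median_breakpoint_diff:.0f} bp")
```

prints

```
spacing model: target mean 219 bp, background mean 51669 bp
call: chr1:4000269-5000000  tier=strong  positions=3076
median breakpoint difference: 134 bp
```

The detector recovered the planted 1 Mb region (true span 4,000,000–5,000,000;
the 269 bp start error is the expected first-position offset at 200 bp target
spacing), the fitted mixture means sit near the configured 200 bp target /
50 kb background spacing, and the spacing-based and depth-based breakpoints
agree to well under one 1 kb depth window.

A `dopseqkit` console script exposes the same stages
(`simulate`, `detect`, `cnv`, `compare`, `genes`, `run`) over BED/bedGraph/
TSV/YAML files; `dopseqkit run --config pipeline.yaml --out DIR` executes the
whole pipeline with a provenance log.

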