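# Methods

## Problem setting

A chromosome isolated by flow sorting (hundreds of copies) or microdissection
(a single copy) is amplified (DOP-PCR or WGA), sequenced, and mapped to a
related reference genome. Reads derived from the chromosome pile up densely
over the reference regions it actually carries; contamination and
amplification noise scatter sparsely genome-wide. dopseqkit infers the
present regions from this spacing contrast, and — when whole-genome
sequencing (WGS) of the same individual is available — estimates how many
copies of each region the supernumerary (B) chromosomes carry.

## Coordinates and interval algebra

All coordinates are 0-based half-open; `length = end − start`. Region strings
of the form `CFA13:47122582-47327423` are ingested verbatim as
`(start, end)`; with this convention the shipped fox catalogue (14 regions)
sums to exactly 7,708,416 bp and the raccoon dog catalogue (27 regions) to
8,510,228 bp, matching their published per-species totals, so no ±1 offset
adjustment is applied. The absolute offset convention of the original
catalogues (whether they were 1-based inclusive) cannot be fixed by these
sums; only the lengths are pinned. Book-ended intervals (gap equal to the
join gap) merge — deterministic and consistent with half-open coordinates.
Chromosome names match by exact string equality.

## Read filtering and merged positions

Reads are kept when `mapping_quality ≥ 20` and `aligned_length ≥ 20`
(inclusive thresholds, the conventional reading of a keep-threshold), the
upstream contamination flag is unset, and the read midpoint lies outside the
reference exclusion masks. Masks exist because telomeric and centromeric
repeat stretches generate recurrent false-positive signals in cross-species
mapping; regions composed of masked sequence are therefore never called.
Duplicate reads are not collapsed before merging: every filtered record
counts equally. Overlapping or book-ended reads merge into positions
(join gap 0), so all inter-position gaps are strictly positive and
`log10(gap + 1)` rainfall exports are safe.

## The spacing model and segmentation

Inter-position gaps are modelled as a two-component exponential mixture
(target rate λ_t > background rate λ_b). The EM fit is deterministic:
components initialize at the means of gaps below/above the median gap;
convergence when the log-likelihood improves by < `tol` (default 1e-8, max
500 iterations). At least 20 gaps are required. If the fitted mean ratio
(background/target) is below 5 the model is flagged as carrying no target
signal and the detector returns no calls — on a single spacing scale the
mixture split is arbitrary and any "regions" would be noise.

Smoothing is a two-state Viterbi decode: emissions are the fitted
exponentials, the switch probability is symmetric (default 1e-3 — roughly
one spurious state flip per thousand gaps under the null), and initial state
probabilities are the mixture weights. The decode is verified against
exhaustive enumeration of all 2^n paths on every instance with ≤ 12 gaps
(property-based test). A maximal run of k target-state gaps becomes a call
spanning the k+1 involved positions. The whole detector is deterministic
given its input. A plain threshold mode (`gap < cutoff`) is provided for
comparison.

Tiers follow the catalogue convention: **strong** for calls with more than
`strong_min` (default 5) merged positions — the automatic-recovery tier —
and **weak** for 2..strong_min positions. The published legend defines ">5"
as automatic and "<5" as manual, leaving exactly 5 undefined; we assign 5 to
weak (the conservative choice) and expose `strong_min`. Whether the original
counts were merged positions or raw reads is unstated; we count merged
positions. Weak calls never create consensus rows; they only rescue a
sample's presence in a row another sample established — mirroring manual
recovery by cross-sample evidence.

Internal deletions: within a call, gaps longer than
`max(min_del, Q(quantile))` — `min_del` 10 kb, `quantile` 0.999 of the
fitted target exponential — become deletion intervals spanning from the end
of the left flanking position to the start of the right one.

## Copy number from windowed depth

WGS depth is counted in fixed windows (default 1000 bp; a warning is issued
below 500 bp, where uneven cross-species mapping floods the output with
spurious deletions). Normalization divides by the genome-wide **median**
window count — median, not mean, so the amplified B regions themselves do
not shift the baseline; masked windows are excluded from the median but are
still normalized. Convention: normalized depth 1.0 = diploid, so
`copy number = round(2 × nd)` (half rounds up) and extra copies = CN − 2.
This makes the canonical worked example exact: 6 extra copies in an
individual with three Bs is two copies per B; 20 extra copies is 6.67,
reported as 7 (ties round away from zero). Per-B values below 1 are reported
rather than suppressed — they indicate a region missing from some of the
individual's Bs (B heterogeneity). No GC-bias correction is applied.

Segmentation median-filters the normalized track (span 5 windows) and takes
maximal runs of identical rounded CN; a segment's reported depth is the mean
of its raw windows. At realistic depth (≈30 reads/window) the per-window CN
estimate of a highly amplified region is noisy enough that a region
legitimately fragments into adjacent segments of neighbouring integer CN;
the region-level object for cross-method comparison is therefore the
**amplified run**: CN > 2 segments coalesced when book-ended or separated by
at most 5 windows. Concordance matches spacing-based calls to amplified runs
by best reciprocal overlap (default fraction 0.5) and pools |start−start|
and |end−end| over matched pairs into a median breakpoint difference. The
copy spectrum counts segments per extra-copy value over segments overlapping
the region calls — region parts with different copy numbers count
separately.

## Synthetic data: what it emulates and what it does not

`SimulationScenario` fixes the study conditions: three B chromosomes per
individual, 1 kb windows, 30 reads per diploid window, 200 bp mean target
spacing against 50 kb background, 10% position dropout. Position starts
follow Exponential spacing (dense inside planted regions minus their
deletions, sparse elsewhere); widths are Exponential(50 bp) + a 36 bp
read-length floor — insert geometry is not modelled because only spacing
carries signal downstream. Depth windows are Poisson(baseline × CN/2) with
CN decided at the window midpoint. One master seed with fixed per-track
stream offsets (0 = positions, 1 = depth) makes every output reproducible
and the tracks mutually independent.

Not emulated: sequence content (no FASTQ, no aligner — the pipeline starts
at mapped positions), locus-specific DOP-PCR/WGA amplification bias (the
uniform dropout rate is a declared stand-in), mappability and GC structure,
and a second contaminant genome (contamination is a uniform background rate;
the human-read removal step of real pipelines is upstream of our inputs).
Passing tests on this generator therefore demonstrate correctness of the
inference given the stated spacing/depth laws, not robustness to real
amplification artefacts.

## Problem sizes used in the shipped checks

The simulation-backed checks run on a 20 Mb single-chromosome reference with
five planted regions of 0.2–2 Mb carrying 1–6 extra copies (~25,000 merged
positions, 20,000 depth windows), with 20-seed panels for the null
false-positive and planted-recovery properties — large enough for stable
statistics while keeping the full suite fast on one CPU. On this scenario
the two detection routes recover all five regions and their median
breakpoint difference is a few hundred bp, comfortably below the 1 kb window
resolution that bounds depth-based breakpoint placement.

## Known limitations

- Exponential-mixture identifiability: with genuinely single-scale input the
  EM split is arbitrary; the mean-ratio-5 guard refuses such fits rather
  than calling regions.
- Boundary placement of spacing-based calls is limited by the first/last
  dense position (expected error ≈ the target spacing mean); depth-based
  boundaries are limited by the window size.
- The weak tier needs at least 2 positions inside a consensus row; a region
  represented by a single read position in a sample is treated as absent.
- Gene homology counts assume a well-formed per-gene export; the contract
  `one_to_one ≤ homologs ≤ genes` is enforced and malformed inputs are
  rejected rather than reported.
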