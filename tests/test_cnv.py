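"""Depth normalization, constant-CN segmentation, per-B copies, concordance."""

import numpy as np
import pytest

from dopseqkit.cnv import (
    DegenerateInputError,
    DepthSegment,
    DepthTrack,
    amplified_runs,
    concordance,
    copy_spectrum,
    normalize_depth,
    per_b_copies,
    read_bedgraph,
    segment_depth,
    write_bedgraph,
)
from dopseqkit.detect import RegionCall
from dopseqkit.intervals import GenomicInterval
from dopseqkit.simulate import PlantedRegion, simulate_depth


def iv(c, s, e):
    return GenomicInterval(c, s, e)


def flat_track(value=30, n=500, window=1000, chrom="chr1"):
    return DepthTrack(window, {chrom: np.full(n, value, dtype=np.int64)})


class TestNormalize:
    def test_flat_track_normalizes_to_one(self):
        track = normalize_depth(flat_track())
        assert track.genome_median == 30
        assert np.allclose(track.normalized["chr1"], 1.0)

    def test_masked_windows_excluded_from_median_but_normalized(self):
        counts = np.full(500, 30, dtype=np.int64)
        counts[:250] = 300  # masked half would double the median
        mask = np.zeros(500, dtype=bool)
        mask[:250] = True
        track = DepthTrack(1000, {"chr1": counts}, mask={"chr1": mask})
        track = normalize_depth(track)
        assert track.genome_median == 30
        assert np.allclose(track.normalized["chr1"][:250], 10.0)

    def test_too_few_windows(self):
        with pytest.raises(ValueError, match="100 windows"):
            normalize_depth(flat_track(n=99))

    def test_zero_median_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            normalize_depth(flat_track(value=0))

    def test_null_simulation_median_within_5_percent(self, null_scenario):
        track, _ = simulate_depth(null_scenario(1))
        track = normalize_depth(track)
        assert abs(track.genome_median - 30) / 30 < 0.05

    def test_small_window_warns(self):
        with pytest.warns(UserWarning, match="window size"):
            DepthTrack(200, {"chr1": np.zeros(10, dtype=np.int64)})


class TestSegment:
    def test_flat_genome_single_segment_per_chromosome(self):
        track = DepthTrack(
            1000,
            {
                "chr1": np.full(300, 30, dtype=np.int64),
                "chr2": np.full(200, 30, dtype=np.int64),
            },
        )
        segments = segment_depth(normalize_depth(track))
        assert len(segments) == 2
        assert all(s.copy_number == 2 for s in segments)
        assert segments[0].interval == iv("chr1", 0, 300_000)

    def test_segments_conserve_windows(self):
        rng = np.random.default_rng(0)
        track = DepthTrack(1000, {"chr1": rng.poisson(30, 1000)})
        segments = segment_depth(normalize_depth(track))
        assert sum(s.interval.length() for s in segments) == 1000 * 1000

    def test_noiseless_input_recovers_planted_cn_exactly(self):
        counts = np.full(1000, 30, dtype=np.int64)
        counts[400:500] = 120  # CN 8
        counts[700:720] = 0  # homozygous deletion
        segments = segment_depth(normalize_depth(DepthTrack(1000, {"chr1": counts})))
        by_cn = {s.copy_number: s for s in segments}
        assert by_cn[8].interval == iv("chr1", 400_000, 500_000)
        assert by_cn[0].interval == iv("chr1", 700_000, 720_000)

    def test_planted_amplification_boundaries_within_two_windows(
        self, five_region_scenario
    ):
        scen = five_region_scenario(42)
        track, _ = simulate_depth(scen)
        segments = segment_depth(normalize_depth(track))
        target = scen.planted_regions[4].interval  # extra 6: strongest signal
        runs = [r for r in amplified_runs(segments) if r.overlap(target) > 0]
        assert len(runs) == 1
        assert abs(runs[0].start - target.start) <= 2000
        assert abs(runs[0].end - target.end) <= 2000
        # window-level copy estimates round to the planted CN 8 on average
        inside = [
            s for s in segments
            if s.copy_number > 2 and s.interval.overlap(target) > 0
        ]
        mean_nd = np.average(
            [s.normalized_depth for s in inside],
            weights=[s.interval.length() for s in inside],
        )
        assert round(2 * mean_nd * track.genome_median / 30.0) == 8


class TestPerB:
    @pytest.mark.parametrize(
        "extra, n_b, exact, reported",
        [(6, 3, 2.0, 2), (20, 3, 20 / 3, 7), (0, 3, 0.0, 0), (2, 3, 2 / 3, 1)],
    )
    def test_worked_examples(self, extra, n_b, exact, reported):
        seg = DepthSegment(iv("chr1", 0, 1000), (2 + extra) / 2, 2 + extra)
        got_exact, got_reported = per_b_copies(seg, n_b)
        assert got_exact == pytest.approx(exact)
        assert got_reported == reported

    def test_invalid_n_b(self):
        with pytest.raises(ValueError):
            per_b_copies(DepthSegment(iv("chr1", 0, 1000), 1.0, 2), 0)


def seg(c, s, e, cn):
    return DepthSegment(iv(c, s, e), cn / 2, cn)


class TestConcordance:
    def test_identical_sets_have_zero_median_and_full_recovery(self):
        regions = [iv("chr1", 10_000, 50_000), iv("chr1", 200_000, 400_000)]
        segments = [seg("chr1", r.start, r.end, 4) for r in regions]
        rep = concordance(regions, segments)
        assert rep.median_breakpoint_diff == 0
        assert rep.recovered_fraction_a == 1.0
        assert rep.only_a == [] and rep.only_b == []

    def test_constant_shift_gives_that_median(self):
        regions = [iv("chr1", 10_000, 50_000), iv("chr1", 200_000, 400_000)]
        segments = [seg("chr1", r.start + 700, r.end + 700, 4) for r in regions]
        rep = concordance(regions, segments)
        assert rep.median_breakpoint_diff == 700

    def test_median_symmetric_under_swap(self):
        a = [iv("chr1", 10_000, 50_000), iv("chr1", 200_000, 300_000)]
        b = [seg("chr1", 9_000, 52_000, 4), seg("chr1", 210_000, 290_000, 5)]
        rep_ab = concordance(a, b)
        swapped = concordance(
            [s.interval for s in b],
            [seg("chr1", x.start, x.end, 4) for x in a],
        )
        assert rep_ab.median_breakpoint_diff == swapped.median_breakpoint_diff

    def test_unmatched_regions_reported(self):
        regions = [iv("chr1", 10_000, 50_000), iv("chr2", 0, 10_000)]
        segments = [seg("chr1", 10_000, 50_000, 4), seg("chr3", 0, 10_000, 6)]
        rep = concordance(regions, segments)
        assert [str(x) for x in rep.only_a] == ["chr2:0-10000"]
        assert [str(x) for x in rep.only_b] == ["chr3:0-10000"]

    def test_adjacent_amplified_parts_coalesce(self):
        # one region split into CN 4 | CN 8 parts is still one amplified run
        segments = [seg("chr1", 0, 50_000, 4), seg("chr1", 50_000, 80_000, 8)]
        assert amplified_runs(segments) == [iv("chr1", 0, 80_000)]


class TestCopySpectrum:
    def test_no_overlap_empty(self):
        segments = [seg("chr1", 0, 10_000, 8)]
        assert len(copy_spectrum(segments, [iv("chr2", 0, 10_000)])) == 0

    def test_split_region_counts_parts_separately(self):
        region = iv("chr1", 0, 30_000)
        segments = [
            seg("chr1", 0, 10_000, 2),
            seg("chr1", 10_000, 20_000, 8),
            seg("chr1", 20_000, 30_000, 2),
        ]
        df = copy_spectrum(segments, [region]).set_index("extra_copies")
        assert df.loc[0, "n_segments"] == 2
        assert df.loc[6, "n_segments"] == 1

    def test_noiseless_simulation_matches_planted_multiset(self, five_region_scenario):
        scen = five_region_scenario(42)
        # noiseless: expected counts, no Poisson draw
        counts = np.full(20_000, 30, dtype=np.int64)
        for pr in scen.planted_regions:
            a, b = pr.interval.start // 1000, pr.interval.end // 1000
            counts[a:b] = 30 * (2 + pr.extra_copies) // 2
        track = normalize_depth(DepthTrack(1000, {"chr1": counts}))
        segments = segment_depth(track)
        df = copy_spectrum(segments, [pr.interval for pr in scen.planted_regions])
        got = dict(zip(df["extra_copies"], df["n_segments"]))
        assert got == {1: 1, 2: 1, 3: 1, 4: 1, 6: 1}


class TestRegionCallInput:
    def test_concordance_accepts_region_calls(self):
        calls = [RegionCall(iv("chr1", 10_000, 50_000), 10, 100.0, tier="strong")]
        segments = [seg("chr1", 10_000, 50_000, 4)]
        rep = concordance(calls, segments)
        assert rep.median_breakpoint_diff == 0


def test_bedgraph_round_trip(tmp_path):
    track = DepthTrack(1000, {"chr1": np.arange(150, dtype=np.int64)})
    p = tmp_path / "depth.bedgraph"
    write_bedgraph(track, p)
    back = read_bedgraph(p, window_size=1000)
    assert np.array_equal(back.counts["chr1"], track.counts["chr1"])
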