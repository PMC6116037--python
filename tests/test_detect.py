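"""Spacing-model fit, two-state segmentation, tiers, and deletion calls."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import brute_force_path

from dopseqkit.detect import (
    InsufficientDataError,
    RegionCall,
    SpacingModel,
    assign_tiers,
    call_deletions,
    detect_regions,
    fit_spacing_model,
    region_report,
    segment_chromosome,
    threshold_segment,
    viterbi_path,
)
from dopseqkit.intervals import GenomicInterval, parse_region
from dopseqkit.positions import MergedPosition, distance_track
from dopseqkit.simulate import simulate_positions


def iv(c, s, e):
    return GenomicInterval(c, s, e)


def positions_from_starts(starts, width=50, chrom="chr1"):
    return [MergedPosition(iv(chrom, int(s), int(s) + width)) for s in starts]


class TestSpacingModelFit:
    def test_recovers_mixture_means_within_10_percent(self):
        rng = np.random.default_rng(7)
        gaps = np.concatenate(
            [rng.exponential(100, 5000), rng.exponential(10_000, 5000)]
        )
        model = fit_spacing_model(gaps)
        assert model.converged
        assert abs(model.mean_target - 100) / 100 < 0.10
        assert abs(model.mean_background - 10_000) / 10_000 < 0.10
        assert not model.no_target_signal

    def test_identical_gaps_flag_no_signal(self):
        model = fit_spacing_model(np.full(100, 500.0))
        assert model.no_target_signal

    def test_single_scale_flags_no_signal(self):
        rng = np.random.default_rng(3)
        model = fit_spacing_model(rng.exponential(1000, 2000))
        assert model.no_target_signal

    def test_too_few_gaps(self):
        with pytest.raises(InsufficientDataError):
            fit_spacing_model(np.ones(19) * 100)

    def test_target_is_short_spacing_component(self):
        rng = np.random.default_rng(11)
        gaps = np.concatenate([rng.exponential(50, 500), rng.exponential(5000, 500)])
        model = fit_spacing_model(gaps)
        assert model.lambda_target > model.lambda_background


MODEL = SpacingModel(
    lambda_target=1 / 100, lambda_background=1 / 10_000,
    mixing_weight=0.4, converged=True, log_likelihood=0.0,
)


class TestViterbi:
    @settings(derandomize=True, max_examples=300, deadline=None)
    @given(
        st.lists(st.floats(1.0, 1e6), min_size=1, max_size=12),
        st.floats(1e-5, 0.4),
    )
    def test_matches_exhaustive_enumeration(self, gaps, penalty):
        got = viterbi_path(np.array(gaps), MODEL, penalty)
        want = brute_force_path(gaps, MODEL, penalty)
        assert np.array_equal(got, want)

    def test_all_target_like_gaps_give_single_region(self):
        positions = positions_from_starts(np.arange(30) * 120)
        track = distance_track(positions)
        calls = segment_chromosome(track, MODEL)
        assert len(calls) == 1
        assert calls[0].n_positions == 30
        assert calls[0].interval == iv("chr1", 0, 29 * 120 + 50)

    def test_no_signal_model_returns_no_calls_with_warning(self):
        flat = SpacingModel(1 / 100, 1 / 300, 0.5, True, 0.0)
        track = distance_track(positions_from_starts(np.arange(10) * 500))
        with pytest.warns(UserWarning, match="no target signal"):
            assert segment_chromosome(track, flat) == []

    def test_scale_equivariance(self):
        """Multiplying all coordinates by a constant rescales calls identically."""
        starts = np.concatenate(
            [np.arange(20) * 200, 100_000 + np.arange(20) * 150]
        )
        k = 10
        a = segment_chromosome(distance_track(positions_from_starts(starts)), MODEL)
        scaled = SpacingModel(
            MODEL.lambda_target / k, MODEL.lambda_background / k,
            MODEL.mixing_weight, True, 0.0,
        )
        b = segment_chromosome(
            distance_track(positions_from_starts(starts * k, width=50 * k)), scaled
        )
        assert [(c.interval.start * k, c.interval.end * k) for c in a] == [
            (c.interval.start, c.interval.end) for c in b
        ]

    def test_threshold_mode_agrees_on_well_separated_input(self):
        starts = np.concatenate([np.arange(20) * 200, 500_000 + np.arange(20) * 200])
        track = distance_track(positions_from_starts(starts))
        hmm = segment_chromosome(track, MODEL)
        thr = threshold_segment(track, cutoff=1000)
        assert [c.interval for c in hmm] == [c.interval for c in thr]


class TestTiers:
    @pytest.mark.parametrize(
        "n_positions, tier", [(6, "strong"), (5, "weak"), (3, "weak"), (2, "weak")]
    )
    def test_boundaries(self, n_positions, tier):
        call = RegionCall(iv("chr1", 0, 100), n_positions, 10.0)
        assert assign_tiers([call])[0].tier == tier

    def test_single_position_dropped(self):
        assert assign_tiers([RegionCall(iv("chr1", 0, 100), 1, 0.0)]) == []

    def test_strong_min_validated(self):
        with pytest.raises(ValueError):
            assign_tiers([], strong_min=1)


class TestDeletions:
    def test_large_internal_gap_called(self):
        # dense 200 bp spacing with one 170 kb void
        starts = np.concatenate(
            [np.arange(50) * 200, 170_000 + 50 * 200 + np.arange(50) * 200]
        )
        track = distance_track(positions_from_starts(starts, width=50))
        model = SpacingModel(1 / 200, 1 / 50_000, 0.5, True, 0.0)
        call = RegionCall(
            iv("chr1", 0, int(starts[-1]) + 50), len(starts), 200.0
        )
        out = call_deletions(call, track, model)
        assert len(out.deletions) == 1
        assert out.deletions[0].length() > 160_000

    def test_uniform_dense_region_has_none(self):
        starts = np.arange(100) * 200
        track = distance_track(positions_from_starts(starts))
        model = SpacingModel(1 / 200, 1 / 50_000, 0.5, True, 0.0)
        call = RegionCall(iv("chr1", 0, int(starts[-1]) + 50), 100, 200.0)
        assert call_deletions(call, track, model).deletions == []

    def test_fox_cfa13_region_voids_recover_printed_deletions(self):
        """Positions tiling the fox CFA13:34 Mb region minus its two known
        voids must yield exactly those two deletions at the void edges."""
        region = parse_region("CFA13:34034756-34423363")
        voids = [
            parse_region("CFA13:34121352-34138888"),
            parse_region("CFA13:34202633-34373142"),
        ]
        starts = []
        cursor = region.start
        while cursor < region.end - 50:
            if not any(v.start < cursor + 50 and cursor < v.end for v in voids):
                starts.append(cursor)
            cursor += 200
        # snap flanking positions to the void edges
        positions = []
        for s in starts:
            end = s + 50
            for v in voids:
                if s < v.start < end:
                    end = v.start
            positions.append(MergedPosition(iv("CFA13", s, end)))
        track = distance_track(positions)
        model = SpacingModel(1 / 200, 1 / 50_000, 0.5, True, 0.0)
        call = RegionCall(region, len(positions), 200.0)
        out = call_deletions(call, track, model)
        assert len(out.deletions) == 2
        for got, want in zip(out.deletions, voids):
            assert abs(got.start - want.start) < 200
            assert abs(got.end - want.end) < 200


class TestEndToEnd:
    def test_planted_regions_recovered_single_seed(self, five_region_scenario):
        scen = five_region_scenario(42)
        pos, _ = simulate_positions(scen)
        calls, model = detect_regions(distance_track(pos))
        strong = [c for c in calls if c.tier == "strong"]
        planted = [pr.interval for pr in scen.planted_regions]
        for p in planted:
            assert sum(1 for c in strong if c.interval.overlap(p) > 0) == 1
        assert all(
            any(c.interval.overlap(p) > 0 for p in planted) for c in strong
        )

    def test_region_report_totals(self):
        calls = [
            RegionCall(iv("chr1", 0, 100), 6, 10.0, tier="strong", sample_id="s1"),
            RegionCall(iv("chr1", 500, 800), 4, 50.0, tier="weak", sample_id="s1"),
        ]
        df = region_report(calls)
        assert len(df) == 2
        assert df["size_bp"].sum() == 400

    def test_empty_report(self):
        assert len(region_report([])) == 0
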