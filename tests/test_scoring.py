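"""Core caller: masking, null fits, thresholding, consistency, traceback."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

from tilewave import (
    BasePairSignal,
    HitRegion,
    ScoringParams,
    SimParams,
    call_peaks,
    consistency_filter,
    evaluate_calls,
    fit_level_stats,
    level_log_ratios,
    merge_hits,
    multilevel_decompose,
    simulate_array,
    threshold_candidates,
    traceback_region,
    validate_probe_table,
)
from tilewave.filters import dominant_descendants
from tilewave.scoring import LevelStats, PreparedTable, fit_stats


def _pyramids(red_vals, green_vals, max_level):
    r = multilevel_decompose(BasePairSignal("chr1", 0, red_vals), max_level)
    g = multilevel_decompose(BasePairSignal("chr1", 0, green_vals), max_level)
    return r, g


class TestLevelLogRatios:
    def test_equal_channels_give_zero(self):
        vals = np.full(256, 50.0)
        r, g = _pyramids(vals, vals.copy(), 4)
        ratios = level_log_ratios(r, g, floor=1.0)
        for m in range(1, 5):
            assert np.ma.allclose(ratios[m], 0.0, atol=1e-12)
            assert not ratios[m].mask.any()

    def test_below_floor_masked(self):
        red = np.full(64, 0.25)  # approx coefficients stay < 1
        green = np.full(64, 3.0)
        r, g = _pyramids(red, green, 1)
        ratios = level_log_ratios(r, g, floor=1.0)
        assert ratios[1].mask.all()

    def test_mismatched_pyramids_rejected(self, rng):
        r, _ = _pyramids(rng.uniform(1, 2, 256), rng.uniform(1, 2, 256), 4)
        g = multilevel_decompose(
            BasePairSignal("chr2", 10, rng.uniform(1, 2, 256)), 4
        )
        with pytest.raises(ValueError, match="geometry"):
            level_log_ratios(r, g)

    def test_null_log_ratio_mean_bounded_by_jensen_offset(self):
        # red = green * exp(eps), eps ~ N(0, 0.3^2) per probe: coefficients
        # average e^eps across probes, so the level mean sits between 0 and
        # the multiplicative-noise offset ln E[e^eps] = sd^2/2 (mean-centering,
        # the default, removes it before thresholding)
        rng = np.random.default_rng(11)
        sd = 0.3
        n_probes = 10_000
        green = np.full(n_probes * 38, 100.0)
        eps = rng.normal(0, sd, n_probes)
        red = green * np.exp(np.repeat(eps, 38))
        r, g = _pyramids(red, green, 8)
        ratios = level_log_ratios(r, g)
        for m in range(4, 9):
            vals = np.ma.compressed(ratios[m])
            se = vals.std(ddof=1) / np.sqrt(len(vals))
            assert -3 * se <= vals.mean() <= sd**2 / 2 + 3 * se


class TestFitLevelStats:
    def test_two_point_sample(self):
        st_ = fit_level_stats(np.array([-1.0, 1.0]), level=5)
        assert st_.mu == pytest.approx(0.0)
        assert st_.sigma == pytest.approx(np.sqrt(2))
        assert st_.n_used == 2

    def test_constant_sample_sigma_zero(self):
        assert fit_level_stats(np.full(10, 0.7), 5).sigma == 0.0

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            fit_level_stats(np.ma.masked_array([1.0, 2.0], [False, True]), 5)

    def test_robust_option_ignores_outliers(self, rng):
        vals = np.concatenate([rng.normal(0, 1, 5000), np.full(100, 50.0)])
        plain = fit_level_stats(vals, 5)
        robust = fit_level_stats(vals, 5, robust=True)
        assert robust.sigma < plain.sigma
        assert robust.sigma == pytest.approx(1.0, rel=0.1)

    def test_sigma_decreases_with_level_on_null_arrays(self):
        # coarser coefficients average more probes, shrinking the spread
        params = ScoringParams(m1=8, m2=10)
        for seed in range(1, 11):
            probes, _ = simulate_array(
                SimParams(genome_length=1_000_000, gap_fraction=0.0, n_peaks=0),
                seed=seed,
            )
            prep = PreparedTable(validate_probe_table(probes), params.m2)
            stats = fit_stats(prep.ratio_maps(prep.red_values, params), params)
            sig = [stats[m].sigma for m in range(6, 11)]
            assert all(a > b for a, b in zip(sig, sig[1:]))


def _gaussian_ratio_fixture(rng, params, n0=100_000):
    """Masked per-level ratio dicts drawn from an exact standard normal."""
    ratios, stats = {}, {}
    n = n0
    for m in params.support_levels:
        vals = rng.normal(0.0, 1.0, n)
        ratios[m] = np.ma.masked_array(vals, np.zeros(n, bool))
        stats[m] = fit_level_stats(vals, m)
        n //= 2
    return ratios, stats


class TestThresholdCandidates:
    def test_infinite_alpha_empty(self, rng):
        params = ScoringParams(m1=4, m2=5, alpha=1e9)
        ratios, stats = _gaussian_ratio_fixture(rng, params, 4096)
        assert threshold_candidates(ratios, stats, params) == set()

    def test_gaussian_null_tail_calibration(self):
        # exceedance of mu + alpha*sigma on an exact Gaussian null matches
        # the one-sided normal tail within 3 binomial standard errors
        rng = np.random.default_rng(123)
        params = ScoringParams(m1=4, m2=4, alpha=3.0, center=True)
        ratios, stats = _gaussian_ratio_fixture(rng, params)
        for m in params.support_levels:
            cand = {n for (lm, n) in threshold_candidates(ratios, stats, params)
                    if lm == m}
            n = ratios[m].count()
            p = norm.sf(3.0)
            se = np.sqrt(p * (1 - p) / n)
            assert abs(len(cand) / n - p) <= 3 * se

    def test_candidate_sets_nested_in_alpha(self, rng):
        params3 = ScoringParams(m1=4, m2=5, alpha=3.0)
        ratios, stats = _gaussian_ratio_fixture(rng, params3, 8192)
        c3 = threshold_candidates(ratios, stats, params3)
        c4 = threshold_candidates(ratios, stats, replace(params3, alpha=4.0))
        assert c4 <= c3

    def test_zero_sigma_rejected(self, rng):
        params = ScoringParams(m1=4, m2=4)
        ratios, stats = _gaussian_ratio_fixture(rng, params, 4096)
        stats[3] = LevelStats(3, 0.0, 0.0, 100)
        with pytest.raises(ValueError, match="sigma"):
            threshold_candidates(ratios, stats, params)


def _manual_setup(parent_level=5, length=8):
    """Hand-built ratio arrays at levels 3..5 (m1=5, m2=5)."""
    params = ScoringParams(m1=5, m2=5, alpha=2.0, min_consistent=3, center=False)
    ratios = {
        5: np.ma.masked_array(np.zeros(length), np.zeros(length, bool)),
        4: np.ma.masked_array(np.zeros(2 * length), np.zeros(2 * length, bool)),
        3: np.ma.masked_array(np.zeros(4 * length), np.zeros(4 * length, bool)),
    }
    stats = {m: LevelStats(m, 0.0, 1.0, 100) for m in (3, 4, 5)}
    return params, ratios, stats


class TestConsistencyFilter:
    def test_min_consistent_zero_keeps_callable_candidates(self, rng):
        params = ScoringParams(m1=4, m2=5, alpha=2.5, min_consistent=0)
        ratios, stats = _gaussian_ratio_fixture(rng, params, 8192)
        cands = threshold_candidates(ratios, stats, params)
        confirmed = consistency_filter(cands, ratios, stats, params)
        assert confirmed == {(m, n) for (m, n) in cands if m >= params.m1}

    def test_parent_without_support_rejected(self):
        params, ratios, stats = _manual_setup()
        ratios[5].data[2] = 10.0  # lone parent above threshold
        cands = threshold_candidates(ratios, stats, params)
        assert (5, 2) in cands
        assert consistency_filter(cands, ratios, stats, params) == set()

    def test_parent_with_supporting_children_confirmed(self):
        params, ratios, stats = _manual_setup()
        ratios[5].data[2] = 10.0
        for child in (6, 7, 8):  # dominant children of index 2
            ratios[4].data[child] = 10.0
        cands = threshold_candidates(ratios, stats, params)
        confirmed = consistency_filter(cands, ratios, stats, params)
        assert (5, 2) in confirmed

    def test_confirmed_subset_of_candidates(self, rng):
        params = ScoringParams(m1=4, m2=5, alpha=2.0, min_consistent=1)
        ratios, stats = _gaussian_ratio_fixture(rng, params, 8192)
        cands = threshold_candidates(ratios, stats, params)
        assert consistency_filter(cands, ratios, stats, params) <= cands


class TestTraceback:
    def test_level_one_spans_three_bases(self):
        for n in (0, 3, 9):
            start, end = traceback_region(1, n, origin=0, valid_len=10_000)
            assert (start, end) == (2 * n + 2, 2 * n + 5)

    @pytest.mark.parametrize("level", range(1, 9))
    def test_closed_form_matches_enumeration(self, level):
        # oracle: brute-force dominant-descendant enumeration to level 0
        for n in (0, 2, 11):
            desc = dominant_descendants(n, level)
            assert desc == list(range(desc[0], desc[-1] + 1))  # contiguity
            span = traceback_region(level, n, origin=0, valid_len=10**9)
            assert span == (desc[0], desc[-1] + 1)
            assert span[1] - span[0] <= 6 * (1 << level)

    def test_adjacent_coefficients_trace_to_overlapping_spans(self):
        for level in range(1, 9):
            a = traceback_region(level, 4, 0, 10**9)
            b = traceback_region(level, 5, 0, 10**9)
            assert b[0] <= a[1]  # overlap or abut

    def test_padding_only_span_dropped(self):
        assert traceback_region(3, 10, origin=0, valid_len=50) is None

    def test_clipping_to_valid_extent(self):
        start, end = traceback_region(3, 10, origin=100, valid_len=100)
        assert start == 100 + 94 and end == 100 + 100


class TestMergeHits:
    def test_overlapping_merge(self):
        merged = merge_hits(
            [("chr1", 100, 200, (8,), 3.0), ("chr1", 150, 300, (9,), 4.0)]
        )
        assert merged == [HitRegion("chr1", 100, 300, (8, 9), 4.0)]

    def test_disjoint_untouched(self):
        merged = merge_hits(
            [("chr1", 100, 200, (8,), 3.0), ("chr1", 300, 400, (8,), 2.0)]
        )
        assert len(merged) == 2

    def test_bookended_merge(self):
        merged = merge_hits(
            [("chr1", 100, 200, (8,), 1.0), ("chr1", 200, 250, (8,), 2.0)]
        )
        assert len(merged) == 1 and merged[0].end == 250

    def test_chromosomes_kept_separate(self):
        merged = merge_hits(
            [("chr1", 100, 200, (8,), 1.0), ("chr2", 100, 200, (8,), 1.0)]
        )
        assert len(merged) == 2

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(seed=st.integers(0, 1000), n=st.integers(1, 30))
    def test_idempotent(self, seed, n):
        rng = np.random.default_rng(seed)
        starts = rng.integers(0, 1000, n)
        items = [
            ("chr1", int(s), int(s + rng.integers(1, 100)), (8,), float(rng.normal()))
            for s in starts
        ]
        once = merge_hits(items)
        assert merge_hits(once) == once
        assert all(a.end < b.start for a, b in zip(once, once[1:]))


class TestCallPeaks:
    def test_pure_null_no_hits_at_extreme_alpha(self):
        alpha = float(norm.isf(1e-6))
        for seed in (1, 2, 3):
            probes, _ = simulate_array(
                SimParams(genome_length=2_000_000, gap_fraction=0.0, n_peaks=0),
                seed=seed,
            )
            assert call_peaks(probes, ScoringParams(m1=8, m2=9, alpha=alpha)) == []

    def test_single_spike_detected(self):
        probes, truth = simulate_array(
            SimParams(genome_length=1_000_000, gap_fraction=0.0, n_peaks=1,
                      peak_width=(1000, 1000), enrichment=(5, 5)),
            seed=3,
        )
        hits = call_peaks(probes, ScoringParams(m1=8, m2=9, alpha=4.0))
        assert evaluate_calls(hits, truth).tp == 1

    def test_scale_invariance(self):
        probes, _ = simulate_array(
            SimParams(genome_length=1_000_000, gap_fraction=0.0, n_peaks=1,
                      peak_width=(1000, 1000), enrichment=(5, 5)),
            seed=3,
        )
        params = ScoringParams(m1=8, m2=9, alpha=4.0)
        doubled = probes.assign(red=probes["red"] * 2, green=probes["green"] * 2)
        assert call_peaks(probes, params) == call_peaks(doubled, params)

    def test_hit_count_monotone_in_alpha(self, spike_array_3mb):
        probes, _ = spike_array_3mb
        counts = [
            len(call_peaks(probes, ScoringParams(m1=8, m2=9, alpha=a)))
            for a in (2.5, 3.0, 3.5, 4.0, 5.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_enlarging_m2_never_removes_existing_level_hits(self, spike_array_3mb):
        probes, _ = spike_array_3mb
        narrow = call_peaks(probes, ScoringParams(m1=8, m2=9, alpha=3.5))
        wide = call_peaks(probes, ScoringParams(m1=8, m2=10, alpha=3.5))
        # every narrow hit is still covered by a wide hit
        for h in narrow:
            assert any(
                w.chrom == h.chrom and w.start <= h.start and w.end >= h.end
                for w in wide
            )

    def test_empty_table_no_hits(self):
        empty = pd.DataFrame(columns=["chrom", "start", "end", "red", "green"])
        assert call_peaks(empty, ScoringParams()) == []
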