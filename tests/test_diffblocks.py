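"""Differential window test calibration, merging, and planted-block recovery."""

import numpy as np
import pytest

from chromcode.diffblocks import (
    DetectorConfig,
    WindowStat,
    call_blocks_all_marks,
    call_differential_blocks,
    merge_and_filter,
    scan_windows,
)
from chromcode.simulate import CohortConfig, generate_cohort
from chromcode.trackio import GenomicInterval, normalize_track
from tests.conftest import make_track


def nb_track(rng, n_bins, mean, r=10.0, n_reps=3, mark="H4Ac", condition="wt", bin_size=25):
    mean = np.broadcast_to(mean, (n_bins,))
    p = r / (r + mean)
    counts = rng.negative_binomial(r, p[None, :], size=(n_reps, n_bins)).astype(float)
    return make_track({"chr1": counts}, bin_size=bin_size, mark=mark, condition=condition)


class TestScanWindows:
    def test_identical_tracks_yield_no_signal(self):
        rng = np.random.default_rng(0)
        t = nb_track(rng, 400, 5.0)
        stats = scan_windows(t, t)
        assert all(w.p_value == 1.0 for w in stats)
        assert all(w.log2fc == 0.0 for w in stats)

    def test_hand_fold_change(self):
        # window sums: wt 100, induced 25; c=1 -> log2(26/101)
        wt = make_track({"chr1": np.full((2, 120), 2.5)})
        ind = make_track({"chr1": np.full((2, 120), 0.625)}, condition="induced")
        stats = scan_windows(wt, ind)
        assert stats[0].mean_wt == pytest.approx(100.0)
        assert stats[0].mean_induced == pytest.approx(25.0)
        assert stats[0].log2fc == pytest.approx(np.log2(26 / 101), abs=1e-9)

    def test_null_type_I_error_near_nominal(self):
        # 10,000 windows of pure NB noise in both conditions
        rng = np.random.default_rng(42)
        n_bins = 5_000_500 // 25
        wt = nb_track(rng, n_bins, 5.0)
        ind = nb_track(rng, n_bins, 5.0, condition="induced")
        stats = scan_windows(wt, ind)
        assert len(stats) == 10_000
        frac = np.mean([w.p_value < 0.05 for w in stats])
        assert 0.035 <= frac <= 0.065

    def test_poisson_fallback_warns_with_single_replicates(self):
        rng = np.random.default_rng(1)
        wt = nb_track(rng, 200, 5.0, n_reps=1)
        ind = nb_track(rng, 200, 5.0, n_reps=1, condition="induced")
        with pytest.warns(UserWarning, match="Poisson"):
            scan_windows(wt, ind)

    def test_condition_swap_negates_everything(self):
        rng = np.random.default_rng(7)
        mean = np.full(800, 5.0)
        mean[200:280] = 1.5
        wt = nb_track(rng, 800, 5.0)
        ind = nb_track(rng, 800, mean, condition="induced")
        fwd = scan_windows(wt, ind)
        rev = scan_windows(ind, wt)
        for a, b in zip(fwd, rev):
            assert a.log2fc == pytest.approx(-b.log2fc, abs=1e-12)
            assert a.p_value == pytest.approx(b.p_value, abs=1e-12)
        cfg = DetectorConfig(refine_edges=False)
        blocks_fwd = merge_and_filter(fwd, cfg)
        blocks_rev = merge_and_filter(rev, cfg)
        assert [b.interval for b in blocks_fwd] == [b.interval for b in blocks_rev]
        swap = {"decrease": "increase", "increase": "decrease"}
        assert [b.direction for b in blocks_fwd] == [
            swap[b.direction] for b in blocks_rev
        ]


class TestMergeAndFilter:
    def windows(self, triples):
        out = []
        for start, lfc, p in triples:
            out.append(
                WindowStat(GenomicInterval("chr1", start, start + 1000), 10, 10, lfc, p)
            )
        return out

    def test_fold_change_threshold_excludes_significant_but_flat(self):
        blocks = merge_and_filter(self.windows([(0, 0.3, 0.01)]))
        assert blocks == []

    def test_three_consecutive_windows_merge_to_union(self):
        blocks = merge_and_filter(
            self.windows([(0, -0.9, 0.01), (500, -1.1, 0.001), (1000, -0.8, 0.02)])
        )
        assert len(blocks) == 1
        b = blocks[0]
        assert (b.interval.start, b.interval.end) == (0, 2000)
        assert b.direction == "decrease"
        assert b.n_windows == 3
        assert b.p_value == 0.001
        assert b.log2fc == pytest.approx((-0.9 - 1.1 - 0.8) / 3)

    def test_direction_change_splits_blocks(self):
        blocks = merge_and_filter(
            self.windows([(0, -0.9, 0.01), (500, 0.9, 0.01)])
        )
        assert len(blocks) == 2
        assert {b.direction for b in blocks} == {"decrease", "increase"}


class TestRecovery:
    def planted_pair(self, seed=3, start=100_000, end=102_000, lfc=1.5):
        rng = np.random.default_rng(seed)
        n_bins = 200_000 // 25
        mean = np.full(n_bins, 5.0)
        mean[start // 25 : end // 25] = 5.0 * 2.0**-lfc
        wt = nb_track(rng, n_bins, 5.0)
        ind = nb_track(rng, n_bins, mean, condition="induced")
        return wt, ind

    def test_planted_block_recovered_with_high_jaccard(self):
        wt, ind = self.planted_pair()
        blocks = call_differential_blocks(wt, ind)
        truth = GenomicInterval("chr1", 100_000, 102_000)
        best = 0.0
        for b in blocks:
            inter = min(b.interval.end, truth.end) - max(b.interval.start, truth.start)
            union = max(b.interval.end, truth.end) - min(b.interval.start, truth.start)
            if inter > 0:
                best = max(best, inter / union)
        assert best >= 0.8

    def test_block_count_monotone_in_effect_size(self):
        counts = []
        for lfc in (0.6, 1.0, 1.5, 2.5):
            cfg = CohortConfig(
                seed=9,
                n_chroms=1,
                chrom_length=300_000,
                n_genes=30,
                class_counts=(12, 8, 10),
                planted_effect_log2fc=lfc,
            )
            cohort = generate_cohort(cfg)
            wt = normalize_track(cohort.track("H4Ac", "wt"))
            ind = normalize_track(cohort.track("H4Ac", "induced"))
            counts.append(len(call_differential_blocks(wt, ind)))
        assert counts == sorted(counts)


class TestAllMarks:
    def test_h3_control_stays_quiet(self, small_cohort):
        normalized = {k: normalize_track(t) for k, t in small_cohort.tracks.items()}
        blocks = call_blocks_all_marks(normalized, ["H4Ac", "H3"])
        assert len(blocks["H3"]) <= 2  # no planted effects, noise only
        assert len(blocks["H4Ac"]) > 5 * max(len(blocks["H3"]), 1)

    def test_missing_mark_skipped_and_empty_input_empty_output(self):
        assert call_blocks_all_marks({}, []) == {}
        assert call_blocks_all_marks({}, ["H4Ac"]) == {}
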