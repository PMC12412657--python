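"""BCS detection, the UBCS statistic, and the fission-time formula."""

import random

import numpy as np
import pytest

from fissionkit.formats import RegionSpec
from fissionkit.ubcs import (
    count_bcs,
    estimate_fission_time,
    find_bcs,
    ubcs_by_window,
    ubcs_for_region,
)
from oracles import bcs_bruteforce


class TestFindBcs:
    def test_three_ws_below_min_subs(self, snd_builder):
        snds = snd_builder([0, 50, 100], [True] * 3)
        assert not any(c.is_bcs for c in find_bcs(snds))

    def test_cluster_of_four_qualifies_distant_ws_does_not(self, snd_builder):
        snds = snd_builder([0, 100, 200, 290, 600], [True] * 5)
        calls = find_bcs(snds)
        marks = [c.is_bcs for c in calls]
        positions = np.array([0, 100, 200, 290, 600])
        expected = bcs_bruteforce(positions, np.ones(5, bool))
        assert marks == list(expected)
        assert marks == [True, True, True, True, False]
        for c in calls[:4]:
            lo, hi = c.supporting_window
            assert lo <= c.index * 0 + positions[c.index] < hi  # window contains it

    def test_exact_eighty_percent_boundary(self, snd_builder):
        # 5 substitutions, 4 ws: fraction exactly 0.8 qualifies; only ws are BCS
        snds = snd_builder([0, 20, 40, 60, 80], [True, True, False, True, True])
        marks = [c.is_bcs for c in find_bcs(snds)]
        assert marks == [True, True, False, True, True]

    def test_unsorted_input_rejected(self, snd_builder):
        snds = snd_builder([100, 0], [True, True])
        with pytest.raises(ValueError, match="sorted"):
            find_bcs(snds)

    def test_left_shifted_window_can_exclude_trailing_nonws(self, snd_builder):
        # ws at 0..30 qualify only through an interval that excludes the
        # non-ws run starting at 250 — a left-anchored-only scan misses it
        snds = snd_builder(
            [0, 10, 20, 30, 250, 260, 270],
            [True, True, True, True, False, False, False],
        )
        marks = [c.is_bcs for c in find_bcs(snds)]
        expected = bcs_bruteforce(
            np.array([0, 10, 20, 30, 250, 260, 270]),
            np.array([1, 1, 1, 1, 0, 0, 0], bool),
        )
        assert marks == list(expected)
        assert marks[:4] == [True] * 4

    @pytest.mark.parametrize("trial", range(30))
    def test_agrees_with_all_offsets_bruteforce(self, trial, snd_builder):
        rng = np.random.default_rng(1000 + trial)
        n = int(rng.integers(5, 300))
        positions = np.sort(rng.choice(rng.integers(2_000, 20_000), n, replace=False))
        ws = rng.random(n) < rng.uniform(0.2, 0.9)
        snds = snd_builder(positions, ws)
        assert [c.is_bcs for c in find_bcs(snds)] == list(bcs_bruteforce(positions, ws))

    def test_adding_ws_snd_never_decreases_observed(self, snd_builder):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = int(rng.integers(6, 60))
            positions = np.sort(rng.choice(5_000, n, replace=False))
            ws = rng.random(n) < 0.6
            base = int(count_bcs(positions, ws))
            # insert a ws SND inside an existing qualifying window (if any)
            calls = [c for c in find_bcs(snd_builder(positions, ws)) if c.is_bcs]
            if not calls:
                continue
            lo, hi = calls[0].supporting_window
            newpos = (lo + hi) // 2
            positions2 = np.sort(np.append(positions, newpos))
            k = int(np.searchsorted(positions2, newpos))
            ws2 = np.insert(ws, k, True)
            assert count_bcs(positions2, ws2) >= base


class TestUbcsWindows:
    def test_empty_window_is_zero(self, snd_builder):
        region = RegionSpec("chr1", 0, 1_000_000)
        with pytest.warns(UserWarning, match="no query-derived"):
            res = ubcs_for_region([], "query", region, n_perm=10, seed=1)
        assert res.observed_bcs == 0 and res.ubcs == 0.0

    def test_all_ws_labels_make_shuffle_a_noop(self, snd_builder):
        rng = np.random.default_rng(3)
        positions = np.sort(rng.choice(1_000_000, 500, replace=False))
        snds = snd_builder(positions, [True] * 500)
        wins = ubcs_by_window(snds, "query", n_perm=20, seed=5)
        assert all(w.ubcs == 0.0 for w in wins)

    def test_planted_cluster_positive_against_naive_permutation_oracle(
        self, snd_builder
    ):
        rng = np.random.default_rng(11)
        cluster = np.sort(rng.choice(300, 20, replace=False)) + 400_000
        scattered = np.sort(rng.choice(1_000_000, 80, replace=False))
        positions = np.concatenate([cluster, scattered])
        ws = np.concatenate([np.ones(20, bool), np.zeros(80, bool)])
        order = np.argsort(positions)
        positions, ws = positions[order], ws[order]
        snds = snd_builder(positions, ws)
        win = ubcs_by_window(snds, "query", n_perm=1000, seed=1)[0]
        assert win.ubcs > 0

        # independent Monte-Carlo expectation with its own shuffling code
        py_rng = random.Random(99)
        labels = list(ws)
        totals = []
        for _ in range(400):
            py_rng.shuffle(labels)
            totals.append(
                sum(bcs_bruteforce(positions, np.array(labels, bool)))
            )
        naive_expected = float(np.mean(totals))
        assert win.expected_bcs == pytest.approx(naive_expected, abs=3.0)
        assert win.observed_bcs == 20

    def test_region_equals_matching_tile(self, snd_builder):
        rng = np.random.default_rng(21)
        positions = np.sort(rng.choice(1_000_000, 300, replace=False))
        snds = snd_builder(positions, rng.random(300) < 0.5)
        tile = ubcs_by_window(snds, "query", n_perm=50, seed=9)[0]
        region = ubcs_for_region(
            snds, "query", RegionSpec("chr1", 0, 1_000_000), n_perm=50, seed=9
        )
        assert region.observed_bcs == tile.observed_bcs
        assert region.expected_bcs == tile.expected_bcs

    def test_window_smaller_than_cluster_window_rejected(self, snd_builder):
        with pytest.raises(ValueError, match="cluster_window"):
            ubcs_by_window(snd_builder([1], [True]), "query", window=100, seed=0)

    def test_determinism(self, snd_builder):
        rng = np.random.default_rng(33)
        positions = np.sort(rng.choice(2_000_000, 400, replace=False))
        snds = snd_builder(positions, rng.random(400) < 0.4)
        a = ubcs_by_window(snds, "query", n_perm=40, seed=17)
        b = ubcs_by_window(snds, "query", n_perm=40, seed=17)
        assert [w.expected_bcs for w in a] == [w.expected_bcs for w in b]


class TestFissionTime:
    def test_equal_ratios_give_zero(self):
        est = estimate_fission_time(2.8e6, 1.5, 1.0, 3.0, 2.0)
        assert est.t == pytest.approx(0.0)

    def test_zero_r1_gives_t_div(self):
        est = estimate_fission_time(2.8e6, 0.0, 1.0, 3.0, 1.0)
        assert est.t == pytest.approx(2.8e6)

    def test_direct_evaluation(self):
        est = estimate_fission_time(2.8e6, 1.2, 1.0, 2.0, 1.0)
        assert est.r1 == pytest.approx(1.2)
        assert est.r2 == pytest.approx(2.0)
        assert est.t == pytest.approx(1.12e6)
        assert not est.out_of_range

    def test_out_of_range_flagged_not_clamped(self):
        est = estimate_fission_time(1e6, 3.0, 1.0, 2.0, 1.0)
        assert est.t < 0 and est.out_of_range

    @pytest.mark.parametrize(
        "kwargs,match",
        [
            (dict(ubcs_query_bp=1, ubcs_target_bp=0, ubcs_query_tel=1,
                  ubcs_query_ctrl=1), "target breakpoint"),
            (dict(ubcs_query_bp=1, ubcs_target_bp=1, ubcs_query_tel=1,
                  ubcs_query_ctrl=0), "control"),
            (dict(ubcs_query_bp=1, ubcs_target_bp=1, ubcs_query_tel=0,
                  ubcs_query_ctrl=1), "telomeric"),
        ],
    )
    def test_degenerate_ubcs_named(self, kwargs, match):
        with pytest.raises(ZeroDivisionError, match=match):
            estimate_fission_time(1e6, **kwargs)
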