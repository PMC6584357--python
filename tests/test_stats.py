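import itertools

import numpy as np
import pandas as pd
import pytest

from protrusim.stats import (
    binned_mean_dt,
    collapse_pairs,
    conditional_dx_distribution,
    ks_compare,
    pairwise_dxdt,
    proportion_within,
    sequential_dx,
    spearman_rho,
)


class TestSequentialDx:
    def test_three_events_in_a_line(self, toy_events):
        events = toy_events([(0, 0.0, 1.0), (0, 30.0, 2.0), (0, 60.0, 3.0)])
        s = sequential_dx(events)
        assert list(s.values) == [30.0, 30.0]
        assert s.mean == 30.0

    def test_window_excludes_long_jumps(self, toy_events):
        events = toy_events([(0, 0.0, 1.0), (0, 100.0, 2.0)])
        assert sequential_dx(events).n == 0

    def test_transition_beyond_window_is_dropped_not_searched(self, toy_events):
        # 0 -> 100 jump contributes nothing; 100 -> 130 is retained
        events = toy_events([(0, 0.0, 1.0), (0, 100.0, 2.0), (0, 130.0, 3.0)])
        assert list(sequential_dx(events).values) == [30.0]

    def test_stretches_kept_separate(self, toy_events):
        events = toy_events([(0, 0.0, 1.0), (1, 30.0, 2.0)])
        assert sequential_dx(events).n == 0

    def test_time_reversal_invariance(self, toy_events):
        rng = np.random.default_rng(0)
        events = toy_events([(0, x, t) for t, x in enumerate(rng.uniform(0, 300, 15))])
        fwd = sorted(sequential_dx(events).values)
        reversed_events = events.copy()
        reversed_events["time"] = -reversed_events["time"]
        rev = sorted(sequential_dx(reversed_events).values)
        assert fwd == pytest.approx(rev)

    def test_translation_invariance(self, toy_events):
        events = toy_events([(0, x, t) for t, x in enumerate([5.0, 60.0, 33.0, 90.0])])
        shifted = events.copy()
        shifted["position_um"] += 123.4
        shifted["time"] += 55.0
        assert sorted(sequential_dx(events).values) == pytest.approx(
            sorted(sequential_dx(shifted).values)
        )

    def test_exhaustive_oracle_small_tables(self, toy_events):
        # on <= 6 events, compare against a hand enumeration
        rng = np.random.default_rng(3)
        for _ in range(25):
            n = int(rng.integers(2, 7))
            pos = rng.uniform(0, 200, n)
            t = rng.permutation(n).astype(float)
            events = toy_events([(0, p, tt) for p, tt in zip(pos, t)])
            order = np.argsort(t, kind="stable")
            expected = [
                abs(pos[order[i + 1]] - pos[order[i]])
                for i in range(n - 1)
                if abs(pos[order[i + 1]] - pos[order[i]]) <= 80.0
            ]
            assert sorted(sequential_dx(events).values) == pytest.approx(sorted(expected))

    def test_empty_summary_warns(self, toy_events):
        events = toy_events([(0, 5.0, 1.0)])
        with pytest.warns(UserWarning):
            s = sequential_dx(events)
        assert s.n == 0 and np.isnan(s.mean)

    def test_histogram_covers_window(self, toy_events):
        events = toy_events([(0, 0.0, 1.0), (0, 15.0, 2.0), (0, 90.0, 3.0), (0, 25.0, 4.0)])
        hist = sequential_dx(events).histogram()
        assert hist["count"].sum() == sequential_dx(events).n
        assert hist["bin_right_um"].iloc[-1] == 80.0


class TestProportionWithin:
    def test_none_within(self, toy_events):
        events = toy_events([(0, 0.0, 1.0), (0, 50.0, 2.0), (0, 120.0, 3.0)])
        pooled, _ = proportion_within(events, threshold=42.6)
        assert pooled == 0.0

    def test_direct_count(self, toy_events):
        # 10 transitions, exactly 2 within threshold
        xs = [0, 10, 30, 100, 170, 240, 310, 380, 450, 520, 590]
        events = toy_events([(0, float(x), float(t)) for t, x in enumerate(xs)])
        pooled, per_stretch = proportion_within(events, threshold=42.6)
        assert pooled == pytest.approx(0.2)
        assert per_stretch[0] == pytest.approx(0.2)

    def test_window_proportion_is_one_by_construction(self, toy_events):
        rng = np.random.default_rng(1)
        events = toy_events([(0, x, t) for t, x in enumerate(rng.uniform(0, 200, 20))])
        dx = sequential_dx(events, window=80.0).values
        assert float((dx <= 80.0).mean()) == 1.0


class TestPairwise:
    def test_pair_counts(self, toy_events):
        events = toy_events([(0, 0.0, 1.0), (0, 10.0, 2.0), (0, 30.0, 3.0)])
        assert len(pairwise_dxdt(events)) == 3

    def test_no_cross_stretch_pairs(self, toy_events):
        events = toy_events(
            [(0, 0.0, 1.0), (0, 10.0, 2.0), (1, 0.0, 1.0), (1, 10.0, 2.0)]
        )
        pairs = pairwise_dxdt(events)
        assert len(pairs) == 2

    def test_exhaustive_oracle(self, toy_events):
        rng = np.random.default_rng(0)
        pos = rng.uniform(0, 100, 5)
        t = rng.uniform(0, 10, 5)
        events = toy_events([(0, p, tt) for p, tt in zip(pos, t)])
        pairs = pairwise_dxdt(events)
        expected = sorted(
            (abs(pos[i] - pos[j]), abs(t[i] - t[j]))
            for i, j in itertools.combinations(range(5), 2)
        )
        got = sorted(zip(pairs["dx"], pairs["dt"]))
        assert got == pytest.approx(expected)


class TestSpearman:
    def test_perfect_anticorrelation(self, toy_events):
        pairs = pd.DataFrame({"dx": [1.0, 2.0, 3.0], "dt": [9.0, 5.0, 1.0]})
        rho, _ = spearman_rho(pairs)
        assert rho == pytest.approx(-1.0)

    def test_independent_pairs_near_zero(self):
        rng = np.random.default_rng(0)
        n = 4000
        pairs = pd.DataFrame({"dx": rng.uniform(0, 1, n), "dt": rng.uniform(0, 1, n)})
        rho, p = spearman_rho(pairs)
        assert abs(rho) < 3 / np.sqrt(n)
        assert p > 1e-4

    def test_constant_input_rejected(self):
        pairs = pd.DataFrame({"dx": [1.0, 1.0, 1.0], "dt": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            spearman_rho(pairs)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            spearman_rho(pd.DataFrame({"dx": [1.0], "dt": [2.0]}))


class TestConditionalAndBinned:
    def test_infinite_dt_max_is_unconditional(self, toy_events):
        rng = np.random.default_rng(2)
        events = toy_events([(0, x, t) for t, x in enumerate(rng.uniform(0, 150, 10))])
        pairs = pairwise_dxdt(events)
        assert sorted(conditional_dx_distribution(pairs, np.inf)) == pytest.approx(
            sorted(pairs["dx"])
        )

    def test_no_qualifying_pairs_warns(self):
        pairs = pd.DataFrame({"dx": [1.0, 2.0], "dt": [5.0, 6.0]})
        with pytest.warns(UserWarning):
            out = conditional_dx_distribution(pairs, 0.1)
        assert out.size == 0

    def test_single_pair_bin(self):
        pairs = pd.DataFrame({"dx": [15.0], "dt": [2.0]})
        out = binned_mean_dt(pairs)
        assert len(out) == 1
        assert out["bin_left_um"].iloc[0] == 10.0
        assert out["mean_dt"].iloc[0] == 2.0

    def test_empty_bins_absent(self):
        pairs = pd.DataFrame({"dx": [5.0, 75.0], "dt": [1.0, 3.0]})
        out = binned_mean_dt(pairs)
        assert list(out["bin_left_um"]) == [0.0, 70.0]


class TestKs:
    def test_identical_samples(self):
        a = np.array([1.0, 2.0, 3.0])
        stat, p = ks_compare(a, a)
        assert stat == 0.0 and p == pytest.approx(1.0)

    def test_disjoint_supports(self):
        stat, _ = ks_compare(np.arange(10.0), np.arange(100.0, 110.0))
        assert stat == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ks_compare(np.array([]), np.array([1.0]))


class TestCollapsePairs:
    def test_daughters_become_midpoint_event(self):
        events = pd.DataFrame(
            {
                "stretch_id": [0, 0, 0],
                "cell_id": [0, 0, 1],
                "position_um": [10.0, 20.0, 100.0],
                "time": [1.0, 1.0, 2.0],
                "genotype": ["wt"] * 3,
                "pair_id": pd.array(["p0", "p0", pd.NA]),
            }
        )
        out = collapse_pairs(events)
        assert len(out) == 2
        pair_row = out[out["time"] == 1.0].iloc[0]
        assert pair_row["position_um"] == pytest.approx(15.0)

    def test_residual_time_ties_broken_by_position(self, toy_events):
        events = toy_events([(0, 50.0, 1.0), (0, 10.0, 1.0), (0, 30.0, 2.0)])
        out = collapse_pairs(events)
        assert list(out["position_um"]) == [10.0, 50.0, 30.0]
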