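from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import fisher_exact

import cnacohort as cc
from cnacohort.calling import GAIN, LOSS, NORMAL
from cnacohort.stats import _welch, margin_table_probabilities


class TestExactConditionalTest:
    def test_strong_exposure_association(self):
        # gains 16/26 exposed vs 3/17 unexposed, no losses
        p = cc.exact_conditional_test([[16, 3], [0, 0], [10, 14]])
        assert p == pytest.approx(0.005821, abs=1e-6)
        assert cc.truncate_p(p, 3) == 0.005

    def test_proportional_columns_give_one(self):
        assert cc.exact_conditional_test([[2, 1], [0, 0], [4, 2]]) == pytest.approx(1.0)

    def test_zero_loss_row_reduces_to_two_by_two(self):
        p3 = cc.exact_conditional_test([[7, 0], [0, 0], [19, 17]])
        p2 = cc.exact_conditional_test([[7, 0], [19, 17]])
        assert p3 == p2

    def test_matches_fisher_oracle_on_all_small_tables(self):
        # every 2x2 table with grand total <= 16 against the closed-form
        # two-sided hypergeometric test (the full <= 30 sweep runs in the
        # acceptance suite)
        for n in range(1, 17):
            for a in range(n + 1):
                for b in range(n - a + 1):
                    for c in range(n - a - b + 1):
                        d = n - a - b - c
                        if a + c == 0 or b + d == 0:
                            continue
                        ours = cc.exact_conditional_test([[a, b], [c, d]])
                        oracle = fisher_exact([[a, b], [c, d]]).pvalue
                        assert ours == pytest.approx(oracle, abs=1e-12), (a, b, c, d)

    @settings(max_examples=60, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_enumeration_probabilities_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        total = int(rng.integers(2, 61))
        cuts = np.sort(rng.integers(0, total + 1, size=2))
        rows = [int(cuts[0]), int(cuts[1] - cuts[0]), int(total - cuts[1])]
        c1 = int(rng.integers(1, total))
        tbl = []
        rem = c1
        for r in rows:
            a = min(r, rem)
            tbl.append([a, r - a])
            rem -= a
        probs = margin_table_probabilities(tbl)
        assert sum(probs) == Fraction(1)

    @settings(max_examples=40, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_column_and_row_permutation_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        tbl = rng.integers(0, 8, size=(3, 2))
        if tbl.sum() == 0 or (tbl.sum(axis=0) == 0).any():
            return
        p = cc.exact_conditional_test(tbl)
        assert cc.exact_conditional_test(tbl[:, ::-1]) == pytest.approx(p, abs=1e-12)
        assert cc.exact_conditional_test(tbl[::-1, :]) == pytest.approx(p, abs=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            cc.exact_conditional_test([[0, 0], [0, 0]])

    def test_empty_column_rejected(self):
        with pytest.raises(ValueError):
            cc.exact_conditional_test([[3, 0], [2, 0]])


class TestTruncateP:
    def test_floor_not_round(self):
        assert cc.truncate_p(0.037440, 2) == 0.03
        assert cc.truncate_p(0.005821, 3) == 0.005

    def test_one_stays_one(self):
        assert cc.truncate_p(1.0, 2) == 1.0

    def test_decimal_artifact_guard(self):
        assert cc.truncate_p(0.29, 2) == 0.29

    def test_report_convention_switches_at_one_percent(self):
        assert cc.report_p(0.005821) == 0.005
        assert cc.report_p(0.037440) == 0.03

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            cc.truncate_p(0.5, 0)
        with pytest.raises(ValueError):
            cc.truncate_p(1.5, 2)


class TestBhFdr:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(cc.bh_fdr([0.04]), [0.04])

    def test_step_up_by_hand(self):
        np.testing.assert_allclose(cc.bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_monotone_in_sorted_order(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(0.001, 1.0, size=30)
        q = cc.bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        assert (q >= p - 1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            cc.bh_fdr([0.0, 0.5])


class TestRegionSampleState:
    def _setup(self, column):
        pm = pd.DataFrame(
            {
                "probe_id": [f"p{i}" for i in range(len(column))],
                "chrom": "1",
                "pos": np.arange(len(column)) * 1000 + 1,
            }
        )
        calls = pd.DataFrame(
            {"S": np.array(column, dtype=np.int8)}, index=pm["probe_id"].to_numpy()
        )
        region = {"chrom": "1", "start_pos": 1, "end_pos": 10_000_000}
        return cc.region_sample_state(calls, pm, region, min_run=3)["S"]

    def test_long_gain_run(self):
        assert self._setup([GAIN] * 5) == "gain"

    def test_short_run_is_normal(self):
        assert self._setup([GAIN, GAIN, NORMAL, NORMAL]) == "normal"

    def test_majority_direction_wins(self):
        assert self._setup([GAIN] * 4 + [LOSS] * 6) == "loss"

    def test_tie_goes_to_gain(self):
        assert self._setup([GAIN] * 3 + [NORMAL] + [LOSS] * 3) == "gain"


class TestWelch:
    def test_identical_groups(self):
        r = _welch(np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 3.0]))
        assert r.t == pytest.approx(0.0) and r.p == pytest.approx(1.0)

    def test_hand_computed_example(self):
        r = _welch(np.array([1.0, 2.0, 3.0]), np.array([4.0, 5.0, 6.0]))
        assert r.t == pytest.approx(-3.674, abs=1e-3)
        assert r.mean_exposed == 2.0 and r.mean_unexposed == 5.0

    def test_perfect_separation_zero_variance(self):
        r = _welch(np.array([0.0] * 4), np.array([10.0] * 4))
        assert r.p == 0.0 and r.t == -np.inf

    def test_degenerate_equal_constant_groups(self):
        r = _welch(np.array([2.0, 2.0]), np.array([2.0, 2.0]))
        assert r.t == 0.0 and r.p == 1.0

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            _welch(np.array([1.0]), np.array([1.0, 2.0]))


class TestFragileSiteIncidence:
    def _design(self):
        return pd.DataFrame(
            {
                "sample_id": ["A", "B", "C", "D"],
                "group": ["exposed", "exposed", "unexposed", "unexposed"],
            }
        )

    def _track(self):
        return pd.DataFrame(
            {"chrom": ["1"], "start": [1_000], "end": [2_000], "name": ["FRA1"]}
        )

    def _segments(self, rows):
        return pd.DataFrame(
            rows,
            columns=["sample_id", "chrom", "start_pos", "end_pos", "n_probes",
                     "state", "mean_copies"],
        )

    def test_counting_fractions(self):
        # A: 1 of 4 gains overlap (25%); B: 3 of 4 overlap (75%)
        rows = []
        for i in range(4):
            inside = i < 1
            rows.append(("A", "1", 1500 if inside else 5000 + i * 10,
                         1600 if inside else 5005 + i * 10, 3, "gain", 3.0))
        for i in range(4):
            inside = i < 3
            rows.append(("B", "1", 1500 + i if inside else 9000,
                         1600 + i if inside else 9005, 3, "gain", 3.0))
        incidence, _ = cc.fragile_site_gain_incidence(
            self._segments(rows), self._track(), self._design()
        )
        assert incidence["A"] == pytest.approx(25.0)
        assert incidence["B"] == pytest.approx(75.0)

    def test_all_inside_and_none_inside(self):
        rows = [
            ("A", "1", 1100, 1200, 3, "gain", 3.0),
            ("C", "2", 1100, 1200, 3, "gain", 3.0),
        ]
        incidence, _ = cc.fragile_site_gain_incidence(
            self._segments(rows), self._track(), self._design()
        )
        assert incidence["A"] == 100.0
        assert incidence["C"] == 0.0

    def test_samples_without_gains_score_zero(self):
        incidence, _ = cc.fragile_site_gain_incidence(
            self._segments([]), self._track(), self._design()
        )
        assert (incidence == 0.0).all()

    def test_empty_track_rejected(self):
        with pytest.raises(ValueError):
            cc.fragile_site_gain_incidence(
                self._segments([]), pd.DataFrame(), self._design()
            )
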