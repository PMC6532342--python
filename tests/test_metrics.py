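"""Performance indicators: search time, outlier fences, slopes, summaries."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from searchmatch import (
    LevelSpec,
    MetricsError,
    board_search_time,
    board_table,
    filter_outliers,
    processing_time_per_item,
    search_slope,
    summarize_session,
)


def entries(times_accuracy, hint_last=False, board_index=1, trial_id="t0", w=4, h=4, t=4):
    rows = []
    for i, (elapsed, acc) in enumerate(times_accuracy, start=1):
        rows.append(
            {
                "participant_id": "p0",
                "group": "g",
                "w": w,
                "h": h,
                "t": t,
                "trial_id": trial_id,
                "board_index": board_index,
                "move_number": i,
                "move": "0 0 0 1",
                "elapsed_time": elapsed,
                "accuracy": acc,
                "hint_used": hint_last and acc == "correct",
                "difficulty_rating": None,
            }
        )
    return pd.DataFrame(rows)


class TestBoardSearchTime:
    def test_false_moves_are_summed_into_search_time(self):
        df = entries([(1.2, "false"), (0.8, "false"), (2.0, "correct")])
        assert board_search_time(df) == pytest.approx(4.0)

    def test_single_correct_move_identity(self):
        assert board_search_time(entries([(2.74, "correct")])) == pytest.approx(2.74)

    def test_zero_elapsed_rejected(self):
        with pytest.raises(MetricsError):
            board_search_time(entries([(0.0, "correct")]))

    def test_incomplete_board_rejected(self):
        with pytest.raises(MetricsError):
            board_search_time(entries([(1.0, "false")]))


class TestFilterOutliers:
    def test_tukey_fences_with_interpolated_quartiles(self):
        # Q1=2, Q3=3, IQR=1 -> fences [0.5, 4.5]; 20 is dropped
        res = filter_outliers([1, 2, 2, 3, 20])
        assert list(res.retained) == [1, 2, 2, 3]
        assert res.n_removed == 1

    def test_all_equal_values_untouched(self):
        res = filter_outliers([5.0] * 6)
        assert res.n_removed == 0

    def test_groups_filtered_independently(self):
        vals = [1, 2, 2, 3, 20, 100, 101, 102, 101, 4]
        groups = ["a"] * 5 + ["b"] * 5
        res = filter_outliers(vals, groups)
        assert not res.mask[4]  # 20 is an outlier within a
        assert not res.mask[9]  # 4 is an outlier within b
        assert res.mask[[5, 6, 7, 8]].all()

    def test_small_group_passes_through_with_warning(self):
        with pytest.warns(UserWarning, match="outlier filter skipped"):
            res = filter_outliers([1, 2, 1000], ["a"] * 3)
        assert res.n_removed == 0

    def test_single_pass_not_iterated(self):
        # after removing 20, 3 would become an outlier of {1,2,2,3}; the
        # documented rule applies the fences once only
        res = filter_outliers([2, 2, 2, 2.1, 20])
        assert 2.1 in res.retained


class TestProcessingTimePerItem:
    def test_division_by_set_size(self):
        assert processing_time_per_item(4.0, LevelSpec(4, 4, 4)) == pytest.approx(0.25)
        assert processing_time_per_item(0.0, LevelSpec(5, 5, 4)) == 0.0

    @given(st.floats(0.001, 1e4), st.sampled_from([(4, 4), (5, 7), (8, 8)]))
    def test_identity_with_set_size(self, t_search, wh):
        level = LevelSpec(wh[0], wh[1], 4)
        assert processing_time_per_item(t_search, level) * level.set_size == pytest.approx(
            t_search, abs=1e-9
        )


class TestSearchSlope:
    def test_perfect_linear_data(self):
        df = pd.DataFrame(
            {"set_size": [16, 25, 36, 49], "search_time": [1.6, 2.5, 3.6, 4.9]}
        )
        fit = search_slope(df)
        assert fit.slope == pytest.approx(0.1)
        assert fit.stderr == pytest.approx(0.0, abs=1e-12)

    def test_constant_times_zero_slope(self):
        df = pd.DataFrame({"set_size": [16, 25, 36], "search_time": [2.0, 2.0, 2.0]})
        assert search_slope(df).slope == pytest.approx(0.0)

    def test_single_set_size_rejected(self):
        df = pd.DataFrame({"set_size": [16, 16], "search_time": [1.0, 2.0]})
        with pytest.raises(MetricsError):
            search_slope(df)

    def test_gamma_glm_cross_check(self):
        rng = np.random.default_rng(0)
        ss = rng.choice([16, 25, 36, 49, 64], size=800)
        mu = 1.0 + 0.2 * ss
        times = rng.gamma(4.0, mu / 4.0)
        df = pd.DataFrame({"set_size": ss, "search_time": times})
        fit, glm = search_slope(df, gamma=True)
        assert fit.slope == pytest.approx(0.2, abs=0.03)
        # log-link GLM: positive set-size coefficient
        assert glm.params["set_size"] > 0

    def test_synthetic_gamma_slope_recovery(self):
        """Gamma noise around a linear mean with slope 0.2: OLS on the raw
        times recovers the mean-scale slope."""
        rng = np.random.default_rng(12)
        ss = np.repeat([16, 25, 36, 49, 64], 400)
        times = rng.gamma(4.0, (0.5 + 0.2 * ss) / 4.0)
        df = pd.DataFrame({"set_size": ss, "search_time": times})
        assert search_slope(df).slope == pytest.approx(0.2, abs=0.03)


class TestSummarize:
    @staticmethod
    def two_board_log():
        b1 = entries([(1.0, "correct")], board_index=1)
        b2 = entries([(4.0, "correct")], board_index=2)
        return pd.concat([b1, b2], ignore_index=True)

    def test_arithmetic_and_geometric_means(self):
        s = summarize_session(self.two_board_log())
        assert s.avg_search_time_with_hints == pytest.approx(2.5)
        assert s.avg_search_time_without_hints == pytest.approx(2.5)
        assert s.geometric_mean_search_time == pytest.approx(2.0)  # sqrt(1*4)
        assert s.n_false_moves == 0 and s.n_hints == 0

    def test_geometric_le_arithmetic(self):
        rng = np.random.default_rng(3)
        frames = [
            entries([(float(rng.gamma(2, 1) + 0.01), "correct")], board_index=i, trial_id=f"t{i}")
            for i in range(1, 9)
        ]
        s = summarize_session(pd.concat(frames, ignore_index=True))
        assert s.geometric_mean_search_time <= s.avg_search_time_without_hints

    def test_all_hint_boards_flagged_missing_not_zero(self):
        df = pd.concat(
            [
                entries([(1.0, "correct")], hint_last=True, board_index=1),
                entries([(2.0, "correct")], hint_last=True, board_index=2),
            ],
            ignore_index=True,
        )
        s = summarize_session(df)
        assert s.avg_search_time_without_hints is None
        assert s.geometric_mean_search_time is None
        assert s.n_hints == 2

    def test_hint_exclusion_consistency(self):
        # no hints anywhere: with- and without-hint means coincide
        s = summarize_session(self.two_board_log())
        assert s.avg_search_time_with_hints == s.avg_search_time_without_hints

    def test_false_move_count(self):
        df = pd.concat(
            [
                entries([(1.0, "false"), (0.5, "false"), (1.0, "correct")], board_index=1),
                entries([(2.0, "false"), (2.0, "correct")], board_index=2),
            ],
            ignore_index=True,
        )
        assert summarize_session(df).n_false_moves == 3

    def test_outlier_trial_excluded_and_counted(self):
        frames = [
            entries([(2.0 + 0.01 * i, "correct")], board_index=1, trial_id=f"t{i}")
            for i in range(8)
        ]
        frames.append(entries([(500.0, "correct")], board_index=1, trial_id="t_out"))
        s = summarize_session(pd.concat(frames, ignore_index=True))
        assert s.n_trials_excluded_outlier == 1
        assert s.avg_search_time_with_hints < 3.0

    def test_empty_log_rejected(self):
        with pytest.raises(MetricsError):
            summarize_session(pd.DataFrame())

    def test_completion_time_in_minutes(self):
        s = summarize_session(self.two_board_log())
        assert s.task_completion_time == pytest.approx(5.0 / 60.0)
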