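"""Synthetic player: determinism, noise model, and effect recovery."""

import numpy as np
import pandas as pd
import pytest

from searchmatch import (
    LevelSpec,
    PlayerModel,
    board_table,
    enumerate_valid_moves,
    search_slope,
    simulate_cohort,
    simulate_trial,
)


class TestModel:
    def test_mean_structure(self):
        m = PlayerModel(base_time=1.0, set_size_effect=0.1, tile_type_effect=-0.05,
                        group_multiplier=2.0)
        assert m.mean_search_time(4, 4, 4) == pytest.approx(2.0 * (1 + 1.6 - 0.2))

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            PlayerModel(shape=0.0)
        with pytest.raises(ValueError):
            PlayerModel(p_false=1.5)


class TestSimulateTrial:
    def test_no_false_no_hint_gives_one_entry_per_board(self, trial_bank):
        model = PlayerModel(p_false=0.0, p_hint=0.0)
        trial = trial_bank[(4, 4, 4)][0]
        log, _ = simulate_trial(model, trial, np.random.default_rng(0))
        assert len(log.entries) == 4
        assert all(e.accuracy == "correct" for e in log.entries)

    def test_deterministic_under_seed(self, trial_bank):
        trial = trial_bank[(5, 5, 5)][0]
        model = PlayerModel(p_false=0.3, p_hint=0.2)
        a, _ = simulate_trial(model, trial, np.random.default_rng(9))
        b, _ = simulate_trial(model, trial, np.random.default_rng(9))
        assert a.entries == b.entries

    def test_correct_moves_are_the_unique_valid_moves(self, trial_bank):
        """Replay property: every logged correct move is the unique valid
        move of its board (checked with the brute-force oracle)."""
        trial = trial_bank[(4, 4, 4)][1]
        model = PlayerModel(p_false=0.5)
        log, _ = simulate_trial(model, trial, np.random.default_rng(2))
        boards = trial.boards()
        for e in log.entries:
            if e.accuracy == "correct":
                assert enumerate_valid_moves(boards[e.board_index - 1]) == {e.move}

    def test_flat_model_mean_close_to_base_time(self, trial_bank):
        """With no set-size or tile-type effects the simulated mean search
        time is the base time, across levels, within Monte-Carlo error."""
        model = PlayerModel(base_time=2.0, set_size_effect=0.0, tile_type_effect=0.0,
                            p_false=0.0, p_hint=0.0, shape=4.0)
        rng = np.random.default_rng(5)
        times = []
        for level in [(4, 4, 4), (8, 8, 8)]:
            trial = trial_bank[level][0]
            level_times = []
            for _ in range(350):
                log, _ = simulate_trial(model, trial, rng, rate_difficulty=False)
                level_times.extend(e.elapsed_time for e in log.entries)
            times.append(np.mean(level_times))
        # gamma(k=4, mean 2) sd = 1; n=1400 boards/level -> sem ~ 0.027
        assert times[0] == pytest.approx(2.0, abs=0.15)
        assert times[1] == pytest.approx(2.0, abs=0.15)


class TestSimulateCohort:
    def test_requires_models_and_trials(self, trial_bank):
        with pytest.raises(ValueError):
            simulate_cohort({}, trial_bank[(4, 4, 4)], seed=0)
        with pytest.raises(ValueError):
            simulate_cohort({"g": PlayerModel()}, [], seed=0)

    def test_same_seed_identical_logs(self, trial_bank):
        models = {"young": PlayerModel(), "older": PlayerModel(group_multiplier=1.6)}
        trials = trial_bank[(4, 4, 4)]
        a = simulate_cohort(models, trials, seed=11, n_participants=2)
        b = simulate_cohort(models, trials, seed=11, n_participants=2)
        assert [l.entries for l in a] == [l.entries for l in b]

    def test_group_multiplier_ordering_recovered(self, trial_bank):
        """Three groups with multipliers 1 < 1.6 < 3.1 produce strictly
        ordered group mean search times (young < older < oldest analogue)."""
        models = {
            "g1_young": PlayerModel(group_multiplier=1.0),
            "g2_older": PlayerModel(group_multiplier=1.6),
            "g3_oldest": PlayerModel(group_multiplier=3.1),
        }
        trials = trial_bank[(4, 4, 4)] + trial_bank[(5, 5, 5)]
        logs = simulate_cohort(models, trials, seed=21, n_participants=12)
        df = pd.concat([l.to_dataframe() for l in logs], ignore_index=True)
        means = board_table(df).groupby("group")["search_time"].mean()
        assert means["g1_young"] < means["g2_older"] < means["g3_oldest"]


class TestEffectRecovery:
    def test_set_size_and_group_effects_significant(self, trial_bank):
        """Smoke test of the full stack: simulated positive set-size and
        group effects are recovered with p < 0.01 in a simple regression."""
        import statsmodels.formula.api as smf

        models = {
            "a_fast": PlayerModel(set_size_effect=0.1, tile_type_effect=0.0,
                                  group_multiplier=1.0, p_false=0.0, p_hint=0.0),
            "b_slow": PlayerModel(set_size_effect=0.1, tile_type_effect=0.0,
                                  group_multiplier=2.0, p_false=0.0, p_hint=0.0),
        }
        trials = [trial_bank[k][0] for k in [(4, 4, 4), (5, 5, 5), (6, 6, 6), (7, 7, 7)]]
        logs = simulate_cohort(models, trials, seed=33, n_participants=15)
        df = pd.concat([l.to_dataframe() for l in logs], ignore_index=True)
        boards = board_table(df)
        fit = smf.ols("search_time ~ set_size + C(group)", data=boards).fit()
        assert fit.params["set_size"] > 0 and fit.pvalues["set_size"] < 0.01
        assert fit.params["C(group)[T.b_slow]"] > 0
        assert fit.pvalues["C(group)[T.b_slow]"] < 0.01

    def test_tile_type_effect_direction(self, trial_bank):
        """More tile types -> faster search, recovered as a negative slope
        of search time on t at fixed set size."""
        model = PlayerModel(base_time=3.0, set_size_effect=0.0, tile_type_effect=-0.2,
                            p_false=0.0, p_hint=0.0, rng_seed=1)
        rng = np.random.default_rng(44)
        rows = []
        from searchmatch import generate_trial

        def first_trial(level):
            for seed in range(20):
                t = generate_trial(level, seed)
                if hasattr(t, "matches"):
                    return t
            raise AssertionError(f"no playable trial found for {level}")

        t_values = (5, 6)
        trials = {t: first_trial(LevelSpec(6, 6, t)) for t in t_values}
        for t, trial in trials.items():
            for _ in range(150):
                log, _ = simulate_trial(model, trial, rng, rate_difficulty=False)
                rows.append((t, np.mean([e.elapsed_time for e in log.entries])))
        df = pd.DataFrame(rows, columns=["t", "mean_time"])
        means = df.groupby("t")["mean_time"].mean()
        assert means[t_values[1]] < means[t_values[0]]
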