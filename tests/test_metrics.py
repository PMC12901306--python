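"""Behavioural indices: hand-worked examples and relabelling invariance."""

import numpy as np
import pandas as pd
import pytest

import seqsampler as ss
from seqsampler.agents import ChoiceDataset
from seqsampler.metrics import (
    sequence_is_stereotyped,
    sequence_repeat_counts,
    sequence_similarity,
    uncertainty_direction_random_cohort,
)


def tiny_dataset(choices_per_seq, condition=ss.GUESS, target=0, cats=(1, -1),
                 shades=None, participant=0):
    """Build a one-participant ChoiceDataset from explicit choice lists."""
    rows = []
    for pos, choices in enumerate(choices_per_seq):
        sh = shades[pos] if shades else [0.5] * len(choices)
        for t, ch in enumerate(choices):
            rows.append(dict(
                participant=participant, condition=condition, position=pos,
                sequence_id=pos, trial=t + 1, choice=ch, shade=sh[t],
                side=ch - 1, target_colour=target, length=len(choices),
                category1=cats[0], category2=cats[1],
            ))
    return ChoiceDataset(pd.DataFrame(rows), pd.DataFrame())


class TestFractionRepeat:
    def test_hand_counts(self):
        hits, opps = sequence_repeat_counts([1, 1, 1, 2, 1])
        # repeats at t2 (fam 1) and t3 (fam 2); misses at t4 (fam 3), t5 (fam 1)
        assert opps[0] == 2 and hits[0] == 1
        assert opps[1] == 1 and hits[1] == 1
        assert opps[2] == 1 and hits[2] == 0
        _, curve = ss.fraction_repeat(tiny_dataset([[1, 1, 1, 2, 1]]))
        assert curve.loc[(0, ss.GUESS, 1), "fraction_repeat"] == 0.5

    def test_all_same_and_alternating(self):
        overall, _ = ss.fraction_repeat(tiny_dataset([[1] * 8]))
        assert overall["fraction_repeat"].iloc[0] == 1.0
        overall, _ = ss.fraction_repeat(tiny_dataset([[1, 2] * 4]))
        assert overall["fraction_repeat"].iloc[0] == 0.0


class TestChoiceSimilarity:
    def test_hand_comparison(self):
        m = sequence_similarity([1, 1, 2, 2])
        assert m[0, 1] == 1.0 and m[0, 2] == 0.0 and m[2, 3] == 1.0
        assert np.isnan(m[1, 0]) and np.isnan(m[0, 0]) and np.isnan(m[0, 5])

    def test_deterministic_agent_all_ones(self):
        sim = ss.choice_similarity(tiny_dataset([[2] * 8, [1] * 12]))
        mat = sim[ss.GUESS]
        vals = mat[np.isfinite(mat)]
        assert np.all(vals == 1.0)

    def test_random_agent_near_half(self, small_guess_design):
        ds = ss.simulate_dataset(
            small_guess_design, None, 3, policy="random", n_participants=8
        )
        mat = ss.choice_similarity(ds)[ss.GUESS]
        assert abs(np.nanmean(mat) - 0.5) < 0.03

    def test_lag1_diagonal_matches_fraction_repeat(self, small_guess_design):
        # internal consistency: the lag-1 similarity equals repeat fractions
        p = ss.ParameterSet(beta_unc=1.0, b_rep=1.0, theta=1.5, epsilon=0.9)
        ds = ss.simulate_dataset(small_guess_design, p, 5, n_participants=1)
        overall, _ = ss.fraction_repeat(ds)
        # recompute the weighted lag-1 agreement per sequence by hand
        hits = n = 0
        for _, grp in ds.trials.groupby("position"):
            c = grp.sort_values("trial")["choice"].to_numpy()
            hits += np.sum(c[1:] == c[:-1])
            n += len(c) - 1
        assert overall["fraction_repeat"].iloc[0] == pytest.approx(hits / n)


class TestPerformance:
    def test_optimal_match_agent_near_one(self, space):
        cfg = ss.DatasetConfig("m", (ss.MATCH,), 24, 4, "option")
        design = ss.generate_experiment(cfg, 5, space=space)
        ds = ss.simulate_dataset(design, None, 6, policy="optimal",
                                 n_participants=4)
        perf = ss.performance(ds)
        assert perf["last_choice_target_fraction"].mean() > 0.85

    def test_random_agent_near_chance(self, space):
        cfg = ss.DatasetConfig("m", (ss.MATCH,), 48, 4, "option")
        design = ss.generate_experiment(cfg, 6, space=space)
        ds = ss.simulate_dataset(design, None, 7, policy="random",
                                 n_participants=8)
        perf = ss.performance(ds)
        assert abs(perf["last_choice_target_fraction"].mean() - 0.5) < 0.1

    def test_final_accuracy_above_chance_for_accumulating_agent(
        self, small_guess_design
    ):
        p = ss.ParameterSet(beta_unc=1.0, b_rep=0.5)
        ds = ss.simulate_dataset(small_guess_design, p, 8, n_participants=6)
        perf = ss.performance(ds)
        acc = perf["final_accuracy"].mean()
        assert acc > 0.6  # sign-readout of accumulated logLR beats chance

    def test_no_single_target_sequences_gives_nan(self):
        ds = tiny_dataset([[1, 2, 1]], condition=ss.MATCH, target=1, cats=(1, 1))
        perf = ss.performance(ds)
        assert np.isnan(perf["last_choice_target_fraction"].iloc[0])


class TestChoiceDirection:
    def test_first_trial_tie_credit(self, space):
        ds = tiny_dataset([[1, 1]], shades=[[0.5, 0.5]])
        _, unc = ss.choice_direction(ds, space)
        assert np.isnan(unc.iloc[0, 0])  # trial 1 has no score
        assert unc.iloc[0, 1] == 0.0     # chose the sampled (more certain) option

    def test_anti_uncertainty_agent_scores_zero(self, space):
        # always re-choose the (unique) higher-|x| option
        ds = tiny_dataset([[1, 1, 1, 1]], shades=[[0.5] * 4])
        _, unc = ss.choice_direction(ds, space)
        assert np.all(unc.iloc[0, 1:4].to_numpy() == 0.0)

    def test_relabelling_invariance(self, small_two_condition_design):
        p = ss.ParameterSet(1.0, 1.0, 0.8, theta=1.0, epsilon=0.9)
        ds = ss.simulate_dataset(small_two_condition_design, p, 9,
                                 n_participants=2)
        space = small_two_condition_design.space
        _, unc = ss.choice_direction(ds, space)
        overall, _ = ss.fraction_repeat(ds)
        # swap options 1↔2 jointly with categories
        sw = ds.trials.copy()
        sw["choice"] = 3 - sw["choice"]
        c1, c2 = sw["category1"].copy(), sw["category2"].copy()
        sw["category1"], sw["category2"] = c2, c1
        ds2 = ChoiceDataset(sw, ds.finals)
        _, unc2 = ss.choice_direction(ds2, space)
        overall2, _ = ss.fraction_repeat(ds2)
        pd.testing.assert_frame_equal(unc, unc2)
        pd.testing.assert_frame_equal(overall, overall2)

    def test_fast_random_cohort_matches_pipeline_statistically(
        self, small_guess_design
    ):
        ds = ss.simulate_dataset(
            small_guess_design, None, 11, policy="random", n_participants=60
        )
        _, unc = ss.choice_direction(ds, small_guess_design.space)
        pipe = np.nanmean(unc.to_numpy(), axis=0)
        fast = np.nanmean(
            uncertainty_direction_random_cohort(
                small_guess_design, 60, np.random.default_rng(12)
            ),
            axis=0,
        )
        # two independent 60-participant cohorts: difference SE ≈ 0.018/point
        ok = np.isfinite(pipe) & np.isfinite(fast)
        assert np.all(np.abs(pipe[ok] - fast[ok]) < 0.09)
        assert abs(np.mean(pipe[ok]) - np.mean(fast[ok])) < 0.02


class TestStereotypy:
    def test_flag_patterns(self):
        assert sequence_is_stereotyped([1, 2, 1, 2, 1, 2])["option_alternation"]
        assert sequence_is_stereotyped([1] * 8)["single_option"]
        flags = sequence_is_stereotyped([1, 1, 2, 1], sides=[0, 1, 0, 1])
        assert flags["side_alternation"]
        assert not flags["option_alternation"] and not flags["single_option"]

    def test_exclusion_threshold_strictly_above_half(self):
        # 2 of 5 stereotyped (40%) → keep; 3 of 5 (60%) → exclude
        keep = [[1, 2] * 4, [1] * 8, [1, 1, 2, 2], [1, 2, 2, 1], [2, 1, 1, 2]]
        ds = tiny_dataset(keep)
        assert not ss.flag_stereotyped(ds)["excluded"].iloc[0]
        drop = [[1, 2] * 4, [1] * 8, [2] * 8, [1, 2, 2, 1], [2, 1, 1, 2]]
        ds = tiny_dataset(drop)
        assert ss.flag_stereotyped(ds)["excluded"].iloc[0]

    def test_exclusion_any_condition(self):
        a = tiny_dataset([[1, 1, 2, 2]] * 4, condition=ss.MATCH)
        b = tiny_dataset([[1] * 6] * 4, condition=ss.GUESS)
        ds = ChoiceDataset(
            pd.concat([a.trials, b.trials], ignore_index=True), pd.DataFrame()
        )
        out = ss.flag_stereotyped(ds)
        assert out["excluded"].iloc[0]
        assert out["frac_MATCH"].iloc[0] == 0.0
        assert out["frac_GUESS"].iloc[0] == 1.0
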