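"""Behaviour simulator: determinism, uniform limit, learning, criterion."""

import itertools
from collections import Counter

import numpy as np
import pytest

from coaca.credit import Params
from coaca.maze import SL, SR
from coaca.simulate import (
    DEFAULT_PARAMS,
    LearningCriterionError,
    SimulationDesign,
    reaches_learning_criterion,
    simulate_log,
    simulate_log_with_lc,
)

from conftest import log_from_labels


def records_tuple(log):
    return tuple(
        (r.session_index, r.ordinal_in_experiment, r.path.label, r.edge_durations)
        for r in log.all_records()
    )


class TestDeterminism:
    def test_same_design_same_log(self):
        d = SimulationDesign("Hybrid2", DEFAULT_PARAMS, 3, 40, seed=11)
        assert records_tuple(simulate_log(d)) == records_tuple(simulate_log(d))

    def test_different_seeds_differ(self):
        d1 = SimulationDesign("Hybrid2", DEFAULT_PARAMS, 3, 40, seed=11)
        d2 = SimulationDesign("Hybrid2", DEFAULT_PARAMS, 3, 40, seed=12)
        assert records_tuple(simulate_log(d1)) != records_tuple(simulate_log(d2))

    def test_lc_wrapper_deterministic(self):
        d = SimulationDesign("Hybrid3", DEFAULT_PARAMS, 10, 75, seed=5)
        log1, n1 = simulate_log_with_lc(d)
        log2, n2 = simulate_log_with_lc(d)
        assert n1 == n2 and records_tuple(log1) == records_tuple(log2)


class TestStructure:
    def test_session_budgets_and_ordinals(self):
        d = SimulationDesign("Turns", DEFAULT_PARAMS, 4, (10, 20, 30, 5), seed=0)
        log = simulate_log(d)
        assert [len(s) for s in log.sessions] == [10, 20, 30, 5]
        assert [r.ordinal_in_experiment for r in log.all_records()] == list(
            range(1, 66)
        )

    def test_sessions_resume_at_previous_supplier(self):
        d = SimulationDesign("Paths", DEFAULT_PARAMS, 5, 13, seed=3, start_supplier=SL)
        log = simulate_log(d)
        assert log.sessions[0][0].path.origin == SL
        for prev, cur in zip(log.sessions, log.sessions[1:]):
            assert cur[0].path.origin == prev[-1].path.destination

    def test_invalid_designs_rejected(self):
        with pytest.raises(ValueError):
            SimulationDesign("Paths", DEFAULT_PARAMS, 0, 10)
        with pytest.raises(ValueError):
            SimulationDesign("Paths", DEFAULT_PARAMS, 2, 10, lc_threshold=0.0)
        with pytest.raises(ValueError):
            SimulationDesign("Paths", DEFAULT_PARAMS, 2, (10,))


class TestUniformLimit:
    def test_alpha_zero_gives_uniform_path_choice(self):
        """With alpha=0 credits never move, so each of the six paths from a
        supplier is taken with probability 1/6 (checked within 3 binomial
        standard errors over >= 3000 paths)."""
        d = SimulationDesign("Paths", Params(0.0, 0.5), 1, 3600, seed=21)
        log = simulate_log(d)
        counts = Counter(r.path.label for r in log.all_records())
        by_origin = Counter(r.path.origin for r in log.all_records())
        for label, c in counts.items():
            n = by_origin[label.split(":")[0]]
            se = np.sqrt((1 / 6) * (5 / 6) / n)
            assert abs(c / n - 1 / 6) < 3 * se, label

    def test_alpha_zero_episode_type_distribution_matches_enumeration(self):
        """Episode (length, reward) frequencies under uniform choice match a
        brute-force enumeration of all episode types up to 4 paths."""
        # per step from any supplier: 2 loops (stay), 1 good cross, 3 other
        # crosses (switch), each elementary path w.p. 1/6
        step_types = [("loop", 0, 2 / 6), ("good", 1, 1 / 6), ("cross", 1, 3 / 6)]
        exact = Counter()
        for length in range(1, 5):
            for combo in itertools.product(step_types, repeat=length):
                pos = 0  # 0 = at origin supplier, 1 = at the opposite one
                seen = False
                closed_early = False
                for kind, moves, _ in combo[:-1]:
                    pos ^= moves
                    seen = seen or pos == 1
                    if seen and pos == 0:
                        closed_early = True
                if closed_early:
                    continue
                kind, moves, _ = combo[-1]
                pos ^= moves
                seen = seen or pos == 1
                if not (seen and pos == 0):
                    continue
                prob = np.prod([p for _, _, p in combo])
                reward = sum(1 for k, _, _ in combo if k == "good")
                exact[(length, reward)] += prob
        total_exact = sum(exact.values())

        # the Paths model's uniform-softmax limit is the uniform-path limit
        d = SimulationDesign("Paths", Params(0.0, 1.0), 1, 4000, seed=8)
        log = simulate_log(d)
        episodes = log.episodes_per_session[0]
        short = [ep for ep in episodes if len(ep.paths) <= 4]
        empirical = Counter((len(ep.paths), ep.reward) for ep in short)
        for key, p in exact.items():
            expected = p / total_exact
            observed = empirical.get(key, 0) / len(short)
            se = np.sqrt(expected * (1 - expected) / len(short))
            assert abs(observed - expected) < 4 * se + 1e-3, key


class TestLearning:
    def test_default_condition_learns_above_start(self):
        """Under the default generating condition the final-session success
        rate exceeds the first session's in the large majority of seeds."""
        wins = 0
        for seed in range(1, 13):
            d = SimulationDesign("Hybrid3", DEFAULT_PARAMS, 20, 75, seed=seed)
            rates = simulate_log(d).success_rates()
            wins += rates[-1] > rates[0]
        assert wins >= 9

    def test_forgetting_produces_start_of_session_drops(self):
        """With between-session forgetting, performance at the start of a
        session sits below the end of the previous one on average (pooled
        over the non-saturated transitions of 10 fixed seeds)."""
        diffs = []
        for seed in range(1, 11):
            d = SimulationDesign("Hybrid3", DEFAULT_PARAMS, 20, 75, seed=seed)
            log = simulate_log(d)
            for prev, cur in zip(log.sessions, log.sessions[1:]):
                prev_end = np.mean([r.path.is_good for r in prev[-25:]])
                cur_start = np.mean([r.path.is_good for r in cur[:25]])
                if 0.5 <= prev_end <= 0.96:
                    diffs.append(cur_start - prev_end)
        assert len(diffs) > 30
        assert np.mean(diffs) < 0.0


class TestLearningCriterion:
    def test_session_above_threshold(self):
        log = log_from_labels([["SL:good", "SR:good", "SL:good", "SR:good"]])
        assert reaches_learning_criterion(log, 0.80)

    def test_all_sessions_below_threshold(self):
        log = log_from_labels([["SL:good", "SR:cross_low"] * 4])
        assert not reaches_learning_criterion(log, 0.80)

    def test_threshold_comparison_is_inclusive(self):
        labels = ["SL:good", "SR:good", "SL:good", "SR:good", "SL:loop_low"]
        log = log_from_labels([labels])
        assert log.success_rates()[0] == pytest.approx(0.8)
        assert reaches_learning_criterion(log, 0.80)

    def test_attempt_cap_raises(self):
        d = SimulationDesign("Paths", Params(0.0, 1.0), 1, 20, seed=0)
        with pytest.raises(LearningCriterionError):
            simulate_log_with_lc(d, max_attempts=3)
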