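"""Likelihood engine, MLE fitting and hold-out selection."""

import math

import numpy as np
import pytest

from coaca.credit import Params
from coaca.inference import (
    HoldoutSplit,
    OptimizerConfig,
    confusion_experiment,
    fit_mle,
    holdout_select,
    log_likelihood,
    parameter_recovery_curve,
)
from coaca.maze import MazeError
from coaca.simulate import DEFAULT_PARAMS, SimulationDesign, simulate_log
from coaca.strategies import MODEL_NAMES, build_model

from conftest import log_from_labels

FAST_OPT = OptimizerConfig(restarts=20, maxiter=40, seed=0)


def unrolled_ll(model, params, log):
    """Brute-force reference: materialise every probability table by plain
    dict arithmetic, episode by episode, straight from the update formula."""
    credits = {}  # (state id, action id) -> credit

    def logp(state, action):
        acts = model.available_actions(state)
        ks = [credits.get((state.identifier, a.identifier), 0.0) for a in acts]
        m = max(ks)
        denom = sum(math.exp(k - m) for k in ks)
        k_chosen = credits.get((state.identifier, action.identifier), 0.0)
        return (k_chosen - m) - math.log(denom)

    total = 0.0
    for si, (episodes, fragment) in enumerate(
        zip(log.episodes_per_session, log.trailing_fragment_per_session)
    ):
        if si > 0:
            for key in credits:
                credits[key] *= params.gamma
        for ep in episodes:
            steps = []
            for rec in ep.paths:
                for state, action, (a, b) in model.decomposition(rec.path.label):
                    steps.append((state, action, sum(rec.edge_durations[a:b])))
            for state, action, _ in steps:
                total += logp(state, action)
            d_episode = sum(d for _, _, d in steps)
            for state, action, d in steps:
                key = (state.identifier, action.identifier)
                credits[key] = credits.get(key, 0.0) + params.alpha * (
                    d / d_episode
                ) * ep.reward
        for rec in fragment:
            for state, action, _ in model.decomposition(rec.path.label):
                total += logp(state, action)
    return total


class TestClosedForms:
    def test_alpha_zero_paths_model_uniform(self, toy_log):
        ll = log_likelihood("Paths", Params(0.0, 0.3), toy_log, "all")
        assert ll == pytest.approx(toy_log.n_paths * math.log(1 / 6), abs=1e-10)

    def test_alpha_zero_turns_model_half_per_action(self, toy_log):
        turns = build_model("Turns")
        n_actions = sum(
            len(turns.decomposition(r.path.label)) for r in toy_log.all_records()
        )
        ll = log_likelihood(turns, Params(0.0, 0.9), toy_log, "all")
        assert ll == pytest.approx(n_actions * math.log(0.5), abs=1e-10)


class TestOracleEquivalence:
    @pytest.mark.parametrize("model_name", MODEL_NAMES)
    @pytest.mark.parametrize(
        "params", [Params(0.05, 0.8), Params(0.5, 0.3), Params(1.0, 1.0)]
    )
    def test_incremental_equals_unrolled_on_toy_logs(self, toy_log, model_name, params):
        """Incremental engine vs hand-unrolled recursion, multi-session toy
        log with trailing fragment, to 1e-10."""
        model = build_model(model_name)
        assert log_likelihood(model, params, toy_log, "all") == pytest.approx(
            unrolled_ll(model, params, toy_log), abs=1e-10
        )

    def test_equivalence_on_simulated_log(self):
        design = SimulationDesign("Hybrid2", DEFAULT_PARAMS, 3, 25, seed=9)
        log = simulate_log(design)
        for name in ("Paths", "Hybrid3", "Turns"):
            model = build_model(name)
            assert log_likelihood(model, Params(0.2, 0.7), log, "all") == pytest.approx(
                unrolled_ll(model, Params(0.2, 0.7), log), abs=1e-10
            )


class TestPhases:
    def test_ll_additivity(self, toy_log):
        params = Params(0.3, 0.6)
        for cut in (2, 5, 9):
            early = log_likelihood("Hybrid3", params, toy_log, "early", cut=cut)
            late = log_likelihood("Hybrid3", params, toy_log, "late", cut=cut)
            full = log_likelihood("Hybrid3", params, toy_log, "all")
            assert early + late == pytest.approx(full, abs=1e-10)

    def test_duration_rescaling_invariance(self, toy_log):
        """Only activity ratios enter the dynamics, so likelihoods are
        invariant to rescaling every duration by a positive constant."""
        from coaca.maze import BehaviorLog, PathRecord

        scaled = BehaviorLog(
            [
                [
                    PathRecord(
                        r.session_index,
                        r.ordinal_in_experiment,
                        r.path,
                        tuple(37.5 * d for d in r.edge_durations),
                    )
                    for r in session
                ]
                for session in toy_log.sessions
            ]
        )
        params = Params(0.4, 0.7)
        for name in MODEL_NAMES:
            assert log_likelihood(name, params, toy_log, "all") == pytest.approx(
                log_likelihood(name, params, scaled, "all"), abs=1e-9
            )

    def test_cut_outside_log_rejected(self, toy_log):
        with pytest.raises(MazeError):
            log_likelihood("Paths", Params(0.1, 0.5), toy_log, "late", cut=50)

    def test_freeze_flag_changes_late_ll_only(self):
        log = simulate_log(SimulationDesign("Hybrid3", DEFAULT_PARAMS, 6, 40, seed=2))
        params = Params(0.15, 0.8)
        early_live = log_likelihood("Hybrid3", params, log, "early", cut=120)
        early_frozen = log_likelihood(
            "Hybrid3", params, log, "early", cut=120, freeze_after_cut=True
        )
        assert early_live == pytest.approx(early_frozen, abs=1e-10)
        late_live = log_likelihood("Hybrid3", params, log, "late", cut=120)
        late_frozen = log_likelihood(
            "Hybrid3", params, log, "late", cut=120, freeze_after_cut=True
        )
        assert late_live != pytest.approx(late_frozen, abs=1e-6)


class TestFitting:
    def test_fit_is_deterministic(self):
        log = simulate_log(SimulationDesign("Hybrid3", DEFAULT_PARAMS, 8, 75, seed=1))
        f1 = fit_mle("Hybrid3", log, HoldoutSplit(400), FAST_OPT)
        f2 = fit_mle("Hybrid3", log, HoldoutSplit(400), FAST_OPT)
        assert f1.params == f2.params and f1.train_ll == f2.train_ll

    def test_alpha_zero_data_fits_to_uniform_ll(self):
        log = simulate_log(SimulationDesign("Paths", Params(0.0, 0.5), 2, 150, seed=6))
        fit = fit_mle("Paths", log, HoldoutSplit(250), FAST_OPT)
        uniform = 250 * math.log(1 / 6)
        assert fit.train_ll >= uniform - 1e-6
        assert fit.train_ll <= uniform + 3.0  # mild overfit headroom only

    def test_fitted_ll_beats_true_params_on_train(self):
        log = simulate_log(SimulationDesign("Hybrid3", DEFAULT_PARAMS, 10, 75, seed=3))
        fit = fit_mle("Hybrid3", log, HoldoutSplit(500), FAST_OPT)
        true_ll = log_likelihood("Hybrid3", DEFAULT_PARAMS, log, "early", cut=500)
        assert fit.train_ll >= true_ll - 1e-6
        assert 0.0 <= fit.params.alpha <= 1.0 and 0.0 <= fit.params.gamma <= 1.0


class TestSelection:
    def test_short_log_rejected(self):
        log = log_from_labels([["SL:good", "SR:good"] * 3])
        with pytest.raises(MazeError):
            holdout_select(log, MODEL_NAMES, HoldoutSplit(800), FAST_OPT)

    def test_generating_model_selected_on_one_replicate(self):
        design = SimulationDesign("Hybrid3", DEFAULT_PARAMS, 20, 75, seed=2)
        log = simulate_log(design)
        report = holdout_select(log, MODEL_NAMES, HoldoutSplit(800), FAST_OPT)
        assert report.selected == "Hybrid3"
        assert report.test_ll["Hybrid3"] == max(report.test_ll.values())
        assert all(v <= 0 for v in report.test_ll.values())

    def test_pairwise_differences_and_ratio(self, toy_log):
        report = holdout_select(
            toy_log, ("Paths", "Turns"), HoldoutSplit(6), FAST_OPT
        )
        diffs = report.pairwise_differences()
        assert diffs[("Paths", "Turns")] == pytest.approx(
            -diffs[("Turns", "Paths")], abs=1e-12
        )
        assert report.likelihood_ratio() == pytest.approx(
            math.exp(report.smallest_margin())
        )


class TestExperiments:
    def test_confusion_rows_are_proportions(self):
        designs = {
            "Hybrid3": SimulationDesign("Hybrid3", DEFAULT_PARAMS, 12, 75),
        }
        matrix = confusion_experiment(
            designs,
            MODEL_NAMES,
            HoldoutSplit(500),
            OptimizerConfig(restarts=20, maxiter=25, seed=0),
            replicates=3,
            seed=5,
        )
        assert matrix.shape == (1, 6)
        assert matrix.loc["Hybrid3"].sum() == pytest.approx(1.0)

    def test_recovery_curve_shrinks_error(self):
        """Estimates at the largest training window are closer to truth than
        at the smallest (median over 3 seeds), and one row per grid point."""
        closer_alpha = 0
        for seed in (1, 2, 3):
            design = SimulationDesign("Hybrid3", DEFAULT_PARAMS, 20, 75, seed=seed)
            table = parameter_recovery_curve(
                design, grid=(100, 1400), optimizer=FAST_OPT
            )
            assert list(table["paths_used"]) == [100, 1400]
            first, last = table.iloc[0], table.iloc[-1]
            closer_alpha += abs(last.alpha_hat - DEFAULT_PARAMS.alpha) <= abs(
                first.alpha_hat - DEFAULT_PARAMS.alpha
            )
            assert last.sessions_spanned > first.sessions_spanned
        assert closer_alpha >= 2
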