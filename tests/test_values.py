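"""Value estimation: psychometric fits, bias tests, trade-offs, choice models."""

import numpy as np
import pytest

from nutrichoice import synth
from nutrichoice.datatypes import Session, Trial
from nutrichoice.values import (
    choice_bias_tests,
    fit_nutrient_model,
    implied_rho_ratio,
    psychometric_fit,
    tradeoff_quantification,
    transitivity_check,
    value_transform_validate,
)

from conftest import build_session


def _sessions(agent, stimuli, pairs, n, seed):
    sched = [((stimuli[a], stimuli[b]), n) for a, b in pairs]
    return synth.make_dataset([agent], sched, seed=seed)


class TestPsychometricFit:
    def test_indifferent_agent_ci_contains_one(self, factorial_stimuli):
        agent = synth.NutrientValueFunction("n", temperature=2.0)
        data = _sessions(agent, factorial_stimuli, [("LFLS", "HFLS")], 800, 21)
        fit = psychometric_fit(data, "LFLS", "HFLS", n_bootstrap=400, seed=1)
        assert fit.ci_low <= 1.0 <= fit.ci_high

    def test_magnitude_rescaling_leaves_fit_unchanged(self, factorial_stimuli):
        agent = synth.NutrientValueFunction("a", w_fat=0.1, temperature=2.0)
        data = _sessions(agent, factorial_stimuli, [("LFLS", "HFLS")], 500, 22)
        fit1 = psychometric_fit(data, "LFLS", "HFLS", n_bootstrap=100, seed=2)
        doubled = [
            Session(
                id=s.id,
                agent_id=s.agent_id,
                trials=[
                    Trial(t.session_id, t.index, t.stim_left, t.stim_right,
                          2 * t.mag_left, 2 * t.mag_right, t.choice)
                    for t in s.trials
                ],
            )
            for s in data
        ]
        fit2 = psychometric_fit(doubled, "LFLS", "HFLS", n_bootstrap=100, seed=2)
        assert fit2.indifference_point == pytest.approx(fit1.indifference_point, rel=1e-9)

    def test_uniform_choices_have_no_inflection(self):
        sess = build_session([("A", "B", m, 1.0, "left") for m in (0.5, 1.0, 1.5, 2.0)] * 5)
        with pytest.raises(ValueError, match="inflection"):
            psychometric_fit([sess], "A", "B")

    def test_bootstrap_reproducible_under_seed(self, factorial_stimuli):
        agent = synth.NutrientValueFunction("a", w_sugar=0.08, temperature=2.0)
        data = _sessions(agent, factorial_stimuli, [("LFLS", "LFHS")], 400, 23)
        f1 = psychometric_fit(data, "LFLS", "LFHS", n_bootstrap=200, seed=7)
        f2 = psychometric_fit(data, "LFLS", "LFHS", n_bootstrap=200, seed=7)
        assert (f1.ci_low, f1.ci_high) == (f2.ci_low, f2.ci_high)


class TestChoiceBiasTests:
    def test_alternating_sequence_is_antipersistent_not_biased(self):
        specs = [("A", "B", 1.0, 1.0, "left" if i % 2 == 0 else "right") for i in range(100)]
        res = choice_bias_tests(build_session(specs))
        assert res["binomial_p"] > 0.9
        assert res["runlength_lr_p"] < 0.001
        assert res["run_length_summary"]["max_run_length"] == 1

    def test_constant_sequence_extreme_binomial(self):
        specs = [("A", "B", 1.0, 1.0, "left")] * 100
        res = choice_bias_tests(build_session(specs))
        assert res["binomial_p"] < 1e-20

    def test_fair_coin_type_i_error_calibrated(self):
        rng = np.random.default_rng(99)
        n_reps, n = 1000, 400
        rej_binom = rej_run = 0
        for _ in range(n_reps):
            seq = rng.random(n) < 0.5
            specs = [("A", "B", 1.0, 1.0, "left" if c else "right") for c in seq]
            res = choice_bias_tests(build_session(specs))
            rej_binom += res["binomial_p"] < 0.05
            rej_run += res["runlength_lr_p"] < 0.05
        assert 0.025 <= rej_binom / n_reps <= 0.075
        assert 0.025 <= rej_run / n_reps <= 0.075

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError, match="10"):
            choice_bias_tests(build_session([("A", "B", 1.0, 1.0, "left")] * 5))


class TestTradeoffQuantification:
    def test_magnitude_maximizer_forgoes_nothing(self, factorial_stimuli):
        specs = [
            ("LFLS", "HFLS", 2.0, 1.0, "left"),
            ("HFLS", "LFLS", 0.5, 1.5, "right"),
        ] * 3
        res = tradeoff_quantification(build_session(specs), factorial_stimuli)
        assert res["pct_magnitude_forgone"] == pytest.approx(0.0)
        assert res["pct_fat_gained"] == pytest.approx(0.0)

    def test_always_hfls_agent_matches_hand_summation(self, factorial_stimuli, toy_hfls_session):
        # agent total: 4 x 1 mL of HFLS; oracle picks the 2 mL side each trial (LFLS)
        res = tradeoff_quantification(toy_hfls_session, factorial_stimuli)
        assert res["pct_magnitude_forgone"] == pytest.approx(100.0 * (8 - 4) / 8)
        fat_agent = 4 * 1.0 * 3.6 / 100
        fat_oracle = 4 * 2.0 * 0.1 / 100
        assert res["pct_fat_gained"] == pytest.approx(100.0 * (fat_agent - fat_oracle) / fat_oracle)

    def test_scale_invariance(self, factorial_stimuli, toy_hfls_session):
        scaled = build_session(
            [
                (t.stim_left, t.stim_right, 3 * t.mag_left, 3 * t.mag_right, t.choice)
                for t in toy_hfls_session.trials
            ]
        )
        a = tradeoff_quantification(toy_hfls_session, factorial_stimuli)
        b = tradeoff_quantification(scaled, factorial_stimuli)
        assert a["pct_magnitude_forgone"] == pytest.approx(b["pct_magnitude_forgone"])
        assert a["pct_sugar_gained"] == pytest.approx(b["pct_sugar_gained"])


ALL_PAIRS = [("LFLS", "HFLS"), ("LFLS", "LFHS"), ("HFLS", "LFHS"), ("LFLS", "HFHS")]


class TestNutrientModel:
    def test_aic_and_pseudo_r2_definitions(self, factorial_stimuli):
        agent = synth.NutrientValueFunction("a", w_fat=0.08, w_sugar=0.12, temperature=2.0)
        data = _sessions(agent, factorial_stimuli, ALL_PAIRS, 300, 31)
        fit = fit_nutrient_model(data, factorial_stimuli)
        assert fit.aic == pytest.approx(2 * len(fit.params) - 2 * fit.llf)
        assert fit.pseudo_r2 == pytest.approx(1 - fit.llf / fit.ll_null)
        assert 0 < fit.pseudo_r2 <= 1

    def test_nutrient_blind_agent_coefficients_not_significant(self, factorial_stimuli):
        blind = synth.NutrientValueFunction("b", temperature=2.0)
        hits = 0
        n_reps = 40
        for rep in range(n_reps):
            data = _sessions(blind, factorial_stimuli, ALL_PAIRS, 150, 500 + rep)
            fit = fit_nutrient_model(data, factorial_stimuli)
            z_fat = abs(fit.params["dfat"] / fit.bse["dfat"])
            z_sugar = abs(fit.params["dsugar"] / fit.bse["dsugar"])
            hits += (z_fat < 2.576) and (z_sugar < 2.576)
        assert hits >= int(0.85 * n_reps)

    def test_interaction_and_level_coding_supported(self, factorial_stimuli):
        agent = synth.NutrientValueFunction(
            "i", w_fat=0.05, w_sugar=0.1, w_interaction=0.01, temperature=2.0
        )
        data = _sessions(agent, factorial_stimuli, ALL_PAIRS, 200, 32)
        fit = fit_nutrient_model(data, factorial_stimuli, include_interaction=True)
        assert "dfat_x_sugar" in fit.params.index
        fit_lvl = fit_nutrient_model(data, factorial_stimuli, coding="level")
        assert abs(fit_lvl.params["dfat"]) < 10  # dichotomous coding stays finite

    def test_session_effects_fixed_and_random_agree(self, factorial_stimuli):
        rng = np.random.default_rng(42)
        sessions = []
        for i in range(6):
            agent = synth.NutrientValueFunction(
                "a", w_sugar=0.15, temperature=2.0, side_bias=float(rng.normal(0, 0.5))
            )
            sessions.append(
                synth.simulate_session(
                    agent,
                    (factorial_stimuli["LFLS"], factorial_stimuli["LFHS"]),
                    250,
                    seed=600 + i,
                    session_id=f"s{i}",
                )
            )
        fixed = fit_nutrient_model(
            sessions, factorial_stimuli, session_effects="fixed"
        )
        random = fit_nutrient_model(
            sessions, factorial_stimuli, session_effects="random"
        )
        assert random.sigma_session > 0.05
        assert random.params["dsugar"] == pytest.approx(fixed.params["dsugar"], rel=0.15)

    def test_history_regressors_recover_feedback_sign(self, factorial_stimuli):
        sticky = synth.NutrientValueFunction(
            "h", w_fat=0.05, temperature=1.5, h_fat=0.8
        )
        data = _sessions(sticky, factorial_stimuli, [("LFLS", "HFLS")] * 4, 400, 33)
        fit = fit_nutrient_model(data, factorial_stimuli, include_history=True)
        assert fit.params["hist_fat"] > 0
        assert fit.params["hist_fat"] / fit.bse["hist_fat"] > 2

    def test_requires_two_sessions_for_session_effects(self, factorial_stimuli):
        agent = synth.NutrientValueFunction("a", w_fat=0.1)
        data = _sessions(agent, factorial_stimuli, [("LFLS", "HFLS")], 100, 34)
        with pytest.raises(ValueError, match="2 sessions"):
            fit_nutrient_model(data, factorial_stimuli, session_effects="fixed")


class TestValueTransformValidate:
    def test_generator_consistent_values_predict_well(self, factorial_stimuli):
        agent = synth.NutrientValueFunction("a", w_fat=0.10, w_sugar=0.14, temperature=2.5)
        data = _sessions(agent, factorial_stimuli, ALL_PAIRS, 1250, 41)
        rv = {
            sid: agent.rho_ratio(factorial_stimuli[sid], factorial_stimuli["LFLS"])
            for sid in ("HFLS", "LFHS", "HFHS")
        }
        res = value_transform_validate(data, rv, "LFLS", k_folds=10, seed=4)
        assert res["adjusted_R2"] > 0.9

    def test_shuffled_choices_have_no_predictive_value(self, factorial_stimuli):
        agent = synth.NutrientValueFunction("a", w_fat=0.10, w_sugar=0.14, temperature=2.5)
        data = _sessions(agent, factorial_stimuli, ALL_PAIRS, 500, 42)
        rv = {
            sid: agent.rho_ratio(factorial_stimuli[sid], factorial_stimuli["LFLS"])
            for sid in ("HFLS", "LFHS", "HFHS")
        }
        rng = np.random.default_rng(5)
        r2s = []
        for rep in range(10):
            # destroyed signal: independent fair-coin choices
            shuffled = []
            for s in data:
                shuffled.append(
                    Session(
                        id=s.id,
                        agent_id=s.agent_id,
                        trials=[
                            Trial(t.session_id, t.index, t.stim_left, t.stim_right,
                                  t.mag_left, t.mag_right,
                                  "left" if rng.random() < 0.5 else "right")
                            for t in s.trials
                        ],
                    )
                )
            r2s.append(
                value_transform_validate(shuffled, rv, "LFLS", seed=rep)["adjusted_R2"]
            )
        assert abs(np.mean(r2s)) < 0.05

    def test_reference_only_sessions_reduce_to_magnitude(self, factorial_stimuli):
        sess = build_session(
            [("LFLS", "LFLS", 1.0, 0.4, "left"), ("LFLS", "LFLS", 0.3, 0.9, "right")] * 10
        )
        res = value_transform_validate([sess], {}, "LFLS", k_folds=2, seed=0)
        diffs = [t.mag_left - t.mag_right for t in sess.trials]
        assert sorted(np.round(res["curve"]["value_diff"], 9).unique()) == sorted(
            set(np.round(diffs, 9))
        )

    def test_fewer_trials_than_folds_rejected(self, factorial_stimuli):
        sess = build_session([("LFLS", "HFLS", 1.0, 1.0, "left")] * 5)
        with pytest.raises(ValueError, match="folds"):
            value_transform_validate([sess], {"HFLS": 1.5}, "LFLS", k_folds=10)


class TestTransitivity:
    def test_implied_value_multiplies(self):
        fits = {("B", "A"): 2.0, ("C", "B"): 3.0, ("C", "A"): 6.5}
        table = transitivity_check(fits)
        row = table.iloc[0]
        assert row["implied"] == pytest.approx(6.0)
        assert row["measured"] == pytest.approx(6.5)

    def test_disconnected_graph_rejected(self):
        with pytest.raises(ValueError, match="disconnected"):
            transitivity_check({("B", "A"): 2.0, ("D", "C"): 3.0})

    def test_generative_values_are_transitive(self, factorial_stimuli):
        agent = synth.NutrientValueFunction("t", w_fat=0.09, w_sugar=0.13, temperature=2.5)
        hits = total = 0
        for rep in range(15):
            fits = {}
            for ref, tgt in (("LFLS", "HFLS"), ("HFLS", "LFHS"), ("LFLS", "LFHS")):
                data = _sessions(agent, factorial_stimuli, [(ref, tgt)], 400, 700 + 10 * rep)
                fits[(ref, tgt)] = psychometric_fit(
                    data, ref, tgt, n_bootstrap=300, seed=rep
                )
            table = transitivity_check(fits)
            for _, row in table.iterrows():
                if not np.isnan(row["within_ci"]):
                    total += 1
                    hits += bool(row["within_ci"])
        assert hits >= 0.8 * total


def test_estimators_agree_on_relative_value(factorial_stimuli):
    """Psychometric indifference point and the regression-implied value
    ratio are two estimators of the same generative quantity."""
    agent = synth.NutrientValueFunction("c", w_fat=0.12, temperature=2.0)
    data = _sessions(agent, factorial_stimuli, [("LFLS", "HFLS")], 3000, 51)
    psy = psychometric_fit(data, "LFLS", "HFLS", n_bootstrap=100, seed=1)
    reg = fit_nutrient_model(data, factorial_stimuli)
    implied = implied_rho_ratio(reg, factorial_stimuli["HFLS"], factorial_stimuli["LFLS"])
    assert implied == pytest.approx(psy.indifference_point, rel=0.10)
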