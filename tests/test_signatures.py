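import math

import numpy as np
import pandas as pd
import pytest

from conftest import build_session
from creditrl.agents import simulate_session
from creditrl.models import ParamSet, Variant, run_model
from creditrl.signatures import (
    StayEvent,
    _logit_table,
    behavioral_metrics,
    choice_prediction_regression,
    credit_gradient,
    extract_stay_events,
    pairtype_accuracy,
    parameter_condition_tests,
    stay_events_frame,
    stay_signature_regression,
)
from creditrl.task import (
    Condition,
    generate_reward_walk,
    generate_schedule,
    make_stimulus_set,
)

TAB_AGENT = ParamSet(0, 0, 0, 0.4, 0.8, 4.0, Variant.TABULAR)
ELG_AGENT = ParamSet(0.35, 0.6, 4.0, 0, 0, 0, Variant.ELIGIBILITY)


def _oracle_session(seed, choose="max"):
    stimset = make_stimulus_set(seed)
    schedule = generate_schedule(8, 2, seed=seed + 1)
    walk = generate_reward_walk(stimset, schedule.n_trials, seed=seed + 2)
    pick = (np.argmax if choose == "max" else np.argmin)
    choices = [pair[pick([walk.delivered[t, pair[0]], walk.delivered[t, pair[1]]])]
               for t, pair in enumerate(schedule.pairs)]
    return build_session(stimset, walk, choices, schedule.pairs, Condition.CONJOINT)


class TestBehavioralMetrics:
    def test_oracle_agent(self):
        assert behavioral_metrics(_oracle_session(1))["optimal_choice"] == 1.0

    def test_anti_oracle_agent(self):
        sess = _oracle_session(2, choose="min")
        metrics = behavioral_metrics(sess)
        # ties count optimal for either pick, so the floor is the tie rate
        ties = np.mean([
            sess.walk.delivered[t, a] == sess.walk.delivered[t, b]
            for t, (a, b) in enumerate(tr.pair for tr in sess.trials)
        ])
        assert metrics["optimal_choice"] == pytest.approx(ties)

    def test_hand_computed_four_trials(self, canonical_stimset, flat_walk):
        # delivered values are the start values: id0=4, id1=1, id2=-1, id5=1
        sess = build_session(canonical_stimset, flat_walk,
                             [0, 2, 1, 5], [(0, 1), (2, 3), (1, 5), (4, 5)],
                             Condition.CONJOINT)
        m = behavioral_metrics(sess)
        # optimal: t0 (4>1) yes, t1 (-1>-4) yes, t2 (1 vs 1 tie) yes, t3 (1<4) no
        assert m["optimal_choice"] == pytest.approx(3 / 4)
        assert m["average_outcome"] == pytest.approx((4 - 1 + 1 + 1) / 4)


class TestStayEvents:
    @pytest.mark.parametrize("condition", list(Condition))
    def test_engineered_reappearance(self, condition, canonical_stimset, flat_walk):
        pairs = [(4, 0), (1, 5), (0, 2), (4, 2), (0, 1), (2, 3), (0, 3), (1, 2)]
        choices = [4, 1, 0, 4, 0, 2, 3, 1]
        sess = build_session(canonical_stimset, flat_walk, choices, pairs, condition)
        events = extract_stay_events(sess)
        assert len(events) == 1
        ev = events[0]
        assert (ev.t, ev.stay) == (0, True)
        # t0 shows nothing (delayed choice, no queue) -> negative;
        # t2 delivers the origin's delayed 4 -> positive
        assert not ev.reward_0f_positive
        assert ev.reward_2f_positive

    def test_component_valence_source(self, canonical_stimset, flat_walk):
        pairs = [(4, 0), (1, 5), (0, 2), (4, 2), (0, 1), (2, 3), (0, 3), (1, 2)]
        choices = [4, 1, 0, 4, 0, 2, 3, 1]
        sess = build_session(canonical_stimset, flat_walk, choices, pairs,
                             Condition.DISJOINT)
        ev = extract_stay_events(sess, valence_source="component")[0]
        assert not ev.reward_0f_positive and ev.reward_2f_positive

    def test_immediate_only_choices_yield_nothing(self, canonical_stimset, flat_walk):
        pairs = [(0, 1), (1, 2), (2, 3), (0, 2), (1, 3), (0, 3)]
        choices = [0, 1, 2, 0, 3, 0]
        sess = build_session(canonical_stimset, flat_walk, choices, pairs,
                             Condition.CONJOINT)
        assert extract_stay_events(sess) == []

    def test_event_count_bounded_and_idempotent(self, simulated_session_factory):
        sess = simulated_session_factory(7)
        events = extract_stay_events(sess)
        n_delayed = sum(
            1 for tr in sess.trials
            if tr.choice is not None and sess.stimset.is_delayed(tr.choice)
        )
        assert len(events) <= n_delayed
        assert extract_stay_events(sess) == events


def _random_events(n, rng):
    return [
        StayEvent("p%d" % (i % 10), rng.choice(list(Condition)), i,
                  stay=bool(rng.random() < 0.5),
                  reward_0f_positive=bool(rng.random() < 0.5),
                  reward_2f_positive=bool(rng.random() < 0.5))
        for i in range(n)
    ]


class TestStayRegression:
    def test_two_by_two_odds_ratio_oracle(self):
        # stay/switch 30/10 under pos vs 20/20 under neg -> OR = 3
        rows = (
            [{"stay": 1, "pos": 1}] * 30 + [{"stay": 0, "pos": 1}] * 10
            + [{"stay": 1, "pos": 0}] * 20 + [{"stay": 0, "pos": 0}] * 20
        )
        table = _logit_table(pd.DataFrame(rows), "stay ~ pos")
        coef = table.set_index("term").loc["pos"]
        assert coef.odds_ratio == pytest.approx(3.0, rel=1e-6)

    def test_null_events_give_unit_odds_ratios(self):
        rng = np.random.default_rng(42)
        table = stay_signature_regression(_random_events(2000, rng))
        for _, row in table.coef_table.iterrows():
            if row.term == "Intercept":
                continue
            assert abs(math.log(row.odds_ratio)) < 0.5
            assert row.or_ci_low < 1.0 < row.or_ci_high

    def test_cell_means_structure(self):
        rng = np.random.default_rng(3)
        table = stay_signature_regression(_random_events(400, rng))
        cells = table.cell_means
        assert len(cells) == 8
        assert cells.stay_rate.between(0, 1).all()
        assert cells.n.sum() == 800

    def test_empty_events_rejected(self):
        with pytest.raises(ValueError):
            stay_signature_regression([])


def test_tabular_agents_use_delayed_feedback(simulated_session_factory):
    """Tabular agents in disjoint show a larger positive-vs-negative
    stay gap for the two-trials-forward reward than for the immediate
    one."""
    events = []
    for seed in range(25):
        sess = simulated_session_factory(100 + seed, Condition.DISJOINT,
                                         params=TAB_AGENT)
        events.extend(extract_stay_events(sess))
    df = stay_events_frame(events)
    rate = df.groupby(["time2f", "pos"]).stay.mean()
    gap_2f = rate[1, 1] - rate[1, 0]
    gap_0f = rate[0, 1] - rate[0, 0]
    assert gap_2f > gap_0f
    assert gap_2f > 0


class TestPairtypeAccuracy:
    def test_self_agreement(self, simulated_session_factory):
        sess = simulated_session_factory(9)
        acc = pairtype_accuracy([sess], [sess]).set_index("pair_type")
        assert (acc.accuracy == 1.0).all()
        # 6 del/del + 6 imm/imm + 16 mixed pair kinds x 12 repeats
        assert acc.loc["del_del", "n"] == 72
        assert acc.loc["imm_imm", "n"] == 72
        assert acc.loc["mixed", "n"] == 192

    def test_chance_agreement_for_random_generator(self, simulated_session_factory):
        observed = simulated_session_factory(10)
        random_params = ParamSet(0.3, 0.5, 0.0, 0.3, 0.5, 0.0)
        from creditrl.task import TrialSchedule

        schedule = TrialSchedule(tuple(t.pair for t in observed.trials), seed=0)
        gen = simulate_session(random_params, schedule, observed.walk,
                               observed.stimset, observed.condition, seed=11,
                               participant_id=observed.participant_id + "@iter0")
        acc = pairtype_accuracy([gen], [observed])
        assert np.all(np.abs(acc.accuracy - 0.5) < 0.12)

    def test_schedule_mismatch_rejected(self, simulated_session_factory):
        a = simulated_session_factory(12)
        b = simulated_session_factory(13)
        b.participant_id = a.participant_id
        with pytest.raises(ValueError, match="mismatch"):
            pairtype_accuracy([b], [a])


def _probs_for(sessions, params):
    return [run_model(s, params).probs for s in sessions]


class TestChoicePredictionRegression:
    def test_planted_truth_prefers_generating_model(self, simulated_session_factory):
        observed = [simulated_session_factory(200 + s, Condition.DISJOINT,
                                              params=TAB_AGENT) for s in range(6)]
        table = choice_prediction_regression(
            observed, _probs_for(observed, ELG_AGENT), _probs_for(observed, TAB_AGENT)
        ).coef_table.set_index("term")
        assert table.loc["tab", "coef"] > 0
        assert table.loc["tab", "p"] < 1e-6
        assert table.loc["tab", "coef"] > abs(table.loc["elg", "coef"])

    def test_constant_predictors_reported_rank_deficient(self, simulated_session_factory):
        observed = [simulated_session_factory(220)]
        n = observed[0].n_trials
        flat = [np.full((n, 2), 0.5)]
        with pytest.raises(ValueError, match="rank-deficient"):
            choice_prediction_regression(observed, flat, flat)

    def test_planted_condition_interaction(self, simulated_session_factory):
        """Boosting the tabular weight in disjoint only plants a
        positive disjoint x tabular interaction."""
        weak = ParamSet(0, 0, 0, 0.4, 0.8, 1.0, Variant.TABULAR)
        strong = ParamSet(0, 0, 0, 0.4, 0.8, 6.0, Variant.TABULAR)
        observed = []
        for s in range(6):
            observed.append(simulated_session_factory(300 + s, Condition.CONJOINT,
                                                      params=weak))
            observed.append(simulated_session_factory(320 + s, Condition.DISJOINT,
                                                      params=strong))
        table = choice_prediction_regression(
            observed, _probs_for(observed, ELG_AGENT), _probs_for(observed, TAB_AGENT)
        ).coef_table.set_index("term")
        assert table.loc["disjoint:tab", "odds_ratio"] > 1.0

    def test_non_finite_predictors_rejected(self, simulated_session_factory):
        observed = [simulated_session_factory(230)]
        bad = [np.full((observed[0].n_trials, 2), np.nan)]
        with pytest.raises(ValueError, match="non-finite"):
            choice_prediction_regression(observed, bad, bad)


class TestCreditGradient:
    def test_tabular_skips_lags_one_and_three(self, simulated_session_factory):
        sessions = [simulated_session_factory(400 + s, params=TAB_AGENT)
                    for s in range(2)]
        grad = credit_gradient(sessions, TAB_AGENT, Variant.TABULAR)
        odd = grad[grad.lag.isin([1, 3])]
        assert not odd.empty
        assert np.all(odd.mean_credit == 0.0)
        even = grad[grad.lag.isin([0, 2])]
        assert np.any(even.mean_credit != 0.0)

    def test_eligibility_geometric_decay(self, simulated_session_factory):
        sessions = [simulated_session_factory(410, params=ELG_AGENT)]
        grad = credit_gradient(sessions, ELG_AGENT, Variant.ELIGIBILITY)
        lam = ELG_AGENT.lambda_elg
        for (_, _), grp in grad.groupby(["condition", "valence"]):
            grp = grp.set_index("lag")
            for lag in range(3):
                if abs(grp.mean_credit[lag]) > 1e-9:
                    assert grp.mean_credit[lag + 1] / grp.mean_credit[lag] == \
                        pytest.approx(lam, rel=1e-9)

    def test_no_learning_no_credit(self, simulated_session_factory):
        frozen = ParamSet(0.0, 0.6, 4.0, 0, 0, 0, Variant.ELIGIBILITY)
        sessions = [simulated_session_factory(420, params=frozen)]
        grad = credit_gradient(sessions, frozen, Variant.ELIGIBILITY)
        assert np.all(grad.mean_credit == 0.0)

    def test_hybrid_rejected(self, simulated_session_factory):
        with pytest.raises(ValueError):
            credit_gradient([], ParamSet(), Variant.HYBRID)


class TestParameterConditionTests:
    @staticmethod
    def _fits(vectors):
        from creditrl.fitting import FitResult

        out = []
        for v in vectors:
            p = ParamSet(*v)
            out.append(FitResult(p, 100.0, 100.0, 6, 336, 212.0, 0.0, 0.1,
                                 {"seed": 0, "iterations": 0, "converged": True}))
        return out

    def test_identical_parameters_null_contrast(self):
        rng = np.random.default_rng(1)
        vecs = rng.uniform(0.1, 0.9, size=(5, 6))
        tab = parameter_condition_tests(self._fits(vecs), self._fits(vecs))
        assert np.all(tab.t == 0)
        assert np.all(tab.cohens_d == 0)

    def test_constant_shift_flagged_degenerate(self):
        rng = np.random.default_rng(2)
        base = rng.uniform(0.2, 0.6, size=(4, 6))
        tab = parameter_condition_tests(self._fits(base + 0.1), self._fits(base))
        assert tab.degenerate.all()
        assert np.all(np.isinf(tab.t))

    def test_hand_computed_pairs(self):
        conj = np.linspace(0.2, 0.65, 10)
        disj = conj + np.linspace(-0.05, 0.13, 10)
        vec_c = np.column_stack([conj] * 6)
        vec_d = np.column_stack([disj] * 6)
        tab = parameter_condition_tests(self._fits(vec_c), self._fits(vec_d))
        diff = conj - disj
        import statistics

        m = statistics.mean(diff)
        sd = statistics.stdev(diff)
        t_expect = m / (sd / math.sqrt(10))
        row = tab.iloc[0]
        assert row.t == pytest.approx(t_expect, rel=1e-9)
        assert row.cohens_d == pytest.approx(m / sd, rel=1e-9)
        assert row.df == 9

    def test_unpaired_inputs_rejected(self):
        rng = np.random.default_rng(3)
        with pytest.raises(ValueError):
            parameter_condition_tests(
                self._fits(rng.uniform(0.1, 0.9, (3, 6))),
                self._fits(rng.uniform(0.1, 0.9, (4, 6))),
            )
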