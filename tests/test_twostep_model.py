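"""Hybrid learner updates, likelihood, simulation, and hierarchical fit."""

import numpy as np
import pandas as pd
import pytest

from fourstep.twostep_model import (
    PARAM_NAMES,
    TwoStepParams,
    choice_probabilities,
    fit_hierarchical,
    loglik_twostep,
    mb_values,
    mf_update,
    new_qtable,
    sample_generating_params,
    simulate_agent,
)
from fourstep.twostep_task import TaskConfig, TwoStepTrial, generate_schedule, \
    trials_to_frame


def _trial(choice1=0, state2=1, choice2=0, reward=0, t=0):
    return TwoStepTrial(trial=t, choice1=choice1, transition="common",
                        state2=state2, choice2=choice2, reward=reward)


class TestModelFreeUpdate:
    def test_reward_propagates_with_full_eligibility(self):
        q, trace = mf_update(new_qtable(), _trial(reward=1), alpha=0.5, lam=1.0)
        assert q[1, 0] == pytest.approx(0.5)
        assert q[0, 0] == pytest.approx(0.5)  # 0 bootstrap + 0.5*1*delta2
        assert trace.delta1 == 0.0 and trace.delta2 == 1.0

    def test_no_reward_no_change_from_zero(self):
        q, _ = mf_update(new_qtable(), _trial(reward=0), alpha=0.5, lam=1.0)
        assert np.all(q == 0)

    def test_lambda_zero_gives_only_bootstrap_to_step1(self):
        q0 = new_qtable()
        q0[1, 0] = 0.8  # pre-existing Step-2 value
        q, trace = mf_update(q0, _trial(reward=1), alpha=0.5, lam=0.0)
        # delta1 = 0.8 - 0 = 0.8 -> Q(s1) += 0.4; no trace contribution
        assert q[0, 0] == pytest.approx(0.4)
        assert trace.delta1 == pytest.approx(0.8)

    def test_q_values_bounded_in_unit_interval(self, rng):
        # with rewards in {0,1} and Q0 = 0, all values stay in [0,1]
        params = TwoStepParams(alpha=0.9, lam=0.9)
        sch = generate_schedule(TaskConfig(), rng)
        q = new_qtable()
        for t in simulate_agent(params, sch, rng):
            q, _ = mf_update(q, t, params.alpha, params.lam)
            assert np.all(q >= 0) and np.all(q <= 1)


class TestModelBasedValues:
    def test_bellman_backup(self):
        q = new_qtable()
        q[1, 0] = 1.0
        assert mb_values(q, 0.75) == pytest.approx([0.75, 0.25])

    def test_equal_maxima_give_equal_values(self):
        q = new_qtable()
        q[1, 1] = 0.6
        q[2, 0] = 0.6
        assert mb_values(q, 0.75)[0] == mb_values(q, 0.75)[1]

    def test_uninformative_transitions_give_equal_values(self):
        q = new_qtable()
        q[1, 0] = 0.9
        qmb = mb_values(q, 0.5)
        assert qmb[0] == qmb[1]


class TestChoiceProbabilities:
    def test_zero_betas_give_uniform(self):
        params = TwoStepParams(beta_mf=0, beta_mb=0, beta_step2=0, p=0.0)
        p1, p2 = choice_probabilities(new_qtable(), np.zeros(2), params, None)
        assert p1 == pytest.approx([0.5, 0.5])
        assert np.allclose(p2, 0.5)

    def test_large_repetition_bias_forces_stay(self):
        params = TwoStepParams(beta_mf=0, beta_mb=0, beta_step2=0, p=50.0)
        p1, _ = choice_probabilities(new_qtable(), np.zeros(2), params, 1)
        assert p1[1] > 0.999

    def test_softmax_closed_form(self):
        params = TwoStepParams(beta_mf=0, beta_mb=1.0, beta_step2=0, p=0.0)
        p1, _ = choice_probabilities(new_qtable(), np.array([0.75, 0.25]),
                                     params, None)
        assert p1[0] == pytest.approx(1 / (1 + np.exp(-0.5)))


class TestSimulationAndLikelihood:
    def test_chance_policy_has_chance_accuracy(self, rng):
        params = TwoStepParams(beta_mf=0, beta_mb=0, beta_step2=0, p=0.0)
        cfg = TaskConfig()
        correct = total = 0
        for _ in range(10):
            sch = generate_schedule(cfg, rng)
            for t in simulate_agent(params, sch, rng):
                hs_state = t.high_shape // 2 + 1
                correct += (t.choice1 == 0) == (hs_state == 1)
                total += 1
        assert abs(correct / total - 0.5) < 3 * np.sqrt(0.25 / total)

    def test_model_based_agent_beats_chance(self, rng):
        params = TwoStepParams(alpha=0.5, beta_mf=0, beta_mb=5.0,
                               beta_step2=5.0, p=0.0)
        cfg = TaskConfig()
        correct = total = 0
        for _ in range(20):
            sch = generate_schedule(cfg, rng)
            for t in simulate_agent(params, sch, rng):
                hs_state = t.high_shape // 2 + 1
                correct += (t.choice1 == 0) == (hs_state == 1)
                total += 1
        assert correct / total > 0.52

    def test_same_seed_identical_simulation(self):
        params = TwoStepParams()
        sch = generate_schedule(TaskConfig(), np.random.default_rng(3))
        a = simulate_agent(params, sch, np.random.default_rng(4))
        b = simulate_agent(params, sch, np.random.default_rng(4))
        assert a == b

    def test_uniform_policy_loglik_closed_form(self, rng):
        params = TwoStepParams(beta_mf=0, beta_mb=0, beta_step2=0, p=0.0)
        sch = generate_schedule(TaskConfig(), rng)
        trials = simulate_agent(params, sch, rng)
        expected = 2 * (288 - 9) * np.log(0.5)
        assert loglik_twostep(params, trials) == pytest.approx(expected)

    def test_generating_params_beat_ablated_model(self, rng):
        gen = TwoStepParams(alpha=0.5, lam=0.5, beta_mf=1.0, beta_mb=3.0,
                            beta_step2=3.0, p=0.2)
        ablated = TwoStepParams(alpha=0.5, lam=0.5, beta_mf=1.0, beta_mb=0.001,
                                beta_step2=3.0, p=0.2)
        diffs = []
        for _ in range(25):
            sch = generate_schedule(TaskConfig(), rng)
            trials = simulate_agent(gen, sch, rng)
            diffs.append(loglik_twostep(gen, trials)
                         - loglik_twostep(ablated, trials))
        assert np.mean(diffs) > 0

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            loglik_twostep(TwoStepParams(), [])
        with pytest.raises(ValueError):
            loglik_twostep(TwoStepParams(), [_trial(t=t) for t in range(5)])

    def test_simulation_frequencies_match_choice_probabilities(self, rng):
        # at fixed Q (first trial, all zeros), step-1 choice frequencies
        # across simulations match the softmax output
        params = TwoStepParams(beta_mf=0.0, beta_mb=0.0, beta_step2=0.0, p=0.0)
        sch = generate_schedule(TaskConfig(), rng)
        firsts = [simulate_agent(params, sch, rng)[0].choice1
                  for _ in range(2000)]
        assert abs(np.mean(firsts) - 0.5) < 3 * np.sqrt(0.25 / 2000)


class TestHierarchicalFit:
    def _cohort(self, rng, n, params_fn):
        frames = []
        for i in range(n):
            params = params_fn(i)
            sch = generate_schedule(TaskConfig(), rng)
            frames.append(trials_to_frame(simulate_agent(params, sch, rng),
                                          subject_id=f"s{i:02d}"))
        return pd.concat(frames, ignore_index=True)

    def test_single_subject_rejected(self, rng):
        data = self._cohort(rng, 1, lambda i: TwoStepParams())
        with pytest.raises(ValueError):
            fit_hierarchical(data, chains=2, samples=50, warmup=20, seed=1)

    def test_posterior_means_respect_constraints(self, rng):
        data = self._cohort(rng, 8, lambda i: sample_generating_params(rng))
        post = fit_hierarchical(data, chains=2, samples=150, warmup=100,
                                n_scans=3, seed=1)
        means = post.subject_means
        assert np.all(means[:, 0] > 0) and np.all(means[:, 0] < 1)   # alpha
        assert np.all(means[:, 1] > 0) and np.all(means[:, 1] < 1)   # lam
        assert np.all(means[:, 2:5] > 0) and np.all(means[:, 2:5] < 10)
        assert set(post.rhat) >= {"mu_alpha", "sigma_p"}

    def test_group_mean_beta_mb_ordering_recovered(self, rng):
        lo = self._cohort(
            rng, 10, lambda i: TwoStepParams(beta_mb=0.3, beta_mf=1.0))
        hi = self._cohort(
            rng, 10, lambda i: TwoStepParams(beta_mb=3.0, beta_mf=1.0))
        post_lo = fit_hierarchical(lo, chains=2, samples=200, warmup=150,
                                   n_scans=4, seed=2)
        post_hi = fit_hierarchical(hi, chains=2, samples=200, warmup=150,
                                   n_scans=4, seed=2)
        k = PARAM_NAMES.index("beta_mb")
        assert post_hi.subject_means[:, k].mean() > \
            post_lo.subject_means[:, k].mean()
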