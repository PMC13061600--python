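import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chasegame import (
    AttractionPair,
    ChaseParams,
    GameSpec,
    build_payoff_matrix,
    chase_session_derivatives,
    chase_session_loglik,
    chase_step,
    init_chase_state,
)
from chasegame.chase import (
    action_prediction_error,
    bayes_update,
    belief_update_kl,
    choice_value,
    distort_likelihood,
    integrated_policy,
    level_likelihood,
    level_policy,
    scaled_matrix,
    softmax,
    update_attractions,
)

from conftest import make_random_session

ROCK, PAPER, SCISSORS = 0, 1, 2
PI3 = build_payoff_matrix(GameSpec()).entries


def one_hot_pair(n, self_idx=None, opp_idx=None):
    a_s = np.full(n, 1.0 / n) if self_idx is None else np.eye(n)[self_idx]
    a_o = np.full(n, 1.0 / n) if opp_idx is None else np.eye(n)[opp_idx]
    return AttractionPair(a_self=a_s, a_opp=a_o)


class TestSoftmax:
    def test_hand_computed_value(self):
        np.testing.assert_allclose(
            softmax(np.array([1.0, 0.0, 0.0]), 1.0),
            [0.57611688, 0.21194156, 0.21194156],
            atol=1e-7,
        )

    def test_zero_temperature_is_uniform(self):
        np.testing.assert_allclose(softmax(np.array([3.0, -1.0, 0.5]), 0.0), [1 / 3] * 3)

    def test_large_temperature_approaches_argmax(self):
        p = softmax(np.array([1.0, 0.0, 0.0]), 1e4)
        assert p[0] > 1 - 1e-12

    def test_negative_temperature_rejected(self):
        with pytest.raises(ValueError):
            softmax(np.array([1.0, 0.0]), -1.0)


class TestAttractions:
    def test_delta_rule_hand_value(self):
        a = update_attractions(np.array([1 / 3] * 3), 1, 0.5)
        np.testing.assert_allclose(a, [1 / 6, 2 / 3, 1 / 6])
        assert abs(a.sum() - 1.0) < 1e-12

    @pytest.mark.parametrize("alpha,expected", [(0.0, [1 / 3] * 3), (1.0, [0, 1, 0])])
    def test_no_learning_and_full_overwrite(self, alpha, expected):
        np.testing.assert_allclose(
            update_attractions(np.array([1 / 3] * 3), 1, alpha), expected
        )

    def test_out_of_range_alpha_rejected(self):
        with pytest.raises(ValueError):
            update_attractions(np.array([1 / 3] * 3), 0, 1.5)


class TestLevelPolicy:
    def test_worked_example_response_chain(self):
        # opponent history concentrated on "paper": a level-1 player responds
        # with scissors; a level-2 player (whose own history shows paper)
        # expects that response and plays rock
        attr = one_hot_pair(3, self_idx=PAPER, opp_idx=PAPER)
        k1 = level_policy(1, attr, "self_play", PI3, 1e4)
        assert k1.argmax() == SCISSORS and k1[SCISSORS] > 0.999
        k2 = level_policy(2, attr, "self_play", PI3, 1e4)
        assert k2.argmax() == ROCK and k2[ROCK] > 0.999

    def test_level_zero_is_softmax_of_base_attraction(self):
        attr = one_hot_pair(3, self_idx=ROCK, opp_idx=PAPER)
        np.testing.assert_allclose(
            level_policy(0, attr, "self_play", PI3, 2.0),
            softmax(attr.a_self, 2.0),
        )
        np.testing.assert_allclose(
            level_policy(0, attr, "opponent_prediction", PI3, 2.0),
            softmax(attr.a_opp, 2.0),
        )

    def test_zero_temperature_gives_uniform_at_any_level(self):
        attr = one_hot_pair(3, self_idx=ROCK, opp_idx=PAPER)
        for k in range(4):
            np.testing.assert_allclose(
                level_policy(k, attr, "self_play", PI3, 0.0), [1 / 3] * 3
            )

    @pytest.mark.parametrize("n", [3, 4])
    def test_best_response_cycle_has_period_n(self, n):
        pi = build_payoff_matrix(GameSpec(n_actions=n)).entries
        attr = one_hot_pair(n, self_idx=0, opp_idx=0)
        maxima = [
            int(level_policy(k, attr, "self_play", pi, 1e5).argmax())
            for k in range(2 * n + 1)
        ]
        # each level best responds to the previous: a cycle through all actions
        assert sorted(maxima[:n]) == list(range(n))
        for k in range(n + 1):
            assert maxima[k + n] == maxima[k]

    def test_parity_rule_mirrors_between_perspectives(self):
        attr = one_hot_pair(3, self_idx=ROCK, opp_idx=PAPER)
        for k in range(4):
            mirrored = AttractionPair(a_self=attr.a_opp, a_opp=attr.a_self)
            np.testing.assert_allclose(
                level_policy(k, attr, "opponent_prediction", PI3, 3.0),
                level_policy(k, mirrored, "self_play", PI3, 3.0),
            )


class TestLevelInference:
    def test_single_level_likelihood(self):
        attr = one_hot_pair(3, opp_idx=ROCK)
        lik = level_likelihood(ROCK, attr, 1, PI3, 5.0)
        assert lik.shape == (1,)
        np.testing.assert_allclose(lik[0], softmax(attr.a_opp, 5.0)[ROCK])

    def test_uninformative_policies_give_uniform_likelihood(self):
        attr = one_hot_pair(3, self_idx=ROCK, opp_idx=PAPER)
        np.testing.assert_allclose(level_likelihood(2, attr, 3, PI3, 0.0), [1 / 3] * 3)

    def test_observed_repeat_favours_level_zero(self):
        # opponent has a history of rock and plays rock again: strong evidence
        # for level-0 (frequency-repeating) play, against level-1
        attr = one_hot_pair(3, opp_idx=ROCK)
        lik = level_likelihood(ROCK, attr, 2, PI3, 1e3)
        # level-1 responds to our (uniform) history, so its prediction is
        # uniform: evidence discriminates level 0 from level 1 at 1 vs 1/3
        assert lik[0] > 0.99
        assert lik[1] == pytest.approx(1 / 3, abs=1e-9)
        # with an informative own history the level-1 prediction is sharp
        attr2 = one_hot_pair(3, self_idx=ROCK, opp_idx=ROCK)
        lik2 = level_likelihood(ROCK, attr2, 2, PI3, 1e3)
        assert lik2[0] > 0.99 and lik2[1] < 0.01  # level 1 would play paper

    def test_distortion_boundaries_and_hand_value(self):
        np.testing.assert_allclose(
            distort_likelihood(np.array([0.8, 0.2]), 0.0), [0.5, 0.5]
        )
        np.testing.assert_allclose(
            distort_likelihood(np.array([0.5, 0.5]), 7.3), [0.5, 0.5]
        )
        np.testing.assert_allclose(
            distort_likelihood(np.array([0.8, 0.2]), 1.0),
            [0.64565631, 0.35434369],
            atol=1e-7,
        )
        with pytest.raises(ValueError):
            distort_likelihood(np.array([0.8, 0.2]), -1.0)

    def test_bayes_update_cases(self):
        np.testing.assert_allclose(
            bayes_update(np.array([0.5, 0.5]), np.array([0.8, 0.2])), [0.8, 0.2]
        )
        b = np.array([0.3, 0.7])
        np.testing.assert_allclose(bayes_update(b, np.array([0.5, 0.5])), b)
        np.testing.assert_allclose(
            bayes_update(np.array([1.0, 0.0]), np.array([0.2, 0.8])), [1.0, 0.0]
        )
        with pytest.raises(ValueError, match="degenerate"):
            bayes_update(np.array([1.0, 0.0]), np.array([0.0, 1.0]))

    def test_kl_divergence_values_and_errors(self):
        assert belief_update_kl(np.array([0.4, 0.6]), np.array([0.4, 0.6])) == 0.0
        np.testing.assert_allclose(
            belief_update_kl(np.array([0.8, 0.2]), np.array([0.5, 0.5])),
            0.8 * np.log(1.6) + 0.2 * np.log(0.4),
            atol=1e-12,
        )
        with pytest.raises(ValueError, match="infinite"):
            belief_update_kl(np.array([0.5, 0.5]), np.array([1.0, 0.0]))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_kl_nonnegative(self, seed):
        rng = np.random.default_rng(seed)
        post = rng.dirichlet(np.ones(3))
        prior = rng.dirichlet(np.ones(3)) + 1e-6
        prior /= prior.sum()
        assert belief_update_kl(post, prior) >= -1e-15

    def test_bu_nondecreasing_in_sensitivity_from_uniform_prior(self):
        lik = np.array([0.7, 0.2, 0.1])
        prior = np.full(3, 1 / 3)
        bus = [
            belief_update_kl(bayes_update(prior, distort_likelihood(lik, g)), prior)
            for g in (0.0, 0.5, 1.0, 2.0, 5.0, 20.0)
        ]
        assert all(b2 >= b1 - 1e-12 for b1, b2 in zip(bus, bus[1:]))
        assert bus[0] == 0.0  # gamma = 0: insensitive learner never updates


class TestValuationSignals:
    def test_choice_value_cases(self):
        rock_hat = np.eye(3)[ROCK]
        assert choice_value(PAPER, rock_hat, PI3) == 1.0
        for a in range(3):
            assert choice_value(a, np.full(3, 1 / 3), PI3) == pytest.approx(0.0)
        pi_l2 = scaled_matrix(GameSpec(), 2.0)
        assert choice_value(
            SCISSORS, np.array([0.5, 0.5, 0.0]), pi_l2
        ) == pytest.approx(-0.5)

    def test_action_prediction_error_cases(self):
        assert action_prediction_error(ROCK, np.eye(3)[ROCK]) == 0.0
        assert action_prediction_error(1, np.full(3, 1 / 3)) == pytest.approx(2 / 3)
        assert action_prediction_error(0, np.array([0.8, 0.1, 0.1])) == pytest.approx(
            0.2
        )

    def test_integrated_policy_marginalizes_beliefs(self):
        rows = np.stack([np.eye(3)[ROCK], np.eye(3)[PAPER]])
        own, pred = integrated_policy(np.array([0.5, 0.5]), rows, PI3, 1e4)
        np.testing.assert_allclose(pred, [0.5, 0.5, 0.0])
        # expected payoffs: rock -0.5+0.5=0... paper +0.5-0.5... scissors -0.5+0.5
        ev = PI3 @ pred
        assert own.argmax() == ev.argmax()
        own_unif, _ = integrated_policy(np.array([0.5, 0.5]), rows, PI3, 0.0)
        np.testing.assert_allclose(own_unif, [1 / 3] * 3)


class TestChaseStep:
    def test_first_trial_of_block_is_uninformed(self):
        params = ChaseParams(alpha=0.3, beta=4.0, gamma=5.0, lam=1.0, kappa=3)
        state = init_chase_state(3, 3)
        _, d = chase_step(state, ROCK, PAPER, params, PI3)
        np.testing.assert_allclose(d.predicted_opp, [1 / 3] * 3, atol=1e-12)
        assert d.ape == pytest.approx(2 / 3)

    def test_bu_chains_on_previous_posterior(self):
        params = ChaseParams(alpha=0.3, beta=4.0, gamma=5.0, lam=1.0, kappa=3)
        state = init_chase_state(3, 3)
        s1, d1 = chase_step(state, ROCK, PAPER, params, PI3)
        s2, d2 = chase_step(s1, ROCK, PAPER, params, PI3)
        expected_prior = s1.beliefs.b
        lik = np.array(
            [
                level_policy(k, s1.attractions, "opponent_prediction", PI3, 4.0)[PAPER]
                for k in range(3)
            ]
        )
        post = bayes_update(expected_prior, distort_likelihood(lik, 5.0))
        assert d2.bu == pytest.approx(belief_update_kl(post, expected_prior), abs=1e-12)


class TestSessionLoglik:
    def test_zero_temperature_likelihood_ceiling(self):
        rng = np.random.default_rng(1)
        session = make_random_session(rng, n_blocks=1, n_trials=40)
        params = ChaseParams(alpha=0.3, beta=0.0, gamma=5.0, lam=1.0, kappa=3)
        assert chase_session_loglik(session, params) == pytest.approx(
            -40 * np.log(3), abs=1e-9
        )

    def test_invariance_under_consistent_action_relabeling(self):
        rng = np.random.default_rng(2)
        session = make_random_session(rng, n_blocks=2, n_trials=15)
        params = ChaseParams(alpha=0.4, beta=3.0, gamma=8.0, lam=1.5, kappa=3)
        ll = chase_session_loglik(session, params)
        # rotating all action labels preserves the circular game structure
        for b in session.blocks:
            b.actions_self = (b.actions_self + 1) % 3
            b.actions_opp = (b.actions_opp + 1) % 3
        assert chase_session_loglik(session, params) == pytest.approx(ll, abs=1e-10)

    def test_derivatives_export_schema_and_zscore(self):
        rng = np.random.default_rng(3)
        session = make_random_session(rng, n_blocks=2, n_trials=10)
        params = ChaseParams(alpha=0.3, beta=3.0, gamma=5.0, lam=1.0, kappa=3)
        df = chase_session_derivatives(session, params)
        assert list(df.columns) == [
            "participant", "block", "trial", "cv", "ape", "bu", "bu_z",
            "modal_level_response",
        ]
        assert len(df) == 20
        assert df["bu"].min() >= 0
        assert df["bu_z"].mean() == pytest.approx(0.0, abs=1e-12)
        assert set(df["modal_level_response"]) <= {1, 2, 3}

    def test_insensitive_learner_never_updates_beliefs(self):
        rng = np.random.default_rng(4)
        session = make_random_session(rng)
        params = ChaseParams(alpha=0.3, beta=3.0, gamma=0.0, lam=1.0, kappa=3)
        df = chase_session_derivatives(session, params)
        np.testing.assert_allclose(df["bu"], 0.0, atol=1e-15)


class TestStepKernelAgreement:
    def test_step_path_matches_session_kernel(self):
        from chasegame import _kernels

        rng = np.random.default_rng(5)
        params = ChaseParams(alpha=0.31, beta=4.2, gamma=7.5, lam=1.7, kappa=3)
        session = make_random_session(rng, n_blocks=2, n_trials=12)
        acts_s, acts_o, blocks = session.to_arrays()
        pi = scaled_matrix(session.game, params.lam)
        _, own, pred, bpri, bpost, cv, ape, bu = _kernels.chase_session(
            acts_s, acts_o, blocks, pi,
            params.alpha, params.beta, params.gamma, params.kappa,
        )
        state = init_chase_state(3, 3)
        for t in range(len(acts_s)):
            if t > 0 and blocks[t] != blocks[t - 1]:
                state = init_chase_state(3, 3)
            state, d = chase_step(state, int(acts_s[t]), int(acts_o[t]), params, pi)
            np.testing.assert_allclose(d.own_policy, own[t], atol=1e-12)
            np.testing.assert_allclose(d.predicted_opp, pred[t], atol=1e-12)
            np.testing.assert_allclose(state.beliefs.b, bpost[t], atol=1e-12)
            assert d.cv == pytest.approx(cv[t], abs=1e-12)
            assert d.ape == pytest.approx(ape[t], abs=1e-12)
            assert d.bu == pytest.approx(bu[t], abs=1e-12)
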