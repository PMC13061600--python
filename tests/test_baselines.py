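import numpy as np
import pytest

from chasegame import GameSpec, MODELS, build_payoff_matrix, model_loglik
from chasegame import _kernels
from chasegame.agents import (
    EWAAgent,
    RLAgent,
    STEWAAgent,
    ToMkAgent,
)
from chasegame.baselines import (
    EWAState,
    RLState,
    ToMkState,
    ewa_step,
    rl_step,
    stewa_step,
    tomk_policy,
    tomk_step,
)

from conftest import make_random_session

GAME = GameSpec()
PI3 = build_payoff_matrix(GAME).entries


class TestRL:
    def test_delta_rule_hand_value(self):
        s = rl_step(RLState(q=np.zeros(3)), 0, 1.0, 0.5)
        np.testing.assert_allclose(s.q, [0.5, 0.0, 0.0])

    def test_unchosen_values_decay_toward_zero(self):
        s = rl_step(RLState(q=np.array([0.4, 0.4, 0.4])), 0, 1.0, 0.5)
        np.testing.assert_allclose(s.q, [0.7, 0.2, 0.2])
        s2 = rl_step(
            RLState(q=np.array([0.4, 0.4, 0.4])), 0, 1.0, 0.5, decay_unchosen=False
        )
        np.testing.assert_allclose(s2.q, [0.7, 0.4, 0.4])

    def test_no_learning_at_zero_rate(self):
        q = np.array([0.2, -0.1, 0.0])
        np.testing.assert_allclose(rl_step(RLState(q=q), 1, -1.0, 0.0).q, q)

    def test_random_play_likelihood_ceiling(self):
        rng = np.random.default_rng(0)
        session = make_random_session(rng, n_blocks=1, n_trials=30)
        ll = model_loglik("rl", session, {"alpha": 0.4, "beta": 0.0})
        assert ll == pytest.approx(-30 * np.log(3), abs=1e-9)


class TestEWA:
    def test_experience_update_hand_value(self):
        s = ewa_step(
            EWAState(a=np.zeros(3), n=1.0), 0, 0, PI3,
            delta=0.5, phi=0.9, rho=0.9,
        )
        assert s.n == pytest.approx(1.9)

    def test_delta_limits_control_foregone_learning(self):
        # opponent played rock (0): foregone payoffs (tie, win, lose)=(0,1,-1)
        full = ewa_step(EWAState(a=np.zeros(3)), 0, 0, PI3, 1.0, 0.9, 0.9)
        np.testing.assert_allclose(full.a, PI3[:, 0])
        realized_only = ewa_step(EWAState(a=np.zeros(3)), 0, 0, PI3, 0.0, 0.9, 0.9)
        np.testing.assert_allclose(realized_only.a, [0.0, 0.0, 0.0])  # tie payoff
        realized_only2 = ewa_step(EWAState(a=np.zeros(3)), 1, 0, PI3, 0.0, 0.9, 0.9)
        np.testing.assert_allclose(realized_only2.a, [0.0, 1.0, 0.0])

    def test_boundary_pure_latest_payoff(self):
        s = ewa_step(EWAState(a=np.full(3, 5.0), n=0.0), 1, 0, PI3, 1.0, 0.0, 0.3)
        np.testing.assert_allclose(s.a, PI3[:, 0])
        assert s.n == 1.0

    def test_reduces_to_rescaled_rl(self):
        # delta=0, rho=0, phi=1-alpha: EWA attractions are RL values / alpha,
        # so policies coincide when beta_ewa = alpha * beta_rl
        rng = np.random.default_rng(1)
        alpha, beta = 0.35, 4.0
        rl_agent = RLAgent(alpha, beta, GAME)
        ewa_agent = EWAAgent(0.0, 1 - alpha, 0.0, alpha * beta, GAME)
        for _ in range(25):
            own, opp = rng.integers(0, 3), rng.integers(0, 3)
            np.testing.assert_allclose(
                rl_agent.policy(), ewa_agent.policy(), atol=1e-12
            )
            rl_agent.observe(own, opp)
            ewa_agent.observe(own, opp)


class TestSelfTuningEWA:
    def test_stationary_opponent_full_window_gives_no_forgetting(self):
        hist = np.array([0, 1, 2, 0, 1, 2, 1])
        state, phi_t = stewa_step(
            EWAState(a=np.zeros(3), n=1.0), 0, 1, PI3, hist, window=len(hist)
        )
        assert phi_t == pytest.approx(1.0)

    def test_surprising_switch_depresses_change_detector(self):
        hist = np.array([0] * 30 + [2])
        _, phi_switch = stewa_step(
            EWAState(a=np.zeros(3)), 0, 2, PI3, hist, window=1
        )
        _, phi_stay = stewa_step(
            EWAState(a=np.zeros(3)), 0, 0, PI3, np.array([0] * 31), window=1
        )
        assert phi_switch < phi_stay
        assert phi_switch < 0.6  # near the floor after a fresh switch

    def test_attention_selects_weakly_better_actions(self):
        # realized payoff is the maximum available: only the chosen action
        # (and equal-payoff actions, none in RPS) attract
        hist = np.array([0, 0])
        state, _ = stewa_step(EWAState(a=np.zeros(3)), 1, 0, PI3, hist)
        assert state.a[1] > 0 and state.a[0] == 0 and state.a[2] == 0


class TestToMk:
    def test_confidence_delta_rule_hand_values(self):
        preds = np.array([[1.0, 0.0, 0.0]])  # level 1 predicted rock
        c = tomk_step(
            ToMkState(
                attr_self=np.full(3, 1 / 3),
                attr_opp=np.full(3, 1 / 3),
                c=np.array([0.5]),
            ),
            preds, 0, 0, 0.2,
        ).c
        assert c[0] == pytest.approx(0.8 * 0.5 + 0.2)
        c_wrong = tomk_step(
            ToMkState(
                attr_self=np.full(3, 1 / 3),
                attr_opp=np.full(3, 1 / 3),
                c=np.array([0.5]),
            ),
            preds, 0, 1, 0.2,
        ).c
        assert c_wrong[0] == pytest.approx(0.4)

    def test_lowest_level_credit_assignment(self):
        # levels 1 and 2 both predict rock, rock occurs: only level 1 gains
        preds = np.array([[1.0, 0, 0], [1.0, 0, 0], [0, 1.0, 0]])
        state = ToMkState(
            attr_self=np.full(3, 1 / 3),
            attr_opp=np.full(3, 1 / 3),
            c=np.array([0.5, 0.5, 0.5]),
        )
        c = tomk_step(state, preds, 0, 0, 0.2).c
        assert c[0] == pytest.approx(0.6)   # credited
        assert c[1] == pytest.approx(0.5)   # explained by a lower level
        assert c[2] == pytest.approx(0.4)   # predicted wrong: decays

    def test_argmax_tie_split_keeps_policy_normalized(self):
        state = ToMkState.initial(3, 2)
        pol, preds = tomk_policy(state, 2, PI3, 5.0)
        assert pol.sum() == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(preds.sum(axis=1), 1.0, atol=1e-12)

    def test_level_zero_responds_to_opponent_frequencies(self):
        state = ToMkState(
            attr_self=np.full(3, 1 / 3), attr_opp=np.eye(3)[0], c=np.zeros(0)
        )
        pol, _ = tomk_policy(state, 0, PI3, 1e4)
        assert pol.argmax() == 1  # paper beats the frequent rock


class TestRegistry:
    def test_parameter_counts_feed_aic(self):
        expected = {"chase": 5, "rl": 2, "fp": 2, "ewa": 4, "stewa": 1, "tomk": 3}
        assert {name: spec.n_params for name, spec in MODELS.items()} == expected

    @pytest.mark.parametrize("name", list(MODELS))
    def test_policies_are_probability_vectors_every_trial(self, name):
        rng = np.random.default_rng(7)
        session = make_random_session(rng, n_blocks=2, n_trials=15)
        acts_s, acts_o, blocks = session.to_arrays()
        kern = {
            "chase": lambda: _kernels.chase_session(
                acts_s, acts_o, blocks, PI3, 0.3, 3.0, 5.0, 3
            )[1],
            "rl": lambda: _kernels.rl_session(
                acts_s, acts_o, blocks, PI3, 0.3, 3.0, True
            )[1],
            "fp": lambda: _kernels.chase_session(
                acts_s, acts_o, blocks, PI3, 0.3, 3.0, 1.0, 1
            )[1],
            "ewa": lambda: _kernels.ewa_session(
                acts_s, acts_o, blocks, PI3, 0.5, 0.8, 0.7, 3.0
            )[1],
            "stewa": lambda: _kernels.stewa_session(
                acts_s, acts_o, blocks, PI3, 3.0, 1
            )[1],
            "tomk": lambda: _kernels.tomk_session(
                acts_s, acts_o, blocks, PI3, 0.3, 3.0, 2, 0.8, 0.5
            )[1],
        }[name]()
        np.testing.assert_allclose(kern.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(kern >= 0)


class TestKernelAgentAgreement:
    """The generative agents and the session kernels implement one model."""

    @pytest.mark.parametrize(
        "name,agent_factory,kernel_call",
        [
            (
                "rl",
                lambda: RLAgent(0.35, 2.5, GAME),
                lambda a_s, a_o, b: _kernels.rl_session(
                    a_s, a_o, b, PI3, 0.35, 2.5, True
                )[1],
            ),
            (
                "ewa",
                lambda: EWAAgent(0.6, 0.85, 0.4, 2.5, GAME),
                lambda a_s, a_o, b: _kernels.ewa_session(
                    a_s, a_o, b, PI3, 0.6, 0.85, 0.4, 2.5
                )[1],
            ),
            (
                "stewa",
                lambda: STEWAAgent(2.5, GAME),
                lambda a_s, a_o, b: _kernels.stewa_session(
                    a_s, a_o, b, PI3, 2.5, 1
                )[1],
            ),
            (
                "tomk",
                lambda: ToMkAgent(0.35, 2.5, 2, GAME),
                lambda a_s, a_o, b: _kernels.tomk_session(
                    a_s, a_o, b, PI3, 0.35, 2.5, 2, 0.8, 0.5
                )[1],
            ),
        ],
    )
    def test_trialwise_policies_match(self, name, agent_factory, kernel_call):
        rng = np.random.default_rng(11)
        session = make_random_session(rng, n_blocks=2, n_trials=18)
        acts_s, acts_o, blocks = session.to_arrays()
        pols = kernel_call(acts_s, acts_o, blocks)
        agent = agent_factory()
        for t in range(len(acts_s)):
            if t > 0 and blocks[t] != blocks[t - 1]:
                agent.reset()
            np.testing.assert_allclose(agent.policy(), pols[t], atol=1e-12)
            agent.observe(int(acts_s[t]), int(acts_o[t]))
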