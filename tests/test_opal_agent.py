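import math

import numpy as np
import pytest
from scipy.special import expit

from opalstar import OpALParams, make_bernoulli_env
from opalstar.opal_agent import (
    FlawFlags,
    OpALAgent,
    action_propensities,
    actor_update,
    anneal_rate,
    compute_rho,
    critic_update,
    init_state,
    meta_critic_update,
    opal_step,
    select_action,
)


def fresh_state(params, n_arms=2, v0=0.5):
    return init_state(params, n_arms, v0)


class TestCritic:
    def test_delta_rule_single_update(self):
        params = OpALParams(alpha_c=0.1, critic="per_arm")
        s = fresh_state(params)
        s, delta = critic_update(s, 0, 1.0, params)
        assert delta == pytest.approx(0.5)
        assert s.V[0] == pytest.approx(0.55)
        assert s.V[1] == 0.5  # other arm untouched

    def test_reward_equal_to_value_is_fixed_point(self):
        params = OpALParams(critic="per_arm")
        s = fresh_state(params)
        s, delta = critic_update(s, 1, 0.5, params)
        assert delta == 0.0
        assert np.all(s.V == 0.5)

    def test_shared_critic_updates_single_value(self):
        params = OpALParams(alpha_c=0.1)  # shared default
        s = fresh_state(params)
        assert s.V.shape == (1,)
        s, delta = critic_update(s, 1, 1.0, params)
        assert delta == pytest.approx(0.5)
        assert s.value(0) == s.value(1) == pytest.approx(0.55)

    def test_non_finite_reward_rejected(self):
        params = OpALParams()
        with pytest.raises(ValueError):
            critic_update(fresh_state(params), 0, float("nan"), params)

    def test_stochastic_convergence_to_arm_mean(self):
        # Monte-Carlo oracle: repeated pulls of a Bernoulli(0.9) arm drive V there
        params = OpALParams(alpha_c=0.01, critic="per_arm")
        s = fresh_state(params)
        rng = np.random.default_rng(11)
        for _ in range(5000):
            r = 1.0 if rng.random() < 0.9 else 0.0
            s, _ = critic_update(s, 0, r, params)
        assert abs(s.V[0] - 0.9) < 0.05


class TestActor:
    def test_first_update_reduces_to_standard_rule(self):
        # with G = N = 1 the multiplicative term is identity
        params = OpALParams(alpha_g=0.3, alpha_n=0.3)
        s = fresh_state(params)
        s = actor_update(s, 0, 0.2, params)
        assert s.G[0] - 1.0 == pytest.approx(0.3 * 0.2, abs=1e-15)
        assert s.N[0] - 1.0 == pytest.approx(-0.3 * 0.2, abs=1e-15)

    def test_zero_delta_leaves_weights(self):
        params = OpALParams()
        s = fresh_state(params)
        s = actor_update(s, 0, 0.0, params)
        assert np.all(s.G == 1.0) and np.all(s.N == 1.0)

    def test_sequential_unroll_matches_hand_product(self):
        # G = 2, rate 0.1, deltas [0.5, -0.5] -> 2 * 1.05 * 0.95
        params = OpALParams(alpha_g=0.1, alpha_n=0.1, T=1e12)  # rate ~ constant
        s = fresh_state(params)
        s.G[0] = 2.0
        for d in (0.5, -0.5):
            s = actor_update(s, 0, d, params)
        assert s.G[0] == pytest.approx(2.0 * 1.05 * 0.95, abs=1e-12)

    def test_only_chosen_arm_changes(self):
        params = OpALParams()
        s = fresh_state(params, n_arms=4)
        s = actor_update(s, 2, 0.7, params)
        untouched = [0, 1, 3]
        assert np.all(s.G[untouched] == 1.0) and np.all(s.N[untouched] == 1.0)

    def test_opponency_directions(self):
        params = OpALParams()
        for d in (0.4, -0.4):
            s = fresh_state(params)
            s = actor_update(s, 0, d, params)
            assert (s.G[0] - 1.0) * (s.N[0] - 1.0) < 0

    def test_cap_flag_limits_weights(self):
        params = OpALParams(flaws=FlawFlags(cap_at_10=True), alpha_g=1.0, alpha_n=1.0)
        s = fresh_state(params)
        s.G[0] = 9.0
        s = actor_update(s, 0, 1.0, params)
        assert s.G[0] == 10.0


class TestAnnealing:
    @pytest.mark.parametrize(
        "alpha,t,T,expected",
        [(0.3, 0, 100.0, 0.3), (0.3, 100, 100.0, 0.15), (0.5, 100, 100.0, 0.25)],
    )
    def test_hyperbolic_form(self, alpha, t, T, expected):
        assert anneal_rate(alpha, t, T) == pytest.approx(expected)

    def test_strictly_decreasing(self):
        rates = [anneal_rate(0.4, t, 100.0) for t in range(0, 500, 50)]
        assert all(a > b for a, b in zip(rates, rates[1:]))

    def test_flaw_flag_sets_fast_annealing(self):
        params = OpALParams(T=100.0, flaws=FlawFlags(T_equals_10=True))
        assert params.effective_T == 10.0


class TestMetaCritic:
    def test_positive_delta_increments_eta(self):
        s = fresh_state(OpALParams())
        s = meta_critic_update(s, 0.3)
        assert (s.eta, s.zeta, s.t) == (2.0, 1.0, 1)

    def test_negative_and_zero_delta_increment_zeta(self):
        for d in (-0.3, 0.0):
            s = fresh_state(OpALParams())
            s = meta_critic_update(s, d)
            assert (s.eta, s.zeta) == (1.0, 2.0)

    def test_count_conservation(self):
        s = fresh_state(OpALParams())
        rng = np.random.default_rng(0)
        for _ in range(500):
            s = meta_critic_update(s, rng.normal())
        assert s.eta + s.zeta == 2.0 + 500
        assert s.t == 500


class TestRho:
    def test_symmetric_counts_give_zero(self):
        s = fresh_state(OpALParams())
        s.eta = s.zeta = 400.0
        assert compute_rho(s, OpALParams(k=20.0)) == 0.0

    def test_k_zero_always_zero(self):
        s = fresh_state(OpALParams())
        s.eta, s.zeta = 900.0, 10.0
        assert compute_rho(s, OpALParams(k=0.0)) == 0.0

    def test_rich_environment_hand_oracle(self):
        # Beta-moment oracle: eta=90, zeta=10 -> m=0.9, s ~ 0.0299, gate open
        s = fresh_state(OpALParams())
        s.eta, s.zeta = 90.0, 10.0
        m = 0.9
        sd = math.sqrt(90 * 10 / (100**2 * 101))
        assert sd == pytest.approx(0.0299, abs=1e-4)
        assert not (m - sd <= 0.5 <= m + sd)
        expected = 2.0 * expit(20.0 * (m - 0.5)) - 1.0
        rho = compute_rho(s, OpALParams(k=20.0, phi=1.0))
        assert rho == pytest.approx(expected, abs=1e-12)
        assert rho == pytest.approx(1.0, abs=1e-3)

    def test_uncertain_counts_gated_to_zero(self):
        s = fresh_state(OpALParams())
        s.eta, s.zeta = 2.0, 1.0  # wide posterior still straddles 0.5
        assert compute_rho(s, OpALParams(k=20.0, phi=1.0)) == 0.0

    def test_rho_bounded(self):
        s = fresh_state(OpALParams())
        s.eta, s.zeta = 1e6, 1.0
        rho = compute_rho(s, OpALParams(k=20.0))
        assert 0.0 < rho < 1.0


class TestChoice:
    def test_equal_propensities_equal_probabilities(self, rng):
        params = OpALParams()
        s = fresh_state(params, n_arms=4)
        props = action_propensities(s, params)
        assert np.allclose(props, props[0])
        counts = np.bincount(
            [select_action(props, rng) for _ in range(40_000)], minlength=4
        )
        se = math.sqrt(0.25 * 0.75 / 40_000)
        assert np.all(np.abs(counts / 40_000 - 0.25) < 4 * se)

    def test_extreme_rho_silences_one_pathway(self):
        params = OpALParams(beta=0.7)
        s = fresh_state(params)
        s.G[:], s.N[:] = [2.0, 1.0], [5.0, 3.0]
        s.rho = 1.0
        assert np.allclose(action_propensities(s, params), 2 * 0.7 * s.G)
        s.rho = -1.0
        assert np.allclose(action_propensities(s, params), -2 * 0.7 * s.N)

    def test_g_only_ignores_n(self):
        params = OpALParams()
        s = fresh_state(params)
        s.N[:] = [9.0, 1.0]
        props = action_propensities(s, params, g_only=True)
        s.N[:] = [1.0, 9.0]
        assert np.allclose(props, action_propensities(s, params, g_only=True))

    def test_closed_form_two_arm_probability(self):
        # propensities [10, 0] -> P(arm 0) = 1/(1+e^-10)
        rng = np.random.default_rng(5)
        n = 20_000
        hits = sum(select_action(np.array([10.0, 0.0]), rng) == 0 for _ in range(n))
        p = 1.0 / (1.0 + math.exp(-10.0))
        assert abs(hits / n - p) < 4 * math.sqrt(p * (1 - p) / n) + 1e-9

    def test_non_finite_propensity_rejected(self, rng):
        with pytest.raises(ValueError):
            select_action(np.array([1.0, float("inf")]), rng)


def unrolled_opal_reference(probabilities, params, seed, n_trials):
    """Straight-line reference trace, arithmetic written out by hand.

    Consumes the rng in the same order as the agent (one uniform for the
    softmax draw, one for the Bernoulli outcome) but shares no code with it.
    """
    rng = np.random.default_rng(seed)
    n = len(probabilities)
    V = params.v0 if params.v0 is not None else 0.5
    G = [1.0] * n
    N = [1.0] * n
    eta = zeta = 1.0
    trace = []
    for t in range(n_trials):
        m = eta / (eta + zeta)
        sd = math.sqrt(eta * zeta / ((eta + zeta) ** 2 * (eta + zeta + 1)))
        if params.k == 0 or (m - params.phi * sd <= 0.5 <= m + params.phi * sd):
            rho = 0.0
        else:
            rho = 2.0 / (1.0 + math.exp(-params.k * (m - 0.5))) - 1.0
        bg, bn = params.beta * (1 + rho), params.beta * (1 - rho)
        x = [bg * G[a] - bn * N[a] for a in range(n)]
        mx = max(x)
        w = [math.exp(v - mx) for v in x]
        cum, acc = [], 0.0
        for v in w:
            acc += v
            cum.append(acc)
        u = rng.random() * acc
        arm = next(i for i, c in enumerate(cum) if u < c)
        reward = 1.0 if rng.random() < probabilities[arm] else 0.0
        delta = reward - V
        V = V + params.alpha_c * delta
        rate_g = params.alpha_g / (1 + t / params.T)
        rate_n = params.alpha_n / (1 + t / params.T)
        G[arm] = max(params.weight_floor, G[arm] + rate_g * G[arm] * delta)
        N[arm] = max(params.weight_floor, N[arm] - rate_n * N[arm] * delta)
        if delta > 0:
            eta += 1.0
        else:
            zeta += 1.0
        trace.append(
            dict(t=t, arm=arm, reward=reward, delta=delta, rho=rho,
                 V=V, G=list(G), N=list(N), eta=eta, zeta=zeta)
        )
    return trace


class TestOpalStep:
    def test_three_trial_trace_matches_hand_unroll(self, env_det):
        params = OpALParams()
        ref = unrolled_opal_reference([1.0, 0.0], params, seed=2024, n_trials=3)
        s = init_state(params, 2, 0.5)
        rng = np.random.default_rng(2024)
        for step_ref in ref:
            s, rec = opal_step(s, env_det, params, rng)
            assert rec.arm == step_ref["arm"]
            assert rec.reward == step_ref["reward"]
            assert rec.delta == pytest.approx(step_ref["delta"], abs=1e-12)
            assert rec.rho == pytest.approx(step_ref["rho"], abs=1e-12)
            assert s.value(0) == pytest.approx(step_ref["V"], abs=1e-12)
            assert np.allclose(s.G, step_ref["G"], atol=1e-12)
            assert np.allclose(s.N, step_ref["N"], atol=1e-12)
            assert (s.eta, s.zeta) == (step_ref["eta"], step_ref["zeta"])

    def test_k_zero_agent_has_zero_rho_throughout(self, env10):
        agent = OpALAgent(OpALParams(k=0.0))
        agent.reset(env10)
        rng = np.random.default_rng(9)
        assert all(agent.step(env10, rng).rho == 0.0 for _ in range(200))

    def test_flaw_flags_change_trajectory(self, env10):
        from opalstar.opal_agent import make_flawed_params

        records = []
        for params in (OpALParams(), make_flawed_params(OpALParams())):
            agent = OpALAgent(params)
            agent.reset(env10)
            rng = np.random.default_rng(33)
            records.append([agent.step(env10, rng).arm for _ in range(300)])
        assert records[0] != records[1]

    def test_forced_sampling_pulls_every_arm_once(self, env10):
        agent = OpALAgent(OpALParams(), forced_sampling=True)
        agent.reset(env10)
        rng = np.random.default_rng(1)
        arms = [agent.step(env10, rng).arm for _ in range(10)]
        assert arms == list(range(10))


class TestBinomialEquivalence:
    def test_positive_rpe_count_equals_reward_count(self):
        # with V strictly inside (0,1), reward 1 <=> positive RPE
        env = make_bernoulli_env([0.7, 0.4])
        agent = OpALAgent(OpALParams(alpha_c=0.05))
        agent.reset(env)
        rng = np.random.default_rng(21)
        rewards = sum(agent.step(env, rng).reward for _ in range(1000))
        assert agent.state.eta - 1.0 == rewards
        assert 0.0 < agent.state.value(0) < 1.0


class TestTailSpecialization:
    def test_actor_gaps_favor_better_arm_on_gaussian_task(self, env_gauss, fig2_params):
        g_gaps, n_gaps = [], []
        for seed in range(30):
            agent = OpALAgent(fig2_params)
            agent.reset(env_gauss)
            rng = np.random.default_rng(seed)
            for _ in range(2000):
                agent.step(env_gauss, rng)
            g_gaps.append(agent.state.G[0] - agent.state.G[1])
            n_gaps.append(agent.state.N[1] - agent.state.N[0])
        assert np.mean(g_gaps) > 0  # G favors the better arm
        assert np.mean(n_gaps) > 0  # N opposes the worse arm
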