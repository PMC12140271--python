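import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pasom import ModelConfig, NetworkState
from pasom.behaviour import (CONSTRUCTIVE, SILENT, TOXIC, apply_toxicity,
                             decide_action, desired_connections, observe,
                             payoff, resolve_chains, toxic_probability)
from pasom.priors import AgentStates


def make_states(pi_S=0.5, pi_A1=0.4, pi_A0=0.4, pi_T1=0.08, pi_T0=0.08,
                lam=1.0, n=1):
    """Single-agent-style state with prescribed expectation medians."""
    total = 10.0
    alpha = np.full(n, pi_S * (total - 2 / 3) + 1 / 3)
    w = 10.0

    def pair(r0, r1):
        return (np.array([np.full(n, r0 * w), np.full(n, r1 * w)]),
                np.array([np.full(n, (1 - r0) * w), np.full(n, (1 - r1) * w)]))

    A_succ, A_fail = pair(pi_A0, pi_A1)
    T_succ, T_fail = pair(pi_T0, pi_T1)
    return AgentStates(
        alpha=alpha, beta=total - alpha,
        A_succ=A_succ, A_fail=A_fail, T_succ=T_succ, T_fail=T_fail,
        interested=np.ones(n, dtype=bool), lam=np.full(n, lam),
    )


class TestPayoff:
    def test_hand_value_mid_opinion(self):
        states = make_states(pi_S=0.5, pi_A1=0.4, pi_T1=0.08)
        U = payoff(1, states, K=10, shocks=(0.0, 0.0), config=ModelConfig())
        assert U[0] == pytest.approx(0.5 * np.log(5) - 1.0 - 1.0, abs=1e-9)

    def test_hand_value_confident_agent(self):
        states = make_states(pi_S=0.9, pi_A1=0.5, pi_T1=0.02)
        U = payoff(1, states, K=20, shocks=(0.0, 0.0), config=ModelConfig())
        assert U[0] == pytest.approx(0.9 * np.log(11) - 0.5 - 1.0, abs=1e-9)

    def test_zero_degree_leaves_only_fixed_cost(self):
        states = make_states(pi_S=0.8)
        U = payoff(1, states, K=0, shocks=(0.0, 0.0), config=ModelConfig())
        assert U[0] == pytest.approx(-1.0, abs=1e-12)

    def test_monotone_in_expectations(self):
        cfg = ModelConfig()
        base = payoff(1, make_states(pi_S=0.7, pi_A1=0.3), 5, (0, 0), cfg)[0]
        assert payoff(1, make_states(pi_S=0.7, pi_A1=0.5), 5, (0, 0), cfg)[0] > base
        hot = payoff(1, make_states(pi_S=0.7, pi_A1=0.3, pi_T1=0.3), 5, (0, 0), cfg)[0]
        assert hot < base


class TestDecideAction:
    def _decide(self, e_1, e_0, f):
        # with K = 0 payoffs collapse to -c_C + f + e_I, so U is set directly
        states = make_states(n=1)
        would, supported, U = decide_action(
            states, np.zeros(1), ((e_0, e_1), f), ModelConfig())
        return bool(would[0]), int(supported[0])

    def test_clear_preference_shares(self):
        would, side = self._decide(e_1=1.5, e_0=0.7, f=0.0)  # U = (0.5, -0.3)
        assert would and side == 1

    def test_undecided_stays_silent(self):
        would, _ = self._decide(e_1=1.5, e_0=1.45, f=0.0)  # U = (0.5, 0.45)
        assert not would

    def test_no_positive_payoff_stays_silent(self):
        would, _ = self._decide(e_1=0.9, e_0=0.6, f=0.0)  # U = (-0.1, -0.4)
        assert not would


class TestToxicProbability:
    def test_hand_value(self):
        assert toxic_probability(0.9, 0.25, 1, 1.0) == pytest.approx(0.6)

    def test_neutral_opinion_never_toxic(self):
        for p_S in (0.0, 0.3, 1.0):
            assert toxic_probability(0.5, p_S, 1, 1.0) == 0.0
            assert toxic_probability(0.5, p_S, 0, 1.0) == 0.0

    def test_cap_binds_at_one(self):
        assert toxic_probability(0.8, 0.0, 1, 2.0) == 1.0

    def test_supporting_against_own_opinion_never_toxic(self):
        assert toxic_probability(0.4, 0.2, 1, 1.0) == 0.0
        assert toxic_probability(0.6, 0.2, 0, 1.0) == 0.0

    @given(pi_S=st.floats(0.001, 0.999), p_S=st.floats(0, 1),
           polarity=st.sampled_from([0, 1]), c_X=st.floats(0, 5))
    @settings(deadline=None)
    def test_always_a_probability(self, pi_S, p_S, polarity, c_X):
        p = toxic_probability(pi_S, p_S, polarity, c_X)
        assert 0.0 <= p <= 1.0
        if c_X == 0:
            assert p == 0.0


def _bfs_oracle(adj, would, orig):
    """Reachability through would-sharers from originators."""
    n = adj.shape[0]
    shares = np.zeros(n, dtype=bool)
    for o in np.flatnonzero(orig):
        if shares[o]:
            continue
        stack, seen = [o], {int(o)}
        while stack:
            v = stack.pop()
            shares[v] = True
            for w in np.flatnonzero(adj[v]):
                if would[w] and w not in seen:
                    seen.add(int(w))
                    stack.append(int(w))
    return shares


class TestResolveChains:
    def test_silent_agent_breaks_the_chain(self):
        net = NetworkState(3, edges=[(0, 1), (1, 2)])
        would = np.array([True, False, True])
        orig = np.array([True, False, False])
        shares, chain = resolve_chains(would, orig, net)
        assert shares.tolist() == [True, False, False]
        assert chain.tolist() == [0, -1, -1]

    def test_connected_sharers_form_one_chain(self):
        net = NetworkState(3, edges=[(0, 1), (1, 2)])
        would = np.ones(3, dtype=bool)
        orig = np.array([True, False, False])
        shares, chain = resolve_chains(would, orig, net)
        assert shares.all()
        assert len(set(chain.tolist())) == 1

    def test_two_components_two_chain_ids(self):
        net = NetworkState(4, edges=[(0, 1), (2, 3)])
        would = np.ones(4, dtype=bool)
        orig = np.array([True, False, True, False])
        shares, chain = resolve_chains(would, orig, net)
        assert shares.all()
        assert chain[0] == chain[1] != chain[2] == chain[3]
        assert set(chain.tolist()) == {0, 1}

    def test_matches_bfs_oracle_on_small_graphs(self):
        rng = np.random.default_rng(99)
        for n in range(1, 9):
            for _ in range(25):
                adj = np.triu(rng.random((n, n)) < 0.4, k=1)
                adj = adj | adj.T
                net = NetworkState(n)
                net.adj = adj
                for _ in range(12):
                    would = rng.random(n) < 0.6
                    orig = would & (rng.random(n) < 0.4)
                    shares, chain = resolve_chains(would, orig, net)
                    np.testing.assert_array_equal(
                        shares, _bfs_oracle(adj, would, orig))
                    # chain IDs defined exactly on sharers
                    assert ((chain >= 0) == shares).all()


class TestApplyToxicity:
    def test_zero_propensity_all_constructive(self, rng):
        net = NetworkState(4, edges=[(0, 1), (1, 2), (2, 3)])
        states = make_states(pi_S=0.9, n=4)
        shares = np.ones(4, dtype=bool)
        supported = np.ones(4, dtype=np.int8)
        cfg = ModelConfig(c_X=0.0)
        action, _, p_X, _ = apply_toxicity(shares, supported, net, states, cfg, rng)
        assert (action == CONSTRUCTIVE).all() and (p_X == 0).all()

    def test_unanimous_support_never_toxic(self, rng):
        net = NetworkState(3, edges=[(0, 1), (0, 2)])
        states = make_states(pi_S=0.95, n=3)
        shares = np.ones(3, dtype=bool)
        supported = np.ones(3, dtype=np.int8)
        action, p_S, p_X, _ = apply_toxicity(shares, supported, net, states,
                                             ModelConfig(), rng)
        assert p_S[0] == 1.0 and p_X[0] == 0.0 and action[0] == CONSTRUCTIVE

    def test_toxic_fraction_tracks_probability(self):
        # Monte-Carlo: isolated sharers with p_S = 0 and pi_S = 0.8 -> p_X = 0.6
        n = 10_000
        net = NetworkState(n)
        states = make_states(pi_S=0.8, n=n)
        shares = np.ones(n, dtype=bool)
        supported = np.ones(n, dtype=np.int8)
        action, _, p_X, _ = apply_toxicity(shares, supported, net, states,
                                           ModelConfig(), np.random.default_rng(0))
        assert p_X[0] == pytest.approx(0.6)
        assert (action == TOXIC).mean() == pytest.approx(0.6, abs=0.01)


class TestObserve:
    def test_counts_by_polarity_and_kind(self):
        # agent 0 with 6 neighbours: 2 constructive-pro, 1 toxic attacking pro
        # (supports anti), 3 silent
        net = NetworkState(7, edges=[(0, k) for k in range(1, 7)])
        action = np.array([SILENT, CONSTRUCTIVE, CONSTRUCTIVE, TOXIC,
                           SILENT, SILENT, SILENT], dtype=np.int8)
        supported = np.array([-1, 1, 1, 0, -1, -1, -1], dtype=np.int8)
        A, T, p_S, n_active = observe(net, action, supported)
        assert (A[1][0], A[0][0], T[1][0], T[0][0]) == (2, 0, 1, 0)
        assert p_S[0] == pytest.approx(2 / 3)
        assert n_active[0] == 3

    def test_all_silent_and_isolated(self):
        net = NetworkState(3, edges=[(0, 1)])
        action = np.zeros(3, dtype=np.int8)
        supported = np.full(3, -1, dtype=np.int8)
        A, T, p_S, n_active = observe(net, action, supported)
        assert not A.any() and not T.any() and not p_S.any()
        assert n_active[2] == 0  # isolated agent


class TestDesiredConnections:
    def test_hand_value(self):
        states = make_states(pi_S=0.8, pi_A1=0.4, pi_T1=0.08)
        cfg = ModelConfig(c_TG=1.0, c_KG=0.05, c_BG=0.2, b_AG=1.0)
        K = desired_connections(states, cfg)
        assert K.K_1[0] == pytest.approx(0.8 / 0.13 - 2.5 + 0.2, abs=1e-6)

    def test_no_expected_toxicity_limit(self):
        states = make_states(pi_S=1.0 - 1e-12)
        states.A_fail[1] = 0.0  # pi_A1 exactly 1
        states.T_succ[1] = 0.0  # pi_T1 exactly 0
        K = desired_connections(states, ModelConfig())
        assert K.K_1[0] == pytest.approx(1 / 0.05 - 1 + 0.2, abs=1e-6)

    def test_interest_loss_shrinks_demand(self):
        hot = make_states(pi_S=0.8, lam=1.0)
        cold = make_states(pi_S=0.8, lam=0.2)
        cfg = ModelConfig()
        assert desired_connections(cold, cfg).K_1[0] < \
            desired_connections(hot, cfg).K_1[0]

    def test_zero_denominator_reports_inf_with_warning(self):
        states = make_states()
        states.T_succ[1] = 0.0  # pi_T1 exactly 0
        cfg = ModelConfig(c_KG=0.0)
        with pytest.warns(RuntimeWarning):
            K = desired_connections(states, cfg)
        assert np.isinf(K.K_1[0])
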