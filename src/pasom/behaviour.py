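"""Per-round decision logic.

Agents hold continuous opinions but can only act discretely: each round they
either stay silent or share in support of the pro- (I = 1) or anti-science
(I = 0) position, and a share is either constructive (persuasive) or toxic
(an attack on the opposing position).  Decisions come from payoff functions
that weigh the expected constructive response against the expected toxic
response — the sanction mechanism: toxic posts raise observers' expected
toxicity toward the attacked side, suppressing future support for it.

Within a round the order is fixed: (i) would-share decisions from
start-of-round beliefs; (ii) sharing-chain resolution — only connected
components of would-sharers that contain an originator actually share;
(iii) the constructive-vs-toxic draw from the resolved support pattern;
(iv) observation counts from the final actions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .config import ModelConfig
from .network import NetworkState
from .priors import AgentStates

__all__ = [
    "SILENT", "CONSTRUCTIVE", "TOXIC",
    "RoundRecord", "DesiredConnections",
    "payoff", "decide_action", "toxic_probability",
    "resolve_chains", "apply_toxicity", "observe", "desired_connections",
]

SILENT, CONSTRUCTIVE, TOXIC = 0, 1, 2


@dataclass
class RoundRecord:
    """Everything that happened in one round, as arrays over agents."""

    e: np.ndarray                      # (2,) round shocks e_j0, e_j1
    f: np.ndarray                      # (n,) agent shocks f_ij
    action: np.ndarray                 # (n,) SILENT / CONSTRUCTIVE / TOXIC
    supported: np.ndarray              # (n,) polarity I, -1 when silent
    originator: np.ndarray             # (n,) bool
    chain: np.ndarray                  # (n,) chain ID, -1 when not in a chain
    A: np.ndarray                      # (2, n) constructive posts seen per polarity
    T: np.ndarray                      # (2, n) toxic posts seen attacking each polarity
    n_active_nb: np.ndarray            # (n,) active neighbours observed
    p_S: np.ndarray                    # (n,) share of active neighbours supporting pro
    U: np.ndarray                      # (2, n) payoffs
    p_X: np.ndarray                    # (n,) toxic probability of the round's sharers
    edges_added: int = 0
    edges_removed: int = 0

    @classmethod
    def empty(cls, n: int) -> "RoundRecord":
        return cls(
            e=np.zeros(2), f=np.zeros(n),
            action=np.zeros(n, dtype=np.int8),
            supported=np.full(n, -1, dtype=np.int8),
            originator=np.zeros(n, dtype=bool),
            chain=np.full(n, -1, dtype=np.int32),
            A=np.zeros((2, n)), T=np.zeros((2, n)),
            n_active_nb=np.zeros(n, dtype=np.int64),
            p_S=np.zeros(n), U=np.zeros((2, n)), p_X=np.zeros(n),
        )


@dataclass
class DesiredConnections:
    """Optimal connection counts for the next round, per polarity."""

    K_1: np.ndarray
    K_0: np.ndarray

    def for_side(self, supported: int):
        return self.K_1 if supported == 1 else self.K_0


def payoff(polarity: int, states: AgentStates, K, shocks, config: ModelConfig):
    """Expected payoff of sharing information of ``polarity``.

    U_ijI = b_A * lambda * w_I * ln(K * pi_AI* + 1) - c_T * K * pi_TI* - c_C
            + f_ij + e_jI

    where w_1 = pi_S* and w_0 = 1 - pi_S*: more connections mean both more
    expected constructive responses (log benefit) and more expected toxic
    ones (linear cost).  ``shocks`` is ``(e_I, f)``; the log argument is at
    least 1 so the benefit term is never negative.  Vectorised over agents.
    """
    e_I, f = shocks
    K = np.asarray(K, dtype=float)
    pi_S = states.opinion
    weight = pi_S if polarity == 1 else 1.0 - pi_S
    pi_A = states.pi_A[polarity]
    pi_T = states.pi_T[polarity]
    return (config.b_A * states.lam * weight * np.log(K * pi_A + 1.0)
            - config.c_T * K * pi_T - config.c_C + f + e_I)


def decide_action(states: AgentStates, K, shocks, config: ModelConfig):
    """Would-share decision for every agent.

    Agents share the higher-payoff polarity iff some payoff is positive and
    the payoff gap exceeds the indecision threshold ``u``; otherwise silent.

    ``shocks`` is ``((e_0, e_1), f)``.  Returns ``(would_share, supported,
    U)`` with ``supported`` = -1 for silent agents and ``U`` stacked
    ``(2, n)`` in polarity order (anti, pro).
    """
    (e_0, e_1), f = shocks
    U_1 = payoff(1, states, K, (e_1, f), config)
    U_0 = payoff(0, states, K, (e_0, f), config)
    would_share = (np.maximum(U_1, U_0) > 0) & (np.abs(U_1 - U_0) > config.u)
    supported = np.where(would_share, (U_1 > U_0).astype(np.int8), np.int8(-1))
    return would_share, supported, np.stack([U_0, U_1])


def toxic_probability(pi_S, p_S, polarity, c_X: float):
    """Probability of sharing toxically rather than constructively.

    p_X = min(1, 2 c_X (pi_S* - 0.5)(1 - p_S))  if pi_S* > 0.5 and I = 1
          min(1, 2 c_X (0.5 - pi_S*) p_S)       if pi_S* < 0.5 and I = 0
          0                                      otherwise

    The more of an agent's active connections oppose it, the less persuasive
    its posts would be, so the likelier it is to attack instead; an agent
    whose active neighbourhood is unanimous on its own side never attacks.
    Agents near neutrality (or supporting the side opposite their own
    opinion) do not act toxically.  Vectorised over agents.
    """
    pi_S = np.asarray(pi_S, dtype=float)
    p_S = np.asarray(p_S, dtype=float)
    polarity = np.asarray(polarity)
    pro = (pi_S > 0.5) & (polarity == 1)
    anti = (pi_S < 0.5) & (polarity == 0)
    p = np.where(pro, 2.0 * c_X * (pi_S - 0.5) * (1.0 - p_S),
                 np.where(anti, 2.0 * c_X * (0.5 - pi_S) * p_S, 0.0))
    p = np.minimum(p, 1.0)
    return p if p.ndim else float(p)


def resolve_chains(would_share: np.ndarray, originators: np.ndarray,
                   network: NetworkState):
    """Resolve sharing chains from the would-share pattern.

    A sharing chain is a connected component of the graph restricted to
    would-sharers (of either polarity) that contains at least one
    originator.  Agents in such components actually share; every other
    would-sharer had nobody to react to and stays silent.

    Returns ``(shares, chain)``: a boolean mask of actual sharers and a
    chain ID per agent (-1 outside every chain).  Chain IDs are the
    component labels of the restricted graph, renumbered consecutively in
    order of their smallest member.
    """
    n = network.n_agents
    chain = np.full(n, -1, dtype=np.int32)
    shares = np.zeros(n, dtype=bool)
    idx = np.flatnonzero(would_share)
    if idx.size == 0:
        return shares, chain
    sub = csr_matrix(network.adj[np.ix_(idx, idx)])
    n_comp, labels = connected_components(sub, directed=False)
    has_orig = np.zeros(n_comp, dtype=bool)
    np.logical_or.at(has_orig, labels, originators[idx])
    live = has_orig[labels]
    shares[idx[live]] = True
    # renumber live components consecutively
    renumber = np.cumsum(has_orig) - 1
    chain[idx[live]] = renumber[labels[live]].astype(np.int32)
    return shares, chain


def active_support_share(shares: np.ndarray, supported: np.ndarray,
                         network: NetworkState):
    """p_S and active-neighbour counts from the round's actual sharers.

    p_S is the fraction of an agent's *active* connections supporting the
    pro-science side; agents with no active connections get p_S = 0 (silent
    neighbours produce no information).
    """
    active = shares.astype(float)
    pro_active = (shares & (supported == 1)).astype(float)
    n_active = network.adj @ active
    n_pro = network.adj @ pro_active
    with np.errstate(invalid="ignore", divide="ignore"):
        p_S = np.where(n_active > 0, n_pro / np.maximum(n_active, 1.0), 0.0)
    return p_S, n_active.astype(np.int64)


def apply_toxicity(shares: np.ndarray, supported: np.ndarray,
                   network: NetworkState, states: AgentStates,
                   config: ModelConfig, rng: np.random.Generator):
    """Convert each actual sharer to constructive or toxic.

    Each sharer is toxic with its own ``toxic_probability``, independently;
    a toxic share attacks the polarity opposite to the sharer's supported
    side.  Returns ``(action, p_S, p_X, n_active_nb)``.
    """
    n = network.n_agents
    p_S, n_active = active_support_share(shares, supported, network)
    p_X = np.zeros(n)
    if shares.any():
        p_X[shares] = toxic_probability(states.opinion[shares], p_S[shares],
                                        supported[shares], config.c_X)
    draws = rng.random(n)
    action = np.where(shares, np.where(draws < p_X, TOXIC, CONSTRUCTIVE),
                      SILENT).astype(np.int8)
    return action, p_S, p_X, n_active


def observe(network: NetworkState, action: np.ndarray, supported: np.ndarray):
    """Observation counts for every agent from the round's final actions.

    Observation is passive: each agent sees all of its neighbours' posts
    regardless of its own activity.  ``A[I]`` counts neighbours who shared
    constructively in support of I; ``T[I]`` counts neighbours whose toxic
    share attacked I (i.e. toxic sharers supporting 1 - I).  Also returns
    p_S over active neighbours and the active-neighbour count.
    """
    adj = network.adj
    A = np.stack([
        adj @ ((action == CONSTRUCTIVE) & (supported == 0)).astype(float),
        adj @ ((action == CONSTRUCTIVE) & (supported == 1)).astype(float),
    ])
    T = np.stack([
        adj @ ((action == TOXIC) & (supported == 1)).astype(float),
        adj @ ((action == TOXIC) & (supported == 0)).astype(float),
    ])
    p_S, n_active = active_support_share(action != SILENT, supported, network)
    return A, T, p_S, n_active


def desired_connections(states: AgentStates, config: ModelConfig) -> DesiredConnections:
    """Optimal connection counts for the next round.

    K_I = b_AG * lambda * w_I / (c_TG * pi_TI* + c_KG) - 1 / pi_AI* + c_BG

    with w_1 = pi_S* and w_0 = 1 - pi_S*: the utility of the network rises
    with expected constructive responses to the agent's side and falls with
    expected toxic ones and with per-connection upkeep.  Values may be
    fractional or negative.  A non-positive denominator is reported as +inf
    with a warning.
    """
    pi_S = states.opinion
    out = []
    for polarity, weight in ((1, pi_S), (0, 1.0 - pi_S)):
        denom = config.c_TG * states.pi_T[polarity] + config.c_KG
        if np.any(denom <= 0):
            warnings.warn("non-positive denominator in desired connections; "
                          "reporting +inf", RuntimeWarning, stacklevel=2)
        with np.errstate(divide="ignore"):
            first = np.where(denom > 0,
                             config.b_AG * states.lam * weight / np.maximum(denom, 1e-300),
                             np.inf)
        out.append(first - 1.0 / states.pi_A[polarity] + config.c_BG)
    return DesiredConnections(K_1=out[0], K_0=out[1])
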