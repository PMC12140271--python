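"""Round, simulation and batch orchestration.

Each round walks the seven sub-models in order:

1. originator opportunities (probability q per agent);
2. would-share decisions from start-of-round beliefs, then sharing-chain
   resolution — only components of would-sharers containing an originator
   actually share;
3. the constructive-vs-toxic draw for every actual sharer;
4. opinion, expectation and interest updates from the observed actions;
5. toxic-driven disconnections (constructive sharers with surplus
   connections);
6. new connections to same-side originators in the same chain (constructive
   sharers short of connections);
7. reconnection of isolated agents.

Rewiring decisions in steps 5-6 are computed against the pre-rewiring graph
snapshot and applied in agent-ID order, skipping operations an earlier one
invalidated; step 7 acts on the live graph, also in agent-ID order.  One
master seed spawns named child streams (network, then one per simulation)
so results are bit-reproducible and independent of n_sims.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import beliefs as _beliefs
from . import metrics as _metrics
from .behaviour import (CONSTRUCTIVE, RoundRecord, apply_toxicity,
                        decide_action, desired_connections, observe,
                        resolve_chains)
from .config import ModelConfig, config_hash
from .network import (NetworkState, connect_originator, disconnect_toxic,
                      generate_network, reconnect_isolated)
from .priors import AgentStates, init_agent_beliefs

__all__ = ["SimState", "SimulationResult", "BatchResult",
           "run_round", "run_simulation", "run_batch"]

logger = logging.getLogger(__name__)


@dataclass
class SimState:
    """Mutable state of one running simulation."""

    states: AgentStates
    network: NetworkState
    round_index: int = 0


@dataclass
class SimulationResult:
    """Trajectories and final state of one simulation.

    ``opinions`` and ``ec_label`` are (n_agents, n_rounds + 1) matrices whose
    column 0 is the initial state; column r is the state after round r.
    """

    opinions: np.ndarray
    ec_label: np.ndarray
    actions_summary: pd.DataFrame
    initial_network: NetworkState
    final_network: NetworkState
    seed: object
    config_hash: str


@dataclass
class BatchResult:
    """A batch of simulations over a shared configuration."""

    results: list[SimulationResult]
    summary: pd.DataFrame
    master_seed: object
    config_hash: str


def run_round(state: SimState, config: ModelConfig,
              rng: np.random.Generator) -> RoundRecord:
    """Advance the model by one round, mutating ``state`` in place."""
    n = config.n_agents
    states, network = state.states, state.network
    record = RoundRecord.empty(n)

    # 1. originator opportunities
    opportunity = rng.random(n) < config.q

    # 2. shocks, would-share decisions, chain resolution
    record.e = rng.normal(0.0, config.sigma_e, size=2)  # (e_0, e_1)
    record.f = rng.normal(0.0, config.sigma_f, size=n)
    K = network.degree()
    would_share, supported, record.U = decide_action(
        states, K, ((record.e[0], record.e[1]), record.f), config)
    record.originator = opportunity & would_share
    shares, record.chain = resolve_chains(would_share, record.originator, network)
    record.supported = np.where(shares, supported, np.int8(-1))

    # 3. constructive vs toxic
    record.action, p_S_sharing, record.p_X, _ = apply_toxicity(
        shares, record.supported, network, states, config, rng)

    # 4. observe and update beliefs
    record.A, record.T, record.p_S, record.n_active_nb = observe(
        network, record.action, record.supported)
    _beliefs.update_opinion(states, record.A[1], record.A[0], config.theta)
    # expectation trials: in rounds with an active neighbourhood every
    # connection is an exposure (silent neighbours are observed non-responses);
    # with nothing to observe, no evidence accrues
    exposures = np.where(record.n_active_nb > 0, K, 0)
    _beliefs.update_expectations(states, (record.A, record.T), exposures, config)
    _beliefs.update_interest(states, config)

    # 5-6. rewiring by constructive sharers, from the pre-rewiring snapshot
    constructive = np.flatnonzero(record.action == CONSTRUCTIVE)
    if constructive.size:
        desired = desired_connections(states, config)
        snapshot = network.copy()
        for agent in constructive:
            side = int(record.supported[agent])
            want = float(desired.for_side(side)[agent])
            if disconnect_toxic(agent, side, want, network, record, rng,
                                snapshot=snapshot):
                record.edges_removed += 1
        for agent in constructive:
            side = int(record.supported[agent])
            want = float(desired.for_side(side)[agent])
            if connect_originator(agent, side, want, int(record.chain[agent]),
                                  record, network, rng, snapshot=snapshot):
                record.edges_added += 1

    # 7. isolated agents reconnect on the live graph
    isolated = np.flatnonzero(network.degree() == 0)
    if isolated.size:
        opinions = states.opinion
        for agent in isolated:
            if network.degree_of(agent) == 0:
                if reconnect_isolated(int(agent), opinions, config.gamma,
                                      network, rng):
                    record.edges_added += 1

    state.round_index += 1
    if logger.isEnabledFor(logging.INFO):
        logger.info("round %d: sharers=%d toxic=%d edges+%d/-%d",
                    state.round_index, int((record.action != 0).sum()),
                    int((record.action == 2).sum()),
                    record.edges_added, record.edges_removed)
    return record


def _actions_row(record: RoundRecord) -> dict:
    from .behaviour import TOXIC
    sup = record.supported
    act = record.action
    return {
        "n_originators": int(record.originator.sum()),
        "n_constructive_pro": int(((act == CONSTRUCTIVE) & (sup == 1)).sum()),
        "n_constructive_anti": int(((act == CONSTRUCTIVE) & (sup == 0)).sum()),
        "n_toxic_pro": int(((act == TOXIC) & (sup == 1)).sum()),
        "n_toxic_anti": int(((act == TOXIC) & (sup == 0)).sum()),
        "edges_added": record.edges_added,
        "edges_removed": record.edges_removed,
    }


def run_simulation(config: ModelConfig, network: NetworkState | None = None,
                   seed=None) -> SimulationResult:
    """Run one simulation of ``config.n_rounds`` rounds.

    ``seed`` may be an int or a :class:`numpy.random.SeedSequence`.  When
    ``network`` is omitted a starting network is generated from the same
    stream.  The same seed and network always reproduce the result
    bit-identically.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    if network is None:
        network = generate_network(config.network, config.n_agents, rng)
    else:
        network = network.copy()
    initial_network = network.copy()

    states = init_agent_beliefs(config, rng)
    state = SimState(states=states, network=network)

    n, rounds = config.n_agents, config.n_rounds
    opinions = np.empty((n, rounds + 1))
    labels = np.empty((n, rounds + 1), dtype=np.int8)
    opinions[:, 0] = states.opinion
    labels[:, 0] = _metrics.label_population(opinions[:, 0], network)

    rows = []
    for r in range(rounds):
        record = run_round(state, config, rng)
        opinions[:, r + 1] = states.opinion
        labels[:, r + 1] = _metrics.label_population(opinions[:, r + 1], network)
        rows.append(_actions_row(record))

    summary = pd.DataFrame(rows, index=pd.RangeIndex(1, rounds + 1, name="round"))
    return SimulationResult(
        opinions=opinions, ec_label=labels, actions_summary=summary,
        initial_network=initial_network, final_network=network,
        seed=seed, config_hash=config_hash(config))


def run_batch(config: ModelConfig, n_sims: int | None = None,
              master_seed=None) -> BatchResult:
    """Run ``n_sims`` simulations with deterministically derived child seeds.

    The starting network is generated once from its own child stream and
    shared by every simulation unless the network spec requests regeneration
    per simulation.
    """
    config.validate()
    if n_sims is None:
        n_sims = config.n_sims
    if master_seed is None:
        master_seed = config.seed
    ss = master_seed if isinstance(master_seed, np.random.SeedSequence) \
        else np.random.SeedSequence(master_seed)
    net_ss, *sim_seeds = ss.spawn(n_sims + 1)

    shared_network = None
    if not config.network.regenerate_per_simulation:
        shared_network = generate_network(
            config.network, config.n_agents, np.random.default_rng(net_ss))

    results = [run_simulation(config, network=shared_network, seed=s)
               for s in sim_seeds]
    return BatchResult(results=results,
                       summary=_metrics.summarize_batch(results),
                       master_seed=master_seed,
                       config_hash=config_hash(config))
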