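"""Bayesian belief updating: opinions, interaction expectations, interest.

Opinions update by conjugate beta-binomial accumulation of the constructive
posts an agent observed, with a mild pro-science weight theta on pro
evidence — opinion pseudo-counts only ever grow, so agents become
progressively harder to persuade.  Interaction expectations instead carry
exponentially decayed memory (rates d_A, d_T), keeping them responsive to
the recent behaviour of the neighbourhood.  Once total opinion evidence
crosses mu the agent permanently loses interest and its attention
multiplier drops from 1 to nu.

All three updates mutate the passed :class:`~pasom.priors.AgentStates` in
place and return it; they are vectorised over agents.
"""

from __future__ import annotations

import numpy as np

from .config import ModelConfig
from .priors import AgentStates

__all__ = ["update_opinion", "update_expectations", "update_interest"]


def update_opinion(states: AgentStates, A_1, A_0, theta: float) -> AgentStates:
    """Accumulate observed constructive posts into the opinion.

    alpha += lambda * A_1 * theta;  beta += lambda * A_0.

    theta > 1 weights pro-science information up relative to anti-science;
    after interest loss (lambda = nu) all information counts less.
    """
    states.alpha += states.lam * np.asarray(A_1, dtype=float) * theta
    states.beta += states.lam * np.asarray(A_0, dtype=float)
    return states


def update_expectations(states: AgentStates, obs, n_exposures,
                        config: ModelConfig) -> AgentStates:
    """Decayed beta-binomial update of the four interaction expectations.

    ``obs`` is ``(A, T)`` with shape (2, n) each; ``n_exposures`` is the
    trial count of the round's evidence — the engine passes the agent's
    degree in rounds where its neighbourhood was active (every connection
    was an observed responder or non-responder) and 0 otherwise.  History
    first decays (d_A for constructive, d_T for toxic memory), then the
    round is added: for polarity I the constructive pair gains (A_I
    successes, n_exposures - A_I failures) and the toxic pair (T_I
    successes, n_exposures - T_I failures).

    Rounds with nothing to observe only decay, which rescales both
    pseudo-counts equally and leaves the expectation unchanged.
    """
    A, T = obs
    n_exposures = np.asarray(n_exposures, dtype=float)
    states.A_succ *= config.d_A
    states.A_fail *= config.d_A
    states.T_succ *= config.d_T
    states.T_fail *= config.d_T
    states.A_succ += A
    states.A_fail += n_exposures - A
    states.T_succ += T
    states.T_fail += n_exposures - T
    return states


def update_interest(states: AgentStates, config: ModelConfig) -> AgentStates:
    """Permanent interest loss once total opinion evidence reaches mu."""
    lost = states.interested & (states.alpha + states.beta >= config.mu)
    states.interested[lost] = False
    states.lam[lost] = config.nu
    return states
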