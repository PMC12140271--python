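"""Agent state and prior initialisation.

Each agent carries a beta-distributed opinion over the probability that the
pro-science position is true (pseudo-counts ``alpha``/``beta``), plus four
decayed beta pseudo-count pairs: the expected probabilities of a connection
responding constructively (pi_A*) or toxically (pi_T*) to pro- and
anti-science information.  Attention is ``lam`` (1 while interested, ``nu``
after interest loss).

State is stored as arrays over agents (struct-of-arrays) so that round
updates vectorise; every per-agent operation broadcasts over these arrays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import ModelConfig

__all__ = ["AgentStates", "opinion_median", "init_agent_beliefs"]

#: clamp width keeping medians strictly inside (0, 1)
_EPS = 1e-9


def opinion_median(alpha_S, beta_S):
    """Approximate median of a Beta(alpha_S, beta_S) distribution.

    Uses the standard closed form (alpha - 1/3) / (alpha + beta - 2/3),
    clamped to the open unit interval.  Accepts scalars or arrays.
    """
    alpha_S = np.asarray(alpha_S, dtype=float)
    beta_S = np.asarray(beta_S, dtype=float)
    if np.any(alpha_S <= 0) or np.any(beta_S <= 0):
        raise ValueError("beta pseudo-counts must be positive")
    m = (alpha_S - 1.0 / 3.0) / (alpha_S + beta_S - 2.0 / 3.0)
    m = np.clip(m, _EPS, 1.0 - _EPS)
    return m if m.ndim else float(m)


@dataclass
class AgentStates:
    """Vectorised per-agent beliefs for a whole population.

    Arrays indexed by agent ID; expectation pseudo-counts are shaped
    ``(2, n)`` with the first axis the polarity I (index 0 = anti, 1 = pro).

    Interaction-expectation pseudo-count pairs decay each round (rates d_A,
    d_T), so the expectations weight recent interactions most heavily.
    """

    alpha: np.ndarray          # opinion pseudo-counts, pro-science evidence
    beta: np.ndarray           # opinion pseudo-counts, anti-science evidence
    A_succ: np.ndarray         # constructive-response expectation successes, (2, n)
    A_fail: np.ndarray
    T_succ: np.ndarray         # toxic-response expectation successes, (2, n)
    T_fail: np.ndarray
    interested: np.ndarray     # bool, (n,)
    lam: np.ndarray            # attention multiplier, 1 or nu

    _FIELDS = ("alpha", "beta", "A_succ", "A_fail", "T_succ", "T_fail",
               "interested", "lam")

    @property
    def n_agents(self) -> int:
        return self.alpha.shape[0]

    @property
    def opinion(self) -> np.ndarray:
        """pi_S*: the opinion median of every agent."""
        return opinion_median(self.alpha, self.beta)

    @property
    def pi_A(self) -> np.ndarray:
        """Expected constructive-response probability per polarity, (2, n)."""
        return self.A_succ / (self.A_succ + self.A_fail)

    @property
    def pi_T(self) -> np.ndarray:
        """Expected toxic-response probability per polarity, (2, n)."""
        return self.T_succ / (self.T_succ + self.T_fail)

    def copy(self) -> "AgentStates":
        return AgentStates(*(getattr(self, f).copy() for f in self._FIELDS))


def init_agent_beliefs(config: ModelConfig, rng: np.random.Generator) -> AgentStates:
    """Draw initial beliefs for ``config.n_agents`` agents.

    Opinion medians are uniform on the prior's median range, so the
    population starts spread relatively evenly across (0, 1).  The total
    pseudo-count behind a median m is
    ``strength_mid + (strength_edge - strength_mid) * |2m - 1|`` (times the
    regime multiplier): agents in the middle of the spectrum hold less
    evidence and are more malleable than agents near the extremes.  The
    median relation is inverted exactly, so the drawn m *is* the agent's
    initial opinion.

    Interaction expectations start at the configured toxic and constructive
    response rates for both polarities, and every agent starts interested
    (lambda = 1).
    """
    prior = config.prior
    n = config.n_agents
    lo, hi = prior.opinion_median_range
    m = rng.uniform(lo, hi, size=n)

    total = prior.strength_mid + (prior.strength_edge - prior.strength_mid) * np.abs(2 * m - 1)
    total = total * prior.strength_multiplier
    alpha = m * (total - 2.0 / 3.0) + 1.0 / 3.0
    beta = total - alpha

    w = prior.expectation_prior_weight
    shape = (2, n)
    a_rate = prior.constructive_rate_prior
    t_rate = prior.toxic_rate_prior
    return AgentStates(
        alpha=alpha,
        beta=beta,
        A_succ=np.full(shape, a_rate * w),
        A_fail=np.full(shape, (1.0 - a_rate) * w),
        T_succ=np.full(shape, t_rate * w),
        T_fail=np.full(shape, (1.0 - t_rate) * w),
        interested=np.ones(n, dtype=bool),
        lam=np.ones(n),
    )
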