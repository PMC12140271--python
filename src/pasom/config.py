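"""Model configuration: every global parameter of the simulator plus prior and
network specifications, with validation and YAML/JSON loading.

The baseline values describe a popular, controversial science topic on a
social network of 500 agents: agents occasionally get an exogenous reason to
post (``q``), weigh the expected benefit of constructive replies against the
expected cost of toxic ones, and pay a fixed cost ``c_C`` for posting at all.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

__all__ = [
    "ConfigError",
    "RangeError",
    "PriorSpec",
    "NetworkSpec",
    "ModelConfig",
    "load_config",
    "config_from_dict",
    "config_hash",
]


class ConfigError(ValueError):
    """A configuration does not match the documented schema.

    ``fields`` names the offending keys.
    """

    def __init__(self, message: str, fields: list[str] | None = None):
        super().__init__(message)
        self.fields = fields or []


class RangeError(ConfigError):
    """A configuration value is outside its permitted range."""


@dataclass(frozen=True)
class PriorSpec:
    """How agents' initial beliefs are drawn.

    Opinions are beta distributions over the probability that the pro-science
    position is true.  Initial opinion medians are spread evenly over
    ``opinion_median_range`` and the total pseudo-count behind a median
    interpolates between ``strength_mid`` (malleable middle) and
    ``strength_edge`` (firmer extremes); ``strength_multiplier`` scales both,
    distinguishing the weak (1) and strong (5) prior regimes.

    Interaction expectations start at ``toxic_rate_prior`` /
    ``constructive_rate_prior`` for both polarities, carried by
    ``expectation_prior_weight`` pseudo-observations each.  Both rates are
    per-connection response probabilities.  The constructive rate is an
    expected 40% response rate per connection; the toxic default spreads an
    expected 8% toxic response to a post as a whole over a typical
    six-connection neighbourhood (the payoff charges the toxic cost once per
    connection, so the per-post rate and the mean degree jointly set the
    per-connection prior that keeps opening-round decision margins at the
    level where roughly a tenth to a fifth of agents would post before
    shocks).
    """

    opinion_median_range: tuple[float, float] = (0.025, 0.975)
    strength_mid: float = 4.0
    strength_edge: float = 10.0
    strength_multiplier: float = 1.0
    toxic_rate_prior: float = 0.08 / 6.0
    constructive_rate_prior: float = 0.40
    expectation_prior_weight: float = 10.0

    def validate(self) -> None:
        bad: list[str] = []
        lo, hi = self.opinion_median_range
        if not (0.0 < lo < hi < 1.0):
            bad.append("opinion_median_range")
        for name in ("strength_mid", "strength_edge", "strength_multiplier",
                     "expectation_prior_weight"):
            if getattr(self, name) <= 0:
                bad.append(name)
        for name in ("toxic_rate_prior", "constructive_rate_prior"):
            if not (0.0 < getattr(self, name) < 1.0):
                bad.append(name)
        if bad:
            raise RangeError(f"prior values out of range: {bad}", bad)


@dataclass(frozen=True)
class NetworkSpec:
    """Starting-network family.

    ``cluster`` is the default: ``n_clusters`` groups with mean size
    ``mean_cluster_size``, fully connected within groups (``p_within`` = 1)
    and sparsely connected between them.  ``lattice`` builds a 3-D grid;
    ``file`` reads an edge-list CSV or GraphML from ``path``.
    """

    kind: str = "cluster"
    n_clusters: int = 100
    mean_cluster_size: int = 5
    p_within: float = 1.0
    p_between: float = 2.0 / 500.0
    path: str | None = None
    # Paper-style batches reuse one starting network for every simulation;
    # set True to draw a fresh network per simulation instead.
    regenerate_per_simulation: bool = False

    def validate(self, n_agents: int | None = None) -> None:
        bad: list[str] = []
        if self.kind not in ("cluster", "lattice", "file"):
            bad.append("kind")
        if not (0.0 <= self.p_within <= 1.0):
            bad.append("p_within")
        if not (0.0 <= self.p_between <= 1.0):
            bad.append("p_between")
        if self.kind == "cluster":
            if self.n_clusters < 1:
                bad.append("n_clusters")
            if self.mean_cluster_size < 1:
                bad.append("mean_cluster_size")
            if (n_agents is not None and "n_clusters" not in bad
                    and self.n_clusters * self.mean_cluster_size != n_agents):
                bad.append("n_clusters")
        if self.kind == "file" and not self.path:
            bad.append("path")
        if bad:
            raise RangeError(f"network spec invalid: {bad}", bad)


@dataclass(frozen=True)
class ModelConfig:
    """All global parameters of the simulator.

    Defaults are the baseline parameter set.  Symbols follow the model's
    conventions: subscripts i (agent), j (round) and I (polarity; 1 =
    pro-science, 0 = anti-science) are used throughout the package.
    """

    n_agents: int = 500
    n_rounds: int = 200
    n_sims: int = 200
    #: probability an agent gets the opportunity to originate a sharing chain
    q: float = 0.1
    #: std of the per-round, per-polarity information shock e_jI
    sigma_e: float = 0.15
    #: std of the per-agent, per-round motivation shock f_ij
    sigma_f: float = 0.4
    #: benefit coefficients for constructive interactions (payoff / network utility)
    b_A: float = 1.0
    b_AG: float = 1.0
    #: cost coefficients for toxic interactions (payoff / network utility);
    #: c_T may be negative (agents who *prefer* toxic interactions)
    c_T: float = 1.25
    c_TG: float = 1.0
    #: fixed cost of posting
    c_C: float = 1.0
    #: per-connection benefit and maintenance cost in the network utility
    c_BG: float = 0.2
    c_KG: float = 0.05
    #: propensity to act toxically (>= 0; one cannot share less toxically than not at all)
    c_X: float = 1.0
    #: indecision threshold on |U_1 - U_0|
    u: float = 0.2
    #: total-evidence threshold at which agents lose interest in the topic
    mu: float = 500.0
    #: attention multiplier after interest loss (lambda drops from 1 to nu)
    nu: float = 0.2
    #: memory decay rates for toxic / constructive expectations (1 = no decay)
    d_T: float = 0.9
    d_A: float = 0.9
    #: opposing-view tolerance when an isolated agent reconnects
    gamma: float = 0.1
    #: pro-science information weight (> 1 biases updating toward pro)
    theta: float = 1.1
    prior: PriorSpec = field(default_factory=PriorSpec)
    network: NetworkSpec = field(default_factory=NetworkSpec)
    seed: int | None = None

    def validate(self) -> "ModelConfig":
        bad: list[str] = []
        if self.n_agents < 1:
            bad.append("n_agents")
        if self.n_rounds < 0:
            bad.append("n_rounds")
        if self.n_sims < 1:
            bad.append("n_sims")
        if not (0.0 <= self.q <= 1.0):
            bad.append("q")
        for name in ("sigma_e", "sigma_f", "u", "gamma"):
            if getattr(self, name) < 0:
                bad.append(name)
        if self.c_X < 0:
            bad.append("c_X")
        for name in ("d_T", "d_A"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                bad.append(name)
        if self.mu <= 0:
            bad.append("mu")
        if not (0.0 < self.nu <= 1.0):
            bad.append("nu")
        if self.theta <= 0:
            bad.append("theta")
        if bad:
            raise RangeError(f"config values out of range: {bad}", bad)
        self.prior.validate()
        self.network.validate(self.n_agents)
        return self

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["prior"]["opinion_median_range"] = list(self.prior.opinion_median_range)
        return d


_PRIOR_KEYS = {f.name for f in dataclasses.fields(PriorSpec)}
_NETWORK_KEYS = {f.name for f in dataclasses.fields(NetworkSpec)}
_CONFIG_KEYS = {f.name for f in dataclasses.fields(ModelConfig)}


def config_from_dict(data: dict[str, Any] | None) -> ModelConfig:
    """Build a validated :class:`ModelConfig` from a nested dict.

    Unspecified fields take baseline values; unknown keys are rejected.
    """
    data = dict(data or {})
    unknown = sorted(set(data) - _CONFIG_KEYS)
    if unknown:
        raise ConfigError(f"unknown config keys: {unknown}", unknown)

    prior_data = dict(data.pop("prior", {}) or {})
    unknown = sorted(set(prior_data) - _PRIOR_KEYS)
    if unknown:
        raise ConfigError(f"unknown prior keys: {unknown}", unknown)
    if "opinion_median_range" in prior_data:
        prior_data["opinion_median_range"] = tuple(prior_data["opinion_median_range"])

    net_data = dict(data.pop("network", {}) or {})
    unknown = sorted(set(net_data) - _NETWORK_KEYS)
    if unknown:
        raise ConfigError(f"unknown network keys: {unknown}", unknown)

    try:
        cfg = ModelConfig(prior=PriorSpec(**prior_data),
                          network=NetworkSpec(**net_data), **data)
    except TypeError as exc:  # pragma: no cover - defensive
        raise ConfigError(str(exc)) from exc
    return cfg.validate()


def load_config(path: str | Path) -> ModelConfig:
    """Load a YAML or JSON configuration file.

    An empty file yields the full baseline configuration.
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError("config file must contain a mapping")
    return config_from_dict(data)


def config_hash(config: ModelConfig) -> str:
    """Stable SHA-256 digest of a configuration (for manifests)."""
    payload = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()
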