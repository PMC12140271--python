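"""Echo-chamber classification and aggregate summaries.

An agent is in an anti-science echo chamber when its opinion is below 0.4
and at least 90% of its connections hold opinions below 0.5; pro-science
membership is the mirror image (opinion above 0.6, at least 90% of
connections above 0.5).  Agents with no connections are labelled none.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import NetworkState

__all__ = [
    "EC_NONE", "EC_PRO", "EC_ANTI",
    "classify_echo_chamber", "label_population",
    "summarize_batch", "per_round_summary",
    "DensityTable", "density_table", "select_quantile_run",
]

EC_NONE, EC_PRO, EC_ANTI = 0, 1, 2

#: opinion bands and the neighbour-agreement quorum of the membership rule
ANTI_OPINION_MAX = 0.4
PRO_OPINION_MIN = 0.6
NEIGHBOUR_QUORUM = 0.9


def classify_echo_chamber(opinion: float, neighbour_opinions) -> str:
    """Label a single agent: ``"pro"``, ``"anti"`` or ``"none"``.

    Neighbour comparisons are strict (> 0.5 pro side, < 0.5 anti side); a
    neighbour at exactly 0.5 counts for neither.  The 90% quorum is
    inclusive.  An agent with no neighbours is ``"none"``.
    """
    nb = np.asarray(neighbour_opinions, dtype=float)
    if nb.size == 0:
        return "none"
    if opinion < ANTI_OPINION_MAX and np.mean(nb < 0.5) >= NEIGHBOUR_QUORUM:
        return "anti"
    if opinion > PRO_OPINION_MIN and np.mean(nb > 0.5) >= NEIGHBOUR_QUORUM:
        return "pro"
    return "none"


def label_population(opinions: np.ndarray, network: NetworkState) -> np.ndarray:
    """Vectorised labels for a whole population (codes EC_*)."""
    adj = network.adj
    K = adj.sum(axis=1)
    n_pro_nb = adj @ (opinions > 0.5).astype(float)
    n_anti_nb = adj @ (opinions < 0.5).astype(float)
    Kf = np.maximum(K, 1)
    labels = np.zeros(opinions.shape[0], dtype=np.int8)
    has_nb = K > 0
    anti = has_nb & (opinions < ANTI_OPINION_MAX) & (n_anti_nb / Kf >= NEIGHBOUR_QUORUM)
    pro = has_nb & (opinions > PRO_OPINION_MIN) & (n_pro_nb / Kf >= NEIGHBOUR_QUORUM)
    labels[anti] = EC_ANTI
    labels[pro] = EC_PRO
    return labels


def per_round_summary(result) -> pd.DataFrame:
    """Per-round mean opinion and echo-chamber percentages of one simulation.

    Index is the round (0 = initial state); percentages are over all agents,
    isolated agents included in the denominator.
    """
    opinions = result.opinions
    labels = result.ec_label
    n = opinions.shape[0]
    return pd.DataFrame({
        "mean_opinion": opinions.mean(axis=0),
        "pct_pro_ec": 100.0 * (labels == EC_PRO).sum(axis=0) / n,
        "pct_anti_ec": 100.0 * (labels == EC_ANTI).sum(axis=0) / n,
        "pct_total_ec": 100.0 * (labels != EC_NONE).sum(axis=0) / n,
    }).rename_axis("round")


def summarize_batch(results) -> pd.DataFrame:
    """Cross-simulation mean and 95% CI of the per-round summaries.

    For each round and each of mean_opinion / pct_pro_ec / pct_anti_ec /
    pct_total_ec, reports the mean over simulations and mean +/- 1.96 sd /
    sqrt(n_sims).
    """
    results = list(results)
    if not results:
        raise ValueError("summarize_batch needs at least one simulation result")
    tables = [per_round_summary(r) for r in results]
    stacked = {col: np.stack([t[col].to_numpy() for t in tables]) for col in tables[0]}
    n_sims = len(results)
    out = {}
    for col, mat in stacked.items():
        mean = mat.mean(axis=0)
        half = 1.96 * mat.std(axis=0, ddof=1) / np.sqrt(n_sims) if n_sims > 1 else np.zeros_like(mean)
        out[col] = mean
        out[col + "_ci_lo"] = mean - half
        out[col + "_ci_hi"] = mean + half
    return pd.DataFrame(out).rename_axis("round")


@dataclass
class DensityTable:
    """2-D histogram of (own opinion, mean neighbour opinion) pairs.

    ``grid[i, j]`` is the density of agents whose own opinion falls in bin i
    and whose neighbours' mean opinion falls in bin j; occupied cells sum to
    one.  Isolated agents are excluded from the grid and counted in
    ``n_isolated``.
    """

    grid: np.ndarray
    bin_edges: np.ndarray
    n_isolated: int

    def to_frame(self) -> pd.DataFrame:
        """Long format: one row per cell (own_bin, neigh_bin, density)."""
        ii, jj = np.nonzero(self.grid)
        return pd.DataFrame({
            "own_bin": self.bin_edges[ii],
            "neigh_bin": self.bin_edges[jj],
            "density": self.grid[ii, jj],
        })


def density_table(result, round_index: int, bins: int = 50) -> DensityTable:
    """Density of agents over own vs mean-neighbour opinion at one round.

    Only the initial (0) and final rounds are available: simulation results
    keep the starting and finishing networks but not the full edge history.
    Negative indices address rounds from the end.
    """
    n_cols = result.opinions.shape[1]
    if round_index < 0:
        round_index += n_cols
    if not (0 <= round_index < n_cols):
        raise ValueError(f"round {round_index} out of range")
    opinions = result.opinions[:, round_index]
    if round_index == 0:
        adj = result.initial_network.adj
    elif round_index == n_cols - 1:
        adj = result.final_network.adj
    else:
        raise ValueError("density tables are available for the initial and "
                         "final rounds only (no network history is kept)")
    K = adj.sum(axis=1)
    has_nb = K > 0
    mean_nb = np.zeros_like(opinions)
    mean_nb[has_nb] = (adj @ opinions)[has_nb] / K[has_nb]
    edges = np.linspace(0.0, 1.0, bins + 1)
    grid, _, _ = np.histogram2d(opinions[has_nb], mean_nb[has_nb], bins=[edges, edges])
    total = grid.sum()
    if total > 0:
        grid /= total
    return DensityTable(grid=grid, bin_edges=edges[:-1], n_isolated=int((~has_nb).sum()))


def select_quantile_run(results, statistic: str = "mean_opinion", rank: int = 1):
    """The rank-th simulation after ascending sort by final-round statistic.

    ``rank`` is 1-based: rank 1 is the most anti-science run, rank n_sims
    the most pro-science one.  Ties break by simulation order.
    """
    results = list(results)
    if not (1 <= rank <= len(results)):
        raise ValueError(f"rank {rank} out of range 1..{len(results)}")
    if statistic != "mean_opinion":
        raise ValueError(f"unknown statistic {statistic!r}")
    keyed = sorted(enumerate(results),
                   key=lambda kv: (float(kv[1].opinions[:, -1].mean()), kv[0]))
    return keyed[rank - 1][1]
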