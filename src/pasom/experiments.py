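"""Canned experiments: the baseline batch and the parameter sweeps.

These wrap :func:`pasom.engine.run_batch` into the study designs the model
was built to explore — the baseline echo-chamber batch, sweeps over
sensitivity to toxic behaviour (c_T, with c_TG coupled at 0.8 c_T),
propensity to toxic behaviour (c_X) and prior strength, and extraction of
extreme runs.  Replicate counts default to desk scale (10); pass
``n_replicates=200`` for full-scale batches.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ModelConfig
from .engine import BatchResult, run_batch
from .metrics import density_table, select_quantile_run

__all__ = ["SweepSpec", "run_sweep", "baseline_report",
           "STRONG_PRIOR_MULTIPLIER"]

#: prior-strength multiplier of the "strong priors" regime
STRONG_PRIOR_MULTIPLIER = 5.0

#: default sweep axes, mirroring the explored parameter ranges
DEFAULT_C_T_VALUES = (-0.5, -0.1, 0.1, 0.5, 0.9, 1.25)
DEFAULT_C_X_VALUES = (0.0, 0.1, 0.25, 0.5, 0.75, 1.0)


@dataclass
class SweepSpec:
    """A grid of parameter values to sweep, with replication.

    ``c_TG`` follows ``0.8 * c_T`` unless ``couple_c_TG`` is disabled, in
    which case the configured c_TG is kept.
    """

    c_T_values: tuple[float, ...] = (ModelConfig.c_T,)
    c_X_values: tuple[float, ...] = (ModelConfig.c_X,)
    prior_multipliers: tuple[float, ...] = (1.0,)
    couple_c_TG: bool = True
    n_replicates: int = 10
    master_seed: int | None = None


def _cell_config(base: ModelConfig, c_T: float, c_X: float,
                 prior_multiplier: float, couple: bool) -> ModelConfig:
    prior = dataclasses.replace(base.prior, strength_multiplier=prior_multiplier)
    kwargs = dict(c_T=c_T, c_X=c_X, prior=prior)
    if couple:
        kwargs["c_TG"] = 0.8 * c_T
    return dataclasses.replace(base, **kwargs)


def run_sweep(spec: SweepSpec, config: ModelConfig | None = None) -> pd.DataFrame:
    """Run a batch per grid cell and collect final-round outcomes.

    Returns one row per (cell, replicate): the cell's parameters plus the
    replicate's final-round echo-chamber percentages and mean opinion —
    the long-format table behind the box-plot style summaries.
    """
    base = config or ModelConfig()
    cells = [(c_T, c_X, pm)
             for pm in spec.prior_multipliers
             for c_T in spec.c_T_values
             for c_X in spec.c_X_values]
    if not cells:
        raise ValueError("empty sweep grid")
    ss = np.random.SeedSequence(spec.master_seed)
    cell_seeds = ss.spawn(len(cells))

    rows = []
    for (c_T, c_X, pm), cell_ss in zip(cells, cell_seeds):
        cfg = _cell_config(base, c_T, c_X, pm, spec.couple_c_TG)
        batch = run_batch(cfg, n_sims=spec.n_replicates, master_seed=cell_ss)
        for rep, res in enumerate(batch.results):
            labels = res.ec_label[:, -1]
            n = labels.shape[0]
            rows.append({
                "c_T": c_T, "c_TG": cfg.c_TG, "c_X": c_X,
                "prior_multiplier": pm, "replicate": rep,
                "final_pct_pro_ec": 100.0 * (labels == 1).sum() / n,
                "final_pct_anti_ec": 100.0 * (labels == 2).sum() / n,
                "final_pct_total_ec": 100.0 * (labels != 0).sum() / n,
                "final_mean_opinion": float(res.opinions[:, -1].mean()),
            })
    return pd.DataFrame(rows)


def baseline_report(master_seed=None, n_sims: int = 10,
                    config: ModelConfig | None = None) -> dict:
    """Run the baseline batch and bundle its headline outputs.

    The bundle contains the per-round batch time-series (anti-EC %, pro-EC
    %, total-EC % and mean opinion, each with a 95% CI), final-round
    headline percentages, and density tables for the most anti-science, the
    median and the most pro-science runs.
    """
    cfg = config or ModelConfig()
    batch = run_batch(cfg, n_sims=n_sims, master_seed=master_seed)
    summary = batch.summary
    final = summary.iloc[-1]

    def _headline(col):
        return {"mean": float(final[col]),
                "ci": [float(final[col + "_ci_lo"]), float(final[col + "_ci_hi"])]}

    extremes = {
        "most_anti": select_quantile_run(batch.results, rank=1),
        "median": select_quantile_run(batch.results, rank=(n_sims + 1) // 2),
        "most_pro": select_quantile_run(batch.results, rank=n_sims),
    }
    return {
        "batch": batch,
        "timeseries": summary,
        "headline": {col: _headline(col)
                     for col in ("pct_anti_ec", "pct_pro_ec", "pct_total_ec",
                                 "mean_opinion")},
        "density": {name: density_table(res, -1) for name, res in extremes.items()},
        "density_initial": density_table(batch.results[0], 0),
        "master_seed": master_seed,
    }
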