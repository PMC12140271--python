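"""Readers and writers for networks, summaries and run manifests.

All writers are deterministic for identical inputs: rows are emitted in a
stable order and floats are formatted at 10 significant digits, so digests
recorded in a manifest reproduce exactly on a rerun.
"""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .config import ModelConfig
from .network import NetworkState

__all__ = [
    "write_network", "read_network",
    "write_summary", "write_manifest", "verify_manifest", "file_digest",
]

_FLOAT_FMT = "%.10g"


def write_network(network: NetworkState, opinions: np.ndarray | None,
                  path: str | Path, format: str | None = None) -> Path:
    """Write a network as edge-list CSV or GraphML.

    Edge lists store each undirected edge once with source < target;
    GraphML additionally carries per-node ``opinion`` attributes.  The
    format defaults from the file suffix (.csv / .graphml).
    """
    path = Path(path)
    if format is None:
        format = "graphml" if path.suffix == ".graphml" else "edgelist-csv"
    if format == "edgelist-csv":
        df = pd.DataFrame(network.edges(), columns=["source", "target"])
        df.to_csv(path, index=False)
    elif format == "graphml":
        nx.write_graphml(network.to_networkx(opinions), path)
    else:
        raise ValueError(f"unknown network format {format!r}")
    return path


def read_network(path: str | Path, n_agents: int | None = None) -> NetworkState:
    """Read a network written by :func:`write_network`.

    For edge lists the node count is the larger of ``n_agents`` and the
    highest referenced ID + 1 (edge lists cannot declare isolated trailing
    nodes; pass ``n_agents`` to fix the population size).
    """
    path = Path(path)
    if path.suffix == ".graphml":
        g = nx.read_graphml(path)
        g = nx.relabel_nodes(g, {node: int(node) for node in g.nodes()})
        n = max(n_agents or 0, g.number_of_nodes())
        return NetworkState.from_networkx(g, n_agents=n)
    df = pd.read_csv(path)
    n = n_agents or 0
    if len(df):
        n = max(n, int(df[["source", "target"]].to_numpy().max()) + 1)
    return NetworkState(n, edges=df[["source", "target"]].itertuples(index=False))


def write_summary(summary: pd.DataFrame, path: str | Path) -> Path:
    """Write a per-round summary table as CSV with fixed float formatting."""
    path = Path(path)
    summary.to_csv(path, float_format=_FLOAT_FMT)
    return path


def file_digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(path: str | Path, config: ModelConfig, seeds,
                   files: dict[str, str | Path] | None = None) -> Path:
    """Write a JSON run manifest: config snapshot, seeds, file digests.

    The manifest suffices to reproduce the run: rebuild the config, rerun
    with the recorded seeds and compare digests with
    :func:`verify_manifest`.
    """
    from . import __version__
    path = Path(path)
    inventory = {
        name: {"path": str(Path(p)), "sha256": file_digest(p)}
        for name, p in sorted((files or {}).items())
    }
    manifest = {
        "config": config.to_dict(),
        "seeds": seeds,
        "version": __version__,
        "python": platform.python_version(),
        "files": inventory,
    }
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return path


def verify_manifest(path: str | Path) -> dict[str, bool]:
    """Recompute the digest of every file in a manifest.

    Returns {name: matches}; a tampered or missing file reports False.
    """
    manifest = json.loads(Path(path).read_text())
    out = {}
    for name, entry in manifest.get("files", {}).items():
        p = Path(entry["path"])
        out[name] = p.exists() and file_digest(p) == entry["sha256"]
    return out
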