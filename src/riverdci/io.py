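"""Readers, writers and run manifests.

Networks travel as node-table CSVs (one row per reach: ``id``,
``parent_id``, ``length``, ``alpha_up``, ``alpha_down``; the alphas
describe the barrier on the edge to the parent and are empty for the
root) or as GraphML with the same attributes.  Result tables are tidy
CSVs with deterministic column order; every sweep writes a JSON
manifest capturing the config snapshot, master seed, package version
and output files, which together suffice to reproduce the run.

All structural validation happens at parse time: cycles, disconnected
nodes, out-of-range passabilities and nonpositive lengths are rejected
with a message naming the offending element.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .networks import NetworkValidationError, RiverNetwork
from .metapop import SpeciesParams
from .experiments import SweepConfig

__all__ = [
    "RunManifest",
    "read_network",
    "write_network",
    "load_sweep_config",
    "write_results",
]


def _from_node_table(df: pd.DataFrame, origin: str) -> RiverNetwork:
    required = {"id", "parent_id", "length", "alpha_up", "alpha_down"}
    missing = required - set(df.columns)
    if missing:
        raise NetworkValidationError(f"{origin}: missing columns {sorted(missing)}")
    df = df.sort_values("id").reset_index(drop=True)
    ids = df["id"].astype(int).to_numpy()
    n = len(df)
    if not np.array_equal(ids, np.arange(1, n + 1)):
        raise NetworkValidationError(
            f"{origin}: reach ids must be exactly 1..{n} (got {list(ids)[:10]}...)"
        )
    parent_raw = df["parent_id"].to_numpy()
    parent = np.empty(n, dtype=int)
    for k, v in enumerate(parent_raw):
        if pd.isna(v) or (isinstance(v, str) and v.strip() == ""):
            parent[k] = -1
        else:
            parent[k] = int(v) - 1
    alpha_up = df["alpha_up"].astype(float).to_numpy()
    alpha_down = df["alpha_down"].astype(float).to_numpy()
    # The root carries no barrier; blank cells parse to NaN, as stored.
    return RiverNetwork(
        lengths=df["length"].astype(float).to_numpy(),
        parent=parent,
        alpha_up=alpha_up,
        alpha_down=alpha_down,
    )


def read_network(path: str | Path, format: str | None = None) -> RiverNetwork:
    """Read and validate a river network from CSV or GraphML.

    ``format`` defaults to the file extension.  Any violation of the
    rooted-tree invariants raises :class:`NetworkValidationError`.
    """
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt == "csv":
        return _from_node_table(pd.read_csv(path), str(path))
    if fmt == "graphml":
        g = nx.read_graphml(path)
        rows = []
        for node, data in g.nodes(data=True):
            rows.append(
                {
                    "id": int(node),
                    "parent_id": np.nan,
                    "length": float(data["length"]),
                    "alpha_up": np.nan,
                    "alpha_down": np.nan,
                }
            )
        df = pd.DataFrame(rows).set_index("id", drop=False)
        for child, parent, data in g.edges(data=True):
            c = int(child)
            df.loc[c, "parent_id"] = int(parent)
            df.loc[c, "alpha_up"] = float(data["alpha_up"])
            df.loc[c, "alpha_down"] = float(data["alpha_down"])
        return _from_node_table(df.reset_index(drop=True), str(path))
    raise ValueError(f"unknown network format {fmt!r}")


def write_network(net: RiverNetwork, path: str | Path, format: str | None = None) -> None:
    """Write a network as a node-table CSV or GraphML file."""
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt == "csv":
        df = pd.DataFrame(
            {
                "id": net.reach_ids,
                "parent_id": [
                    "" if p < 0 else p + 1 for p in net.parent
                ],
                "length": net.lengths,
                "alpha_up": ["" if np.isnan(a) else repr(float(a)) for a in net.alpha_up],
                "alpha_down": [
                    "" if np.isnan(a) else repr(float(a)) for a in net.alpha_down
                ],
            }
        )
        df.to_csv(path, index=False)
        return
    if fmt == "graphml":
        g = nx.DiGraph()
        for i in range(net.n_reaches):
            g.add_node(str(i + 1), length=float(net.lengths[i]))
        for i in range(1, net.n_reaches):
            g.add_edge(
                str(i + 1),
                str(net.parent[i] + 1),
                alpha_up=float(net.alpha_up[i]),
                alpha_down=float(net.alpha_down[i]),
            )
        nx.write_graphml(g, path)
        return
    raise ValueError(f"unknown network format {fmt!r}")


def load_sweep_config(path: str | Path) -> SweepConfig:
    """Load a sweep configuration from a YAML file keyed by scenario axes."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    species = SpeciesParams(**raw.pop("species", {}))
    kwargs = {}
    for key in ("topologies", "passability_modes", "dispersal_modes", "sizes"):
        if key in raw:
            kwargs[key] = tuple(raw.pop(key))
    for key in ("n_replicates", "seed"):
        if key in raw:
            kwargs[key] = int(raw.pop(key))
    if raw:
        raise ValueError(f"unknown config keys: {sorted(raw)}")
    return SweepConfig(species=species, **kwargs)


@dataclass(frozen=True)
class RunManifest:
    """Record of one pipeline run: inputs, seed, and produced files."""

    config: dict
    seed: int
    version: str
    files: dict[str, str]

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def write_results(
    tables: dict[str, pd.DataFrame],
    out_dir: str | Path,
    config: SweepConfig | None = None,
    seed: int | None = None,
) -> RunManifest:
    """Write result tables as CSVs plus a ``manifest.json``.

    Column order and float formatting are deterministic, so reruns with
    the same seed produce byte-identical files.
    """
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files = {}
    for name in sorted(tables):
        p = out_dir / f"{name}.csv"
        tables[name].to_csv(p, index=False)
        files[name] = p.name
    cfg_dict = {}
    if config is not None:
        cfg_dict = dataclasses.asdict(config)
        cfg_dict["species"] = dataclasses.asdict(config.species)
    manifest = RunManifest(
        config=cfg_dict,
        seed=config.seed if config is not None else (seed if seed is not None else 0),
        version=__version__,
        files=files,
    )
    (out_dir / "manifest.json").write_text(manifest.to_json())
    return manifest
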