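"""Scenario sweep, rank correlations and barrier-removal sensitivity.

The simulation design crosses four axes — topology (linear vs. binary),
barrier symmetry (symmetric vs. asymmetric passability), dispersal
scale (global vs. local) and network size — with 60 Latin-hypercube
replicates per cell by default.  For every replicate we record the
structural indices (DCI_p, per-reach DCI_s), the relative
metapopulation metrics (G_s, R_s, P_s at the network scale, O_s and V_s
per reach) and, for every barrier, the relative change in DCI_p and in
the basic reproduction number R when that single barrier is removed
(passability set to one); the removal ratio is oriented as
removed / present, so it is always >= 1.

Spearman rank correlations then link structure to dynamics at three
levels: DCI_p against each network-scale metric per scenario cell,
DCI_s against each reach-scale metric per reach, and the two removal
ratios against each other per barrier.  Correlations of a constant
column are undefined and reported as NaN with ``defined = False``
rather than coerced to zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .networks import (
    DispersalMode,
    PassabilityMode,
    RiverNetwork,
    ScenarioConfig,
    Topology,
    dispersal_distance,
    generate_replicates,
)
from .connectivity import ConnectivityResult, connectivity
from .metapop import (
    SpeciesParams,
    colonization_matrix,
    extinction_rates,
    relative_metrics,
    reproduction_number,
)

__all__ = [
    "ReplicateTable",
    "SweepConfig",
    "spearman",
    "removal_ratios",
    "run_scenario",
    "network_scale_correlations",
    "reach_scale_correlations",
    "sensitivity_correlations",
    "run_sweep",
]

SCENARIO_KEYS = ["topology", "passability_mode", "dispersal_mode", "n_reaches"]
NETWORK_METRICS = ["G_s", "R_s", "P_s"]
REACH_METRICS = ["O_s", "V_s"]

DEFAULT_SIZES = (3, 5, 7, 10, 15, 20, 30, 40, 50)


def spearman(x, y) -> float:
    """Spearman rank correlation (Pearson correlation of average ranks).

    Returns NaN when either input is constant (the correlation is then
    undefined) instead of raising.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("spearman expects two equal-length vectors of size >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho = stats.spearmanr(x, y).statistic
    return float(rho)


def removal_ratios(
    net: RiverNetwork,
    params: SpeciesParams,
    barrier_label: int,
    conn: ConnectivityResult | None = None,
) -> tuple[float, float]:
    """Relative change of DCI_p and of R when one barrier is removed.

    Each quantity is computed with the barrier in place and again with
    its passability set to unity in both directions; the ratio
    removed / present is returned, so both values are >= 1.
    """
    if conn is None:
        conn = connectivity(net)
    E = extinction_rates(net, params)
    R_present = reproduction_number(colonization_matrix(net, params, conn), E)

    removed = net.with_barrier_removed(barrier_label)
    conn_removed = connectivity(removed)
    R_removed = reproduction_number(
        colonization_matrix(removed, params, conn_removed), E
    )
    return conn_removed.dci_p / conn.dci_p, R_removed / R_present


@dataclass(frozen=True)
class ReplicateTable:
    """Per-replicate simulation records of one or more scenario cells.

    ``network``: one row per replicate (indices and network-scale metrics).
    ``reach``: long format, one row per replicate x reach.
    ``removal``: long format, one row per replicate x barrier.
    """

    network: pd.DataFrame
    reach: pd.DataFrame
    removal: pd.DataFrame

    @staticmethod
    def concat(tables: "list[ReplicateTable]") -> "ReplicateTable":
        return ReplicateTable(
            network=pd.concat([t.network for t in tables], ignore_index=True),
            reach=pd.concat([t.reach for t in tables], ignore_index=True),
            removal=pd.concat([t.removal for t in tables], ignore_index=True),
        )


def run_scenario(
    config: ScenarioConfig, params: SpeciesParams | None = None
) -> ReplicateTable:
    """Simulate one scenario cell: generate replicate networks, compute
    indices, metrics and per-barrier removal ratios.

    ``params.D`` is overridden by the dispersal rule of the scenario
    (global: D = L, local: D = L/N) for each replicate.  Replicates
    where a numerical step fails are kept with NaN metrics and the error
    message in the ``error`` column, never silently dropped.
    """
    if params is None:
        params = SpeciesParams()
    keys = {
        "topology": config.topology,
        "passability_mode": config.passability_mode,
        "dispersal_mode": config.dispersal_mode,
        "n_reaches": config.n_reaches,
    }
    net_rows, reach_rows, removal_rows = [], [], []
    for r, net in enumerate(generate_replicates(config)):
        row = dict(keys, replicate=r, error="")
        try:
            D = dispersal_distance(net, config.dispersal_mode)
            p = SpeciesParams(
                c=params.c,
                e=params.e,
                omega=params.omega,
                gamma=params.gamma,
                epsilon=params.epsilon,
                D=D,
            )
            conn = connectivity(net)
            m = relative_metrics(net, p, conn)
            row.update(
                dci_p=conn.dci_p,
                lam=m.lam,
                lam0=m.lam0,
                R=m.R,
                R0=m.R0,
                G_s=m.G_s,
                R_s=m.R_s,
                P_s=m.P_s,
                occupancy_defined=m.occupancy_defined,
            )
            for i in range(net.n_reaches):
                reach_rows.append(
                    dict(
                        keys,
                        replicate=r,
                        reach_id=i + 1,
                        dci_s=conn.dci_s[i],
                        O_s=m.O_s[i],
                        V_s=m.V_s[i],
                    )
                )
            for b in net.barrier_labels:
                rho_dci, rho_R = removal_ratios(net, p, int(b), conn)
                removal_rows.append(
                    dict(
                        keys,
                        replicate=r,
                        barrier=int(b),
                        rho_dci=rho_dci,
                        rho_R=rho_R,
                    )
                )
        except Exception as exc:  # flagged, not dropped
            row.setdefault("dci_p", np.nan)
            row["error"] = f"{type(exc).__name__}: {exc}"
        net_rows.append(row)
    return ReplicateTable(
        network=pd.DataFrame(net_rows),
        reach=pd.DataFrame(reach_rows),
        removal=pd.DataFrame(removal_rows),
    )


def _corr_record(scenario: dict, x, y, pair: str, **extra) -> dict:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    rho = spearman(x[ok], y[ok]) if ok.sum() >= 2 else float("nan")
    return dict(
        scenario,
        **extra,
        pair=pair,
        rho=rho,
        n=int(ok.sum()),
        defined=bool(np.isfinite(rho)),
    )


def network_scale_correlations(table: ReplicateTable) -> pd.DataFrame:
    """Spearman rho between DCI_p and each network-scale metric, per cell."""
    records = []
    for cell, g in table.network.groupby(SCENARIO_KEYS, sort=True):
        scenario = dict(zip(SCENARIO_KEYS, cell))
        for metric in NETWORK_METRICS:
            records.append(
                _corr_record(scenario, g["dci_p"], g[metric], f"dci_p~{metric}")
            )
    return pd.DataFrame(records)


def reach_scale_correlations(table: ReplicateTable) -> pd.DataFrame:
    """Spearman rho between DCI_s and O_s / V_s per reach (breadth-first
    order), per scenario cell."""
    records = []
    for cell, g in table.reach.groupby(SCENARIO_KEYS, sort=True):
        scenario = dict(zip(SCENARIO_KEYS, cell))
        for reach_id, gr in g.groupby("reach_id", sort=True):
            for metric in REACH_METRICS:
                records.append(
                    _corr_record(
                        scenario,
                        gr["dci_s"],
                        gr[metric],
                        f"dci_s~{metric}",
                        reach_id=int(reach_id),
                    )
                )
    return pd.DataFrame(records)


def sensitivity_correlations(table: ReplicateTable) -> pd.DataFrame:
    """Spearman rho between the DCI_p and R removal ratios per barrier
    (breadth-first order), per scenario cell."""
    records = []
    for cell, g in table.removal.groupby(SCENARIO_KEYS, sort=True):
        scenario = dict(zip(SCENARIO_KEYS, cell))
        for barrier, gb in g.groupby("barrier", sort=True):
            records.append(
                _corr_record(
                    scenario,
                    gb["rho_dci"],
                    gb["rho_R"],
                    "rho_dci~rho_R",
                    barrier=int(barrier),
                )
            )
    return pd.DataFrame(records)


@dataclass(frozen=True)
class SweepConfig:
    """Full simulation design: the cross of all scenario axes."""

    topologies: tuple[Topology, ...] = ("linear", "binary")
    passability_modes: tuple[PassabilityMode, ...] = ("symmetric", "asymmetric")
    dispersal_modes: tuple[DispersalMode, ...] = ("global", "local")
    sizes: tuple[int, ...] = DEFAULT_SIZES
    n_replicates: int = 60
    seed: int = 0
    species: SpeciesParams = field(default_factory=SpeciesParams)

    def cells(self) -> list[ScenarioConfig]:
        return [
            ScenarioConfig(
                topology=t,
                passability_mode=p,
                dispersal_mode=d,
                n_reaches=n,
                n_replicates=self.n_replicates,
                seed=self.seed,
            )
            for t in self.topologies
            for p in self.passability_modes
            for d in self.dispersal_modes
            for n in self.sizes
        ]


def run_sweep(config: SweepConfig) -> dict[str, pd.DataFrame]:
    """Run every scenario cell and assemble replicate and correlation tables.

    Returns a dict of tidy DataFrames: ``network``, ``reach`` and
    ``removal`` (per-replicate records) plus ``network_scale``,
    ``reach_scale`` and ``sensitivity`` (correlation records).
    """
    tables = [run_scenario(cell, config.species) for cell in config.cells()]
    table = ReplicateTable.concat(tables)
    return {
        "network": table.network,
        "reach": table.reach,
        "removal": table.removal,
        "network_scale": network_scale_correlations(table),
        "reach_scale": reach_scale_correlations(table),
        "sensitivity": sensitivity_correlations(table),
    }
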