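"""River networks as rooted metric trees, and their random generation.

A river network is represented as a rooted tree whose nodes are stream
reaches and whose root is the river mouth.  Reach ids are 1-based and
follow a breadth-first numbering starting at the mouth (root = reach 1).
The edge connecting reach ``k`` (k >= 2) to its parent carries the
barrier labelled ``b_k`` with an upstream and a downstream passability
in (0, 1]; a passability of 1 means "no barrier in that direction".

Random networks are generated on two topology classes (linear chains and
complete binary trees), with reach lengths uniform on (l_max/2, l_max)
(l_max normalised to 1) and barrier base passabilities uniform on (0, 1)
drawn by Latin hypercube sampling.  Symmetric and asymmetric barrier
scenarios built from the same Latin hypercube row share the per-barrier
passability *product*, so undirected cumulative passabilities — and with
them every DCI value — coincide between the paired scenarios.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Literal, Sequence

import numpy as np
from scipy.stats import qmc

__all__ = [
    "RiverNetwork",
    "ScenarioConfig",
    "NetworkValidationError",
    "build_topology",
    "lhs_matrix",
    "assign_attributes",
    "dispersal_distance",
    "generate_replicates",
    "barrier_free",
]

Topology = Literal["linear", "binary"]
PassabilityMode = Literal["symmetric", "asymmetric"]
DispersalMode = Literal["global", "local"]

# Guard keeping LHS draws strictly inside the open unit interval; the
# model excludes fully impassable barriers (alpha = 0) and reserves
# alpha = 1 for "no barrier".
_OPEN_UNIT_EPS = 1e-12


class NetworkValidationError(ValueError):
    """Raised when a node table does not describe a valid rooted tree."""


@dataclass(frozen=True)
class RiverNetwork:
    """Rooted metric tree of river reaches with per-edge barrier passabilities.

    Arrays are indexed by reach id minus one (reach ``k`` -> index ``k-1``).
    ``parent[0]`` is ``-1`` (the root has no parent); ``alpha_up[0]`` and
    ``alpha_down[0]`` are unused and stored as NaN.

    Parameters
    ----------
    lengths
        Positive reach lengths (dimensionless; maximal length normalised to 1).
    parent
        ``parent[i]`` is the 0-based index of the parent (downstream
        neighbour) of reach ``i+1``; ``-1`` for the root.
    alpha_up, alpha_down
        Passability of barrier ``b_{i+1}`` (on the edge to the parent) in
        the upstream / downstream direction, each in (0, 1].
    """

    lengths: np.ndarray
    parent: np.ndarray
    alpha_up: np.ndarray
    alpha_down: np.ndarray

    def __post_init__(self) -> None:
        lengths = np.asarray(self.lengths, dtype=float)
        parent = np.asarray(self.parent, dtype=int)
        a_up = np.asarray(self.alpha_up, dtype=float)
        a_down = np.asarray(self.alpha_down, dtype=float)
        object.__setattr__(self, "lengths", lengths)
        object.__setattr__(self, "parent", parent)
        object.__setattr__(self, "alpha_up", a_up)
        object.__setattr__(self, "alpha_down", a_down)
        self._validate()

    def _validate(self) -> None:
        n = self.lengths.size
        if n < 1:
            raise NetworkValidationError("network must contain at least one reach")
        for name, arr in (
            ("parent", self.parent),
            ("alpha_up", self.alpha_up),
            ("alpha_down", self.alpha_down),
        ):
            if arr.shape != (n,):
                raise NetworkValidationError(
                    f"{name} has shape {arr.shape}, expected ({n},)"
                )
        if not np.all(self.lengths > 0):
            bad = int(np.argmin(self.lengths > 0)) + 1
            raise NetworkValidationError(f"reach {bad} has nonpositive length")
        roots = np.flatnonzero(self.parent < 0)
        if roots.size != 1 or roots[0] != 0:
            raise NetworkValidationError(
                "exactly one root expected and it must be reach 1 "
                f"(found root candidates at ids {list(roots + 1)})"
            )
        if np.any(self.parent[1:] >= n) or np.any(self.parent[1:] < 0):
            raise NetworkValidationError("parent id out of range")
        # Every reach must reach the root by following parents; a pointer
        # loop (cycle) or self-parent would make the walk exceed n steps.
        for i in range(1, n):
            node, steps = i, 0
            while node != 0:
                node = int(self.parent[node])
                steps += 1
                if node < 0 or steps > n:
                    raise NetworkValidationError(
                        f"reach {i + 1} is disconnected from the root "
                        "(cycle or broken parent chain)"
                    )
        for name, arr in (("alpha_up", self.alpha_up), ("alpha_down", self.alpha_down)):
            vals = arr[1:]
            if vals.size and not np.all((vals > 0) & (vals <= 1)):
                bad = int(np.argmin((vals > 0) & (vals <= 1))) + 2
                raise NetworkValidationError(
                    f"barrier b{bad}: {name} must lie in (0, 1]"
                )

    @property
    def n_reaches(self) -> int:
        return int(self.lengths.size)

    @property
    def total_length(self) -> float:
        """Total network length L = sum of reach lengths."""
        return float(self.lengths.sum())

    @property
    def reach_ids(self) -> np.ndarray:
        return np.arange(1, self.n_reaches + 1)

    @property
    def barrier_labels(self) -> np.ndarray:
        """Barrier labels b_2 .. b_N (one per non-root reach)."""
        return np.arange(2, self.n_reaches + 1)

    def children(self, reach_id: int) -> list[int]:
        idx = _check_id(self, reach_id)
        return [int(i) + 1 for i in np.flatnonzero(self.parent == idx)]

    def depths(self) -> np.ndarray:
        """Number of edges between each reach and the root."""
        d = np.zeros(self.n_reaches, dtype=int)
        for i in range(1, self.n_reaches):
            d[i] = d[self.parent[i]] + 1
        return d

    def with_barrier_removed(self, barrier_label: int) -> "RiverNetwork":
        """Copy of the network with barrier ``b_label`` fully passable."""
        if not (2 <= barrier_label <= self.n_reaches):
            raise KeyError(f"unknown barrier label b{barrier_label}")
        a_up = self.alpha_up.copy()
        a_down = self.alpha_down.copy()
        a_up[barrier_label - 1] = 1.0
        a_down[barrier_label - 1] = 1.0
        return replace(self, alpha_up=a_up, alpha_down=a_down)


def _check_id(net: RiverNetwork, reach_id: int) -> int:
    if not (1 <= reach_id <= net.n_reaches):
        raise KeyError(f"unknown reach id {reach_id} (network has {net.n_reaches})")
    return reach_id - 1


def barrier_free(net: RiverNetwork) -> RiverNetwork:
    """Baseline network: same topology and lengths, every passability = 1."""
    a = np.ones(net.n_reaches)
    a[0] = np.nan
    return replace(net, alpha_up=a.copy(), alpha_down=a.copy())


@dataclass(frozen=True)
class ScenarioConfig:
    """One cell of the simulation design.

    The axes are network topology (linear chain vs. complete binary tree),
    barrier passability construction (symmetric: alpha_u = alpha_d;
    asymmetric: alpha_d = 1 with alpha_u carrying the full product),
    dispersal scale (global: D = L; local: D = L/N) and network size.
    """

    topology: Topology
    passability_mode: PassabilityMode
    dispersal_mode: DispersalMode
    n_reaches: int
    n_replicates: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        if self.topology not in ("linear", "binary"):
            raise ValueError(f"unknown topology {self.topology!r}")
        if self.passability_mode not in ("symmetric", "asymmetric"):
            raise ValueError(f"unknown passability mode {self.passability_mode!r}")
        if self.dispersal_mode not in ("global", "local"):
            raise ValueError(f"unknown dispersal mode {self.dispersal_mode!r}")
        if not (3 <= self.n_reaches <= 50):
            raise ValueError("n_reaches must lie in [3, 50]")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")


def build_topology(shape: Topology, n_reaches: int) -> RiverNetwork:
    """Build the tree skeleton with unit lengths and placeholder passabilities.

    ``linear`` produces the chain s1–s2–…–sN rooted at s1.  ``binary``
    produces the complete binary tree filled left-to-right in breadth-first
    order (parent of reach k is reach k // 2), which degenerates to the full
    binary tree when N = 2**h − 1.
    """
    if shape not in ("linear", "binary"):
        raise ValueError(f"unknown topology {shape!r}")
    if n_reaches < 1:
        raise ValueError(f"invalid network size {n_reaches}: need at least 1 reach")
    if shape == "linear":
        parent = np.arange(-1, n_reaches - 1)
    else:
        ids = np.arange(1, n_reaches + 1)
        parent = ids // 2 - 1  # 0-based; root gets -1
    alpha = np.ones(n_reaches)
    alpha[0] = np.nan
    return RiverNetwork(
        lengths=np.ones(n_reaches),
        parent=parent,
        alpha_up=alpha.copy(),
        alpha_down=alpha.copy(),
    )


def lhs_matrix(
    n_samples: int,
    n_dims: int,
    seed: int | np.random.SeedSequence | np.random.Generator,
) -> np.ndarray:
    """Latin hypercube sample on the open unit cube.

    Each of the ``n_dims`` columns contains exactly one point per stratum
    [k/n, (k+1)/n), k = 0..n-1.  Values are clamped away from 0 and 1.
    Reproducible for a fixed seed.
    """
    if n_samples < 1 or n_dims < 1:
        raise ValueError("n_samples and n_dims must be positive")
    rng = np.random.default_rng(seed)
    sampler = qmc.LatinHypercube(d=n_dims, seed=rng)
    m = sampler.random(n=n_samples)
    return np.clip(m, _OPEN_UNIT_EPS, 1.0 - _OPEN_UNIT_EPS)


def assign_attributes(
    skeleton: RiverNetwork, mode: PassabilityMode, lhs_row: Sequence[float]
) -> RiverNetwork:
    """Attach random lengths and barrier passabilities to a skeleton.

    ``lhs_row`` holds N values for lengths (by reach id) followed by N−1
    base passabilities a_k (by barrier label).  Lengths are
    ``0.5 + 0.5 u`` (uniform on (1/2, 1) with l_max = 1).  Symmetric mode
    sets alpha_u = alpha_d = a_k; asymmetric mode sets alpha_d = 1 and
    alpha_u = a_k**2, so the per-barrier product alpha_u * alpha_d — and
    hence every undirected cumulative passability — is identical between
    the two modes.
    """
    n = skeleton.n_reaches
    row = np.asarray(lhs_row, dtype=float)
    if row.shape != (2 * n - 1,):
        raise ValueError(
            f"lhs_row must have 2N-1 = {2 * n - 1} entries, got {row.shape}"
        )
    lengths = 0.5 + 0.5 * row[:n]
    base = row[n:]
    alpha_up = np.empty(n)
    alpha_down = np.empty(n)
    alpha_up[0] = alpha_down[0] = np.nan
    if mode == "symmetric":
        alpha_up[1:] = base
        alpha_down[1:] = base
    elif mode == "asymmetric":
        alpha_up[1:] = base * base
        alpha_down[1:] = 1.0
    else:
        raise ValueError(f"unknown passability mode {mode!r}")
    return replace(
        skeleton, lengths=lengths, alpha_up=alpha_up, alpha_down=alpha_down
    )


def dispersal_distance(net: RiverNetwork, mode: DispersalMode) -> float:
    """Mean dispersal distance D for a dispersal scenario.

    Global dispersal spans the network (D = L); local dispersal spans an
    average reach (D = L / N).
    """
    if mode == "global":
        return net.total_length
    if mode == "local":
        return net.total_length / net.n_reaches
    raise ValueError(f"unknown dispersal mode {mode!r}")


_TOPOLOGY_KEY = {"linear": 0, "binary": 1}


def _cell_seed_sequence(config: ScenarioConfig) -> np.random.SeedSequence:
    # The spawn key deliberately excludes passability and dispersal mode so
    # that paired scenario cells draw identical Latin hypercube designs.
    return np.random.SeedSequence(
        entropy=config.seed,
        spawn_key=(_TOPOLOGY_KEY[config.topology], config.n_reaches),
    )


def generate_replicates(config: ScenarioConfig) -> Iterator[RiverNetwork]:
    """Yield the replicate networks of one scenario cell.

    All replicates of a cell come from one joint Latin hypercube design of
    dimension 2N−1 (N lengths, N−1 barriers).  Cells that differ only in
    passability or dispersal mode share the design, so symmetric and
    asymmetric runs are paired draw-for-draw.
    """
    skeleton = build_topology(config.topology, config.n_reaches)
    design = lhs_matrix(
        config.n_replicates, 2 * config.n_reaches - 1, _cell_seed_sequence(config)
    )
    for row in design:
        yield assign_attributes(skeleton, config.passability_mode, row)
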