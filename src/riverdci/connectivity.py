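"""Path structure, cumulative passabilities and dendritic connectivity indices.

On a tree there is exactly one path between any two reaches.  The
undirected cumulative passability

    c_ij = prod_m alpha_u,m * alpha_d,m

multiplies both directional passabilities of every barrier m on that
path (empty product = 1), while the directed cumulative passability
c~_ij (source j -> recipient i) takes, for each barrier, only the
passability in the direction actually swum: alpha_d while descending
from the source to the lowest common ancestor, alpha_u while ascending
to the recipient.  The two are linked by c~_ij * c~_ji = c_ij.

The Dendritic Connectivity Index for potamodromous fish is the
length-weighted average pairwise cumulative passability,

    DCI_p = sum_i sum_j c_ij (l_i / L)(l_j / L) * 100,

with the double sum running over all ordered pairs including i = j
(c_ii = 1), so that a barrier-free network scores exactly 100.  Its
reach-scale counterpart DCI_s(j) = sum_i c_ij (l_i / L) * 100 measures
how connected one segment is to the whole network; DCI_p is the
length-weighted average of the DCI_s values.

Swim distances d_ij are measured along the channel from reach midpoint
to reach midpoint: half of each endpoint reach plus the full lengths of
intermediate reaches.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .networks import RiverNetwork, _check_id

__all__ = [
    "PathDescriptor",
    "ConnectivityResult",
    "tree_path",
    "cumulative_passability",
    "directed_cumulative_passability",
    "swim_distance",
    "dci_p",
    "dci_s",
    "connectivity",
]

Direction = Literal["upstream", "downstream"]


@dataclass(frozen=True)
class PathDescriptor:
    """The unique tree path between two reaches, barrier by barrier.

    ``steps`` lists ``(barrier_label, direction)`` in travel order from
    the source: downstream steps toward the lowest common ancestor, then
    upstream steps toward the target.
    """

    source_id: int
    target_id: int
    steps: tuple[tuple[int, Direction], ...]

    @property
    def n_barriers(self) -> int:
        return len(self.steps)


def _ancestor_chain(net: RiverNetwork, idx: int) -> list[int]:
    """0-based indices from ``idx`` up to the root, inclusive."""
    chain = [idx]
    while net.parent[chain[-1]] >= 0:
        chain.append(int(net.parent[chain[-1]]))
    return chain


def tree_path(net: RiverNetwork, source_id: int, target_id: int) -> PathDescriptor:
    """Describe the unique path from ``source_id`` to ``target_id``.

    Water flows toward the root, so each edge crossed on the way down to
    the lowest common ancestor is a downstream step and each edge on the
    way back up to the target is an upstream step.
    """
    s = _check_id(net, source_id)
    t = _check_id(net, target_id)
    up_s = _ancestor_chain(net, s)
    up_t = _ancestor_chain(net, t)
    common = set(up_s) & set(up_t)
    steps: list[tuple[int, Direction]] = []
    for node in up_s:
        if node in common:
            break
        steps.append((node + 1, "downstream"))  # crossing barrier b_{node+1}
    ascend = []
    for node in up_t:
        if node in common:
            break
        ascend.append((node + 1, "upstream"))
    steps.extend(reversed(ascend))
    return PathDescriptor(source_id=source_id, target_id=target_id, steps=tuple(steps))


def cumulative_passability(net: RiverNetwork, i: int, j: int) -> float:
    """Undirected cumulative passability c_ij (product of alpha_u * alpha_d)."""
    path = tree_path(net, j, i)
    out = 1.0
    for label, _ in path.steps:
        out *= net.alpha_up[label - 1] * net.alpha_down[label - 1]
    return out


def directed_cumulative_passability(
    net: RiverNetwork, source_j: int, recipient_i: int
) -> float:
    """Directed cumulative passability c~_ij from source j to recipient i."""
    path = tree_path(net, source_j, recipient_i)
    out = 1.0
    for label, direction in path.steps:
        alpha = net.alpha_down if direction == "downstream" else net.alpha_up
        out *= alpha[label - 1]
    return out


def swim_distance(net: RiverNetwork, i: int, j: int) -> float:
    """Along-channel distance "as the fish swims", midpoint to midpoint.

    d_ij = l_i/2 + (lengths of intermediate reaches) + l_j/2, and d_ii = 0.
    """
    ii = _check_id(net, i)
    jj = _check_id(net, j)
    if ii == jj:
        return 0.0
    path = tree_path(net, i, j)
    # Nodes visited strictly between i and j: the path steps cross barriers
    # b_k whose reach k is a path node; drop the endpoints.
    nodes = {label - 1 for label, _ in path.steps}
    # A downstream step from node k lands on parent(k); collect landing nodes.
    for label, _ in path.steps:
        k = label - 1
        nodes.add(int(net.parent[k]))
    nodes.discard(ii)
    nodes.discard(jj)
    mid = float(net.lengths[list(nodes)].sum()) if nodes else 0.0
    return 0.5 * float(net.lengths[ii]) + mid + 0.5 * float(net.lengths[jj])


@dataclass(frozen=True)
class ConnectivityResult:
    """All pairwise connectivity quantities of one network.

    ``c`` is symmetric with unit diagonal; ``c_dir[i, j]`` is the directed
    cumulative passability from source ``j+1`` to recipient ``i+1``;
    ``d`` holds midpoint-to-midpoint swim distances.  ``dci_s[j]`` is the
    segment index of reach ``j+1`` and ``dci_p`` the network index.
    """

    c: np.ndarray
    c_dir: np.ndarray
    d: np.ndarray
    dci_p: float
    dci_s: np.ndarray

    @property
    def n_reaches(self) -> int:
        return self.c.shape[0]


def connectivity(net: RiverNetwork) -> ConnectivityResult:
    """Compute all pairwise passabilities, distances and DCI values.

    Uses cumulative products along root paths: for reaches x with root-path
    products A_u(x), A_d(x) (of upstream / downstream passabilities) and
    lowest common ancestor a = lca(i, j),

        c_ij   = P(i) P(j) / P(a)^2          with P = A_u * A_d,
        c~_ij  = (A_d(j) / A_d(a)) * (A_u(i) / A_u(a)),

    because barriers on the shared root path below the LCA cancel.
    """
    n = net.n_reaches
    depth = net.depths()
    max_depth = int(depth.max())

    # anc[i, k] - reach k+1 is an ancestor of (or equal to) reach i+1
    anc = np.zeros((n, n), dtype=bool)
    # anc_at_depth[i, d] = 0-based ancestor of i at depth d (valid d <= depth[i])
    anc_at_depth = np.zeros((n, max_depth + 1), dtype=int)
    for i in range(n):
        node = i
        anc[i, node] = True
        anc_at_depth[i, depth[node]] = node
        while net.parent[node] >= 0:
            node = int(net.parent[node])
            anc[i, node] = True
            anc_at_depth[i, depth[node]] = node

    a_up = np.where(np.isnan(net.alpha_up), 1.0, net.alpha_up)
    a_down = np.where(np.isnan(net.alpha_down), 1.0, net.alpha_down)
    # Root-path cumulative products and length sums (inclusive of the reach).
    # The undirected product accumulates the per-barrier product a_up * a_down
    # directly, so networks that share those products (e.g. paired symmetric
    # and asymmetric scenario draws) get bit-identical c matrices.
    cum_up = np.ones(n)
    cum_down = np.ones(n)
    cum_prod = np.ones(n)
    cum_len = net.lengths.astype(float).copy()
    for i in range(1, n):
        p = int(net.parent[i])
        cum_up[i] = cum_up[p] * a_up[i]
        cum_down[i] = cum_down[p] * a_down[i]
        cum_prod[i] = cum_prod[p] * (a_up[i] * a_down[i])
        cum_len[i] = cum_len[p] + net.lengths[i]

    # The common ancestors of i and j form the root chain down to the LCA,
    # so their count is depth(lca) + 1.
    n_common = anc.astype(np.int64) @ anc.T.astype(np.int64)
    lca = anc_at_depth[np.arange(n)[:, None], n_common - 1]

    c = cum_prod[:, None] * cum_prod[None, :] / cum_prod[lca] ** 2
    # c_dir[i, j]: source j descends (alpha_down), recipient i is ascended to.
    c_dir = (cum_down[None, :] / cum_down[lca]) * (cum_up[:, None] / cum_up[lca])

    lengths = net.lengths
    path_node_len = (
        cum_len[:, None] + cum_len[None, :] - 2.0 * cum_len[lca] + lengths[lca]
    )
    d = path_node_len - 0.5 * (lengths[:, None] + lengths[None, :])
    np.fill_diagonal(d, 0.0)
    np.fill_diagonal(c, 1.0)
    np.fill_diagonal(c_dir, 1.0)

    w = lengths / net.total_length
    dci_s_vec = (c @ w) * 100.0
    dci_p_val = float(w @ c @ w * 100.0)
    return ConnectivityResult(c=c, c_dir=c_dir, d=d, dci_p=dci_p_val, dci_s=dci_s_vec)


def dci_p(net: RiverNetwork) -> float:
    """Network-scale Dendritic Connectivity Index (0, 100]."""
    return connectivity(net).dci_p


def dci_s(net: RiverNetwork, j: int) -> float:
    """Reach-scale Dendritic Connectivity Index of reach ``j``."""
    jj = _check_id(net, j)
    return float(connectivity(net).dci_s[jj])
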