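"""Barrier-aware patch-occupancy metapopulation model on river networks.

Each reach is a patch whose occupancy probability p_i(t) follows

    dp_i/dt = C_i(p) (1 - p_i) - E_i p_i,

with a length-dependent extinction rate E_i = e / l_i^omega and a
colonization rate

    C_i(p) = c l_i^gamma sum_{j != i} l_j^eps exp(-d_ij / D) c~_ij p_j

that discounts colonizers by swim distance (mean dispersal distance D)
and by the directed cumulative barrier passability c~_ij.  With all
passabilities equal to one and omega = eps = 1, gamma = 0 the model
reduces to the classic incidence-function metapopulation of terrestrial
landscapes.

Persistence is governed by the linearization at the extinction state
p = 0: the Jacobian J = B - diag(E) with colonization-gain matrix
B_ij = c l_i^gamma l_j^eps exp(-d_ij/D) c~_ij (zero diagonal) is a
Metzler matrix, irreducible on a connected tree with positive
passabilities, so its dominant eigenvalue lambda is real.  The
metapopulation persists iff lambda > 0, equivalently iff the basic
reproduction number R — the spectral radius of the next-generation
matrix K_ij = B_ij / E_j, i.e. the expected number of reaches a single
occupied reach colonizes over its mean occupied lifetime 1/E_j —
exceeds one.  When it persists, occupancies approach the unique
positive steady state p* solving p_i = C_i(p) / (C_i(p) + E_i).

Relative metrics compare a fragmented network against the barrier-free
baseline (same topology and lengths, all passabilities 1): growth
G_s = exp(lambda - lambda_0), reproduction R_s = R / R_0, mean occupancy
P_s = pbar / pbar_0 at the network scale; per-reach occupancy ratio
O_s(i) = p_i*/p_{i,0}* and reproductive-value ratio V_s(i) = v_i/v_{i,0}
at the reach scale, where v is the positive left eigenvector of lambda
normalized to sum v_i^2 = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, optimize

from .networks import RiverNetwork, barrier_free
from .connectivity import ConnectivityResult, connectivity

__all__ = [
    "SpeciesParams",
    "LinearizationResult",
    "MetricBundle",
    "ConvergenceError",
    "extinction_rates",
    "colonization_matrix",
    "linearize",
    "growth_rate",
    "reproduction_number",
    "reproductive_values",
    "steady_state",
    "relative_metrics",
    "integrate_occupancy",
]


class ConvergenceError(RuntimeError):
    """Steady-state solver failed to reach the requested tolerance."""


@dataclass(frozen=True)
class SpeciesParams:
    """Species-specific model parameters.

    c, e
        Colonization strength and extinction parameter (per unit time);
        long-term outcomes depend only on the ratio c/e (default 10).
    omega
        Length–extinction exponent in [0, 1] (1: extinction inversely
        proportional to length).
    gamma
        Length–attractiveness exponent (0: colonization independent of
        recipient length).
    epsilon
        Length–productivity exponent (1: colonizers proportional to
        source length).
    D
        Mean dispersal distance, in the same (dimensionless) units as
        reach lengths.
    """

    c: float = 10.0
    e: float = 1.0
    omega: float = 1.0
    gamma: float = 0.0
    epsilon: float = 1.0
    D: float = 1.0

    def __post_init__(self) -> None:
        if self.c <= 0 or self.e <= 0 or self.D <= 0:
            raise ValueError("c, e and D must be positive")
        if not 0.0 <= self.omega <= 1.0:
            raise ValueError("omega must lie in [0, 1]")
        if self.gamma < 0 or self.epsilon < 0:
            raise ValueError("gamma and epsilon must be nonnegative")


def extinction_rates(net: RiverNetwork, params: SpeciesParams) -> np.ndarray:
    """Per-reach extinction rates E_i = e / l_i^omega."""
    return params.e / net.lengths**params.omega


def colonization_matrix(
    net: RiverNetwork, params: SpeciesParams, conn: ConnectivityResult
) -> np.ndarray:
    """Colonization-gain matrix B with B_ij the rate at which an occupied
    reach j generates colonizations of reach i; zero diagonal.

    The colonization rate functional is C_i(p) = sum_j B_ij p_j.
    """
    if conn.n_reaches != net.n_reaches:
        raise ValueError(
            "connectivity result does not match the network "
            f"({conn.n_reaches} vs {net.n_reaches} reaches)"
        )
    l = net.lengths
    B = (
        params.c
        * l[:, None] ** params.gamma
        * l[None, :] ** params.epsilon
        * np.exp(-conn.d / params.D)
        * conn.c_dir
    )
    np.fill_diagonal(B, 0.0)
    return B


@dataclass(frozen=True)
class LinearizationResult:
    """Linearization of the occupancy model at the extinction state."""

    B: np.ndarray
    E: np.ndarray
    J: np.ndarray
    lam: float
    v: np.ndarray
    R: float


def growth_rate(B: np.ndarray, E: np.ndarray) -> float:
    """Metapopulation growth rate: dominant eigenvalue of J = B - diag(E).

    J is Metzler (nonnegative off-diagonal) and irreducible, so the
    rightmost eigenvalue is real.
    """
    J = B - np.diag(E)
    eig = np.linalg.eigvals(J)
    lam = eig[np.argmax(eig.real)]
    return float(lam.real)


def reproduction_number(B: np.ndarray, E: np.ndarray) -> float:
    """Basic reproduction number: spectral radius of K, K_ij = B_ij / E_j."""
    K = B / E[None, :]
    return float(np.max(np.abs(np.linalg.eigvals(K))))


def reproductive_values(B: np.ndarray, E: np.ndarray) -> tuple[float, np.ndarray]:
    """Dominant eigenvalue and positive left eigenvector of J = B - diag(E).

    The left Perron vector is returned with nonnegative entries and
    normalized to sum of squares one.
    """
    J = B - np.diag(E)
    eig, vecs = np.linalg.eig(J.T)
    k = int(np.argmax(eig.real))
    v = vecs[:, k].real
    if v.sum() < 0:
        v = -v
    v = np.abs(v)  # Perron direction is entrywise positive; scrub -0.0 noise
    return float(eig[k].real), v / np.sqrt((v**2).sum())


def linearize(
    net: RiverNetwork, params: SpeciesParams, conn: ConnectivityResult | None = None
) -> LinearizationResult:
    """Assemble B, E, J and the derived persistence quantities."""
    if conn is None:
        conn = connectivity(net)
    B = colonization_matrix(net, params, conn)
    E = extinction_rates(net, params)
    lam, v = reproductive_values(B, E)
    return LinearizationResult(
        B=B, E=E, J=B - np.diag(E), lam=lam, v=v, R=reproduction_number(B, E)
    )


def steady_state(
    B: np.ndarray,
    E: np.ndarray,
    lam: float | None = None,
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> np.ndarray:
    """Long-term occupancy probabilities p*.

    Returns the zero vector when the metapopulation goes extinct
    (lambda <= 0); otherwise the unique positive fixed point of
    p_i = C_i(p) / (C_i(p) + E_i), found by monotone fixed-point
    iteration from p = 1 (the map is monotone, so iterates decrease
    toward p* from above).  A residual root-finder takes over if the
    iteration stalls short of ``tol``.
    """
    if lam is None:
        lam = growth_rate(B, E)
    n = E.size
    if lam <= 0:
        return np.zeros(n)
    p = np.ones(n)
    for _ in range(max_iter):
        C = B @ p
        p_next = C / (C + E)
        if np.max(np.abs(p_next - p)) < tol:
            return p_next
        p = p_next

    def residual(q: np.ndarray) -> np.ndarray:
        return (B @ q) * (1.0 - q) - E * q

    sol = optimize.root(residual, p, method="hybr", tol=1e-14)
    if not sol.success or np.max(np.abs(residual(sol.x))) > 1e-8:
        raise ConvergenceError(
            "steady-state iteration did not converge "
            f"(residual {np.max(np.abs(residual(p))):.2e})"
        )
    return np.clip(sol.x, 0.0, 1.0)


@dataclass(frozen=True)
class MetricBundle:
    """Relative persistence metrics of a network against its barrier-free
    baseline, at the network scale (G_s, R_s, P_s) and per reach
    (O_s, V_s).  Occupancy ratios are NaN (and ``occupancy_defined`` is
    False) when the baseline metapopulation does not persist.
    """

    G_s: float
    R_s: float
    P_s: float
    O_s: np.ndarray
    V_s: np.ndarray
    lam: float
    lam0: float
    R: float
    R0: float
    pbar: float
    pbar0: float
    p_star: np.ndarray
    p_star0: np.ndarray
    v: np.ndarray
    v0: np.ndarray
    occupancy_defined: bool = field(default=True)


def relative_metrics(
    net: RiverNetwork,
    params: SpeciesParams,
    conn: ConnectivityResult | None = None,
) -> MetricBundle:
    """Compute all relative metrics for a focal network.

    The baseline shares the focal network's topology and lengths with
    every passability set to one, so a barrier-free focal network scores
    G_s = R_s = P_s = 1 and unit ratios on every reach.
    """
    if conn is None:
        conn = connectivity(net)
    lin = linearize(net, params, conn)
    base_net = barrier_free(net)
    # Baseline distances and lengths are unchanged; only passabilities move.
    lin0 = linearize(base_net, params, connectivity(base_net))

    p_star0 = steady_state(lin0.B, lin0.E, lin0.lam)
    p_star = steady_state(lin.B, lin.E, lin.lam)
    pbar = float(p_star.mean())
    pbar0 = float(p_star0.mean())

    occupancy_defined = lin0.lam > 0
    n = net.n_reaches
    if occupancy_defined:
        P_s = pbar / pbar0
        O_s = p_star / p_star0
    else:
        P_s = float("nan")
        O_s = np.full(n, np.nan)
    return MetricBundle(
        G_s=float(np.exp(lin.lam - lin0.lam)),
        R_s=lin.R / lin0.R if lin0.R > 0 else float("nan"),
        P_s=P_s,
        O_s=O_s,
        V_s=lin.v / lin0.v,
        lam=lin.lam,
        lam0=lin0.lam,
        R=lin.R,
        R0=lin0.R,
        pbar=pbar,
        pbar0=pbar0,
        p_star=p_star,
        p_star0=p_star0,
        v=lin.v,
        v0=lin0.v,
        occupancy_defined=occupancy_defined,
    )


def integrate_occupancy(
    net: RiverNetwork,
    params: SpeciesParams,
    p0: np.ndarray,
    t_end: float,
    rtol: float = 1e-9,
    atol: float = 1e-11,
    conn: ConnectivityResult | None = None,
):
    """Integrate the occupancy ODE from p0 over [0, t_end].

    Used for validation of the steady-state solver; returns the
    ``scipy.integrate.solve_ivp`` result (``.y[:, -1]`` is the final
    state, which remains in [0, 1]^N).
    """
    p0 = np.asarray(p0, dtype=float)
    if p0.shape != (net.n_reaches,) or np.any(p0 < 0) or np.any(p0 > 1):
        raise ValueError("p0 must be a vector in [0, 1]^N")
    if conn is None:
        conn = connectivity(net)
    B = colonization_matrix(net, params, conn)
    E = extinction_rates(net, params)

    def rhs(_t: float, p: np.ndarray) -> np.ndarray:
        return (B @ p) * (1.0 - p) - E * p

    sol = integrate.solve_ivp(
        rhs, (0.0, t_end), p0, method="LSODA", rtol=rtol, atol=atol
    )
    if not sol.success:
        raise RuntimeError(f"occupancy integration failed: {sol.message}")
    return sol
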