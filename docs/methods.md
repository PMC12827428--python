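# Methods

## Network representation

A river network is a rooted metric tree: nodes are stream reaches,
the root (reach 1) is the river mouth, and water flows root-ward.
Reach ids follow breadth-first numbering from the mouth, and the edge
joining reach `k ≥ 2` to its parent carries barrier `b_k` with an
upstream and a downstream passability in (0, 1].  Fully impassable
barriers (α = 0) are excluded — a reach behind one is simply not part
of the accessible network — and α = 1 means "no barrier in that
direction", so the tree is always connected and every linearized model
matrix below is irreducible.

Two topology classes are supported as the limiting cases of dendritic
branching: the linear chain, and the *complete* binary tree filled
left-to-right in breadth-first order (parent of reach `k` is reach
`⌊k/2⌋`).  The complete-tree fill is the unique choice that is
consistent with breadth-first labelling at every size and coincides
with the full binary tree whenever `N = 2^h − 1`.

## Connectivity indices

The cumulative passability between reaches is the product of
`α_u·α_d` over the barriers on the unique connecting path; DCI_p is its
length-weighted average over all *ordered* pairs including `i = j`
(with `c_ii = 1`) times 100, and DCI_s(j) the length-weighted
connectivity of one reach to all reaches.  Including the diagonal is
required for the anchor identity DCI_p = 100 on a barrier-free network;
it also makes DCI_p the length-weighted average of the DCI_s values, an
identity the tests check to 1e−10.

The directed cumulative passability `c̃_ij` used by the colonization
rate multiplies, at each barrier, only the passability in the direction
the fish actually swims: downstream from the source to the lowest
common ancestor, then upstream to the recipient.  Consequently
`c̃_ij·c̃_ji = c_ij` holds barrier by barrier.

Swim distance `d_ij` is measured midpoint-to-midpoint: half of each
endpoint reach plus the full lengths of intermediate reaches, giving a
symmetric matrix with zero diagonal and additivity along tree paths.
The endpoint convention is not canonical in the connectivity
literature; midpoints were chosen because they are the only symmetric
convention with `d_ii = 0` that needs no extra geometry, and it is the
single convention this package implements.

All pairwise quantities are computed from cumulative root-path
products and a pairwise lowest-common-ancestor table (shared-ancestor
counts give the LCA depth directly on a tree), which is O(N²) per
network after an O(N·depth) setup — ample at N ≤ 50.  The undirected
product accumulates the per-barrier product `α_u·α_d` as a unit, so
scenario pairs constructed to share those products (see below) produce
bit-identical `c` matrices and DCI values.

## Metapopulation model

Occupancy probabilities follow the patch-occupancy equation

    dp_i/dt = C_i(p)(1 − p_i) − E_i p_i

with `E_i = e/l_i^ω` and
`C_i(p) = c l_i^γ Σ_{j≠i} l_j^ε exp(−d_ij/D) c̃_ij p_j`.  Reach length
is a proxy for habitat amount and quality; with all passabilities 1,
ω = ε = 1 and γ = 0 the model reduces to the classic incidence-function
metapopulation for terrestrial patch networks.

The linearization at extinction has Jacobian `J = B − diag(E)` with
`B_ij = c l_i^γ l_j^ε exp(−d_ij/D) c̃_ij` and zero diagonal.  `J` is
Metzler and irreducible, so its rightmost eigenvalue λ is real and its
left/right Perron vectors are positive.  The basic reproduction number
is defined through the next-generation matrix `K_ij = B_ij/E_j`
(colonizations of `i` produced by an occupied `j` over its mean
occupied lifetime `1/E_j`); `R = ρ(K)` then satisfies the threshold
equivalence sign(λ) = sign(R − 1), which the tests verify on 500 random
networks spanning both regimes.

Steady state: when λ > 0 the positive equilibrium solves
`p_i = C_i(p)/(C_i(p) + E_i)`.  The iteration of this map from `p = 1`
is monotone decreasing and converges to the unique positive fixed
point; we iterate to 1e−10 in max norm (at most 10 000 iterations) and
hand the iterate to a Powell-hybrid root finder on the residual in the
rare near-threshold cases where the linear convergence rate approaches
one.  When λ ≤ 0 the equilibrium is the origin and is returned
directly.  The ODE integrator (LSODA, rtol 1e−9) exists purely as an
independent check of this solver and agrees to 1e−6 on random networks.

## Relative metrics and their baselines

Every metric is expressed relative to the *barrier-free baseline*:
the identical topology and lengths with all passabilities set to one.
This is the reading under which DCI_p = 100 and every relative metric
equals 1 simultaneously on an unfragmented network.  Network scale:
`G_s = e^{λ−λ₀}` (annualized growth ratio), `R_s = R/R₀`,
`P_s = p̄/p̄₀`; reach scale: `O_s(i) = p_i*/p_{i,0}*` and
`V_s(i) = v_i/v_{i,0}` with `v` normalized to Σv_i² = 1.  If the
baseline itself does not persist, the occupancy ratios are undefined
and reported as NaN with an explicit flag, never as zero.

One caveat worth stating: long-term *outcomes* (persistence, p*, all
ratios) depend only on c/e, but `G_s` depends on the absolute time
scale — jointly rescaling (c, e) by k raises `G_s` to the power k.
Because the analysis is rank-based, this changes no Spearman
correlation: rank invariance under joint rescaling is what the
simulations rely on, and it is asserted in the tests rather than
silently assumed.

## Synthetic scenario design

The generator emulates the study conditions directly:

- **Lengths** uniform on (1/2, 1) with the maximal length normalized to
  1 (avoiding very short reaches); a KS test across 6000 generated
  lengths is part of the suite.
- **Passabilities** uniform on (0, 1) (clamped away from the endpoints
  by 1e−12: 0 is excluded by the accessibility assumption, 1 is
  reserved for "no barrier").
- **Latin hypercube sampling**, one joint design of dimension 2N − 1
  per scenario cell (N lengths, then N − 1 barriers in label order),
  60 replicates by default.  Whether the original design sampled
  lengths and passabilities jointly or separately is not documented;
  a joint design was chosen as the simpler reproducible option.
- **Barrier symmetry**: symmetric cells set `α_u = α_d = a_k`;
  asymmetric cells set `α_d = 1` and `α_u = a_k²` from the *same* LHS
  draw, so the per-barrier product — and with it every DCI value — is
  identical between the paired cells while the directed passabilities
  differ.  Pairing is achieved by deriving the cell's seed only from
  (topology, size, master seed).
- **Dispersal**: global `D = L`, local `D = L/N`.
- **Species defaults**: e = 1, c = 10 (fixing c/e = 10), ω = 1, ε = 1,
  γ = 0.  Only the ratio c/e matters for ranks (above); the exponents
  are exposed in the config for other choices.
- **Sizes**: the default grid {3, 5, 7, 10, 15, 20, 30, 40, 50} spans
  the studied 3–50 range with denser coverage at the small end where
  topology effects are strongest; the grid is configurable.

What the generator does **not** emulate: realistic drainage geometries
(optimal channel networks, comb networks), spatially correlated
passabilities, partially barriered networks (a barrier sits on *every*
edge), or habitat quality beyond the quality-adjusted length proxy.
Passing tests therefore demonstrate the structural-index/persistence
relationship under idealized fragmentation, not its strength in any
particular real watershed.

## Sensitivity analysis

For each barrier, DCI_p and R are computed with the barrier in place
and with its passability set to unity in both directions; the ratio
removed/present is the relative change.  Both ratios are ≥ 1 — removing
a barrier can only increase products of passabilities, and `R` is the
spectral radius of a nonnegative matrix that is entrywise nondecreasing
in every passability.  The orientation (removed/present rather than its
reciprocal or complement) is a documented convention; Spearman
correlations are invariant to any strictly monotone reorientation.
Baseline quantities are barrier-independent and computed once per
replicate.

## Statistical choices

Spearman rank correlation (average ranks on ties) links indices to
metrics: per scenario cell at the network scale, per reach (in
breadth-first order) at the reach scale, and per barrier for the
removal analysis.  A correlation of a constant column is undefined and
is reported as NaN with `defined = False` — deliberately not coerced to
0, which would fabricate a "no association" result.  Replicates where a
numerical step fails are kept with the error message attached rather
than dropped, so cell sample sizes are always auditable.

## Numerical conventions

- Eigencomputations use dense solvers (N ≤ 50); the dominant eigenvalue
  is selected by maximal real part and the left eigenvector's sign is
  fixed to the positive Perron direction before normalization.
- Degenerate inputs: a single reach has λ = −E₁, R = 0 and no barriers;
  identity paths have cumulative passability 1 and distance 0.
- Fixed master seed ⇒ byte-identical outputs: sub-seeds are derived
  deterministically per scenario cell via seed-sequence spawn keys, and
  result CSVs use deterministic column order and float formatting.

## Problem sizes in the test suite

The end-to-end tests run the full default design (4 scenario axes,
9 sizes, 60 LHS replicates — 4320 networks) twice to check bit-level
reproducibility, which completes in a few minutes on one core; the
structural identities are checked on a few hundred random networks and
the dynamics cross-checks on a few dozen, sizes chosen so each check
still spans both persistence regimes and all topology classes.
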