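# riverdci

Structural connectivity indices and metapopulation persistence on
barrier-fragmented river networks.

River networks are dendritic: every pair of stream reaches is joined by
exactly one path, and human-made barriers (dams, culverts) along that
path reduce the probability that a fish can move between them.
Practitioners summarize this with the Dendritic Connectivity Index.
For a network of `N` reaches with lengths `l_i` (total length `L`) and
cumulative passability `c_ij` — the product of upstream and downstream
passabilities `α_u·α_d` over every barrier on the path between reaches
`i` and `j` — the network-scale index for potamodromous fish is

    DCI_p = Σ_i Σ_j c_ij (l_i/L)(l_j/L) × 100,

and the reach-scale index `DCI_s(j) = Σ_i c_ij (l_i/L) × 100`.  A
barrier-free network scores 100.

Whether these *structural* indices track anything *demographic* is the
question this package addresses, for modellers and conservation
planners who use DCI to rank restoration options.  It implements a
barrier-aware patch-occupancy metapopulation model,

    dp_i/dt = C_i(p)(1 − p_i) − E_i p_i,
    E_i = e / l_i^ω,
    C_i(p) = c l_i^γ Σ_{j≠i} l_j^ε exp(−d_ij/D) c̃_ij p_j,

where `c̃_ij` is the direction-aware cumulative passability (only the
passability in the swum direction counts at each barrier) and `d_ij`
the along-channel distance between reach midpoints.  From the
linearization at extinction (`J = B − diag(E)` with
`B_ij = c l_i^γ l_j^ε exp(−d_ij/D) c̃_ij`) it derives the
metapopulation growth rate `λ` (dominant eigenvalue), the basic
reproduction number `R` (spectral radius of the next-generation matrix
`B_ij/E_j`; persistence iff `R > 1` iff `λ > 0`), the steady-state
occupancies `p*`, and per-reach reproductive values `v_i` (left Perron
eigenvector).  Each quantity is expressed relative to the same network
with all barriers removed: `G_s = e^{λ−λ₀}`, `R_s = R/R₀`,
`P_s = p̄/p̄₀`, `O_s(i) = p_i*/p_{i,0}*`, `V_s(i) = v_i/v_{i,0}`.

A simulation engine sweeps four scenario axes — topology (linear chain
vs. complete binary tree), barrier symmetry (symmetric `α_u = α_d` vs.
fully passable downstream), dispersal scale (`D = L` vs. `D = L/N`) and
network size (3–50 reaches) — with Latin-hypercube-sampled lengths and
passabilities (60 replicates per cell), then computes Spearman rank
correlations between indices and metrics at the network scale, the
reach scale, and per barrier for a removal sensitivity analysis.

## Worked example

```python
import numpy as np, dataclasses
import riverdci as rd

# the 7-reach complete binary tree, unit lengths, every barrier at 0.5/0.5
net = rd.build_topology("binary", 7)
a = np.full(7, 0.5); a[0] = np.nan
net = dataclasses.replace(net, alpha_up=a.copy(), alpha_down=a.copy())

print(rd.dci_p(net))
params = rd.SpeciesParams(D=rd.dispersal_distance(net, "global"))
m = rd.relative_metrics(net, params)
print(m.R, m.R0, m.R_s)
print(rd.removal_ratios(net, params, barrier_label=4))
```

prints

```
22.512755102040817
13.224709267065657 43.92348536168221 0.3010851520130635
(1.21671388101983, 1.2498818953289232)
```

With every barrier half-passable in both directions the network keeps
only 22.5 of its 100 connectivity points; the basic reproduction number
drops to 30 % of its barrier-free value (13.2 vs. 43.9) — the
metapopulation still persists (`R > 1`), but with far less margin.
Removing barrier `b₄` alone would raise DCI_p by 22 % and `R` by 25 %.

The same operations are available from a shell:

```sh
riverdci generate --topology binary --n-reaches 7 --n-replicates 60 --seed 1 --out nets/
riverdci dci nets/replicate_000.csv
riverdci metrics nets/replicate_000.csv --dispersal global
riverdci sensitivity nets/replicate_000.csv
riverdci sweep --seed 1 --out results/sweep/
```

`riverdci sweep` runs the full scenario design and writes tidy CSVs
(per-replicate records plus the three correlation tables) and a
`manifest.json` that pins the config and master seed; reruns with the
same seed are byte-identical.

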