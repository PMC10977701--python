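# Methods

## The model

`beardsim` simulates a two-strain microbial colony growing on a 3-D
cubic lattice of `N_c x N_c x N_z` sites (default 50 x 50 x 100), each
site holding at most one cell. The two strains are a slow grower `S`
(baseline division rate `r_S0 = 0.05` divisions per unit time, the
cooperator paying the cost of public-good production) and a fast grower
`F` (`r_F0 = 0.1`). A cell's division rate depends on the occupancy
fractions `phi_S`, `phi_F` of its cubic interaction neighborhood
(Chebyshev radius `R_i = 3`, in-lattice sites only, focal site
excluded):

    r_S = (r_S0 + r_SF*phi_F + r_SS*phi_S) * [1 - chi*(phi_S + phi_F)]
    r_F = (r_F0 + r_FS*phi_S + r_FF*phi_F) * [1 - chi*(phi_S + phi_F)]

`r_ij` is the benefit neighbors of type `j` confer on a cell of type
`i`; the crowding coefficient `chi = 1` makes the rate exactly zero in
a full neighborhood. Social scenarios are sparsity patterns of the
`r_ij` matrix with a single shared strength `r`:

| scenario            | r_SS | r_SF | r_FS | r_FF |
|---------------------|------|------|------|------|
| baseline            | 0    | 0    | 0    | 0    |
| obligate            | r    | 0    | r    | 0    |
| greenbeard          | r    | 0    | 0    | 0    |
| two_greenbeards     | r    | r    | r    | r    |
| slow_poly_fast_gb   | r    | r    | 0    | r    |
| fast_poly_slow_gb   | r    | 0    | r    | r    |
| both_poly           | r    | 0    | 0    | r    |

Maximizing the own-type rate `(r_i0 + r_ii*phi)(1 - chi*phi)` over
`phi` gives the interior optimum `phi* = (r_ii - chi*r_i0) / (2*chi*
r_ii)` and `r_max = (chi*r_ii + r_i0)^2 / (4*r_ii*chi)`; `r_max` is the
natural x-axis for presenting sweep results because it is what a
cooperator can actually attain. For a non-cooperator (`r_ii = 0`) the
maximum is `r_i0` in an empty neighborhood; for `r_ii < chi*r_i0` the
interior optimum does not exist and `phi*` is clamped to the boundary.
Growth rates are clamped at zero from below — unreachable at `chi = 1`,
but it keeps the contract total for `chi > 1` explorations. The
fast-strain maximum reuses the same closed form with `(r_F0, r_FF)`;
the algebra is strain-agnostic.

## Simulation procedure

A run starts from `n0 = round(0.05 * 15^2) = 11` cells placed uniformly
without replacement in the centered `15 x 15` square of the bottom
layer, `round(f_S * n0)` of them slow. Rounding is half-up for both
counts, so replicate composition is deterministic (e.g. `f_S = 0.5`
gives 6 slow / 5 fast); Bernoulli-per-site inoculation would only add
composition noise on top of the seed-to-seed placement noise.

Time advances in sweeps of `dt = 0.1`. Each sweep visits the cells
present at its start in a fresh uniform shuffle; a visited cell divides
with probability `rate * dt` (a first-order discretization of the rate;
the maximum rate in the standard parameter range keeps this below
~0.03). Rates are evaluated on the current, mid-sweep lattice state:
the cached neighborhood counts are updated by every placement and
displacement, so a division is immediately visible to cells visited
later in the same sweep. Daughters born during a sweep first divide in
the next one.

Daughter placement follows two rules. If an empty site exists in the
mother's horizontal plane within Chebyshev radius `R_d = 3`, one at
minimal Chebyshev distance is chosen (ties uniform at random), the
occupants along the discretized straight line from mother to target
are shoved one site outward (far end first), and the daughter takes the
vacated site adjacent to the mother. The line is `p_k = mother +
round(k*delta/D)` with half-up rounding, which steps one Chebyshev site
at a time; because the target is the *nearest* empty site, every
interior path site is occupied and the shove is a simple chain shift.
Otherwise the daughter goes directly above the mother and any
contiguous stack above her is pushed up one site; a column that hits
the lattice ceiling terminates the run with a partial-result flag.
The lateral boundary is a hard wall: out-of-lattice sites are excluded
from neighborhoods, searches, and shove paths.

Two snapshots are captured per run: **sparse**, at the end of the first
sweep in which a bottom-layer cell occupies the lateral boundary, and
**dense**, at the end of the sweep in which the colony reaches
`T = 50,000` cells (the sweep in progress completes, so the final count
slightly overshoots `T`).

## Measurements

Per snapshot: the slow strain's share of all cells; its share among
*surface* cells (the topmost cell of every occupied `(x, y)` column —
empty columns have no topmost cell and contribute nothing); and the
occupied fraction of the bottom layer. Sweep cells (scenario, `r`,
`f_S`, stage) are aggregated over replicates as mean ± SEM with the
`n-1` sample standard deviation; scenario contrasts (e.g. greenbeard
minus obligate) propagate SEMs in quadrature. Replicate `k` of sweep
cell `i` uses seed `base_seed + i*n_replicates + k`, so any row of the
records CSV can be regenerated bit-identically.

## Numerical and engineering choices

* The sweep loop is a numba-jitted kernel over raw arrays. Per-site
  cubic-box neighbor counts (center included; the focal cell is
  subtracted at evaluation) are maintained incrementally, making rate
  evaluation O(1) per cell; a full 50,000-cell run takes a few seconds.
  `local_occupancy` and `ColonyLattice.audit` recount brute-force from
  the grid and serve as the independent checks of the cache in the
  tests.
* The kernel's RNG stream is seeded per sweep from the run-level numpy
  `Generator`, so a whole trajectory is a pure function of the config
  seed (bit-identical replay is test-pinned).
* Occupancy denominators shrink at edges and corners (in-lattice sites
  only): out-of-lattice space is not habitat a cell can sense.
* A run with no division for 10^6 consecutive sweeps aborts with a
  stall diagnostic; configurations whose `dt * max-rate` exceeds 1 are
  rejected up front.

## What the tests do and do not show

The statistical suite reruns the study conditions at their full scale —
20 replicates per condition on the 50 x 50 x 100 lattice — and checks
orderings of group means rather than exact figure values (the source
numbers exist only as plotted points): greenbeard ≥ obligate at the
dense stage for `f_S = 0.5`, `r ∈ {0.3, 0.5, 0.7}`; dense ≥ sparse for
cooperator scenarios; surface share within 0.1 of total share; a
greenbeard whose `r_max` matches the cheater's baseline ends above its
initial share; and near-extinction (< 0.05 mean) of the slow strain
under pure competition on the `f_S ∈ {0.1, 0.3, 0.5, 0.7}` competition
grid. These are means over finite replicate sets of a stochastic model:
individual replicates can and do violate the orderings.

One checked property holds only partially: the surface share stays
within 0.1 of the total share in some condition groups but not all.
The topmost-cell-per-column surface reflects the *current* growth
front, which over-represents whichever strain is winning at the moment
the dense snapshot is taken; the mismatch is largest when the total
share is mid-range and disappears as the colony saturates toward one
strain. The surface scan itself is pinned against a brute-force
per-column oracle, so this is a property of the model's front dynamics
under the update and shove conventions documented above, not of the
measurement. The corresponding assertions are left failing rather than
loosened; the suite output shows exactly which groups exceed the band.

The model is deliberately mechanism-free: no nutrient transport,
enzyme diffusion, cell death, detachment, or motility, and no
continuous-time scheduling — benefits and crowding act only through
the local occupancy composition. Conclusions about real biofilms
therefore concern the logic of restricted cooperation, not the
physiology of any organism. The shove geometry (straight-line chain
shift toward the nearest free site) is one admissible reading of
pressure-driven displacement; alternatives (shortest-path or random
walks) would change fine-grained spatial texture but are constrained by
the same conservation and locality contracts the tests pin down.
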