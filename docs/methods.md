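# Methods

This note documents the models implemented in `stratispread`, the
defaults of the desk-scale case studies, the design decisions taken
where several conventions were defensible, and what the synthetic
experiments do and do not show about real landscapes.

## Population growth

Growth acts cell by cell on an abundance grid, once per time step. The
step length itself carries no units; all rates are "per step".

| family | one-step update | fixed points |
|---|---|---|
| `logistic` | N + rN(1 − N/K) | 0, K |
| `beverton_holt` | eʳN / (1 + (eʳ−1)N/K) | 0, K |
| `ricker` | N·exp(r(1 − N/K)) | 0, K |
| `allee_logistic` | time-1 flow of dN/dt = rN(1 − N/K)(N/A − 1) | 0, A, K |

The Beverton–Holt map is parameterised through the finite rate eʳ so
that `r` means the same thing in every family. Carrying capacity `K`
can be a scalar or a per-cell raster; cells with K ≤ 0 are uninhabitable
and are zeroed. Negative intermediates (logistic overshoot at large r)
are clamped to zero rather than raised.

**Why the Allee family integrates an ODE.** The natural one-step Euler
difference `N + rN(1 − N/K)(N/A − 1)` is violently unstable at K
whenever `r > 2A/(K − A)`; with the case-study values (K = 100, A = 2)
that is any `r > 0.04` — the map overshoots K, the next iterate is
deeply negative, and the population collapses to zero instead of
settling at carrying capacity. Integrating the same vector field over
the step (cached lookup table built with LSODA, ~770 nodes, dense near A
and spanning [0, 4K]) preserves the strong-Allee structure — decline
below A, convergence to K above it — for every `r > 0`, which is the
behaviour the model exists to represent. Abundances above the table's
4K ceiling are clamped to the ceiling before interpolation.

With `stochastic=true` the deterministic update becomes the mean of a
Poisson draw, adding demographic noise.

## Stratified dispersal

**Local dispersal** moves a fixed `proportion` of each cell's
individuals into its neighbourhood: Chebyshev radius `range`, restricted
to the enabled compass directions (a diagonal neighbour requires both of
its axis directions). Allocation is either deterministic (equal split,
exactly mass-conserving away from the boundary) or multinomial (the
real-valued migrant mass is converted to an integer by stochastic
rounding — floor plus a Bernoulli on the fraction — so the expectation
is exact, then allocated by a multinomial draw). Migrants crossing the
grid edge are lost; the boundary is absorbing everywhere in the package,
matching a finite study extent rather than a torus.

**Long-distance dispersal** is an event process: each occupied cell
generates `Poisson(λ)` jump events per step. Each event draws a mixture
component by weight, a distance — `|Cauchy(x0, f)|` (the absolute value
makes the fat-tailed Cauchy a proper distance distribution; for
x0 ≫ f the median is within rounding of x0) or `Exponential(mean)` —
and an angle uniform on [0, 2π), and lands in the cell containing the
source centre plus the displacement. λ is interpreted as
events·cell⁻¹·step⁻¹ (the case-study sources print incongruous units
for it; the numeric values 3 and 5 are used as rates). Propagules are
colonists: they are added at the destination without debiting the
source. An event carries either a fixed `propagule_size` (default 1) or,
with `propagule_fraction` set, that fraction of the source cell's
current abundance — making propagule pressure scale with how large the
source population has grown, which is what couples spread rate to the
intrinsic rate of increase in the factorial experiment.

## Survival

After dispersal, each cell is filtered against a survival layer
`s ∈ [0, 1]` (scalar or raster): binomial thinning of abundances
(deterministic where s is exactly 0 or 1, so real-valued densities are
preserved on binary landscapes; elsewhere the abundance is rounded to
the nearest integer for the draw), or a Bernoulli keep in presence
mode. `scope="all"` filters everything every step; `scope="new_only"`
filters only individuals (or cells) absent at the start of the step —
an establishment filter under which long-settled populations are safe.

## Engine

A step applies growth → local → kernel → survival (order configurable);
the recorded state advances once per step. Replicate *i* uses child *i*
of `numpy.random.SeedSequence(base_seed)`, making runs bit-reproducible
across platforms. The recorded series per replicate and step:
occupied-cell count (abundance ≥ `occupancy_threshold`, default 1),
invaded area (count × cell area), mean density *d* over occupied cells
(an all-cells variant is available), and ROS — cells newly occupied this
step, counting recolonisations unless `ros_first_time_only` is set.

## Neutral landscapes

Fractal surfaces come from diamond-square midpoint displacement on the
smallest (2ⁿ+1)² lattice covering the request, cropped from the
top-left and min-max rescaled to [0, 1]. The per-level displacement
amplitude shrinks by 2^(−H): high H gives smooth, aggregated surfaces.
Over 100 seeds at P = 0.5, mean patch count falls monotonically across
H = 0.3 → 0.5 → 0.7 (checked in the test suite).

Habitat amount is enforced, not expected: exactly `round(P·ncells)`
top-valued cells become habitat, ties at the threshold broken by
row-major index. Multi-class survival maps assign probabilities to
quantile bands of the surface with the same exact-count rule. The
suitability partition of a survival layer is: suitable s > .5, less
suitable .1 ≤ s < .5 (s = .5 included here — both adjacent intervals
are open at .5), marginal s < .1.

These landscapes are neutral: they control composition (P) and
aggregation (H) but carry no topography, land-use history, or
directional structure. Results on them show how the simulator responds
to those two controlled properties, not what any particular real
landscape would do.

## Landscape metrics

Patches are connected components (8-neighbour by default, the common
raster-metric convention; 4-neighbour available). PLAND is the class
percentage of non-nodata cells; NP the patch count; CONNECT the
percentage of same-class patch pairs whose minimum cell-centre
Euclidean distance is within a threshold (map units). n ≤ 1 patches
gives CONNECT = 0 by convention, a numeric stand-in for "not
applicable". The joined-pair count is computed from a KD-tree radius
query over all patch cells — equivalent to the all-pairs minimum
distance (verified against a brute-force oracle on 10⁴ random grids)
but near-linear in cells for small thresholds. The threshold default is
2 cell widths; the case-study source does not report the value it used,
so CONNECT-dependent results are read qualitatively. The
whole-landscape report pools every classed patch (NP sums; CONNECT over
all pairs regardless of class).

## The factorial case study

`FactorialDesign` defaults encode the desk-scale study conditions:

| parameter | value | note |
|---|---|---|
| grid | 65 × 65 cells, cell size 1 | desk-scale stand-in for an unreported full-scale extent |
| steps | 60 (summary runs) | sigmoid-shape checks use 100, the published time horizon |
| H levels | 0.3, 0.5, 0.7 | spatial autocorrelation |
| P levels | 0.35, 0.55, 0.75 | habitat amount |
| λ levels | 3, 5 events·cell⁻¹·step⁻¹ | long-distance event rates |
| r levels | 0.5, 1.5 | per-step intrinsic rates (source values unreported) |
| K | 100 per suitable cell, 0 elsewhere | |
| A | 2 individuals/cell | unreported; set below the 5-individual introduction so a single release can establish |
| introduction | 5 individuals, largest habitat patch nearest the centre | a reproducible version of an "arbitrarily set" site; the largest-patch rule avoids seating the release on an isolated pixel where no spread is possible |
| local proportion | 0.05/step, radius 1, deterministic split | cell size equals the median local-movement distance, so most individuals stay in their natal cell each step |
| kernel | half-Cauchy x0 = 1 cell, f = 0.05; `propagule_fraction` 0.01 | 0.01 ⇒ one individual per event from a cell at K |
| occupancy threshold | A (= 2) | a cell counts as colonised, and emits jump events, once its population is viable; sub-Allee transients are guaranteed to decline under the deterministic model |
| replication | 50 landscapes per (H, P), 1 simulation replicate each | |

Each run yields run-mean density (averaged over occupied cells and
steps) and run-mean ROS, joined with the landscape's PLAND, NP and
CONNECT. `trait_dominance_report` compares the extreme r (and λ) levels
within each landscape and reports the fraction of pairings the higher
level strictly wins.

Under these conditions the harness reproduces the four qualitative
orderings of the case study — ROS rises with PLAND and with CONNECT,
mean density falls with PLAND, and higher r wins essentially all paired
landscapes — but two caveats matter. First, the density–PLAND decline
is small at this grid size (≈0.6 density units between P = 0.35 and
0.75, significant at α = .05 over 1800 runs): frontier dilution at high
P and boundary emigration losses at low P pull in opposite directions
and nearly cancel. Second, trait effects vanish entirely if the grid
saturates, so conclusions are tied to the spread staying inside the
extent for most of the run.

`synthetic_ls_comparison` emulates the paired survival-layer design:
a three-band survival map (20% marginal at s = 0.05, 35% less suitable
at s = 0.3, 45% suitable at s = 0.8) and a stricter variant in which
two-thirds of the suitable cells (lowest surface values) are demoted to
the less-suitable level — a factor-of-three reduction in suitable
PLAND, emulating the effect of adding an extra environmental constraint
to a habitat model. Presence-mode simulations with establishment-stage
(`new_only`) survival filtering give monotone invasion curves; the
stricter layer is invaded less.

## Numerical and interface choices

* Esri ASCII Grid is the interchange format (human-diffable,
  GIS-compatible); the reader validates the header and rejects
  malformed files with a named error. Row 1 of a file is the
  northernmost row, and +y displacement means decreasing row index.
* Model definitions are YAML, validated strictly (unknown keys are
  errors; defaults are echoed to the log). K and s accept scalars or
  raster paths.
* Seeds are integers; every derived stream comes from
  `SeedSequence.spawn`, and the CLI logs seeds and parameters.
* Degenerate inputs: constant fractal surfaces rescale to all-zero;
  thresholding a constant surface still yields the exact habitat count
  (ties broken by index); empty classes give NP = 0 and CONNECT = 0.

## Limitations

* The generator does not emulate real GIS layers (no correlative
  habitat modelling); multi-class maps are quantile bands of one
  fractal surface.
* Kernels are isotropic; no wind fields or transport networks.
* The survival layer is static in time.
* Desk-scale grids compress landscape-structure effect sizes (see the
  density–PLAND caveat above); the harness accepts full-scale settings
  through the same configuration surface when more compute is
  available.
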