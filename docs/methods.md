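# Methods

`aedespop` simulates *Aedes aegypti* populations at the resolution of
individual water-holding containers on a rectangular grid of houses, and
provides the calibration and spatial-evaluation machinery to customize the
simulation to a location and judge its spatial structure.

## Model structure

**Habitat.** The spatial unit is a house cell; each house holds a surveyed
inventory of containers described by type (14 field categories, from
`plastic` to `pet`), indoor/outdoor location, sun exposure, lid, fill method
and volume. A surveyed block (by default 17x9 = 153 houses with 871
containers) can be replicated `n_copies` times into a larger grid; each copy
re-randomizes house placement within its block while keeping every house's
container inventory verbatim, so each house id appears once per block with
different neighbors. Four copies tile 2x2 by default (the most compact
rectangle, minimizing boundary perimeter); the tiling is configurable
because a 1x4 arrangement is equally defensible. Distance is Manhattan
grid steps throughout.

**Food.** The daily food input into a container is

    F = F0 * alpha_i * beta_j * V

with `F0` a baseline (liver-powder-equivalent mg per liter per day),
`alpha_i` a container-type coefficient, `beta_j` an indoor/outdoor
coefficient, and `V` the container volume in liters. Only relative values
of `alpha` and `beta` are identifiable — the product form confounds scale
and shape — so `alpha(large tanks) = 1` and `beta(outside) = 1` are pinned
and `F0` absorbs the overall scale. Each container's food pool follows a
four-term daily balance in fixed order: input, proportional decay,
consumption by larvae, and recycling of a fraction of dead immature biomass.
The pool is clipped at zero by construction (consumption is
`min(food, demand)`), and an audit mode records every term per container-day
so the balance can be verified exactly.

**Immature biology.** The detailed enzyme-kinetic development and
weight-gain equations of the CIMSiM model lineage are deliberately replaced
by a simplified cohort model; the contract that matters for this package —
food-mediated density dependence — is preserved while keeping every
parameter explicit:

* development: linear degree-day accumulation above a threshold
  (`dev_rate_coeff` = 0.009 per degree-day above 13.4 degC, giving ~9 days
  to pupation competence at 27 degC water);
* growth: ingestion is capped at `larval_intake_rate` (1 mg food per mg
  larva per day); scarce food is split across cohorts in proportion to
  demand (weight x count); weight gain is `growth_efficiency` (0.3) times
  intake; pupation requires both full development and a minimum weight
  (1 mg from a 0.02 mg hatchling, ~15 days at ad-libitum intake);
* starvation: a cohort receiving less than `starvation_intake_fraction`
  (0.2) of its demand accrues starving-days, suffers mortality multiplied
  by 3, and dies outright when its reserve (3 days) is exhausted.

Eggs mature for 3 days and hatch only when their container is wet and the
water is at least 22 degC — the threshold that shuts the temperate winter
down. Water temperature is daily mean air temperature +3 degC x sun
exposure outside, -1 degC inside (a monotone-in-exposure stand-in; the
model needs only the ordering). Dry mature eggs persist with reduced daily
survival (0.98 vs 0.99), which is what carries a temperate population
through winter as an egg bank.

**Adults.** Females only (males are not modeled; females are assumed
mated). Emerging pupae become adults of the container's house (female
fraction 0.5); females complete a 4-day gonotrophic cycle, then each lays
one 60-egg batch into one wet container of their house, chosen with
probability proportional to the water-surface proxy `V^(2/3)` (avoids
degenerate all-in-one-container behavior); a gravid female with no wet
container available retries the next day. Daily adult survival is 0.89;
each day a female moves to a Manhattan-adjacent house with probability 0.3.
Displacement after `t` days is therefore bounded by `t` grid steps, which
the tests verify.

**Stochasticity and determinism.** All random events (survival, hatch
allocation to integer counts, dispersal, site choice) are binomial or
multinomial draws from a single seeded generator, executed in a fixed order
each day; a run is a pure function of (grid, weather, parameters, seed).
Immatures are tracked as cohorts in age-indexed arrays; adults as per-house
counts. One vectorized engine steps all containers and houses at once, and
the single-container / single-house operations run the same kernels on
one-element batches, so there is exactly one code path for the biology.

**Initialization.** Every container starts with 10 eggs and 5 larvae; a
1-year burn-in is excluded from all reported output.

## Weather

Synthetic regimes are sinusoid-plus-noise: temperature means with seasonal
amplitudes, a shared daily anomaly (keeping tmin below tmax), Bernoulli
wet-day indicators times exponential depths solved so the expected annual
total matches the regime's rainfall, and bounded humidity noise. The
equatorial preset reproduces a warm aseasonal climate (mean daily maximum
32.2 degC with 5-95% range ~29-35, minimum 21.4 degC, ~2,878 mm annual
rain); the temperate preset uses Southern-hemisphere phase (coldest at
mid-year) with ~1,200 mm of rain. Humidity currently has no effect on the
simplified biology and is carried for interface completeness; a single
daily value per day is assumed.

## Calibration

**Per-type mode.** Iteratively adjust `alpha` (and `beta`, `F0`) until the
simulated share of pupal production per container type matches a target
distribution. Each iteration pools pupal production over seeded replicate
runs and applies damped multiplicative updates
`alpha_i <- alpha_i * (target_i / simulated_i)^eta` with `eta = 0.5`
(full ratio steps oscillate on a stochastic objective), clips every ratio
to [1/4, 4] (so stochastic extinction of a rare type never produces a
division blow-up), and re-normalizes to the reference type/location with
the removed scale absorbed into `F0`. The iteration stops when
`max_i |simulated_i - target_i| <= tol`; five consecutive worsening
iterations halve the step. The stopping rule, replicate count, and update
scheme are this package's own design — declared here rather than
reconstructed from any source.

**F0-only mode.** With `alpha`/`beta` frozen at donor values, a log-scale
bisection finds the `F0` whose simulated mean ovitrap positivity — the
fraction of containers oviposited into within a trailing 7-day window —
matches the mean of an observed weekly positivity series. Mean positivity
is monotone in `F0` over the bracket; a non-bracketing initial interval
[F0/4, 4*F0] is widened geometrically twice before erroring.

**Calibration/evaluation split.** The full-customization pipeline fits
coefficients on a calibration grid built from a survey block disjoint from
the evaluation grid (for synthetic surveys, an independently seeded draw),
so the houses that tune the food coefficients never contribute counts to
the reported spatial statistics.

## Spatial statistics

All three statistics treat per-house pupal counts on the lattice with
Manhattan distance; cumulative neighborhoods `Omega_d(i)` (within `d`,
excluding `i`), integer distance shells, and no geometric edge correction
(the house-pattern statistic `L(d)` plays that role instead — a documented
limitation).

* **Moran's I** with weights `w_ij = 1/d(i,j)`:
  `I = (N/W) * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2`,
  expectation `-1/(N-1)` under random allocation. Significance comes from a
  seeded permutation null (default 999 shuffles of counts over cells) since
  normality of the analytic null is not assumed; the analytic expectation is
  reported alongside.
* **Weighted L.** `K_w(d) = N * sum_i sum_{j in Omega_d(i)} x_i x_j /
  sum_{i != j} x_i x_j`, `L_w = sqrt(K_w / pi)`; `L(d)` uses dummy counts of
  one per house. The normalization is pinned so that (a) dummy weights
  reduce `L_w` to the classic point-pattern `L` and (b) constant counts give
  `L_w = L` exactly — the two structural properties the statistic must
  satisfy. The reported quantity is the per-distance increment difference
  `(L_w(d) - L_w(d-1)) - (L(d) - L(d-1))`, zero under randomness, positive
  where counts cluster at scale `d`, with an optional permutation envelope.
* **Local G_i.** `G_i(d) = (sum_{j in Omega_d(i)} x_j - W_i xbar) /
  (s * sqrt(((N-1) W_i - W_i^2)/(N-1)))` with `W_i = |Omega_d(i)|` and
  `xbar`, `s` the global mean and standard deviation; expectation 0 under
  randomness. Houses with `|Z|` above the two-sided 1% critical value
  (2.5758...) are labeled positive- or negative-cluster members; houses with
  degenerate neighborhoods (`W_i` equal to 0 or N-1) are flagged and labeled
  none. Under permutation of counts the observed label rate is ~1%, within
  the nominal level.

A caveat this package's tests surface explicitly: with cumulative
neighborhoods, the G_i denominator shrinks as `W_i` approaches `N-1`, so on
small grids at distances near the grid diameter a strong localized spot
produces spurious negative flags (the self-exclusion of house `i` dominates
the near-complete neighborhood), and very small lattices bound the
achievable `|Z|` from above (a 2x2 hot block on a 5x5 grid cannot exceed
`|Z|` of about 2.03 at d = 1 regardless of contrast). The constructed-cluster
test therefore plants its 2x2 hot block at the center of a 12x12 lattice
and evaluates membership over d = 1..10, the pipeline's default distance
range, where detection at small d and absence of members beyond d = 5 are
both achievable and robust.

## Synthetic data

The survey generator draws per-house container counts multinomially with
equal cell probabilities — exactly the law of iid Poisson counts
conditioned on the fixed total (871 by default) — then samples type,
volume (per-type lognormal), location, lid, sun and fill attributes from
configurable mixes. The default type frequencies and volume scales are
plausible order-of-magnitude choices (cans and bottles common and small;
large tanks and wells rare and big); they are configuration, not a
reconstruction of any real survey. Target productivity tables are Dirichlet
draws over the 14-type simplex, optionally sorted to decrease along the
canonical category order. Weekly positivity series are clipped seasonal
curves: a single broad summer peak that is exactly zero through the cold
half of the year (temperate) or high and weakly varying (equatorial).

What the generators deliberately do not emulate: real spatial correlation
between neighboring houses' inventories, survey measurement error,
container turnover over time, and the actual Iquitos type frequencies.
Passing tests therefore demonstrate internal consistency of the method —
recovery of known truth, correct null behavior, regime contrasts — not
agreement with any particular field population.

## Problem sizes and numerical choices

Tests exercise the method at the scales the analysis itself uses: grid
construction and spatial statistics at the full 612-house scale;
parameter-recovery calibration on one 9x9 block (~460 containers) with
2 simulated years and 5 replicates per iteration; the exact conservation
audit on one 17x9 block over a full year; and the temperate/equatorial
regime contrast on one 17x9 block over 5 seeds. Food-balance identities are
asserted to 1e-9 (floating-point associativity), demographic ledgers
exactly (integer arithmetic), and oracle equivalence of the vectorized
spatial statistics to 1e-10. Calibration tolerance is 0.02 absolute on
per-type shares, matched to the Monte-Carlo noise of the pooled replicate
shares at these problem sizes.

## Emergent spatial behavior

At default parameters the simulated per-house pupal production shows weak
but detectably *negative* spatial autocorrelation (Moran's I around -0.014
on the 612-house grid, versus the random-allocation expectation of
-0.0016). The mechanism is overcompensating larval competition propagated
by dispersal: a high-capacity house floods its Manhattan neighbors with
ovipositing females, the neighbors' smaller containers overshoot into mass
starvation, and their output drops below what isolation would give.
Disabling dispersal removes most of the effect. This is a real property of
the simplified scramble-competition biology, not a statistical artifact —
the permutation null itself is verified unbiased — and users comparing
against field populations with near-random spatial structure should treat
the sign and magnitude of Moran's I as parameter-sensitive.

## Known limitations

* Biology is deliberately simplified: no enzyme-kinetic development, no
  temperature-dependent adult survival or gonotrophic length, no instalment
  hatching, no male dynamics, no genetics, no disease transmission, no
  control interventions.
* Water dynamics are volumetric fractions with a surface-area proxy; small
  containers do not dry on realistic time scales.
* The G_i statistic's near-complete-neighborhood pathology above; consumers
  should restrict cluster profiles to distances well below the grid
  diameter.
* The pipeline's weekly positivity overlay aggregates the daily proxy by
  calendar week; survey-span averaging of field circuits is exposed only as
  a window-averaging option with no claim of equivalence.
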