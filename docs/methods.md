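# Methods

## The mixing table

All computations are built on one object. Let A = {aⱼ} be the boundaries of
the coarse *model* partition of a continuous stratification feature x (age,
in everything below), B = {bᵢ} those of the fine *output* partition, and
C = A ∪ B the *mixing* partition. Intervals are half-open [c, c′) with the
terminal interval closed, so boundary values belong to the interval they
open. Both partitions must share the same overall support; mismatched
supports raise an error rather than silently clipping population mass.

For a parameter function parameter(x) and a population density ρ(x) > 0,
each mixing interval c gets

    weight_c     = ∫_c parameter(x) ρ(x) dx
    population_c = ∫_c ρ(x) dx

Aggregation sums rows by model group, parameterⱼ = Σweight / Σpopulation,
which is the conditional expectation E[parameter(X) | X ∈ aⱼ] under ρ.
Disaggregation forms the row-stochastic matrix
ω_ji = Σ_{c ∈ bᵢ∩aⱼ} weight_c / Σ_{c ∈ aⱼ} weight_c and maps group
outcomes Y = ωᵀX — Bayes' rule with the parameter as the likelihood of the
outcome given age, so outcomes land proportionally to parameter·ρ rather
than to population alone. Both formulas are ratios, hence invariant to the
normalisation of ρ; we renormalise user densities to unit mass anyway,
which makes Σ population_c = 1 a directly testable conservation invariant.

Degenerate case: a model group on which the parameter is identically zero
has zero total weight and the ω row is undefined. We fall back to
population-proportional apportionment within that group and warn — mass is
conserved without inventing parameter information.

## Interpolation of tabular inputs

Tables of (feature, value) pairs become functions via monotonicity-
preserving cubic interpolation (PCHIP) for parameters — a raw cubic spline
can overshoot below zero between knots of a steep positive curve such as an
IFR — and piecewise-linear interpolation for densities. Outside the
tabulated range both are extrapolated flat (the value at the nearest knot),
which keeps open-ended terminal age groups finite without spline blow-up.
Callers may supply any callable instead.

## Quadrature

Weights and populations use adaptive Gauss–Kronrod quadrature per mixing
interval (absolute and relative tolerance 1e-9, configurable). If the
adaptive rule fails to converge — possible on kinked piecewise-linear
integrands — a deterministic composite Simpson rule on a grid of at most
0.01 feature units takes over. Redistribution rows are renormalised to sum
to exactly 1 after construction, so disaggregation conserves outcome totals
to machine precision rather than to quadrature precision.

Two numerical tie-breaks matter. Interval containment follows the half-open
convention (a value on a boundary belongs to the upper interval; the global
upper bound belongs to the terminal interval). The mean-age disaggregation
computes group means by quadrature, so a mean that is analytically on a
boundary can land on either side by ~1e-16; means within 1e-9 of a boundary
(relative to the support span) are snapped to it before containment.

## The demonstration epidemic model

An age-stratified SEIR model with force of infection

    λᵢ = β Σⱼ cᵢⱼ Iⱼ / Nⱼ

where cᵢⱼ is the daily number of contacts a member of group i has with
group j and Nⱼ the constant group size. Exposed individuals become
infectious at rate τ and recover at rate γ. There is no ageing, demography,
or waning; fatalities remain in R. Deaths are pure post-processing —
deathsⱼ = IFRⱼ × cumulative infectionsⱼ — so trajectories are bit-identical
across IFR choices and deaths are exactly linear in a global IFR scale.

Two pathogen parameterisations: flu-like (β = 0.15 /contact/day, latent
period 1 day, infectious period 2 days, IFR proportional to all-cause
mortality m(x) and therefore U-shaped in age) and COVID-like (β = 0.1,
latent 3 days, infectious 5 days, IFR = 10^(−3.27 + 0.0524x)/100, strictly
increasing). The raw COVID formula crosses 1 just above age 100; the
packaged pathogen clips its IFR at 1 so the probability interpretation
holds, with negligible effect on any integral over [0, 101]. The flu scale
is calibrated so both pathogens produce the same death toll in a reference
setting (no vaccination, rectangular demography, high-resolution model);
since deaths are linear in the scale, the calibration is an exact ratio,
not an iterative search.

The epidemic is seeded with 0.001% of every age group placed in E.
Vaccination is all-or-nought: coverage = doses / target-group population
(capped at 1), and coverage × efficacy (default 50%) of the target group
moves from S to R before simulation. Both fractions are computed from the
full group size, so the order of seeding and vaccination does not affect
the initial state. On a refined partition the same per-group fractions
apply within the target range, which is exactly population-proportional
allocation within the coarse bounds.

Integration uses adaptive RK45 (rtol 1e-8, atol 1e-10) on a 1-day output
grid over a default horizon of 365 days — long enough for the epidemics
considered here to complete (final infectious prevalence far below the
seed). Cumulative infections are tracked as an auxiliary integrated state
(d/dt = λS) rather than by differencing S, avoiding cancellation error.

### High-resolution benchmark

The benchmark re-runs the same epidemic on the output partition (101
single-year groups). Its contact matrix expands the coarse one
block-proportionally: c_fine[i,j] = C[I,J] · N_j / N_J for fine j inside
coarse J, which preserves each individual's total contact rate and makes
block-aggregated fine dynamics match the coarse model exactly when
prevalence is uniform within blocks. Its IFR uses the lower-bound
convention — group [x, x+1) gets IFR(x) — the natural reading of a
single-year table; integral and midpoint variants are available
(`ifr_at_lower_bound` is one choice among defensible alternatives within
the practical margin of uncertainty, and the package exposes the IFR
assignment as a function argument).

## Burden accounting

YLLs attach remaining life expectancy at the age of death:
YLL = Σᵢ deathsᵢ · e(xᵢ), undiscounted and without age-weighting, with the
output group's lower bound as its representative age (matching the
benchmark IFR convention) and e(·) linearly interpolated between tabulated
ages. Deaths averted are baseline minus scenario totals per approach.

`compare_approaches` produces a tidy report with three kinds of rows. The
*aggregation* stage varies only the IFR discretisation (midpoint, mean-age,
blend) and compares death tolls against the high-resolution run. The
*disaggregation* stage fixes the model-group deaths to the blend-based
estimates for every approach (uniform, mean-age, density-proportional,
distill) — the comparison is then purely about where within the groups the
deaths are placed — and its benchmark is, consistently, the high-resolution
run's within-group age-at-death distribution rescaled to those same group
totals. Without that rescaling a YLL comparison would mix aggregation error
(how many deaths per group, which hinges on the benchmark's IFR-assignment
convention above) into a judgement about disaggregation; with it, the two
stages are judged independently. The raw high-resolution deaths and YLLs
are still reported in the *benchmark* stage rows.

A note on the mean-age aggregation: the usual shorthand "IFR at the mean
age" means IFR evaluated at E[age | group] = ∫ x ρ dx / ∫ ρ dx; that is
what `aggregate_mean_age` computes.

## Synthetic fixtures

The generators produce stylised stand-ins for published data so the
pipeline builds and tests offline; they are pure functions of their
arguments and seed.

* **Demography** (1-year resolution on [0, 101], default total 10⁶):
  *rectangular* is flat cohorts with a 2% seeded ripple and a logistic
  old-age taper centred at 85 (scale 5 years), resembling high-income
  pyramids; *young* is strictly decreasing exponential decay with scale
  30 ± 3 years (seeded), resembling low/middle-income pyramids. Counts are
  rescaled so the trapezoidal integral equals the requested total.
* **Life tables**: e(x) declines concavely from e(0) = 81 (rectangular)
  or 64 (young) years to ~2 years at the terminal age; m(x) is U-shaped —
  infant mortality decaying with scale 1.5 years, old-age mortality rising
  with scale 9 years, plus a baseline — and doubles as the flu-like IFR
  shape.
* **Contact matrix**: a convex blend of proportional mixing (contacts
  distributed by partners' population shares; rank-one) and fully
  assortative within-group contact (diagonal), with 8 daily contacts per
  person and default assortativity 0.3. The construction is deterministic.

What the fixtures do *not* emulate: cohort structure (baby booms),
migration, setting-specific contact patterns (school/work/home), reporting
noise, or any real country's demography. Passing tests therefore
demonstrate the correctness and ordering properties of the method on
smooth, well-behaved inputs — not calibrated burden estimates for any real
population. Real demography, life-table and contact-matrix files in the
same CSV schemas can be loaded through `load_table` and used throughout.

## Problem sizes

The shipped comparison uses the 4-group model partition {0, 5, 20, 65,
101}, 101 single-year output groups, a population of 10⁶ per demography,
doses sized to 75% coverage of the 65+ group, and a 365-day horizon — small
enough that the full four-setting comparison (16 coarse plus 16 fine
epidemic runs, plus calibration) completes in well under a minute, while
the 101-group runs remain a genuine high-resolution benchmark.

## Known limitations

* The stratification feature is scalar; joint features (age × risk) are out
  of scope.
* No uncertainty propagation on blended parameters or redistributed
  outcomes.
* No waning immunity, leaky vaccines, births/deaths/ageing, or stochastic
  simulation in the demonstration model; strong within-group depletion
  (e.g. deaths concentrated at the oldest ages shifting a group's
  composition over a long epidemic) is exactly the regime where any fixed
  discretisation — this one included — drifts from a high-resolution model.
* YLLs are undiscounted; no DALY morbidity component or economic costing.
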