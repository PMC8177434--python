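# Methods

## The Language Use Game

A locality has a bilingual fraction α ∈ (0, α\*) of speakers of the
minority language *B*; everyone speaks the majority language *A*.
Interactions are anonymous: linguistic type is private information, so a
bilingual only learns a partner's type through language choice itself.
Bilinguals play one of two stationary strategies — Reveal (R) or Hide
(H) — against partners who are bilingual with probability α.

Payoffs are net communication benefits: *m*(α) for a conversation in
*B*, the constant *n* > 0 for one in *A*, and *n* − *c*(α) for an
R-player forced back to *A* by a monolingual. The admissibility
assumptions, checked by `validate_assumptions`, are:

1. *m*(α) > *n* > *c*(α) > 0 on (0, α\*);
2. *m* and *c* strictly decreasing, with *m* → *n* and *c* → 0 as
   α → α\* (at the aspiration level, where *B* is felt to be safe,
   neither extra benefit nor frustration remains);
3. the weighted-benefit condition *c*(α) < *b*(α) ≔ (*m*(α) − *n*)·α/(1 − α),
   which is what keeps the interior equilibrium inside (0, 1).

α\* is the country-wide aspiration level — the bilingual share at which
the community would consider *B* non-endangered. Locality-level
aspirations are collapsed to this single constant; the model treats it
as the upper end of the α domain (default 0.9). A country-level
aggregate α ≥ 0.5 triggers a warning, not an error: the theory targets
societies where bilinguals are a national minority, but individual
localities routinely have bilingual majorities.

Expected payoffs when a fraction p of bilinguals reveal:

    u_R = α m + (1 − α)(n − c)
    u_H = α [p m + (1 − p) n] + (1 − α) n
    u_R − u_H = α (1 − p)(m − n) − (1 − α) c

The indifference point is the unique interior Nash equilibrium and ESS,

    p* = 1 − (1 − α) c / [α (m − n)],

with shift probability (1 − p\*)² and complementary probability
p\*² + 2p\*(1 − p\*) that *B* is used when two bilinguals meet.

### Built-in payoff family

`PayoffSpec.from_family` provides m(α) = n + μ(α\* − α)^a and
c(α) = κ(α\* − α)^d with μ, κ, a, d > 0 — the simplest family with all
required properties. The theory core accepts arbitrary mappings, so any
other admissible specification can be plugged in. Monotonicity and the
limit behaviour are verified numerically on a grid (default 50 points in
(0.01 α\*, 0.99 α\*), tolerance 1e−9) because the mappings are opaque
callables.

## Dynamics

The replicator equation for the Reveal share,

    dp/dt = p (1 − p) [α (m − n)(1 − p) − c (1 − α)],

is integrated with an adaptive explicit Runge–Kutta scheme (rtol 1e−8,
atol 1e−10 — the ODE is scalar and smooth) and a terminal steady-state
event |dp/dt| < 1e−12. Boundary starts p₀ ∈ {0, 1} are rejected: the
flow is identically zero there and the convergence statement concerns
interior starts only. Rest points are classified by flow signs in
punctured neighbourhoods of radius 1e−4: 0 and 1 repel, p\* attracts.

### Imitation simulator

`simulate_abm` runs pairwise proportional imitation in a population of N
bilingual agents: each round a focal agent and a role model are drawn
uniformly; each plays the LUG once against a random partner (bilingual
with probability α, revealing with the current population frequency);
the focal agent copies the role model with probability equal to the
positive part of the payoff difference divided by the payoff range
m − (n − c). This rule was chosen because its mean-field limit is
exactly the replicator equation; the update rule is isolated in one
function so alternatives (e.g. Fermi updating) can be added. Partner
types are drawn per interaction rather than simulating an explicit
monolingual pool — equivalent in distribution, and monolinguals have no
strategy. The all-Hide state is absorbing at finite N even though it is
dynamically unstable: imitation cannot re-invent an extinct strategy.

## Empirical curves

The fittable equilibrium function is

    p*(α) = β₁ (1 − α)(α^β₃ − α)^(β₂ − 1),   β₁ > 0, β₃ ∈ (0, 1).

The inner term is implemented as α^β₃ − α, which is positive and bounded
on α ∈ (0, 1) for β₃ ∈ (0, 1) and consistent with β₃ drifting toward
zero as aspirations rise; the reading is isolated in one helper so it
can be swapped in a single place. Street use multiplies by α² (both
partners bilingual, one a revealing "militant"; the structural form is
c₁(2α²p\* − c₂α²p\*²), with c₂ discounting the double-count correction
because militants seek each other out; the default c₂ = 0 reflects that
militant–militant matches roughly double). Daily use multiplies by α
(revealers report daily use of *B*). The scales c₀, c₁ cannot be
separated from β₁ and are absorbed into the identified coefficients
β̃₁ = 2c₁β₁ and β̌₁ = c₀β₁ — never estimated separately.

Predicted values outside [0, 1] are *not* clamped during fitting
(clamping would bias least squares); they raise a warning, and only
user-facing generation clips, loudly.

At the package's reference parameter values (β̃₁ = 0.9, β₂ = 1.4,
β₃ = 0.3) the street curve is increasing and convex for small α,
inflects near α ≈ 0.29 and flattens toward the aspiration level; the
"increasing and convex" description of the use–α relation is therefore
a statement about the low-α regime where most localities sit.

## Estimation

Per survey year, the curve is fitted to locality pairs (αᵢ, useᵢ) by
unweighted nonlinear least squares — every locality counts equally,
regardless of population — under box constraints β₁ > 0, β₃ ∈ (0, 1),
|β₂| ≤ 10 (a guard against optimizer escape along flat ridges, with a
warning when active; β₂ is otherwise unrestricted). The model is linear
in β₁, so starting values profile β₁ analytically on a 3×3 grid of
(β₂, β₃) starts with ×{0.5, 1, 2} scale perturbations — 27 starts in
all; trust-region reflective least squares with an analytic Jacobian
does the local work. The best converged solution is reported;
non-convergence is propagated, never dropped.

**Identifiability.** The curve family is nearly degenerate along a
(β₁, β₃) ridge: large correlated changes in β₁ and β₃ move the curve by
less than typical survey noise. Parameters are therefore far better
determined in curve space than in parameter space; recovery experiments
show the median parameter error shrinking steadily with the per-locality
observation count, but parameter-level precision requires extremely
large counts even though the fitted curve itself stabilises quickly.
Uncertainty statements should be read off the confidence band, not the
raw parameter estimates.

**Bootstrap bands.** Pairs (case) bootstrap over localities: the
locality is the sampling unit and the binomial noise is heteroscedastic
by construction, which rules out a residual bootstrap. Each replicate
refits from the point estimate; replicates that fail to converge are
dropped, and a failure rate above 20% aborts with an error. Bands are
pointwise percentile intervals (noted in the fit diagnostics — they are
not simultaneous bands), default n_boot = 999 with 199 used in the
scaled-down studies. A coverage simulation (100 synthetic surveys of
100 localities × 200 observations, nominal 90%, n_boot = 199) yields
mean pointwise coverage ≈ 0.85.

**Specification check.** Local-linear kernel regression of use on α
(statsmodels, Gaussian kernel) with least-squares cross-validated
bandwidth, falling back to the normal-reference rule of thumb with a
warning if selection fails. The summary statistic is the share of band
grid points where the nonparametric fit lies inside the band: near 1
when the parametric family is the truth, and sharply lower (≈ 0.3 in the
misspecification study) when the generator is, e.g., linear in α.

## Synthetic data

The generator emulates one survey year: αᵢ i.i.d. from a Beta(2, 4)
stretched to (0.02, 0.88) — right-skewed, most localities with few
bilinguals, upper end just below the α\* = 0.9 default — true use
μᵢ from the predictive curve, and observed use Binomial(kᵢ, μᵢ)/kᵢ.
The binomial form reflects how the quantities are measured: street use
from counted conversations, daily use from counted respondents. True
μᵢ travels in a separate `true_use` column consumed only by recovery
tests; the estimation surface never sees it. A configuration whose true
curve leaves [0, 1] on more than 5% of localities is rejected (silent
truncation would bias recovery experiments); occasional clipping warns.
Multi-year panels shift the α-distribution support to mimic growth in
bilingual shares; localities are independent across years.

Reference study sizes, chosen once as typical municipal survey volumes:
100 localities × 200 recorded conversations for band-coverage and
specification studies; 200 localities with k ∈ {100, 500, 2000} for the
consistency-in-k experiments. What the generator does *not* emulate:
spatial or network structure, migration between localities, demographic
change, non-random matching in the observation process, or measurement
idiosyncrasies such as survey redesigns. Passing tests therefore show
that the pipeline recovers the model's own structure under its assumed
noise — not that real survey data satisfy those assumptions.

## Numerical conventions

* Proportions are unit-interval fractions everywhere inside the
  package; percentages exist only at I/O boundaries via the
  `percent_columns` flag.
* All randomness flows through numpy `default_rng` seeds; pipeline runs
  derive per-year streams from the top-level seed and record them in the
  run manifest.
* The equilibrium/ODE agreement tolerance is 1e−6; payoff-identity and
  closure identities hold to 1e−12 or better.
* Degenerate inputs fail loudly: fewer than 8 localities, identical α
  across rows, boundary ODE starts, empty aggregation input, c ≥ b.

## Limitations

* The empirical curve's parameters are weakly identified (see above);
  comparisons across years or languages should be made on fitted curves
  and bands.
* The aspiration level enters the theory core as a hard domain bound;
  data with α at or above α\* cannot be scored by the payoff-level
  model (the empirical curves remain defined on all of (0, 1)).
* The imitation simulator is a consistency check for the mean-field
  dynamics, not a calibrated model of any documented social process.
* Bands are pointwise; simultaneous coverage over the whole α grid is
  lower by construction.
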