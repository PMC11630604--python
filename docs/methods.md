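# Methods

## The estimation problem

Census-style migration data record *transitions*: counts `M^j_i` of people
who were in an origin region at one census and in destination `j` at the
next, `n` years later, out of an exposed population `N_i`, tabulated by age
group `[a_i, a_i + b_i)` (age at the start of the interval; the last group
may be open).  The quantity of interest is the complete migration "cube":
for every origin, destination and single year of age `x = 0..ω` (ω = 110),
the probability `ₙm^j_x` that a person aged `x` at the origin is in
destination `j` after `n` years, conditional on surviving and remaining in
the country.

Two features make this hard: the age dimension is blurred twice (each
grouped probability averages the schedule over `[a_i, a_i + b_i + n)`),
and sample noise can be severe because counts cannot be pooled across
years and are quadratic in the number of regions.

## Generation–distribution factorisation

The cube is factorised as `ₙm^j = ₙm × ₙc^j`: out-migration (generation)
times destination ratios (distribution, summing to one over destinations
at every age).  The two factors are estimated separately and the product
satisfies the cube constraints exactly by construction.

### Out-migration: penalized relational (TOPALS-style) Poisson model

The one-year schedule is expressed relative to a positive standard
schedule `m̂`,

    m = m̂ · exp(B θ),

with `B` a quadratic B-spline basis (open-uniform knots every 2.5 years
from age 0 to 180, evaluated on ages 0..ω; the wide knot range keeps the
basis well conditioned near ω) and `θ` the spline weights.  Interval-n
probabilities follow the survival product `ₙm_x = 1 − Π_{x≤k<x+n}(1−m_k)`
(truncated at ω: ages past ω contribute no factor), and grouped model
probabilities are the exposure-weighted averages `M_i(θ) = Σ_x w_{i,x} ₙm_x`
with `w_{i,x} = N_x / N_i` on the group's age range.  θ maximises

    L(θ) = Σ_i N_i ( m̃_i log M_i(θ) − M_i(θ) ) − (λ/2) θ'D_k'D_k θ,

a Poisson log-likelihood of the grouped counts plus a k-th order
difference penalty (k = 1 by default).  As λ → 0 the fit approaches an
interpolation of the grouped sample probabilities (when knots are finer
than groups); as λ → ∞ the spline component tends to a polynomial of
order k − 1 (a constant for k = 1).

**Solver.**  Fisher scoring (iterated penalized weighted least squares)
with the exact chain-rule Jacobian through the survival product and the
grouping, step halving whenever the penalized likelihood would decrease,
convergence at |ΔL| < 1e-8, at most 200 iterations.  The iteration starts
from a constant θ matching the pooled crude implied one-year probability
(θ = 0 with a flat standard would start at m ≡ 1, a clip boundary where
scoring stalls).  Probabilities are clipped to [1e-12, 1 − 1e-12] inside
likelihoods and 0·log 0 = 0.  On small instances the solution agrees with
a generic quasi-Newton maximisation of the same objective to |ΔL| < 1e-8
(tested).

**Penalty choice.**  λ is selected on a 41-point log-spaced grid from
1e-2 to 1e8, scanned in ascending order with warm starts, by minimising
an information criterion: `−2·loglik + penalty·edf` with penalty 2 (AIC),
the small-sample corrected version (AICc), or `log g` (BIC), where the
effective dimension `edf` is the trace of the influence matrix of the
final working regression and `g` (the number of grouped observations) is
the sample size for BIC/AICc.  Ties are broken toward the larger λ.
Heavier sampling noise leads to a lower selected effective dimension
(tested); note that on the absolute λ scale the relationship is not
monotone, because λ competes with Fisher information, which scales with
the exposures.

**Hierarchy of standards.**  Total (all origins pooled) migration is
fitted first with a flat standard (m̂ = 1) and BIC; each origin's
out-migration is then fitted with the fitted total schedule as its
standard.  A table with no movers at all cannot pin down the level and is
returned as the standard scaled to a floor probability, flagged
degenerate.

### Destination ratios: continuation-ratio binomial P-splines

Ratios are re-parameterised as conditional (continuation) ratios
`a^j` — the probability of choosing destination `j` given that
destinations 1..j−1 were not chosen — which are unconstrained in [0, 1]
and map back to ratios through survival products.  Each `a^j` (the last
destination is the remainder) is modelled as `logit a^j = B φ^j` and
fitted by maximising a penalized binomial likelihood weighted by the
at-risk counts `K^j_i = Σ_{k≥j} M^k_i`, with the same basis, first-order
penalty, solver, and AICc-selected λ (grid as above).  Grouped and
single-year conditional ratios are linked by a weight matrix `T^j` whose
rows are proportional to the expected migrants at risk at each exact age,
`N_x · ₙm_x · Π_{k<j}(1 − a^k_x)`, computed from the stage-1 out-migration
fit and the previously fitted conditionals; this mirrors the exposure
weighting of the out-migration stage applied to the at-risk population.
A group with zero expected risk falls back to uniform weights, and an
all-zero at-risk branch to the uniform conditional `1/(d−j)`, both
flagged.  Destinations are fitted in input order by default (an option
orders them by descending total movers, giving the early, most
order-sensitive branches the most data); the decomposition is
order-dependent, but on well-identified data cubes fitted under different
orders agree closely in shape (tested).

## The hybrid comparator

The classical alternative places each closed group's sample probability at
the group midpoint `a_i + b_i/2`, interpolates a natural cubic spline
through the midpoints (the open interval is unused), and fits the result
with a student-peak model migration schedule: childhood exponential,
labour-force and student double-exponentials, Gaussian retirement peak,
elderly exponential, and a constant.  Destination schedules come from a
three-step cascade: (1) total migration is fitted with greedy component
selection (childhood + labour + constant always tried; student,
retirement and elderly added one at a time when a residual-based AIC
improves, skipped entirely when the base fit is already exact to within
0.1 ppm of the data norm); (2) origin out-migration is fitted with all
parameters of the surviving components free, warm-started from step 1;
(3) each destination re-fits the level parameters only.  Components
absent from an earlier step never re-enter.  Fits minimise unweighted
least squares on the probability scale with a bounded trust-region
solver, from the warm start plus four multiplicative ±20% jitters
(seeded); starts pinned at a zero bound are nudged to a data-scaled
interior point because the trust region scales with |x|.  The objective
scale, optimizer and start policy are this package's choices; the
original method statement does not fix them.

## Quality indices and grouping policy

Whipple's index W uses the standard form: 100 times the population at
ages 25, 30, …, 60 over one-fifth of the population aged 23–62 (the
"23 to 63" assessment window read as ages 23..62 inclusive; uniform
counts give 100, complete heaping 500).  The sawtooth index ST quantifies
residual decade preference in five-year grouped counts as the mean of
`2P_i/(P_{i−1}+P_{i+1})` over interior groups starting at multiples of 10
within the assessed range (40+ by default); smooth or linear count
sequences give exactly 1.  This reconstruction is validated only by those
fixed points and is isolated behind one function.  The overstatement
index OS is 100 times the open-group share of the 70+ population divided
by the same share in a reference population.  The grouping policy is a
pure threshold function: W ≥ 110 → five-year groups; additionally
ST ≥ 1.11 → ten-year groups above a configurable age (default 40);
OS ≥ 100 → drop the open interval.

## Goodness-of-fit and plausibility metrics

`dev` is the scaled multinomial deviance `(2/gd) Σ_i N_i [(1−m̃_i)
log((1−m̃_i)/(1−m_i)) + Σ_j m̃^j_i log(m̃^j_i/m^j_i)]` over destinations
plus the stay category; `dev_m` the binomial analogue `(2/g)` for total
out-migration.  Grouped fitted destination probabilities are computed as
the exposure-weighted average of the interval-n destination schedules
(`w · ₙm^j`), for both methods, so the comparison is like-for-like.
Shape deviation is `Σ_j 100(1 − cos(m_ref, m^j))`, scale-invariant per
destination.  Reference schedules average unit-sum one-year schedules and
compose the mean to interval n.

## Synthetic study conditions

The generator defines the default study conditions: 2 origins, 5
destinations, five-year age groups with an open interval at 85+, a
five-year migration interval, ω = 110, and a constant exposed population
of 1e6 per single year of age (1e4 for the noisy method-comparison
setting).  One-year out-migration truths are labour-peak-only model
schedules — the canonical labour double-exponential (level ≈ 0.05, rate
0.10, location 20–21.5 years, ascent rate 0.35) plus a constant floor
0.003, giving unimodal schedules peaking in the early twenties, with
origins differing slightly in level and peak location so the hierarchical
standards are exercised.  Destination ratios are smooth log-linear age
trends plus a mild Gaussian bump per destination, normalised across
destinations, drawn reproducibly from the scenario seed.  The interval-n
truth follows a no-return model (one move per interval, destination
chosen at the year of the move), under which the n-year out-migration is
exactly the survival-product composition of the one-year truth.  Counts
are drawn multinomially per single year of age over (destinations, stay)
and aggregated to the grouping; digit-preference heaping moves a chosen
fraction of each age's population count to the nearest multiple of five.

What the generator does not emulate: return and onward moves within the
interval, mortality and emigration inside the exposed population,
age-varying exposure profiles, correlated reporting errors, and survey
design effects.  Passing tests therefore demonstrate correctness of the
estimators under their own sampling assumptions, not robustness to those
real-data features.

### A known identification limit

With five-year groups and a five-year interval each observation averages
the schedule over a ~10-year span.  At large exposures the fit reproduces
the grouped sample probabilities essentially exactly, and the remaining
one-year error is the within-window profile, which the data do not
identify; it is resolved by the smoothness penalty and the standard.  At
the steep onset of the labour peak this residual profile error reaches
roughly ±10% on the interval-5 scale and tens of percent on the one-year
scale, and is independent of the penalty size and order.  Pointwise
one-year recovery at the onset is therefore limited by information, not
by the solver; shape recovery (cosine deviation from the truth below 0.1
on a 0–100 scale) and grouped-scale fit are unaffected.  The acceptance
suite keeps a pointwise 5% recovery check that documents this limit by
failing at the onset ages.

## Problem sizes and numerical defaults

Tests and the acceptance script run the full protocol on the scenarios
above (penalty grids of 11–41 points, 20 replicates for the method
comparison and 50 for selection behaviour, 500 for Monte-Carlo means on a
reduced scenario) — sizes chosen so the whole suite completes in about a
minute on one CPU while leaving the estimators' behaviour in the regimes
of interest visible.  Numerical defaults: probability clipping 1e-12,
IRLS tolerance 1e-8 (1e-12 in oracle tests), 200 iteration cap, 1e-10
ridge on the scoring system, penalty grid 1e-2..1e8 (41 points), AICc
returns +∞ when its denominator g − edf − 1 is nonpositive, information
criterion ties resolve to the larger λ.  Exposure expansion uses a
monotone PCHIP interpolant of cumulative grouped counts differenced at
integer ages and rescaled for exact conservation, with a geometric open
tail continuous with the last closed group's mean density; non-contiguous
groupings fall back to uniform within-group allocation.

## Known limitations

Event-style (register) data are out of scope; exposures are taken as
given counts; no uncertainty intervals are produced for the fitted
schedules; the continuation-ratio decomposition is order-dependent by
construction; and the hybrid comparator's component selection is a greedy
heuristic.
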