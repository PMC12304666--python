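# Methods

## The model

A predator foraging in a closed arena without prey replacement depletes its
own resource: the instantaneous encounter rate falls as prey are eaten.
Rogers' random predator equation integrates this depletion over an exposure
window of `T` hours. With attack rate `a` (h⁻¹, the per-hour search/
encounter coefficient) and handling time `Th` (hours spent subduing and
consuming one prey), the expected number attacked out of `N0` offered
satisfies

    Na = N0 · {1 − exp[a·(Th·Na − T)]}.

Substituting `w = a·Th·(N0 − Na)` shows `w·e^w = a·Th·N0·e^{a·(Th·N0 − T)}`,
so the unique root in `[0, N0]` is

    Na = N0 − W(a·Th·N0·e^{−a·(T − Th·N0)}) / (a·Th)

with `W` the principal Lambert-W branch. We evaluate `W(e^y)` directly for
`y < 500` and otherwise by Newton iteration on `w + log w = y` from the
asymptotic seed `y − log y`, so the forward model is finite for arbitrarily
large `a·Th·N0` (the naive exponential overflows near `y ≈ 710`). A scalar
bisection solver for the implicit equation is kept in the package purely as
an independent cross-check; the two agree to better than 1e−8 over the
whole working grid (verified in the test suite and the acceptance script).

Limits worth knowing: `a = 0` gives `Na = 0`; `Th = 0` collapses to the
depletion-only form `N0·(1 − e^{−aT})`; `T/Th` is the saturation plateau —
the most prey one predator can process per window. The proportion consumed
`Na/N0` is non-increasing in `N0` (the type II signature).

One terminological caveat: `a` in h⁻¹ is the conventional instantaneous
search/attack rate, which is how it is implemented and interpreted here;
descriptions of it as a "time to kill" appear in parts of the applied
literature but are dimensionally inconsistent with the model.

## Estimation

Parameters are estimated by ordinary least squares on consumption counts
(the classical PROC NLIN-style analysis), minimising
`Σ (na_i − Na(a, Th; n0_i, T))²` with `scipy.optimize.least_squares` under
bounds `a ∈ (1e−6, 10]`, `Th ∈ [0, T]`. Initialisation: `a₀` from inverting
the zero-handling-time limit at the lowest density, `−log(1 − p̄)/T`; `Th₀`
from the plateau `T/max(na)`; plus four seeded log-normal jitters
(multi-start) to guard against local minima. OLS on counts is the default
because it reproduces the semantics of the published analyses; the
heteroscedasticity of binomial counts is absorbed into the residual
variance estimate.

95% confidence limits are asymptotic Wald intervals,
`θ̂ ± t_{0.975, n−2}·SE(θ̂)`, with the covariance `s²·(JᵀJ)⁻¹` taken from
the Jacobian at the optimum and `s² = SSE/(n−2)`. Under the second-instar
study design (densities {2,4,8,16}, 15 replicates, binomial noise) the
measured coverage of the `Th` interval is ≈ 0.92 — acceptable for the small
nonlinear sample, and the reason a seeded nonparametric bootstrap
(resampling replicates within density, percentile intervals) is offered as
an alternative.

A fit whose optimum sits on a parameter bound is returned with
`converged=False` and a diagnostic rather than silently: the canonical case
is every trial consuming all prey, which drives `Th` to its zero boundary
and makes the plateau non-identifiable.

`T/Th` inherits its CL from `Th` by the decreasing transform `x ↦ T/x`
(endpoints swap). `Th = 0` or a CL touching zero is flagged as infinite
capacity, never returned as a number.

Treatments are compared by the CL-overlap rule: a difference is declared
significant exactly when the two 95% intervals are disjoint. Group letters
are the connected components of the overlap graph, lettered in order of the
smallest member estimate. This rule is conservative relative to a t-test on
the difference; it is used because it is the comparison the parameter
tables are built around.

## Response-type classification

The proportion consumed is modelled as a grouped-binomial logistic
polynomial in density (each replicate contributing `na` successes of `n0`
trials), fit by IRLS maximum likelihood (`statsmodels` GLM). Model
selection is backward elimination from the cubic: the highest-order term is
dropped while its Wald χ² p-value exceeds α = 0.05, preserving hierarchy,
so the retained terms are always a prefix of (intercept, linear, quadratic,
cubic). Replicates enter individually, not aggregated per density, which
preserves dispersion information; overdispersion (Pearson χ²/df) is
reported but not corrected by default. The type call uses only the linear
coefficient: significantly negative ⇒ II, significantly positive ⇒ III,
otherwise inconclusive — on short density ladders the quadratic is rarely
identifiable, and the linear sign is the robust summary of the initial
slope of the proportion curve.

Degenerate inputs (all-zero consumption, separation, non-convergence)
return an `inconclusive` fit flagged unconverged rather than an exception,
since a classification caller typically iterates over many groups.

## The synthetic-data generator

The generator encodes the study conditions: three predator instars with
density ladders {2,4,8}, {2,4,8,16} and {2,…,128}, 15 replicates each, 24-h
exposure, and the published (attack rate, handling time) pairs per instar ×
treatment as presets — (0.10, 17.84), (0.14, 8.23), (0.14, 8.26),
(0.07, 5.05), (0.01, 0.60), (0.0087, 0.57). Consumption counts are
`Binomial(n0, μ/n0)` with `μ` the random-predator expectation: the minimal
noise model when only counts out of an offered total are observed.
Beta-binomial noise (intra-arena correlation ρ) is available to stress-test
interval coverage. A type III mechanism — hyperbolic density-dependent
attack rate `a(N0) = b·N0/(1 + c·N0)` with `b = 0.004`, `c = 0.02`,
`Th = 1 h`, chosen to give an unambiguous rising limb of the proportion
curve (≈ 0.17 at `N0 = 2` to ≈ 0.53 at `N0 = 16`) — exists solely to
exercise the classifier and is never fitted.

The damage generator is a daily discrete-time chain (observations are
daily) over 7 days for arenas of 10 prey: each day, toxin mortality thins
survivors binomially; once the predator is released it removes up to its
daily capacity; the remaining survivors feed. Calibrations, all chosen once
from the reported endpoints: per-larva feeding 100/70 %/day so the
untreated arm reaches ≈ 100% defoliation at day 7; Cry3Aa daily mortality
`1 − 0.5^{1/7}` (LC50 semantics: half the cohort dead by day 7);
intoxicated feeding 0.52 %/larva-day so the toxin-only arm ends near 25%
defoliation. Predation precedes feeding within a day — the ordering
consistent with the near-zero defoliation observed when a predator is
present from day 0. The four presets are the treatment arms: water control,
toxin alone, predator alone (release day 0), toxin + predator (release
day 3). Release day and capacity are ordinary parameters, so the 3-h
pre-feeding variants are one argument away.

What the generator does *not* emulate: predator satiation dynamics beyond a
fixed daily capacity, arena spatial structure, between-replicate
heterogeneity in feeding rate, prey stage structure, and partial-consumption
biology (a partially consumed prey counts as consumed, as in the trials).
Passing tests therefore demonstrate correctness of the estimators under
the assumed binomial/thinning mechanisms, not robustness to every field
complication.

## Trend analysis

Survivor and defoliation series are regressed on day by OLS with replicates
pooled as independent observations (SEs then reflect between-arena
variance). The model is a simple line per segment — the minimal choice
consistent with a generic regression analysis — with an optional two-segment
fit split at the predator-release day, where the survivor curve is visibly
discontinuous. A constant response returns the degenerate fit (slope 0,
zero SE, r² reported as 0) with a flag instead of an error. Day-7 endpoint
summaries are cross-replicate means with standard errors and are invariant
to replicate ordering.

## Numerical and design choices

- Lambert-W switch-over at `y = 500` (direct evaluation below, log-space
  Newton above); bisection tolerance 1e−12 in the oracle.
- NLS convergence tolerances 1e−12 (xtol/ftol/gtol); five starts; all
  seeded, so fits are deterministic for a given dataset and seed.
- α = 0.05 throughout, configurable per call.
- Monte-Carlo problem sizes: 200 experiments for recovery/coverage, 500
  replicates per preset for classification rates, 15 arenas per damage arm
  — the study's replication, scaled to keep the suite fast while leaving
  Monte-Carlo standard errors well inside the tolerances checked.
- CSV is the only interchange format (UTF-8, comma, header, `.` decimal);
  counts must be integers, treatments are lowercased on input.
- The per-replicate `excluded` flag is carried through I/O but no exclusion
  rule is applied; exclusion policy is the caller's.

## Known limitations

- Wald intervals are symmetric and can cross zero for weakly identified
  attack rates at short density ladders; the bootstrap option avoids this
  but costs `B` refits.
- The classifier's backward elimination is one reconstruction of standard
  practice; with only 3–4 densities the cubic is never identifiable and is
  capped automatically at (distinct densities − 1).
- Exposure time is assumed constant within a fit (mixed exposures must be
  fit separately or passed explicitly).
- The damage chain's deterministic predation (capacity removed exactly)
  understates day-to-day variance after release; endpoints are unaffected.
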