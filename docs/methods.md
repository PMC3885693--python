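# Methods

## Data model and forest reconstruction

A participant table has one row per respondent: an opaque `pid`, the
recruiter's pid (blank for seeds), the invitation channel, a completion
flag, demographics (age in years, binary gender, three-level ordinal
education, postal region), household size, contact counts for four travel
modes, seven locations and four meals, a symptom set, and the diary
weekday.  Blank count cells are read as *missing*, never as zero: the
survey instructed respondents to leave inapplicable answers empty, so
blanks are zero-filled — but only for respondents who completed the
questionnaire.  Incomplete records keep their missingness and are excluded
from count-based analyses.

The recruitment history is validated as a directed forest: in-degree ≤ 1,
out-degree ≤ 4 (the coupon limit), acyclic.  Waves are breadth-first depths
from seeds; components are weakly connected components labelled by their
smallest member pid so that output is independent of row order.  A
`recruiter_pid` matching no row is a hard error by default (such records
are surprising and should surface loudly); a lenient flag demotes them to
seeds with a warning.  Repeated recruitment of the same person under two
pids cannot be detected from pids alone and is out of scope; pid collisions
are always an error.

## Diary degree and derived measures

Degree is the sum of travel and location contacts reported for the diary
day, censored at 500 contacts/day; contacts while eating are censored at
75.  The caps are parameters so sensitivity analyses can move them.  Values
at the cap are treated as exact observations in all downstream analyses; a
right-censored likelihood for the degree fit exists behind a flag but is
not the default.  Household members come from a separate roster question
and do not enter degree (home *contacts* do, via the home location).

Count variables are right-skewed, so correlation analyses log-transform
them.  Zeros are legitimate, so the default convention is log(x+1), which
keeps every respondent; natural log with zero-exclusion is available for
sensitivity checks.  "Two-or-more symptoms" is `symptom_count >= 2`;
flu-like and cold-like indicators test for configurable symptom subsets
({fever, headache, muscle pain} and {runny nose, sore throat, cough}).

## Negative binomial degree model

NB(μ, k) with variance μ + μ²/k.  The log-likelihood is maximised in
(log μ, log k) by Nelder–Mead from moment-estimate starts, with a grid
fallback over log k; standard errors come from the finite-difference
observed information at the optimum.  A useful identity pins the
optimiser: for any fixed k the mean MLE is exactly the sample mean, and
the tests require agreement to 1e-6.  Under-dispersed input (variance ≤
mean) cannot identify k; the fit warns and pins k at 1e6 (the Poisson
limit), reporting the sample mean as μ.  Constant input raises.

## Assortativity by tree distance

Pairs at tree distance d are enumerated per component by breadth-first
search on the undirected tree.  Two orientation modes:

- **directed** — ancestor-to-descendant pairs only; at d = 1 these are
  (recruiter, recruited).  Used for the recruiter-vs-recruit table.
- **symmetrized** — every unordered pair at undirected distance d enters
  twice, once per orientation, so the estimate is invariant under swapping
  pair members.  Default for distance profiles, because pairs meeting
  through a common ancestor have no natural direction.  Whether such
  profiles should count each unordered pair once or twice is a genuine
  convention choice; entering both orientations changes no estimate (the
  duplicated points are symmetric) and we base inference on the number of
  *unordered* pairs.

Statistics: Pearson's r for counts/continuous attributes, phi (Pearson on
0/1 codes, with a chi-square test) for binary ones, Spearman rank
correlation for ordinal ones.  Degrees of freedom are n_pairs − 2 with
n_pairs the number of (unordered, in symmetrized mode) complete pairs;
pairs with either value missing are dropped per statistic and counted.
Confidence intervals use the Fisher z transform with the same n.  Pairs
sharing individuals are dependent, so p-values and intervals are
approximate — a caveat inherent to tree-pair correlation analysis, noted in
the output rather than corrected, and one reason the Monte-Carlo envelope
check below exists.  Distance profiles default to max_d = 5 with all
larger distances lumped into a "5+" bucket; distances with fewer than
3 complete pairs are reported undefined (NaN) rather than raising.  The
recruiter-recruit report excludes respondents reporting household sizes
above 500 (configurable), mirroring the outlier exclusion used with this
kind of diary data.

## Variance components and ICC

For each variable, the intercept-only two-level model y_ij = μ + u_i +
e_ij with components as level 2.  The REML criterion for the one-way
layout reduces to closed per-group forms (compound-symmetric blocks), and
is maximised by profiling: for a fixed variance ratio λ = σ²_b/σ²_w the
scale estimate is closed-form, leaving a 1-D bounded search in log λ
(tolerance ~1e-12 on the profiled criterion).  Negative between-components
are truncated to 0, giving ICC 0.  Binary and ordinal variables are fitted
as numeric codes in the same linear model, so their variances are on the
coded scale.  The unbalanced ANOVA method-of-moments estimator is exposed
as a cross-check method; on balanced data the two agree to 1e-6 whenever
the moment estimate is interior, and the test suite also pins the REML fit
against statsmodels' MixedLM on unbalanced data.

One published worked example deserves a note: the gender row of the source
study's ICC table prints ICC 0.203 with components 0.049/0.203, but the
formula gives 0.049/(0.049+0.203) = 0.194.  The package always reports the
formula value; the inconsistent row is excluded from the worked-example
checks.

## Volz–Heckathorn estimation

For category A, p̂_A = (Σ_{i∈A} 1/d_i)/(Σ_i 1/d_i).  The censored diary
degree is the default d_i — it is the only network-size measure the survey
collects — but any positive column or mapping can be substituted, and the
choice is recorded in the output.  Respondents with missing categories or
non-positive degree are excluded and counted.  Seeds are included by
default (a flag excludes them).  The estimator is invariant to rescaling
all degrees, and equals the raw share when degrees are equal.  Composition
curves use wave-major order (then pid) as a deterministic proxy for
enrollment order, since the table carries no timestamps.

## Markov-assumption simulation

To ask whether one-link dependence explains an observed distance profile,
an AR(1) process is simulated on the *fixed* observed forest: seeds draw
standard normals; each recruit is ρ·parent + √(1−ρ²)·noise, which keeps
every node's marginal exactly N(0, 1) at any depth.  Per replicate the
distance-d correlations are computed on the same pair sets as the observed
profile; across replicates (default 2000) the median and the 2.5–97.5%
quantile envelope are reported.  A quantile envelope was chosen over a
parametric band because the per-distance correlation distribution on a
small forest is skewed and the replicate quantiles cost nothing.

## Synthetic cohort generator

The generator is the package's test harness: every analysis stage, run on
generated data, must recover its generating parameter.

- **Topology** — a branching process: each completed respondent issues 4
  coupons, each independently yielding a completed recruit with
  probability 0.24, truncated after 6 waves, from 80 seeds.  These
  defaults emulate the pilot survey scale (~400–600 respondents, coupon
  completion near one in four, trees up to six waves).  A small
  per-coupon probability (0.048) yields entrants who never finish and
  appear as incomplete leaf records.
- **Age** — the AR(1)-on-tree process with ρ = 0.555, rescaled to mean
  26.7 / SD 6.73 years and rounded; so the recruiter-recruit age
  correlation equals ρ and distance-d correlations decay like ρ^d.
- **Gender, education** — Markov child-given-parent transitions of the
  "copy with probability s, else fresh from the stationary law" form,
  with stay-probabilities 0.205 (gender, stationary 61.6% female) and
  0.52 (education, stationary 16/63/21%).  This is the simplest
  categorical model consistent with first-order dependence; it makes the
  edge correlation of any scoring equal s and the distance-d correlation
  s^d.
- **Degree** — NB(μ = 88.2, k = 0.57) per respondent, independent of the
  topology by default (matching the random-by-degree mixing such surveys
  observe); a Gaussian-copula knob can correlate degree along edges for
  sensitivity studies.  Totals are split travel-vs-location by a
  Beta(2, 4.7) fraction (mean ≈ 0.30, matching travel's share of daily
  contacts) and multinomially across modes and locations with fixed
  weights.
- **Meals, households, symptoms** — independent draws: eating total
  NB(6.5, 1.2) split across meals; household sizes from a 1–10
  distribution with mean ≈ 3.7; symptom counts Poisson(1.8) capped at the
  8-symptom vocabulary; household symptomatic counts Poisson(0.5) capped
  at household size; weekday uniform; recruiter channels 80/10/10%
  Facebook/direct/forwarded email.

All randomness derives from one integer seed through numpy `SeedSequence`
spawning — the forest, each trait block and each Monte-Carlo replicate get
independent child streams, so outputs are reproducible and independent of
evaluation order.

What the generator does *not* emulate: repeated recruitment of the same
person (collisions across trees), clustering beyond the tree (the
underlying contact network is never generated), missing demographics,
reporting heaping at round numbers, and any dependence of participation on
attributes.  Passing recovery tests therefore show the pipeline is correct
under first-order Markov assortativity on clean forests — not that real
diary data meet those assumptions.

## Problem sizes in the test suite

The suite generates data at sizes chosen to make 3-standard-error recovery
checks sharp while keeping a full run around ten seconds: ~5000
respondents for end-to-end parameter recovery, 2000 replicates on 50
twelve-deep chains for the AR(1) decay check, 100 random forests for the
pair-enumeration oracle, and 50 replicates of n = 1000 for the NB bias
check.  Checks that need the deposited survey table (recruiter–recruit age
r, NB fit of observed degrees, mean censored degree) run only when that
table has been placed at `data/deposited/participants.csv`; they fail with
an explanatory message otherwise, by design.

## Known limitations

- Correlation inference treats tree pairs as independent; it is not.
- The directed mode at d ≥ 2 covers only ancestor–descendant pairs, a
  strict subset of all distance-d pairs.
- VH estimation uses the diary degree as network size, which measures
  *contacts that day*, not the recruitable network; the two differ.
- The REML implementation is specific to the intercept-only one-way
  layout; covariate-adjusted or generalized (logit) multilevel ICCs are
  out of scope.
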