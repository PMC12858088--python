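# Methods

This note records the models, conventions, and design choices behind
`virtualrds`, in the order the pipeline runs them.

## Synthetic population

**Joint distribution from marginals.** Census tables publish marginal
distributions only. The generator therefore builds the joint distribution
of the categorical variables as a log-linear model: a base affinity tensor
(all ones under independence; `exp` of user-supplied two-way log-affinities
otherwise) is rescaled by iterative proportional fitting (IPF) until every
axis reproduces its marginal targets, then cells are drawn multinomially.
Marginals are exact in expectation under any association structure; the
joint itself is a modelling choice, not an estimate of any real population.

**Default category system.** Sex (men 48.1%, women 51.9%), race (white
43.4%, nonwhite 56.6%), a four-level education variable (30.5 / 14.0 /
38.2 / 17.3%), and a five-category fine age variable. The fine age
partition (18–29, 30–39, 40–44, 45–59, 60+, shares 25.0 / 20.9 / 9.5 /
24.5 / 20.1%) exists because the analysis age groups (18–39 / 40–59 / 60+)
and the invitation age groups (18–29 / 30–44 / 45–59 / 60+) share no
boundary between 39 and 45; both groupings derive from the fine variable,
and the splits inside each analysis group were fixed once so the merged
analysis shares equal the census targets (45.9 / 34.0 / 20.1%) exactly.
The 27 federative units are plain labels grouped into five macro-regions
(7/9/4/3/4 units) with region shares 8.1 / 26.3 / 43.3 / 14.6 / 7.7%
split evenly within a region; capital residence is 24.8%.

**Households.** Sizes are truncated geometric (mean 3, cap 10 by default),
assigned within federative unit so a household never spans two units, with
members shuffled demographically. Households exist solely to support the
one-respondent-per-household rule.

**Outcomes.** Each binary outcome follows a logistic model:
`P(y=1 | cell) = expit(logit(baseline) + Σ offsets)`, with offsets per
category on the log-odds scale. Overall prevalence is therefore the
cell-share-weighted mixture of cell prevalences. Default outcomes
(hypertension, depression, any chronic disease) carry age and sex
gradients at roughly national adult levels.

**Response propensity.** The probability that an invited person answers is
logistic in the ordered education level, `expit(-0.6 + 0.35·level)`
(≈ 0.35 → 0.61 from lowest to highest), chosen once to reproduce the
well-known under-representation of low-education groups in web surveys. A
constant propensity is available for null studies.

**Contact network.** Each person draws a target degree from a negative
binomial (mean 12–25 depending on configuration, dispersion k ≈ 4 giving a
realistic heavy tail), emits half of it as stubs, and each stub picks a
partner degree-proportionally. For a trait with homophily strength
`h ∈ (0,1]` the stub constrains its partner to share the person's category
with probability `h`; for `h < 0` to differ with probability `|h|`
(rejection sampling). The probability that a contact shares category *a*
is then `h + (1−h)s_a` (degree-weighted share `s_a`), so the induced
Heckathorn-style homophily index of the contact process equals `h` by
construction — which is what the diagnostics recover in tests. Self-loops
and duplicate edges are removed; realized degree is stored back (floored
at 1, as a chain-referral respondent always reports at least one contact).

## Recruitment simulation

Seeds are a directed choice: per federative unit (default one each, 27
total), candidates are grouped by sex × invitation-age × invitation-
education cell and picked round-robin so no cell repeats before every
represented cell is used — the "maximal diversity" rule. Seeds send one
invitation into each of the 24 strata of the sex(2) × age(4) ×
education(3) cross product among their contacts; a stratum with no contact
is skipped, not refilled. Later participants invite a uniform 3–5 of
their contacts. Invitees answer with their individual propensity, at most
once (the first successful invitation fixes the recruiter; a person may be
invited repeatedly), and at most one respondent per household. Waves are
processed breadth-first with recruiters in id order, so a run is fully
reproducible from its seed. Recruitment stops at the target sample size
(default 3,805), at a wave cap, or on extinction — the latter returns the
partial sample with a flagged warning, never an exception.

## Markov diagnostics

The recruiter→recruitee transition matrix for a trait is the row-normalised
pair count (maximum likelihood); rows with no pairs are reported as
undefined, never imputed. The equilibrium π\* is the left Perron
eigenvector after explicit irreducibility (strongly connected positive
support) and aperiodicity checks; an absorbing or periodic chain raises
with the violating structure named, and the returned vector satisfies
π\*T = π\* within 1e-8 (verified in tests against 200-step power
iteration). Convergence is measured in total-variation distance (default
tolerance 0.02): empirically over observed per-wave compositions, and
theoretically by propagating the seed composition through powers of T.
The homophily index is the bounded normalised diagonal excess,
`H_a = (T[a,a] − π_a)/(1 − π_a)` when `T[a,a] ≥ π_a` and
`(T[a,a] − π_a)/π_a` otherwise, zero under proportionate recruitment. The
design effect divides an achieved variance (bootstrap, or Taylor-linearised
cluster-robust over recruitment chains) by the binomial `p(1−p)/n`; the
conventional planning value for peer recruitment is 2.

## Calibration weights

Raking (IPF over the four margins sex, age group, education, race, in that
fixed order) is the default, matching what a practitioner can do when only
marginal census targets are published; exact joint-cell post-stratification
is available when joint targets exist, with sparse cells collapsible along
a declared order (education first, then age) under a conserved-mass audit
mapping. Weights are normalised to sum to n; convergence requires every
constrained margin within 1e-8 of target (default cap 200 iterations,
typically 4–10 suffice). A category present in the data but absent from a
margin's targets (e.g. a sex category the census does not tabulate) is left
untouched during that margin's update and the listed categories are scaled
to the remaining weight mass — so the other margins still calibrate
exactly while the unlisted category keeps its relative weight. No trimming
is applied by default.

## Estimation

The point estimator is the Hajek weighted proportion. Uncertainty comes
from a Salganik-style chain bootstrap: a replicate of size n draws a seed
uniformly with replacement from the observed seeds, then repeatedly
appends a respondent drawn uniformly with replacement from the pool of
observed recruitees whose recruiter shared the current member's category,
restarting from a fresh resampled seed whenever the drawn seed's observed
chain length is exhausted. A category with no recruitee pool falls back to
the unconditional pool with a logged warning. The conditioning trait
defaults to the race dichotomy (binary, always full support). Replicates
are re-calibrated before their estimate is taken — raked weights depend
only on the joint margin cell, so per-replicate IPF runs vectorised on the
replicates' cell-count matrix (verified to 1e-10 against applying the
exact raking routine to each replicate's multiset) — and the CI is the
equal-tailed percentile interval (linear-interpolation quantiles), B=1000
by default. Seeds are included in estimates by default (exclusion is a
flag). A degree-weighted estimator `Σ(yᵢ/dᵢ)/Σ(1/dᵢ)` is provided as the
standard cross-check for degree-proportional inclusion. Planning sizes use
`n₀ = z²p(1−p)/e²` with the exact ceiling reported alongside the
conventional rounding to the nearest hundred; the design-effect size
multiplies the rounded value.

## Validation studies and problem sizes

Two Monte-Carlo studies (in `studies.py`) tie the stack to ground truth.
The *coverage study* builds one 5,000-person population and zero-homophily
network (mean degree 8), then 500 times re-draws an iid outcome at
prevalence 0.20, recruits n=400 from 10 seeds at exactly 3 invitations
(constant propensity 0.65), rakes, and takes a 95% percentile CI from
B=500 chain-bootstrap replicates; measured coverage is ≈ 94–95% with
unbiased point estimates. The *recovery study* gives the outcome a strong
negative education gradient with education-biased response; over 25
recruitments of n=600 from a 10,000-person population the raked estimate
recovers the population prevalence within Monte-Carlo error while the
unweighted mean is biased low by about 1.6 points. These sizes keep each
study under a minute on one CPU while leaving Monte-Carlo error well below
the effects being measured.

## What the generator does and does not emulate

It emulates: marginal-calibrated demographic structure, cell-dependent
outcome prevalence, degree heterogeneity, tunable trait homophily,
geographically coherent households, and education-graded nonresponse — the
features the weighting and bootstrap machinery are supposed to handle.
It does not emulate: real geography (units are labels; no municipalities),
joint demographic associations of any actual census (independence is the
default), item nonresponse or questionnaire behaviour, invitation
forwarding dynamics, or degree misreporting (the realized network degree
stands in for self-reported network size). Passing tests therefore show
the machinery is correct under its stated assumptions, not that any
particular real survey satisfies them.

## Known limitations

- The chain bootstrap treats chains as exchangeable given recruiter
  category; residual clustering (household, geography) is not resampled,
  so intervals can undercover when outcomes cluster on unmodelled traits.
- Raking corrects only biases expressible through the four margins; a
  response mechanism tied to an omitted variable that also drives the
  outcome leaves residual bias (demonstrated deliberately in the recovery
  study's unweighted arm).
- Equilibrium diagnostics require an ergodic estimated transition matrix;
  with perfect observed homophily the chain is reducible and the
  diagnostics refuse rather than extrapolate.
- The population-size side of RDS inference (successive sampling,
  capture–recapture) is intentionally out of scope.
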