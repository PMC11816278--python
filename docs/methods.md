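# Methods

## Data model and eligibility

The unit of analysis is a participant observed over at least two rounds of
an organized oral-mucosal screening program. Behavior intensity for smoking
and for betel quid chewing is categorized at each screen as `none` (never
used or ceased), `low` (fewer than 20 units per day) or `high` (20 or more
units per day). The 20-unit boundary is counted as high dose; the
classification is monotone in daily units and maps 0 to `none` regardless
of use history.

Eligibility mirrors the screening cohort the package emulates: participants
younger than 30 at their first screen, or with a single screen, are
excluded; age exactly 30 is retained. Age grouping for modelling is
`younger` (≤ 60) vs `elder` (61+). Covariates — sex, age group, education
(low / high / unknown), living area (urban / rural), screening place
(large / small / unknown) and OPMD screening result — are baseline-fixed:
they are read from the first screen and treated as constant. Missing
education and screening place are an explicit `unknown` level, entering the
regression as their own contrast rather than being imputed or dropped;
missing *behavior states* at a screen are allowed at I/O and the likelihood
simply skips transition pairs with a missing endpoint (logged).

## Transition model

Each behavior evolves as a discrete-time, time-homogeneous, three-state
Markov chain whose clock is the screening round, not calendar time: screens
are the program's natural sampling times and inter-screen intervals are not
modelled. For origin state r the stay weight is fixed at 1 and the weight
of the directed transition r→s is exp(α_rs + Σ_k β_rs,k x_k); the one-step
probabilities are the row-normalized weights. This is a conditional
multinomial logit per origin row with "no change" as the reference outcome.
Consequences that the rest of the package relies on:

* every finite parameter vector yields a valid row-stochastic matrix;
* exp(β_rs,k) is exactly the multiplicative effect of covariate k on the
  r→s weight (the stage-specific adjusted relative risk), independent of
  the other covariates' values;
* the intercept-only maximum-likelihood estimate equals the saturated
  count-ratio (empirical) transition matrix.

The likelihood conditions on each participant's first-screen state and
multiplies one-step probabilities over all consecutive screen pairs. All
pairs contribute, not just the first. The two behaviors are modelled
independently; no smoking×betel interaction terms. Because the likelihood
depends on the data only through per-covariate-pattern transition counts,
fitting aggregates to sufficient statistics first, making the cost
independent of cohort size once counts are formed.

## Estimation

**Maximum likelihood.** Each origin row is an independent multinomial
logit, maximized by L-BFGS-B with the analytic gradient and parameters
box-bounded at ±15 (so separation — a transition never observed in a
stratum — produces a bounded estimate and an explicit warning rather than a
divergent one). When the optimum is interior it is polished by Newton steps
with the analytic Hessian to gradient norm 1e-10, which is what makes the
intercept-only fit match the empirical matrix to 1e-8. Standard errors come
from the inverse observed information; 95% intervals are Wald intervals on
the log-weight scale, exponentiated for relative-risk reporting. A
rank-deficient design (a contrast without variation) is rejected up front.

**MCMC.** The Bayesian fit uses independent normal(0, 10²) priors on all
parameters — vague on the log-weight scale — and a random-walk Metropolis
sampler that updates one origin-row block at a time. Proposals are
preconditioned with the Cholesky factor of the inverse observed information
(plus prior curvature) evaluated at the initial estimates, falling back to
the prior scale when the data carry no curvature (e.g. a prior-only run);
a global per-block step factor starts at 2.38/√d and adapts toward a
0.30–0.40 acceptance rate during burn-in only, so the retained draws target
the exact posterior. Chains initialize at the smoothed empirical
intercept-only estimates with per-chain overdispersion jitter; a pure
zero-start random walk would spend most of the run travelling to posteriors
centred far from the origin. Defaults: 4 chains, 5,000 iterations, 2,000
burn-in, rank-normalized split-R̂ ≤ 1.05 as the pass criterion, all driven
by a mandatory seed (identical seeds give identical draws). A chain that
rejects every post-burn-in proposal in a block raises a sampler error with
its step-size trace. Maximum likelihood is retained alongside MCMC because
it is the deterministic reference the sampler is validated against
(Bernstein–von Mises agreement at large n).

**Crude vs adjusted.** "Adjusted" estimates come from a fit containing all
contrasts simultaneously; "crude" from single-contrast fits. Reports carry
both columns.

## Net Force Progression

Two signed summaries of a one-step matrix P:

* from none: [P(N→L) + P(N→H)] − [P(L→N) + P(H→N)];
* between low and high: P(L→H) − P(H→L).

Both are linear in the matrix entries, zero on the identity and uniform
matrices, and antisymmetric under exchanging every progression with its
paired regression. They are computed from one-step probabilities,
consistent with the discrete-time model (not from intensities).

A covariate's relative risk on an NFP pattern is defined as the ratio of
the pattern's value at the contrasted profile to its value at the reference
profile, all other covariates held at reference. This is the only
definition computable from the fitted model that reduces to exp(β) when the
pattern consists of a single rare progression transition the covariate acts
on. It is a ratio of *signed* quantities, so it is reported only where both
net forces are positive; otherwise the package raises an explicit
undefined-ratio error (and report tables print `NA`). Under the default
generator dynamics both net forces are negative at the reference profile —
the screened cohort improves on net — so NFP RRs are typically undefined
there while the per-transition (stage-specific) aRRs, which are always
defined, carry the covariate story. Interval estimates: the ratio is
applied to each posterior draw (MCMC) or to 2,000 parametric-bootstrap
parameter draws from the Wald normal approximation (ML, fixed seed), and
the 2.5/97.5 percentiles are reported. Draws where a net force is not
positive are dropped; if they are the majority the interval is reported as
undefined rather than invented.

## Synthetic cohort generator

The generator defines the study conditions; its defaults are fixed, not
tuned. It emulates the first-screen composition of a 2.57-million
participant screening cohort:

* covariate prevalences are the documented level counts normalized by their
  own totals (e.g. male 2,190,949/2,578,245; education unknown ≈ 46.6%,
  drawn directly as a level, so the default post-hoc missingness injection
  rate is 0 — `inject_missing` remains available and flips education and
  screening place to `unknown` per participant);
* baseline states are drawn from the documented first-screen distributions
  — smoking (22.4, 48.4, 29.2)%; betel (76.7, 16.7, 6.7)% normalized by its
  printed sum of 100.1;
* the low-dose rows of the true one-step matrices are the published values
  (smoking L→N 0.069, L→H 0.142; betel L→N 0.285, L→H 0.096). The none- and
  high-dose rows are not published numerically; the defaults (smoking N:
  0.87/0.10/0.03, H: 0.07/0.22/0.71; betel N: 0.94/0.05/0.01, H:
  0.26/0.22/0.52) were chosen once to respect the documented qualitative
  facts — most participants unchanged, smoking cessation below 10%, more
  than 20% dose reduction in both high-dose groups, and high-dose betel
  chewers quitting roughly four times as often as high-dose smokers;
* default covariate effects are the five published stage-specific aRRs
  (OPMD+ on smoking N→L 0.86; high education on smoking N→H 0.82; large
  hospital on smoking L→H 0.86 and H→L 1.19; high education on betel H→L
  1.07), all other coefficients zero.

Covariates are drawn independently (only marginals are documented), the two
behaviors evolve independently given covariates, OPMD is a fixed baseline
covariate rather than an outcome of behavior, screen counts (uniform on
{2, 3} by default) are independent of states, and ages are drawn at 30+ so
generated cohorts pass the eligibility filter unchanged. Real screening
data would violate several of these simplifications — covariates are
correlated, attendance and behavior are plausibly dependent (informative
dropout), behaviors are correlated within person, and there are secular
trends over a decade of screening — so passing tests demonstrate that the
estimators recover the generating process under the stated conditions, not
that those conditions describe any real cohort.

`recovery_config` builds the single-origin, single-covariate experimental
cohorts used for parameter recovery: all participants start in one state,
attend exactly two screens, and carry at most one binary contrast with a
specified prevalence acting on one transition.

## Numerical and reproducibility choices

* Problem sizes: recovery experiments use 200,000 two-screen participants
  (binomial SE ≈ 0.08 percentage points on a 14% probability; Wald SE
  ≈ 0.03 on a log-aRR with a 7.5%-prevalence covariate), the MCMC
  validation fixture 50,000 participants, and pipeline smoke tests a few
  thousand.
* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; chain seeds are spawned from a root
  `SeedSequence`. Identical config + seed reproduces datasets, draws and
  report bundles byte for byte (log formatting carries no timestamps).
* Ties/degenerate inputs: an origin state never observed leaves its
  empirical row undefined (NaN, reported) and its ML parameters at 0 with
  undefined SEs plus a warning; an empty dataset has log-likelihood 0 by
  the empty-sum convention and a prior-only posterior.
* Report tables are written as TSV with fixed 4-decimal formatting.

## Known limitations

* The NFP relative-risk definition is a package design choice; a
  constrained one-coefficient-per-pattern model would be an alternative
  reading and is expressible in this parameterization but is not the
  default.
* Continuous-time intensities, misclassified/hidden states, random effects,
  calendar-time effects and joint smoking–betel dynamics are out of scope.
* Wald and percentile-bootstrap intervals rely on large-sample normality;
  with rare transitions in small strata (separation), estimates are bounded
  and flagged instead of being regularized.
* The dose boundary follows the "20 and higher is high dose" reading; the
  alternative "strictly more than 20" reading appears in prose descriptions
  of such programs and would shift classifications of exactly-20 users.
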