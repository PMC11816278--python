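# nfpmarkov

Three-state discrete-time Markov modelling of oral risk behavior change —
smoking and betel quid chewing — across repeated rounds of an organized
oral-mucosal screening program, with covariate effects in exponential
(relative-weight) regression form and the **Net Force Progression (NFP)**
summary statistics.

The package is aimed at biostatisticians and screening-program analysts
working with panel data of the form *one row per participant-screen*: a
participant id, a screening round, demographics (sex, age, education,
living area, screening place), an oral-mucosal screening result (OPMD
positive/negative) and the current smoking and betel chewing intensity,
categorized as `none` (never or ceased), `low` (< 20 units/day) or `high`
(≥ 20 units/day). Because real screening registries of this kind are not
publicly deposited, the package ships a first-class synthetic-cohort
generator that reproduces the documented cohort composition and dynamics,
so every stage of the analysis is testable end to end.

## The model

For each behavior separately, states s ∈ {N, L, H} evolve between
consecutive screens as a time-homogeneous Markov chain. For origin state r
the weight of staying is fixed at 1 and the weight of moving to s ≠ r is

    w_rs(x) = exp(α_rs + Σ_k β_rs,k x_k),

where x is the participant's baseline covariate vector. Row-normalizing the
weights gives the one-step matrix P(x) — a multinomial logit per origin row
with "no change" as the reference outcome, so exp(β_rs,k) is the
*stage-specific adjusted relative risk* (aRR): the multiplicative effect of
covariate k on the r→s transition weight.

The matrix is summarized by two signed net forces:

    NFP_none(P) = [P(N→L) + P(N→H)] − [P(L→N) + P(H→N)]
    NFP_LH(P)   = P(L→H) − P(H→L)

(the tendency to initiate vs cease, and to escalate vs reduce dose). A
covariate's NFP relative risk is the ratio of a pattern's net force at the
contrasted covariate profile to its value at the reference profile, defined
when both are positive.

Parameters are estimated by maximum likelihood (L-BFGS-B with Newton
polishing; observed-information Wald intervals) and by adaptive
random-walk Metropolis MCMC with vague normal(0, 10²) priors, 4 chains and
split-R̂ diagnostics. Both are exposed as scikit-learn-style estimators
(`MLTransitionEstimator`, `MCMCTransitionEstimator`) plus panel-level
wrappers (`fit_ml`, `fit_mcmc`).

## Worked example

```python
import nfpmarkov as nm

cfg = nm.default_config(n_participants=50_000, seed=42)   # study conditions
data = nm.apply_exclusions(nm.generate_population(cfg))   # age >= 30, >= 2 screens

emp = nm.empirical_transition_probs(data, "smoking")
print((100 * emp.p.round(4)))

fit = nm.fit_ml(data, "smoking", ["male", "opmd_positive"])
arr = nm.stage_specific_arr(fit, "none->low", "opmd_positive")
print(f"aRR none->low for OPMD+: {arr.rr:.3f} ({arr.lo:.3f}-{arr.hi:.3f})")
```

prints

```
[[86.94 10.08  2.98]
 [ 7.04 79.4  13.57]
 [ 6.98 23.48 69.54]]
aRR none->low for OPMD+: 0.967 (0.801-1.168)
```

The first block is the empirical one-step smoking matrix in percent (rows:
from `none`, `low`, `high`): most participants keep their state; low-dose
smokers escalate (13.6%) about twice as often as they quit (7.0%),
consistent with the generating low-dose row (14.2% / 6.9%). The last line
is the fitted stage-specific aRR of a positive OPMD screening result on
starting low-dose smoking, with its 95% Wald interval. The generating
coefficient is 0.86, and OPMD-positives are only 7.5% of the cohort, so at
n = 50,000 the interval is wide and comfortably brackets the truth; the
200,000-participant recovery experiments below pin it down.

The same pipeline runs from the shell:

```sh
nfpmarkov simulate --seed 1 --n 50000 --out panel.csv
nfpmarkov fit --panel panel.csv --behavior smoking --seed 1 --out fit.json
nfpmarkov nfp --fit fit.json --pattern low_high --out nfp.tsv
nfpmarkov run --config run.yaml          # full simulate->fit->report bundle
```

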