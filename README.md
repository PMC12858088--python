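# virtualrds

Virtual respondent-driven sampling (RDS) surveys: a simulation and
estimation toolkit for online chain-referral health surveys weighted to
census margins.

## The problem

Online health surveys recruited through social media cannot draw a
probability sample: participants are volunteers reached through peer
invitation chains. RDS tames this by structuring the recruitment — a small
set of *seeds* chosen across all 27 federative units each send a fixed
quota of invitations stratified by sex, age group, and education; every
later participant invites three to five contacts; recruiter–recruitee
links, waves, and personal network sizes are all recorded, and only one
person per household may answer. Because the category of a recruitee
depends (approximately) only on the category of their recruiter, the chain
behaves as a Markov process: after enough waves the sample composition
forgets the seeds and approaches the equilibrium of the recruitment
transition matrix.

`virtualrds` implements the whole methodology as reusable, tested code, and
— since real respondent-level data of such surveys are not public —
pairs it with a synthetic-data generator that reproduces the statistical
structure the method assumes: a finite population matching configured
census marginals, binary health outcomes with cell-dependent prevalence, a
contact network with tunable homophily, and education-biased response
propensity. Every downstream claim can therefore be validated against
known ground truth.

It is intended for survey methodologists and epidemiologists who want to
study, teach, or stress-test chain-referral designs before fielding one.

## What is inside

| stage | module | core quantity |
|---|---|---|
| synthetic population & network | `population` | joint cells calibrated to marginals by IPF; stub-matching network where the homophily strength *h* equals the induced Heckathorn-style homophily index |
| recruitment simulation | `recruitment` | wave-by-wave forest of recruiter→recruitee records under the 24-stratum seed quota and 3–5 invitation rule |
| Markov diagnostics | `diagnostics` | transition matrix `T[a,b] = P(recruitee b \| recruiter a)`, its equilibrium π\* (π\*T = π\*), convergence wave, homophily index `H_a`, design effect |
| calibration weights | `weighting` | post-stratification / raking: iterative proportional fitting until every weighted margin equals its census target |
| estimation | `estimation` | weighted prevalence `Σwᵢyᵢ/Σwᵢ` with percentile CIs from a Salganik-style chain bootstrap that regrows recruitment chains conditional on recruiter category (replicates re-raked); Volz–Heckathorn degree-weighted cross-check; planning sizes `n₀ = z²p(1−p)/e²`, inflated by a design effect |
| comparison | `comparison`, `references` | side-by-side ratios and CI-overlap flags against the packaged census (PNADC-2022) and national health survey (PNS-2019) printed values |
| pipeline & CLI | `pipeline`, `io`, `cli` | `generate → recruit → diagnose → weight → estimate → compare`, fully reproducible from one seed |

## Worked example

```python
import virtualrds as v

cfg = v.RunConfig(seed=7, outdir="demo-run", n_pop=30_000, bootstrap_B=500)
result = v.run_pipeline(cfg)
```

This generates a 30,000-person synthetic population (race homophily 0.3 in
the contact network, education-biased response), recruits 3,805 respondents
in 7 waves from 27 seeds, rakes them to the census margins, and estimates
outcome prevalences with chain-bootstrap CIs. The run prints to
`demo-run/estimates.csv`:

```
   indicator  pct  ci_low  ci_high   B       seed  deff
hypertension 23.9    22.6     25.4 500 1956387801 1.074
  depression 18.2    17.1     19.7 500 1956387801 1.122
     any_ncd 54.2    52.5     55.7 500 1956387801 0.970
```

i.e. a weighted hypertension prevalence of 23.9% (95% CI 22.6–25.4) with a
design effect near 1. `demo-run/diagnostics.json` reports, for race, an
estimated homophily index of 0.30 for both categories (recovering the 0.3
used to build the network), an equilibrium composition of (0.565, 0.435) —
the population shares — and empirical convergence by wave 1. The weighted
margins in `demo-run/respondents_weighted.csv` equal the census targets
exactly (white 43.4%, aged 60+ 20.1%), which is the defining property of
post-stratification.

The same stages are available from a shell:

```bash
virtualrds samplesize --p 0.05 --error 0.01 --deff 2
# raw n = 1825; rounded = 1800; with design effect 2: 3600
virtualrds pipeline --seed 7 --outdir demo-run
```

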