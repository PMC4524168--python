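# Methods

## Model structure

The simulator is a discrete-time, individual-level stochastic model of type 2
diabetes complications. Time advances in fixed cycles of `dt = 0.5` years
(configurable) to a maximum horizon of 40 years; a validation run stops at
the study's follow-up, capped at that horizon. Each patient is a vector of
demographics, continuous risk factors, binary risk factors and an event
history (MI and stroke counters; CHF, IHD, amputation, ulcer, blindness and
ESRD as absorbing flags). Cohorts are stored as structures of arrays and the
cycle loop is fully vectorised, so 50,000-patient arms simulate in seconds.

### Within-cycle order

1. natural-history update of risk factors (start of cycle, before risk
   evaluation — a fixed order is required for reproducibility);
2. every eligible nonfatal event equation evaluated as an *independent*
   Bernoulli draw at its cycle probability, with eligibility frozen at the
   cycle start (an MI this cycle cannot trigger a secondary MI until the next
   cycle); no within-cycle competing-risk normalisation is applied — the
   equations are separate per endpoint and independence is the simplest
   contract, and rates are low enough per half-year cycle that the joint
   probability mass above 1 is negligible;
3. mortality equations evaluated last, against the post-event state, so a
   patient can suffer a nonfatal event and die in the same cycle;
4. age, diabetes duration and time-in-model advance by `dt`.

Person-time accrues in full cycles; death ends accrual at the end of the
cycle in which it occurs and there is no half-cycle correction. A
consequence worth knowing: for a pure exponential mortality hazard λ the
mean simulated survival is `dt / (1 − exp(−λ·dt))`, the discrete-time
analogue of `1/λ` (they differ by ≈ `dt/2`). Cumulative incidence at cycle
boundaries, however, is *exactly* `1 − exp(−H(t))` in expectation, because
the per-cycle complements multiply telescopically — this is what the
closed-form oracle tests exploit.

## Risk equations

An equation is `lp = intercept + Σ coef·f(x)` with transforms limited to
identity, offset-centring (`x − c`), indicator (`x > c`) and natural log.
Hazard families and cycle probabilities:

| form        | cumulative hazard `H(t)`          | cycle probability                |
|-------------|-----------------------------------|----------------------------------|
| exponential | `e^lp · t`                        | `1 − exp(H(t) − H(t+dt))`        |
| weibull     | `e^lp · t^shape`                  | same                             |
| gompertz    | `e^lp · (e^{shape·t} − 1)/shape`  | same                             |
| logistic    | annual `p = expit(lp)`            | `1 − (1−p)^dt`                   |

`t` is diabetes duration in years (the convention of the UKPDS outcome
equations), updated per cycle. Weibull with shape 1 reduces exactly to the
exponential; Gompertz converges to it as shape → 0. Probabilities are kept
in `[0, 1)` (clipped at the largest double below 1). Eligibility predicates
use a deliberately small grammar — `covariate op number` atoms joined by
`and`/`or` — which keeps registries declarative and testable. Ineligible
patients get probability 0, not an error, so a registry can always be
evaluated over a whole cohort.

Registries are JSON; structural validation enforces unique endpoints,
positive shapes where required, known covariates/transforms, and
*set discipline*: a `ukpds68`-style registry may not reference the expanded
risk factors (WBC, LDL, eGFR, heart rate, haemoglobin, albuminuria) nor
contain secondary-event equations, while a `ukpds82`-style registry must
reference all of them and contain secondary equations.

**The shipped registries are synthetic placeholders.** Published coefficient
sets are not included; the placeholder intercepts and coefficients were
chosen once to yield realistic annualized complication rates (~0.2–2.5
events per 100 person-years for a contemporary T2DM trial cohort) and
plausible covariate effects. All pipeline validation on synthetic data is
therefore *parameter recovery* against known coefficients, which tests the
machinery, not the published equations.

## Natural history and treatment effects

Defaults follow the usual validation set-up: weight +0.1 kg/year; eGFR
−0.7 ml/min/1.73 m²/year with a floor of 10 (keeps renal covariates
physiological; the floor is configurable); WBC, LDL, albuminuria, heart rate
and haemoglobin held constant. HbA1c, SBP and TC:HDL follow pluggable
parametric curves anchored at the (post-treatment) baseline — a linear drift
(defaults: HbA1c +0.15 %/year, SBP +0.5 mmHg/year, TC:HDL flat, in line with
observed long-term progression in treated T2DM cohorts) or an asymptotic
approach curve; published panel-equation trajectories can be dropped in via
configuration without code changes.

Treatment-effect deltas are applied exactly once, at cycle 0, clamped at
per-factor physiological floors; the panel-curve anchors are re-based on the
post-treatment values, i.e. effects persist as the new trajectory anchor
rather than decaying. A second application is a usage error.

## Synthetic cohorts and baseline uncertainty

Cohorts are drawn from a study-level profile: continuous factors
normal(mean, SD) truncated below at physiological bounds; binary factors and
prior events Bernoulli. Factors are sampled independently (no copula), each
from its own RNG stream keyed by factor name — so fixing one factor (as the
uncertainty sweep does) never perturbs the draws of any other, and adding an
arm or study never perturbs existing results (streams are keyed per
study × arm from the master seed).

Default fall-back values for the expanded factors are the UKPDS-82 reference
values: WBC 6.9 ± 1.8 ×10⁶/ml, LDL 3.0 ± 0.6 mmol/l, eGFR 77.7 ± 15
ml/min/1.73 m², heart rate 72 ± 12 bpm, haemoglobin 145 ± 13 g/l. (The
haemoglobin figure circulates mislabelled as "HbA1c, 145 ± 13 g/l"; the
units are haemoglobin units and it is stored here as haemoglobin.) The
remaining profile defaults (age 62 ± 8, duration 8 ± 6 years, HbA1c
7.5 ± 1.1 %, SBP 140 ± 18 mmHg, TC:HDL 4 ± 1, weight 85 ± 16 kg, 40% female,
15% smokers, 22% albuminuric, 10%/5%/3% prior MI/stroke/CHF, 5% AF, 5% PVD)
were set once to a typical contemporary T2DM outcomes-trial cohort.

Unreported scalar factors can be sampled from a normal centred on the
reference mean, truncated at ±2 standard errors (SD = half-width/2) —
truncation, rather than an unbounded draw, because the sweep's prediction
ranges are defined as the spans produced by values within that interval.
Baseline albuminuria prevalence is sampled hierarchically: the underlying
proportion uniform on 9–35%, then a binomial realisation at the study's
sample size.

## Goodness of fit

MAPE, R² (squared Pearson correlation) and OLS of observed on predicted
annualized rates; the OLS is unweighted across all endpoint pairs (weighting
is deliberately not applied so every validation endpoint counts equally; a
weighted variant belongs in user code on the emitted pair set). Pairs with
observed rate 0 make the percentage error undefined; the low-level `mape`
raises by default, while pipeline summaries exclude such pairs and report
the excluded count. Strata with a single pair (the MVD composite often is
one) report MAPE with R² marked unavailable. Rates are expressed per 100
person-years throughout; MAPE and the regression slope are invariant to
that unit choice, the intercept is not.

The uncertainty sweep re-simulates each of albuminuria, eGFR, heart rate,
LDL and WBC fixed at the ends of its ±2-SE interval (others at profile
values), with identical RNG streams across settings (common random numbers),
so a factor's range is noise-free relative to the point run; the
widest-range factor per endpoint is flagged most influential. The reported
coverage — the fraction of endpoint records whose observed rate falls inside
the across-factor envelope — is a demanding statistic on synthetic demo
data: endpoints whose equations reference none of the five factors get
degenerate (zero-width) envelopes that almost never contain an independently
simulated observation, so demo coverage sits near the share of influenced
endpoints rather than near 100%.

## Problem sizes and numerical choices

The test suite and acceptance script use 50,000 patients per arm for
closed-form and parameter-recovery checks (Monte-Carlo SE on a 1/100-py
endpoint over 5 years ≈ 2–4% relative), 20,000 for the sweep, and a few
hundred for smoke/determinism tests; the demo trials run 2 studies × 2 arms
× 8 endpoints over 4–5 years of follow-up. Agreement tolerances in tests
are 3 binomial/Monte-Carlo SEs for simulated quantities and 1e-10…1e-12 for
closed-form arithmetic. Everything is reproducible bit-for-bit from a single
master seed via `numpy` `SeedSequence` spawning.

## Limitations

* The synthetic generator samples risk factors independently and emulates
  neither correlated baselines, therapy escalation over follow-up, nor
  loss to follow-up; passing parameter-recovery tests demonstrates the
  pipeline's internal consistency, not the predictive validity of any real
  equation set against real trials.
* Only a single first-cycle treatment effect is modelled (no multi-line
  therapy pathways, no effect waning).
* No cost or quality-of-life outputs; this is an event-rate engine.
* The placeholder registries are not the published UKPDS 68/82 coefficient
  sets; conclusions about those equations require transcribing them into
  the registry schema and supplying real trial profiles and observed rates.
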