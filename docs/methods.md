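# Methods

## The design

`mphsccs` implements a self-controlled case series (SCCS) analysis of the
association between methylphenidate (MPH) treatment and incident psychotic
events in patients observed between their 6th and 20th birthdays within a
2001–2014 study period. In an SCCS only *cases* — patients who experienced
both the outcome and the exposure — are analysed, and the incidence of
events is compared across exposure-defined windows *within* each patient.
Conditioning each patient's Poisson interval counts on that patient's event
total turns the likelihood into a product of per-patient multinomials,

```
ℓ(β) = Σ_i Σ_j n_ij · log( t_ij e^{x_ij β} / Σ_k t_ik e^{x_ik β} ),
```

where `t_ij` is the length in days of interval *j* of patient *i*, `x_ij`
the indicator vector of exposure category, age band and season, and `n_ij`
the event count (0 or 1 here, since only the incident event is analysed).
All time-invariant between-person confounding (genetics, ADHD severity at
baseline, socioeconomic factors) cancels out of this likelihood; age and
season are the time-varying confounders adjusted explicitly.

## Person-time construction

*Observation window.* Follow-up runs from the later of the study opening
(2001-01-01) and the 6th birthday to the earliest of the study close
(2014-12-31), the day before the 20th birthday (age 19 is fully included),
the day before the first atomoxetine prescription, and the date of death.
A sensitivity variant additionally censors at the first antidepressant or
antipsychotic prescription. Patients with a qualifying outcome event before
their window start are excluded entirely.

*Exposure episodes.* Prescriptions are converted to day-resolution episodes:
a recorded end date wins; otherwise duration is dispensed quantity divided
by daily dose (rounded, clamped to ≥ 1 day); otherwise the configured median
prescription length (70 days by default) is imputed. Overlapping or abutting
prescriptions merge — continuous supply is treated as continuous exposure —
while any uncovered day separates episodes (drug holidays).

*Categories.* Each window day is classified with precedence
exposed > washout > pre-exposure > baseline:

- **exposed** — days covered by an episode, optionally extended by 1–10
  weeks after each episode end (non-adherence sensitivity); the extension is
  applied before window clipping, so an episode ending just outside the
  window still contributes its extended tail;
- **pre-exposure** — a fixed window (90 days; 30/60-day variants)
  immediately before the *first-ever* episode, absorbing event-driven
  treatment initiation (reverse causality); re-initiations get no
  pre-exposure window, and the window is clipped rather than the patient
  dropped when follow-up starts less than 90 days before first treatment;
- **excluded washout** — 7–21 days immediately before the first episode,
  removed from analysed person-time entirely (taking precedence over
  pre-exposure); a patient whose event falls on a washout day is dropped;
- **baseline** — everything else.

Categories are painted on a vectorised day grid and collapsed to runs, which
makes the precedence rules and the tiling invariant (interval lengths plus
washout days reconstruct the window exactly) correct by construction.

*Age and season.* Intervals are further split at every birthday (12-month
bands; 6-month variant splits at half-birthdays) and at calendar-quarter
boundaries. Quarters are used because they are the minimal conventional
seasonal adjustment; the original analysis does not define "season". Age
bands are anchored at the birthday rather than the calendar year because
entry is the 6th birthday. A Feb-29 birthday rolls to Mar 1 in non-leap
years.

*Day-1 events.* An event on the first day of an episode counts as exposed
unless it is flagged as having occurred before treatment was prescribed, in
which case it is attributed to the interval ending the previous day
(pre-exposure or baseline). A sensitivity variant instead removes such
patients.

*Delayed entry.* One sensitivity variant starts follow-up at the first
ADHD diagnosis or first MPH prescription. Read literally ("whichever
occurred last") this would start follow-up at the first MPH prescription
and leave no pre-exposure person-time at all, yet the design still reports
a pre-exposure estimate under this variant; we therefore start follow-up at
`max(study start, 6th birthday, min(first ADHD diagnosis, first MPH date))`,
which preserves a (possibly truncated) pre-exposure window and reproduces
the intended case attrition (events before the delayed start exclude the
patient).

## Estimation

`SCCSModel.fit()` maximises the exact conditional log-likelihood by
Newton–Raphson with analytic gradient and Hessian, started from zero, with
step-halving; convergence is a gradient max-norm below 1e-8 within 100
iterations. Corner-point coding is used: baseline category, earliest
observed age band and season 1 are the references (exposure IRRs are
invariant to this choice). Patients whose intervals span a single covariate
pattern contribute a constant and are dropped with a count; unobserved
age/season levels are dropped from the design. The covariance is the
inverse negative Hessian at the optimum; Wald intervals and p-values are
normal-based, with |log IRR| > 10 flagged as possible separation. Direct
contrasts between two fitted terms (for example exposed versus
pre-exposure) use the delta-method variance `var_a + var_b − 2 cov_ab`.
No multiplicity adjustment is applied across scenarios, matching the
per-row 5% tests of the original report. P-values below 0.01 print as
"<0.01"; displayed values round half-up to two decimals.

## Sample size and power

The planning module uses the single-exposure binomial approximation: a
case's single event falls in exposed time with probability `π0 = r` under
the null and `π1 = rρ/(rρ + 1 − r)` under the alternative, giving

```
n = ceil( (z_{1−α/2}√(π0(1−π0)) + z_{power}√(π1(1−π1)))² / (π1 − π0)² ).
```

With `r = 223.0/(223.0 + 823.6)` (the exposed share of case person-time),
ρ = 2, α = 0.05 and 80% power this gives 76 cases. `power_given_cases`
inverts the same formula; `simulated_power` estimates the exact rejection
probability by binomial simulation of the Wald test. At large case counts
the two agree closely; at n ≈ 76 the normal approximation sits roughly 3–4
percentage points above the exact binomial power (the score,
likelihood-ratio and Wald variants of the test all reject at the same
integer event count, so this gap is a property of the approximation, not of
the test variant). We deliberately do not add a continuity correction,
which would break the inverse relationship with the published case count.

## The synthetic cohort

The simulator emulates the study population so that every pipeline stage is
testable without the confidential source records: dates of birth uniform
over 1994–2004 (observation windows averaging about ten years), episodic
MPH prescriptions with log-normal durations (median 70 days, log-sd 0.6),
roughly nine episodes per patient separated by exponential gaps (mean 60
days), about two years of cumulative exposure per case, a 5% chance of an
atomoxetine switch (censoring), and an ADHD diagnosis code before first
treatment for 75% of patients. The first psychotic event is drawn from a
piecewise-constant daily hazard

```
λ(t) = λ0 · e^{γ·ageband(t)} · s_quarter(t) · ρ_exp^[exposed(t)] · ρ_pre^[pre(t)]
```

by exact inversion of the cumulative hazard on the day grid, with defaults
λ0 = 1.7e-6 per day (≈ 6 events per 10,000 patient-years, the study's
exposure-period incidence), γ = 0.10 per year of age (a mild adolescent
increase), quarter multipliers (0.90, 1.00, 0.95, 1.15) normalised to mean
1, ρ_exp = 1.0 and ρ_pre = 4.64 (the study's point estimates). Case
cohorts condition on the first event falling inside the observation window;
because acceptance at the realistic rarity is below 2%, `simulate_cases`
uses an exact two-stage rejection scheme — a vectorised upper envelope on
the total hazard computed from the date of birth alone, then the exact
acceptance ratio for envelope-passed candidates — which is distributionally
identical to naive rejection but orders of magnitude faster.

The day grid used by the simulator is the same primitive the segmentation
module uses, so the simulated law is *exactly* the model the fitter
assumes, making parameter-recovery and coverage checks sharp. The test
suite guards this shared primitive with brute-force oracles (plain-Python
per-day reclassification, hazard recomputation and multinomial likelihoods).

What the simulator does **not** model, and what passing tests therefore do
not establish about real data: time-varying confounding between ADHD
severity, prescription intensity and event risk; diagnosis-code noise or
treatment-dependent under-ascertainment; recurrent events; and deaths
during follow-up (none occurred in the study). Because only the first
event is recorded, the simulated law deviates from a true Poisson-process
multinomial by the within-window survival factor; at the default rarity
this is a sub-1% distortion. Events moved to pre-exposure by the day-1
before-treatment flag introduce a similarly negligible mismatch.

## Problem sizes used in validation

The validation experiments are sized to be decisive yet quick: parameter
recovery uses 200 replicate cohorts of 500 cases (mean exposed log-IRR
within ±0.1 of truth; CI coverage within [0.92, 0.975]); type-I error uses
1,000 replicates of 200 cases (rejection in 3–7%); the event-day
distribution check uses 20,000 conditioned draws (KS at the 1% level); and
the full 24-scenario battery runs on a 500-case cohort. These sizes keep
the whole suite to a few minutes while leaving the statistical assertions
well inside their tolerance bands.

## Known limitations

- Incident-event SCCS only; no recurrent-event extension and no
  event-dependent observation-period corrections.
- Discrete age bands only (no spline age effects); season means calendar
  quarter.
- The sample-size module covers a single exposure category with an overall
  exposed-time fraction; age-adjusted planning variants are out of scope.
- The default ICD-9-CM map covers the code groups named in the main
  analysis (298.0/.1/.3/.8/.9 psychosis, 780.1 hallucinations, 303–305
  substance misuse); site-specific code lists can be supplied as YAML.
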