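# mphsccs

Self-controlled case series (SCCS) analysis of methylphenidate (MPH)
exposure and incident psychotic events in children and adolescents, with a
synthetic-cohort simulator for validation.

## The problem

Whether stimulant treatment for ADHD raises the risk of psychotic events is
hard to answer with cohort or case–control designs: patients who receive
MPH differ systematically (ADHD severity, comorbidity, family history) from
those who do not. The SCCS design sidesteps between-person confounding by
analysing only *cases* — patients who experienced both the outcome and the
exposure — and comparing event rates across exposure-defined windows
*within* each patient. This package implements that pipeline end to end for
pharmacoepidemiologists and biostatisticians: prescription-to-episode
construction, observation-window and censoring rules, a 90-day
pre-exposure window to absorb event-driven treatment initiation (reverse
causality), age-band and season adjustment, the conditional Poisson fit, a
battery of 24 sensitivity scenarios, analytic sample-size/power for the
design, and a simulator whose generating law is exactly the fitted model.

## The model

With patient *i*'s window partitioned into intervals *j* of length `t_ij`
days, homogeneous in exposure category (baseline / pre-exposure / exposed),
age band and calendar quarter, and `n_ij` incident events, the conditional
(multinomial) log-likelihood is

```
ℓ(β) = Σ_i Σ_j n_ij · log( t_ij e^{x_ij β} / Σ_k t_ik e^{x_ik β} )
```

and `exp(β)` are incidence rate ratios (IRRs) relative to baseline
person-time. Time-invariant confounders cancel; age and season are
adjusted explicitly. See `docs/methods.md` for the full account.

## Worked example

Simulate a 500-case cohort (true exposed IRR 1.0, true pre-exposure IRR
4.64) and run the two primary analyses:

```python
from mphsccs import SimulationConfig, simulate_cases
from mphsccs.scenarios import ScenarioConfig, run_scenario, render_text

data = simulate_cases(SimulationConfig(n_cases_target=500, seed=3)).to_data()
reports = [
    run_scenario(data, ScenarioConfig(name="primary", pre_exposure_days=0)),
    run_scenario(data, ScenarioConfig(name="primary_pre90")),
]
print(render_text(reports))
```

prints

```
primary (n=500)
  Period with MPH treatment                    0.87 | 0.68–1.12 | 0.29

primary_pre90 (n=500)
  90 days before first MPH treatment           5.15 | 3.62–7.35 | <0.01
  Period with MPH treatment                    1.04 | 0.80–1.35 | 0.77
```

Each row is `IRR | 95% CI | P-value`. The exposed-period IRR is compatible
with 1 (no on-treatment risk increase, matching the simulated truth), while
the 90 days before first treatment show a strongly elevated rate — the
reverse-causality signal the pre-exposure window exists to isolate (the
point estimate 5.15 brackets the simulated 4.64 within its CI). A direct
contrast of the two windows:

```python
est = reports[1].results.contrast("exposed", "pre_exposure")
print(est.format_irr_ci(), "|", est.format_p())   # 0.20 | 0.14–0.30 | <0.01
```

i.e. the on-treatment rate is about one-fifth of the pre-treatment rate.
The full 24-scenario sensitivity battery runs with
`run_battery(data)` or from the shell:

```bash
mphsccs simulate --n-cases 500 --seed 3 --out-dir simulated
mphsccs run --patients simulated/patients.csv \
            --prescriptions simulated/prescriptions.csv \
            --events simulated/events.csv --scenarios all --out-dir results
mphsccs samplesize --r 0.213 --irr 2 --alpha 0.05 --power 0.8
```

The sample-size command prints `{"cases": 76, ...}`: the minimum number of
cases needed to detect an IRR of 2 at 80% power with a two-sided 5% test,
given the exposed fraction of case person-time.

## Layout

| module | role |
| --- | --- |
| `mphsccs.records` | CSV I/O, ICD-9-CM code map, prescription → episode conversion |
| `mphsccs.windows` | observation windows, censoring, incident-event selection |
| `mphsccs.segmentation` | exposure / age / season interval construction |
| `mphsccs.model` | `SCCSModel` / `SCCSResults`: conditional Poisson fit, Wald CIs, contrasts |
| `mphsccs.scenarios` | scenario battery, batch runner, report rendering |
| `mphsccs.samplesize` | analytic sample size and power, Monte-Carlo check |
| `mphsccs.simulate` | synthetic cohorts and deterministic toy fixtures |
| `mphsccs.cli` | `mphsccs run / simulate / samplesize / fixtures` |
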