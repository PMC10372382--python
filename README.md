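# latewave

Wave analysis of screening participation under the continuum-of-resistance
model: can data on *late* participants — people who joined a
population-based screening programme only after one or two reminders —
stand in for the non-participants we never observe?

`latewave` is a Python library (with a thin CLI) for epidemiologists and
biostatisticians working with invitee-level recruitment data: one row per
invited individual, a participation-wave label (joined after the initial
invitation, after the k-th reminder, or never), and characteristic columns
from registers or from the screening itself. It provides

- a validated invitee-table data model with declarative exclusion rules
  and an audit trail,
- per-wave-group summaries (means/proportions with Wald 95% CIs),
- two estimators of full-invited-population values that use participant
  data only, plus bootstrap confidence intervals,
- a synthetic-cohort generator with a configurable participation-propensity
  gradient and known ground truth, and
- a simulation harness measuring estimator bias, RMSE and CI coverage.

## The model

The continuum-of-resistance model assumes invitee characteristics follow a
gradient in the latent propensity to participate, with participation wave
as its observable proxy: early participants sit at one end, non-participants
at the other, late participants in between. Two estimators exploit this.

**Substitution.** The population mean is an exact share-weighted average of
its group components,

    ȳ_pop = α·ȳ_α + β·ȳ_β + γ·ȳ_γ + (1 − α − β − γ)·ȳ_n ,

with α, β, γ the population shares of the participant waves. The unobserved
non-participant value ȳ_n is replaced by the value of the wave least prone
to participate (the last reminder wave). The estimate is a convex
combination of the group values, and becomes exact if non-participants
truly resemble the last wave.

**Linear extrapolation.** Form one cumulative point per wave — cumulative
participation share x̄ against cumulative participant mean ȳ (waves 0..k
pooled) — fit ȳ = a + b·x̄ by unweighted OLS, and predict at x̄ = 1, a
hypothetical cohort in which everyone participated. With two waves this is
the interpolating line extended to full participation.

Both estimators get normal-based bootstrap CIs by resampling invited
individuals with replacement and re-running the entire procedure — shares,
wave values, fit — per replicate.

## Worked example

Generate a cohort shaped like a 14,064-invitee atrial-fibrillation
screening study (three participant waves of 39%/7%/3%, immigrant share
rising from 0.16 among early participants to 0.27 among non-participants)
and estimate the full-population immigrant share from participants only:

```python
import latewave as lw

cfg = lw.scenario_preset("strokestop_like", seed=1)
table, truth = lw.generate_population(cfg)
print(lw.wave_counts(table).counts)        # (5495, 970, 402, 7197)

res = lw.bootstrap_estimates(table, ["immigrant"], B=1000, seed=1)
print(f"true population value : {lw.population_truth(table, 'immigrant').estimate:.3f}")
for m in ("participants", "substitution", "extrapolation"):
    e = res[("immigrant", m)]
    print(f"{m:<14s}: {e.estimate:.3f} (95% CI {e.ci_low:.3f}-{e.ci_high:.3f})")
```

prints

```
(5495, 970, 402, 7197)
true population value : 0.218
participants  : 0.177 (95% CI 0.168-0.186)
substitution  : 0.191 (95% CI 0.169-0.213)
extrapolation : 0.238 (95% CI 0.210-0.266)
```

The unadjusted participant value (0.177) understates the population share
(0.218); substitution moves part of the way toward it, extrapolation
overshoots slightly but lands closer. `lw.accuracy_comparison` formalizes
that reading: both methods improve on the baseline here and extrapolation
wins. On other characteristics — and in the simulation scenarios where the
gradient is flat, non-monotone, or exactly matched to an estimator's
assumption — the ranking shifts; that is precisely what the `evaluation`
module measures.

The same steps are available from the shell:

```
latewave generate --preset strokestop_like --seed 1 --out cohort.csv
latewave estimate --input cohort.csv --schema schema.yaml --method all \
    --bootstrap 1000 --seed 1 --out estimates.csv
```

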