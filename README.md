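# flexforage

Prey-size selectivity estimation from stomach-content surveys, and an
allometric trophic network (ATN) simulator that asks what flexible
foraging does to food webs under warming.

## The problem

Classical food-web models let warming act only through physiology:
metabolic rates rise faster than feeding rates, and consumers starve.
But predators also *behave* — they reallocate foraging effort as
temperature and prey availability change. This package implements both
halves of that question for benthic fish communities:

1. **Estimation.** From paired stomach-content and benthos-sample
   tables, estimate each consumer's *preference distribution* over
   log10 prey body mass — the realized (stomach) distribution divided
   by the environmental one, P(x) = R(x)/E(x) — as inverse-availability
   weighted moments of the stomach masses, w_i = 1/E(r_i):

       μ = (1/W)Σwᵢrᵢ,  σ² = (1/W)Σwᵢ(rᵢ−μ)²,  γ = (1/(Wσ³))Σwᵢ(rᵢ−μ)³

   then regress the summaries on predator mass, temperature, resource
   availability and their interaction (Bayesian linear models, PSIS-LOO
   model comparison), and convert the moments to skew-normal
   (ξ, ω, α) selectivity curves with their own covariate models.

2. **Simulation.** A bioenergetic ATN with two nutrients, Arrhenius
   temperature scaling of all rates, a Ricker feeding niche with
   optimal mass ratio R_opt = 71.68, and a type-III-capable functional
   response. Consumer foraging effort w_ij is either uniform over prey
   (static) or proportional to the empirically parameterized
   skew-normal preference density, re-predicted from the instantaneous
   state (flexible). A paired temperature-gradient experiment counts
   consumer extinctions under both policies and summarizes them with a
   binomial GAM.

Because the original survey data are external, a first-class
`synthetic_data` module generates schema-complete surveys with known
ground-truth selectivity and synthetic 50-species food webs, so every
stage is testable and reproducible offline.

## Worked example

```python
import numpy as np
from flexforage.synthetic_data import SurveyConfig, generate_survey
from flexforage.preference_estimation import estimate_preferences
from flexforage.selectivity_models import (fit_moment_model,
                                           temperature_effect_profile)

tables, truth = generate_survey(SurveyConfig(seed=42))
prefs = estimate_preferences(tables["stomachs"], tables["environment"])
print(len(prefs))                      # 308 statistical fish

fit = fit_moment_model(prefs, response="weighted_median", seed=0)
print(fit.coefficients[["mean", "ci_2.5", "ci_97.5"]].round(3))
```

```
                               mean  ci_2.5  ci_97.5
term
intercept                    -0.883  -1.113   -0.645
log10_fish_mass               0.360   0.304    0.412
temperature_C                 0.155   0.133    0.177
log10_resource                0.348   0.215    0.475
temperature_C:log10_resource -0.105  -0.118   -0.090
```

Reading the table: preferred prey mass rises with predator mass
(0.36 decades per decade), and the temperature effect depends on
resource availability — positive at low resource levels but reversed
by the negative interaction where resources are plentiful, i.e. fish
in warm, productive environments shift toward *smaller* prey.
`temperature_effect_profile(fit, grid)` profiles the posterior of
β_T + β_{T×R}·R along the resource gradient and reports where its 95 %
interval excludes zero.

Running the warming experiment from the shell:

```bash
flexforage experiment --temps 0:18:3 --reps 10 --seed 1 --out scratch/exp
```

prints `mean flexible-minus-static contrast: 0.2503` — averaged over
the gradient, flexible foragers lose about 25 percentage points more of
their 30 consumers than static ones (at 18 °C: 28.2 vs 27.0 extinct on
average; at 0 °C: 2.1 vs 0.0). Flexible foraging makes warming *worse*,
because warm-condition preferences concentrate effort on small,
unprofitable prey.

Other subcommands: `flexforage synth-survey`, `synth-web`, `estimate`,
`fit`, `simulate` — each a thin wrapper over the library (see
`flexforage <cmd> --help`).

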