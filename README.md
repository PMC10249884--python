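# dynbias

Modeling toolkit for perceptual decision bias in dynamically switching
environments.

## The problem

In a two-alternative forced-choice (2AFC) orientation discrimination task, an
observer judges on every trial whether a briefly presented grating is tilted
clockwise (+) or counter-clockwise (−) of vertical. The stimulus orientation
θ is drawn from one of three hidden *contexts* — a uniform, a negatively
skewed, and a positively skewed distribution over a seven-point grid
{−7.5, …, +7.5}° — and the context switches between trials with a hazard
rate h (a 3-state Markov chain with transition probability 1−h on the
diagonal and h/(N−1) off it). A probabilistic cue (modeled as a von
Mises-perturbed angle with concentration κ) indicates the current context,
and stimuli appear at two contrast levels with contrast-dependent sensory
noise, y ~ N(θ, σ²_c).

How should context-specific prior knowledge shape decisions when the context
itself is uncertain and unstable — and how can that influence be measured
from choice data? This package implements the full modeling stack for
researchers in perceptual decision-making and psychophysics:

- **`dynbias.task`** — a synthetic-task generator (context chains, stimuli,
  cues, measurements) and human-like choice simulators.
- **`dynbias.observer`** — a hierarchical Bayesian ideal observer that
  filters a belief p(C_t | cue history) through the context transition
  matrix, mixes the context-specific stimulus pmfs into a prior, combines it
  with the Gaussian likelihood of the noisy measurement, and reports
  p(θ > 0). Four knowledge-ablated variants isolate the value of each model
  component (pooled noise only → + context priors/cue reliability →
  + contrast-specific noise → + environmental dynamics).
- **`dynbias.bias`** — psychometric readouts: the point of subjective
  equality (PSE; the orientation eliciting 50% clockwise choices, from a
  logistic fit), the *aligned bias* (the context-appropriate PSE shift
  relative to the uniform context, positive when choices are pulled toward
  each context's likelier category), its evolution with the number of trials
  S since the last context switch, and Wilcoxon group-test utilities.
- **`dynbias.sdt`** — a Signal Detection Theory process model of choice:
  p(cw) = λ_c/2 + (1−λ_c)·Φ((θ + δ_u + C·δ_c)/σ_c), with contrast-specific
  spreads and lapse rates, ML-fitted with multi-start L-BFGS, 1000-fold
  nonparametric bootstrap CIs, and a four-variant comparison.
- **`dynbias.glm`** — a dynamic Bernoulli GLM: the logit of p(cw) combines
  orientation, its high-contrast interaction, context, the previous response
  and previous orientation, and a nonlinear bias function
  f(S, C) = 1/(1 + e^{γ·S·C}) fitted by a two-step γ grid search. The
  aligned-bias readout with history terms set to zero is
  bias(S) = −(w_C + w_S(0.5 − 1/(1+e^{γS})))/(w_θ + w_e·D_e).
- **`dynbias.reproduce` / the `dynbias` CLI** — seeded end-to-end runs
  (knowledge ladder, run-length statistics, bias-evolution surfaces).

## Worked example

```python
from dynbias.reproduce import reproduce_ladder
print(reproduce_ladder(n_trials=200_000, seed=1).round(4).to_string(index=False))
```

```
 variant  accuracy    se  step_gain  step_se
       1    0.6219 0.001        NaN      NaN
       2    0.6337 0.001     0.0118   0.0009
       3    0.6416 0.001     0.0079   0.0007
       4    0.6485 0.001     0.0069   0.0006
```

The least-informed observer (variant 1, decisions by the sign of the noisy
measurement) is correct on ~62% of trials; each added form of task knowledge
— cue reliability and context priors, contrast-specific noise, and finally
the context-switch dynamics — buys roughly another percentage point
(`step_gain`, with its paired Monte-Carlo SE).

Fitting the SDT process model to a 5,000-trial synthetic observer:

```python
from dynbias import (TaskConfig, simulate_trials, SDTParams,
                     SignalDetectionModel, generate_sdt_observer_choices)

trials = simulate_trials(TaskConfig.test_phase(5000, seed=42))
truth = SDTParams(shift_uniform=0.3, shift_context=0.8, sigma_high=2.0,
                  sigma_low=3.5, lapse_high=0.05, lapse_low=0.08)
data = generate_sdt_observer_choices(trials, truth, 7)
print(SignalDetectionModel(data).fit(seed=0).summary())
```

```
Signal Detection Theory choice model
  variant: 2-shift / 2-spread  (k = 6)
  n trials: 5000
  log-likelihood: -1677.808   AIC: 3367.616
  parameters:
     shift_uniform =  0.1571
     shift_context =  0.6820
        sigma_high =  1.9533
         sigma_low =  3.7580
        lapse_high =  0.0405
         lapse_low =  0.0574
```

`shift_context` (the model-implied aligned bias, truth 0.8°) and the
contrast-specific spreads (truth 2.0/3.5°) are recovered; CIs come from
`results.bootstrap(n_boot=1000)`.

A simulate-and-refit recovery run for the dynamic GLM (rising-bias observer
on a 4,000-trial volatile sequence, 20 replicates):

```python
from dynbias import GLMParams, recovery_experiment
rising = GLMParams(w_alpha=0.0, w_theta=0.35, w_e=0.35, w_C=-0.25,
                   w_S=-0.8, w_r=0.3, w_p=0.02, gamma=0.5)
rep = recovery_experiment(simulate_trials(TaskConfig.test_phase(4000, seed=11)),
                          [rising], n_reps=20, seed=5)
r = rep["observers"][0]
print(r["params"][r["params"].param.isin(["w_r", "w_p"])].round(3).to_string(index=False))
print("truth curve inside 68% recovery band at",
      f"{100*r['curve_coverage']:.0f}% of S values")
```

```
param  truth  mean    sd  mean_error
  w_r   0.30 0.316 0.075       0.016
  w_p   0.02 0.015 0.015      -0.005
truth curve inside 68% recovery band at 100% of S values
```

The history weights (previous response w_r, previous orientation w_p) come
back without systematic bias, and the ground-truth bias-evolution curve lies
inside the 68% band of recovered curves.

The same machinery is scriptable from the shell:

```sh
dynbias simulate-task --n-trials 10000 --seed 1 --out trials.csv
dynbias simulate-observer --variant 4 --n-trials 10000 --seed 1 --out trace.csv
dynbias fit-sdt choices.csv --boot 1000 --seed 1 --out params.json
dynbias fit-glm choices.csv --out glm.json
dynbias reproduce ladder --seed 1 --out ladder.csv
```

## Documentation

`docs/methods.md` describes the models, their assumptions, the default
parameter choices, the numerical methods, and known limitations.
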