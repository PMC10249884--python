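# Methods

This note documents the generative task model, the Bayesian ideal observer,
the two descriptive choice models, the estimation procedures, and the design
choices behind their implementation.

## Task model (synthetic data)

The generator emulates a dynamic-context 2AFC orientation discrimination
experiment.

**Context chain.** A 3-state first-order Markov chain with per-trial switch
probability (hazard) h: stay with probability 1−h, jump to either other
context with probability h/2. The first trial is uniform over contexts.
Contexts are coded −1 (negatively skewed), 0 (uniform), +1 (positively
skewed). Defaults follow the two experimental regimes: h = 6.3%
(training-like) and h = 42.5% (test-like). Across trials the
trials-since-switch count S (first trial of a run = 1) is geometric,
P(S=k) = h(1−h)^{k−1}, with mean 1/h — 15.9 and 2.35 trials for the two
regimes.

**Stimuli.** Orientations live on the seven-point grid {−7.5, −5, −2.5, 0,
2.5, 5, 7.5}°. Each context pmf puts 1/7 on the vertical orientation; the
remaining 6/7 is split 70:30 between positive and negative orientations in
the positively skewed context (30:70 negative, 50:50 uniform), uniformly
within sign. This construction (a) reproduces the 50/70/30% baseline
probabilities of "clockwise correct" among non-vertical trials, and (b)
keeps the marginal distribution of |θ| identical across contexts, so skew
changes response-category balance but not difficulty. The exact
per-orientation probabilities of the original experiment are not published;
this is the simplest pmf satisfying both printed constraints.

**Contrast and sensory noise.** Two contrast levels, drawn independently
with equal probability per trial by default (a blocked mode alternates runs
of eight trials). The sensory measurement is y = θ + N(0, σ²_c) with
contrast-specific scale. The printed noise parameters (10 high / 20 low for
the training-like regime; 2/5 for the test-like regime) are interpreted as
Gaussian SDs in degrees: under this reading the least-informed observer's
analytic accuracy is 62.3%, matching its simulated benchmark (~61.5%),
whereas reading them as variances predicts 82% — far off. The SD reading is
therefore frozen as the default.

**Cues.** Categorical mode: the cue equals the true context code with
probability `cue_validity` (1.0 or 0.8 in the experiment), else one of the
other two codes uniformly. Von Mises mode (used by the ideal observer): an
angle drawn around the context's angular label with concentration κ. Labels
sit at 0, 2π/3, 4π/3 rad, making all context pairs equally confusable.

**Human-like choices.** Two process simulators generate binary choices on a
trial sequence: Bernoulli draws from the SDT model's predicted p(cw), or
from the dynamic GLM's logistic predictor (including the previous *generated*
response, so history dependence is causal). History regressors reset at
block boundaries (48-trial blocks). Seeded integer inputs to the choice
simulators are internally decorrelated from the task-generation stream, so
passing the same integer to `simulate_trials` and a choice generator cannot
couple the switch draws to the simulated choices.

What the generator does *not* emulate: aborted/fixation-break trials,
session-level nonstationarity (learning, fatigue), per-subject sensitivity
tailoring, and any rendering of actual stimuli. Passing tests on this
generator therefore validates the estimators under the assumed model, not
robustness to those real-data features.

## Bayesian ideal observer

Per trial the observer (1) multiplies its context prior by the cue
likelihood and renormalizes; (2) mixes the context-specific stimulus pmfs
with the posterior belief to form a stimulus prior; (3) multiplies by the
Gaussian likelihood N(y; θ, σ²_c) on the orientation grid (computed in log
space with max-subtraction, so extreme measurements never underflow);
(4) reads out p_cw, the posterior mass on θ > 0; (5) chooses clockwise if
p_cw > 0.5, counter-clockwise if < 0.5, a seeded fair coin at exactly 0.5;
(6) propagates the belief through the transition matrix. The initial belief
is uniform. Belief arithmetic is linear-space with per-step renormalization;
all pmfs renormalize to 1 within 1e-10 (property-tested, and the sequential
filter is verified against exhaustive path-sum enumeration on 8-trial
inputs).

**Vertical-orientation mass.** Two readouts of step (4) are implemented.
The literal rule excludes the mass at θ = 0 from p_cw, which pushes every
near-symmetric posterior counter-clockwise and costs the least-informed
variant ~2.4 accuracy points. The `split_zero` rule shares that mass evenly
between the responses, making variant 1's decision exactly the sign of the
measurement. The knowledge-ladder variants default to `split_zero=True`
(it reproduces the documented variant-1 behaviour and the ~61.5% benchmark);
`decide()` itself defaults to the literal rule.

**Knowledge variants.** Variant 1: a single pooled noise level (the RMS of
the two generative SDs), a uniform stimulus pmf for every cue, and a flat
context prior each trial — its decision reduces to sign(y). Variant 2 adds
the true context pmfs and the cue reliability (κ). Variant 3 adds
contrast-specific noise. Variant 4 adds the transition dynamics with an
assumed hazard rate; with assumed hazard 2/3 the transition matrix is flat
and variant 4 reproduces variant 3 choice-for-choice (tested exactly).
Accuracy is scored against the sign of the true orientation, with vertical
trials scored 0.5 (the experiment gave random feedback there).

**Miscalibration sweeps.** The bias-evolution surfaces simulate a volatile
(test-like) generative task while sweeping the observer's *assumed* hazard
(10/20/50%) and assumed cue concentration (0.4/0.2/0.025) — the observer's
generative model, not the world, is varied. Simulated runs default to 10⁶
trials; the per-bin logistic PSE noise at that size is a few hundredths of
a degree for early bins and ~0.2° for the deep bins, and the qualitative
orderings (saturation decreasing in assumed hazard, increasing in assumed
κ; static variant flat; low-contrast bias above high-contrast) are resolved
with fixed seeds.

## Bias estimation

The PSE is −a/b from a binomial-logistic fit logit P(cw) = a + bθ on
per-orientation counts (Newton/IRLS with a 1e-10 ridge and step-halving;
cross-checked against statsmodels GLM to 1e-6). Standard errors are
delta-method. A logistic fit rather than linear interpolation is used
because the 7-point grid is sparse and choices near the extremes saturate.
Fits with non-positive slope, or cells with fewer than `min_trials` trials,
are flagged NaN rather than extrapolated.

Aligned bias defaults to the average over both skewed contexts,
0.5[(PSE_u − PSE_+) + (PSE_− − PSE_u)]; a `clockwise` readout
(PSE_u − PSE_+ only) is provided since the two-context difference is the
form used in the GLM readout. The sign convention makes context-appropriate
bias positive. Normalized bias is aligned bias divided by the fitted
orientation-estimate spread. The bias matrix additionally conditions on the
length of the run preceding the last switch; trials in a sequence's first
run (no previous run) are excluded.

## SDT process model

p(cw | θ, c, C) = λ_c/2 + (1−λ_c)·Φ((θ + δ_u + C·δ_c)/σ_c): six free
parameters — a uniform-context shift δ_u (the decision criterion is
absorbed here, fixing it at zero), a symmetric skew-context shift δ_c
(applied with the context's sign; δ_c *is* the model-implied aligned bias,
and is tested to agree with the psychometric readout), contrast-specific
spreads and lapse rates. A lapse is an unbiased guess. Fitting maximizes
the Bernoulli likelihood aggregated into (θ, contrast, context) binomial
cells (identical MLE, O(42) per evaluation) with bounded L-BFGS-B from 10
Latin-hypercube starts (bounds: |shift| ≤ 15°, σ ∈ [0.05, 60]°,
λ ∈ [0, 0.5]). CIs are percentile intervals from a 1000-fold
trial-resampling bootstrap warm-started at the point estimate; replicate
failures are counted, not dropped. The four-variant comparison ({1,2}
shift × {1,2} spread parameters, lapses always per-contrast) reports AIC
and a subsampled leave-one-out held-out likelihood (count configurable;
full 10,000-fold LOO is unnecessary for the synthetic recovery studies and
scales linearly if wanted).

## Dynamic Bernoulli GLM

Seven linear terms — intercept w_α, orientation w_θ (per deg, low
contrast), the additional high-contrast orientation weight w_e, context
w_C, the bias-function weight w_S, previous response w_r, previous
orientation w_p — plus the bias-function shape γ, for 8 parameters.

**Bias function.** f(S, C) = 1/(1 + e^{γ·S·C}), which equals 1/2 whenever
S = 0 or C = 0. Among the two readings the printed form admits, this is the
one under which differencing the PSE expression across the clockwise and
uniform contexts yields the closed-form bias readout (up to the sign of
w_S, which the fit absorbs):

    bias(S) = −(w_C + w_S(0.5 − 1/(1+e^{γS}))) / (w_θ + w_e·D_e),

history terms at zero, D_e = 1 at high contrast. Note the coding
consequence: a context-appropriate (positive-bias) observer carries
w_C < 0 under this convention.

**Identifiability.** The likelihood is exactly invariant under
(γ, w_S, w_α) → (−γ, −w_S, w_α + w_S); fits are canonicalized to γ ≥ 0
(the bias readout is invariant, so nothing observable changes). Two grid
regimes are excluded from the default search because the model degenerates
there on realistic S supports: for |γ| ≳ 3, f is numerically affine in C
for all S ≥ 1 (w_S and w_C trade off freely), and for |γ| ≲ 0.02, f is
constant over the observed S range (only γ·w_S is identified). The default
coarse grid is therefore 0 plus ±15 log-spaced magnitudes in [0.02, 2.5];
at γ = 0 the f column is exactly collinear with the intercept and the model
is fitted without it (w_S = 0). Step 2 refines on 21 points spanning the
coarse optimum's neighbours. The grid is a tuning range, not a physical
constant, and any grid can be passed explicitly.

**Fitting.** At fixed γ the weight fit is a convex logistic regression,
solved by Newton/IRLS with column scaling, monotone step-halving, and a
gradient tolerance of 1e-8 (agrees with statsmodels Logit to 1e-6 in the
tests; independent starts agree to 1e-6). Quasi-separation (diverging
weights) triggers a flagged ridge-penalized fallback with escalating
penalty. Rank-deficient designs raise.

**Recovery and uncertainty.** `recovery_experiment` simulates choice
datasets from ground-truth observers on a fixed trial sequence, refits
each, and reports per-parameter truth/mean/SD plus the percentile band of
recovered bias curves. At human-scale data
(~4,000 trials) the history weights are recovered essentially without bias,
while the *amplitude* of the recovered bias curve is right-skewed: γ is
weakly identified when the true curvature is mild, the fit occasionally
lands in quasi-linear or fast-saturating regimes, and the curve readout
then inflates. The recovery bands remain calibrated in the coverage sense
(the truth curve sits inside the 68% band), which is the designed readout;
point summaries of w_S or γ alone should not be interpreted at this data
scale. `DynamicGLMResults.parametric_bootstrap` provides the analogous
bands around a fitted model (simulate-from-fit and refit, 1,000 replicates
by default).

**Cross-validation and model comparison.** The dynamic-vs-static comparison
trains both models on trials 1–4 after a switch and scores total held-out
log-likelihood on trials ≥ 5; the static model simply lacks the f(S, C)
regressor (6 linear terms). History regressors are built on the full
sequence before masking, so every trial keeps its true previous
response/orientation. AIC = 2k − 2lnL is reported against the SDT model
with explicit parameter counts (8 vs 6); the counts are reported rather
than reconciled with any nominal "one extra parameter" accounting.

## Problem sizes and numerical defaults

Simulation sizes were chosen so that every check resolves its effect
comfortably: 2×10⁵ trials for the knowledge ladder (Monte-Carlo SE ~0.1
percentage points, paired across variants), 10⁶ trials for chain statistics
and bias surfaces, 100 simulate-and-refit replicates for the recovery
studies, 1000-fold bootstraps for CIs. All generators and fits are
deterministic given integer seeds.

## Known limitations

- The ideal observer operates on the discrete 7-point orientation grid
  only; no continuous-orientation support.
- The GLM's γ is reported per fit but is only weakly identified at a few
  thousand trials unless the bias evolution is strongly curved within the
  observed S range; use the curve bands, not γ̂ alone.
- The SDT variant comparison uses subsampled LOO, not exhaustive LOO.
- No hierarchical (multi-subject) fitting, regularization, or
  reward-asymmetry modeling; no stimulus rendering or eye-movement
  modeling.
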