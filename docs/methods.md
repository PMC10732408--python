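# Methods

This package analyses trial-by-trial fluctuations in binary perceptual
decision-making: the tendency of observers to alternate between an
*external mode*, in which choices track the presented stimulus, and an
*internal mode*, in which choices are attracted to the observer's own
recent history. It provides the behavioral metrics, the time-series
statistics, and a generative observer model, together with a simulator
that produces the synthetic cohorts on which everything is validated.

## Trial data

A trial table has one row per trial with a subject identifier, a grouping
identifier (study or session; the unit of random intercepts in all group
statistics), the stimulus, and the binary choice, plus optional
confidence, response time, and difficulty. Two stimulus dialects are
supported: `binary_category` (stimulus is one of two categories, 0/1) and
`signed_contrast` (stimulus is contrast-right minus contrast-left in
[-1, 1]; its sign defines the correct response, and zero-contrast trials
have no correct answer). Preprocessing follows common practice for the
corresponding public datasets: sessions are dropped when accuracy on
high-contrast trials (|contrast| >= 0.5) falls below 80%, groups are
dropped when pooled accuracy falls below 50%, response times and
confidence are z-scored within groups, and non-normalized quantities are
trimmed at 3 scaled MADs from the median (consistency constant 1.4826, so
3 MAD ~ 3 SD under normality). With a degenerate spread of zero only
entries equal to the center are kept, which retains constant data while
still rejecting gross outliers. Missing optional values propagate as
missing; trials without a recorded choice are rejected at read time.

## Congruence, mode, hazard

A choice is *stimulus-congruent* if it matches the stimulus category and
*history-congruent* if it repeats the previous choice (undefined at trial
1; zero-contrast trials have undefined stimulus-congruence but still count
for history). Sliding probabilities use centered windows of +/-5 trials;
a window's value is defined only when all 11 trials exist and are
non-missing, so every estimate pools the same number of Bernoulli draws
(incomplete edge windows are dropped, keeping the binomial variance
uniform along the series). The *mode* is p(stimulus-congruent) minus
p(history-congruent): positive = externally oriented. Mode-binned outcome
summaries use fixed left-closed 10% bins over [-1, 1], dropping bins with
under 0.5% of trials; mode-outcome regressions fit a linear plus
quadratic term with random intercepts per group (one grouping level; the
nested participant-within-study structure is out of scope). The empirical
hazard is the fraction of consecutive defined stimulus categories that
switch; for the randomized designs emulated here it is 0.5 by
construction.

## Serial dependence and the permutation null

Autocorrelation uses the biased (1/n) sample estimator, the convention of
standard statistical environments. Because congruence indicators are
binary, any marginal imbalance (e.g. a global response bias) produces
spurious positive autocorrelation; each series is therefore compared with
autocorrelations of randomly permuted data (100 iterations, seeded). For
stimulus-congruence the indicator itself is permuted (equivalent to
permuting trials). For history-congruence the *choice sequence* is
permuted and the repeat indicator recomputed: the repeat indicator of even
an i.i.d. biased coin is serially dependent through overlapping trials, so
permuting the indicator directly would understate the null and leave
bias-induced structure in the corrected coefficients. With the
choice-level null the corrected coefficient has exactly zero expectation
for any i.i.d. choice process, which the falsification suite (1,000
agents with 60-90% response bias) verifies; its per-lag band is judged
simultaneously across the 20 tested lags (Bonferroni), since twenty
pointwise 2-SE checks would false-alarm on more than half of runs.

The *individual lag* counts consecutive lags, from lag 1, at which fewer
than 50% of permuted coefficients exceed the true coefficient. Group-level
inference per lag is an intercept-only mixed model on the corrected
coefficients (one-sample t-test when only one group exists), optionally
with covariate autocorrelation profiles (task difficulty, stimulus
sequence) as fixed effects. Lagged logistic regressions and the
choice-history GLM (choice on stimulus, previous choice, and the
subject's centered mean choice as a general-bias regressor) are pooled
with cluster-robust inference by subject; perfect separation falls back
to a small L2 ridge (1e-4) with a warning and no p-values. A sliding
(+/-5 trial) response-bias series is available for fluctuation analyses.

## Spectral analysis

The sliding congruence probabilities, restricted to their complete-window
interior, are treated as unit-spaced series; frequencies are cycles per
trial on the grid k/n, k = 1..n/2. The periodogram is mean-removed (no
taper, no detrending) and smoothed with a single modified Daniell kernel
of width 50 (half-weight endpoints) applied circularly over the full
two-sided periodogram; the structural zero at f = 0 is replaced by the
mean of its neighbors before smoothing. This estimator reproduces R's
`spec.pgram(spans = 50, taper = 0)` to machine precision, which the test
suite pins against frozen reference values. The 1/f exponent is the
pooled slope of log10 density on log10 frequency below 0.1 cycles/trial
with random intercepts per group. Cross-spectra between the two
congruence probability series yield the phase (argument of the smoothed
cross-spectrum, mapped to [0, 2pi)) and squared coherence
|S_xy|^2 / (S_xx S_yy); coherence requires smoothing (span >= 2) to be
non-degenerate, and for independent series its expectation is ~1/span.
Band summaries below 0.1 cycles/trial average coherence arithmetically
and phase circularly.

## Psychometric function

Choice probabilities follow a lapse-rate error function,

    y_p = gamma + (1 - gamma - delta) * (erf((s_w + mu) / t) + 1) / 2,

with lower/upper lapses gamma, delta in [0, 0.5], bias mu, and threshold
t. The threshold enters as a divisor: larger t means a shallower curve,
which is the reading consistent with internal-mode processing showing
*worse* sensitivity (higher threshold) than external mode; the
multiplicative alternative would invert that relation. The weighted
signal is s_w = (s - 0.5) * D_b in the binary dialect — D_b an ordinal
evidence strength obtained by 7-level quantile binning of the trial's
difficulty, coded so that level 7 is the easiest — and the signed
contrast itself in the contrast dialect. Parameter boxes: gamma, delta in
[0, 0.5]; mu in [-5, 5] (binary) or [-0.5, 0.5] (contrast); t in
[0.5, 25] or [0.01, 1.5]. Fits maximize the Bernoulli likelihood with
L-BFGS-B from 8 Latin-hypercube starts plus the box center (both artifact
choices, as is the 20-trial minimum per conditioned fit) and can be
conditioned on the previous choice (prev0/prev1) or restricted by mode
(internal: mode < 0; external: mode > 0).

## The observer model

The bimodal-inference observer accumulates evidence about a binary hidden
state. On trial t the stimulus s_t yields a noisy observation
u = sigmoid(alpha * x) (x = s - 0.5 or the signed contrast) and hence a
log likelihood ratio LLR = log(u / (1 - u)) = alpha * x. The log prior
ratio carries over from the previous posterior through a hazard-rate
transition,

    psi_t = L_{t-1} + log((1-H)/H + e^{-L_{t-1}}) - log((1-H)/H + e^{L_{t-1}}),

which is odd and increasing in L_{t-1} for H < 0.5 and saturates at
+/- log((1-H)/H); H = 0.5 gives a flat prior. Likelihood and prior are
weighted by antiphase sinusoidal precision terms

    omega_LLR = a_LLR * sin(f t + p) + 1,   omega_psi = a_psi * sin(f t + p + pi) + 1,

and combine as L_t = LLR_t * omega_LLR + psi_t * omega_psi, with choice
probability y_p = sigmoid(zeta * L_t). The sine argument is taken
literally with f in radians per trial and t the 1-based trial index, so
f = 0.11 implies a period of 2 pi / f ~ 57 trials; the cycles-per-trial
reading (an extra 2 pi) would place the oscillation above the 0.1
cycles/trial analysis band and is inconsistent with the slow in-band 1/f
structure the model is meant to produce, but remains available by passing
a pre-scaled frequency. The initial prior is psi_1 = 0. Numerical guards:
hazard evaluated on (1e-6, 1 - 1e-6) with the exact limits at 0 and 1,
u clipped at 1e-12, y_p clipped at 1e-9 for the log loss.

Variants: M1 (full, 7 free parameters), M2 (a_psi = 0; 6), M3 (a_LLR = 0;
6), M4 (both amplitudes 0 — pure normative accumulation; alpha, H, zeta),
M5 (additionally H = 0.5; alpha, zeta). Frequency and phase are fixed,
not counted, where both amplitudes vanish. Parameter boxes: alpha [0, 5],
H [0, 1], amplitudes [0, 10], f [1/40, 1/5], p [0, 2 pi], zeta [1, 10].

### Fitting

Fitting minimizes the Bernoulli log loss with L-BFGS-B inside the boxes.
The surface is multimodal in (f, p), and the frequency basin narrows as
1/n, so the default search combines 10 Latin-hypercube starts (amplitude
starts drawn from [0, 2]; very large starting amplitudes put most
precision weights below zero and strand the local search) with warm
starts: the nested no-oscillation variant is fitted first and its
solution crossed with a frequency grid (6-20 points, denser for longer
series) times four phases. All starts are screened with short runs; the
best few are optimized fully and the incumbent polished at tight
tolerance. AIC = 2k + 2 * loss. Fits are deterministic given a seed.

A structural caveat: the likelihood depends on alpha and zeta only
through their product wherever the prior operates in its linear regime
(psi ~ (1 - 2H) L for small |L|), so the (alpha, zeta) split is
identified only by the prior's saturation. At the group posterior-mean
parameters |L| stays well inside the linear regime and the profile
likelihood along the ridge (c * alpha, zeta / c) is flat to within ~1 nat
over a several-fold range of alpha: alpha is effectively not recoverable
from binary-dialect data of this size, while H, f, and the amplitudes
recover well. The parameter-recovery suite documents this honestly
rather than asserting a precision the model cannot support.

## Simulator

Cohorts are simulated agent by agent: i.i.d. stimuli (fair Bernoulli
categories, or a symmetric 7-level contrast grid with levels
{0, ±0.0625, ±0.125, ±0.25, ±1}), one forward pass (the latents depend
only on the stimuli), choices drawn from y_p, and |L_t| recorded as the
simulated confidence. Trial counts are uniform on [300, 700] per agent.
All randomness derives from a single seed through spawned substreams, so
cohorts are bit-reproducible. Default parameters are the group
posterior-mean estimates of the fitted model (human set: alpha = 0.5,
H = 0.45, a_LLR = 0.5, a_psi = 1.44, f = 0.11, p = 2.72, zeta = 4.63;
a mouse set is provided for the contrast dialect); per-agent jitter
(truncated normals) is available but off by default, since the reference
conditions are defined by those printed means. Besides the fitted
variants, the `no_accumulation` configuration pins H at 0.5 while keeping
the oscillation parameters — the control in which history effects must
vanish — and model-free null agents (random, globally biased,
stimulus-only, always-repeat) support falsification tests. What the
generator does not emulate: between-study heterogeneity of tasks and
parameters, learning or fatigue trends, finite inter-trial timing —
passing tests therefore validate the estimators and the model mechanics
under the stated conditions, not robustness to real-data heterogeneity.

The reproduction script (`scripts/acceptance.py`) simulates 500-agent
cohorts, a size at which the pooled statistics are stable to well within
their reporting tolerances while the full pipeline runs in seconds.

## Known limitations

- Group statistics use a single random-intercept level; nested designs
  are out of scope.
- The alpha/zeta trade-off above: point estimates of alpha from
  binary-category data should not be interpreted individually.
- Cohorts simulated at the fixed posterior-mean parameters understate the
  serial-dependence statistics of a heterogeneous population: with all
  agents at H = 0.45 the prior transmits only 1 - 2H = 10% of the
  previous posterior, so pooled history-congruence and the
  history-related spectral/autocorrelation summaries are weaker than in
  cohorts whose hazard rates spread toward lower values. Per-agent jitter
  reproduces the stronger statistics but is deliberately not the default.
- No exponential-decay fits to autocorrelation curves, no confidence
  intervals on spectra, no Bayesian posterior sampling over model
  parameters.
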