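# Methods

This note documents the models, estimators, and synthetic-data design
behind `sgn400`: what is computed, under which assumptions, with which
defaults, and what the passing tests do and do not establish about real
data.

## The Sentence Gestalt model

**Task.** The SG model maps a word sequence to the event it describes,
represented as a set of role-filler vectors: for each argument of the
event, the concatenation of (i) a length-F binary semantic feature vector
for the filler word, (ii) a one-hot identifier over the R thematic roles,
and (iii) a one-hot frame index over K possible event frames. The model
approximates `P(<role, filler> | w_1..w_t)` and is *predictive*: it is
probed about all arguments of the sentence after every word, including
arguments whose words have not yet appeared.

**Architecture.** The update network is a learned input embedding (desk
default 32 units; full scale 600) feeding a one-layer LSTM whose hidden
state is the gestalt `sg_t` (desk 64; full scale 1,200), initialized at
the zero vector. The query network combines `sg_t` with a probe vector
through a tanh hidden layer and emits per-unit logistic activations over
the full role-filler layout; cross-entropy against the complete
role-filler target is the training loss, giving the outputs a per-feature
probability interpretation. A probe is a role-filler vector with either
the role part zeroed (role probe) or the filler part zeroed (filler
probe); the frame index is retained in both kinds, identifying which
event is interrogated. Only arguments actually present in the sentence
are probed.

**Training regime.** Adamax, learning rate 0.01, mini-batches of 32
sentences, sentences shuffled once and the batch list split 90/10 into
training and validation, early stopping on validation loss with patience
10 inside the epoch cap (desk 40; full scale 150); the best-validation
weights are returned. Loss aggregation — where the procedure is
underdetermined — is: cross-entropy summed over output units, averaged
over the probes of a word, summed over words, averaged over the batch.
Probe order is frame-major with role probe before filler probe; it is
fixed purely for reproducibility. Only sentences of 6–15 words with at
most 8 frames enter training, limiting deeply nested subordinate events.

**Filler features.** Real applications binarize pretrained embeddings
(any word2vec-text file is accepted; a unit is 1 iff its raw value
exceeds 0 — the sign threshold gives presence/absence semantics to a
direction-ambiguous rounding rule). The synthetic environment uses seeded
Gaussian embeddings binarized the same way (F = 16 by default). The
lexical-filler variant replaces semantic features with word-identity
one-hots over the lexicon (output width = lexicon size + R + K), probing
for *which word* fills a role rather than which features it has.

**Semantic Update.** `SU_t = (1/H) Σ_j |sg_t[j] − sg_{t−1}[j]|`, with
`sg_0 = 0`. The default read-out is the LSTM hidden vector only; the cell
state is an implementation internal, but a hidden+cell read-out is
available since the field's usage is not settled. Because `sg_0 = 0`, the
sentence-initial SU equals the mean absolute activation after word one;
it is retained in the series, and scoring offers a flag to drop it.

## The language model

Identical embedding/LSTM/post-recurrent stack, softmax over the lexicon,
trained on the raw token sequences with the frame annotation discarded
(Adamax at learning rate 0.002, otherwise the same regime). Surprisal is
reported in natural-log units; a regression on surprisal is invariant to
the log base up to coefficient scale. A sentence-start symbol conditions
the first word, and conditioning is per sentence (stimuli are presented
sentence by sentence). Scoring floors probabilities at 1e−12 with a
warning. The internal-update series applies the SU formula to the LSTM
hidden trajectory (the state after each input word; the row preceding the
first word is the zero vector, exactly as for SU, so the two measures are
computed by the same code path). Both networks are implemented directly
in NumPy (forward pass, backpropagation through time, and Adamax), which
keeps every arithmetic step inspectable and the package free of
deep-learning-framework dependencies.

## Micro-language

A sentence describes one event. Transitive template:
`[time] the <agent> <action> the <patient> [manner] [in the <location>] .`
(6–11 tokens including the terminator, so all sentences pass the training
filter); 25% of utterances are stative: `the <patient> is in the
<location> .`. The default world has 6 agents with a 4:1 frequency range,
4 actions in two semantic families (household: *opened/closed*; food:
*ate/cooked*) with disjoint patient sets `{door, window, box, jar}` vs
`{cake, bread, apple, soup}` and disjoint location sets
`{hallway, garage}` vs `{kitchen, garden}`. Within an action the patient
distribution is 0.85/0.05/0.05/0.05 — the cloze knob. Roles use a 6-label
PropBank-style subset (A0, V, A1, AM-LOC, AM-MNR, AM-TMP); the full
26-label inventory is the default for naturalistic corpora.

The battery contrasts are defined structurally:

* **Congruity** — patient from the action's support vs a patient that
  never occurs with it (other family), same sentence frame.
* **Cloze** — the 0.85 patient vs a 0.05 patient of the same action.
* **Position** — mean SU at the 2nd–3rd words vs the last two
  pre-terminator words of sampled sentences (the sentence-initial token
  is excluded because its SU reflects the zero initial state).
* **Priming** — in the stative frame, the target location after a prime
  patient it co-occurs with in events vs after a prime from the disjoint
  family. Bare two-word prime-target strings are not used: they lie far
  outside the training distribution of a sentence-trained model, so the
  relatedness effect is probed in the minimal frame the model actually
  learned.

What passing the battery shows: Semantic Update in a trained SG model
moves in the N400-like direction for these manipulations *in this world*,
across independently seeded trainings (one-sided exact sign tests). It
does not show effect magnitudes comparable to human data, nor behavior on
naturalistic text, which would require corpus-scale training.

## ERP and EEG generators

The single-trial generator is the exact generative twin of the analysis
model: `n400 = β₀ + β_base·baseline + β_SU·(−SU) + β_surp·surp + u_subj +
s_subj·(−SU) + w_word + ε`, with independent Gaussian random terms
(defaults: subject intercept SD 0.5, by-subject SU slope SD 0.1, word
intercept SD 0.5, residual SD 1.0) and i.i.d. standard-normal baselines.
SU enters negated — the N400 is a negative deflection, so reported SU
coefficients are positive on the flipped axis. Planted fixed effects
default to baseline −0.4, SU 0.2, surprisal 0.15 at 12 subjects × 600
words. Predictors (and the baseline) are z-scored inside the generator
before entering the linear predictor, so planted coefficients are per-SD
effects — the scale on which such coefficients are conventionally
reported — and are directly comparable to the analysis stage's
standardized estimates; a raw-scale mode exists for degenerate-case
contract tests. All latent draws come from independent spawned RNG
streams and are returned for inspection.

The time-course generator plants a parametric effect curve (triangle or
boxcar; default triangle centered at 400 ms, half-width 150 ms) with
per-electrode gains, optional subject/word intercepts and a baseline
effect, and reports the curve's true fractional-area latency from a
0.01 ms grid. The generators emulate only the statistical structure the
analysis assumes — no EEG spectra, artifacts, or electrode geometry — so
passing recovery tests validates the estimators, not the realism of the
noise model.

## Mixed-effects estimation

The analysis model is the generator's structure: fixed intercept,
baseline covariate ("variable of no interest", not subtracted from the
response), and the predictors of interest; crossed random effects —
by-subject intercepts, by-subject slopes for predictors of interest,
by-word intercepts — all mutually independent (no intercept-slope
correlation). Estimation is maximum likelihood, not REML, so that
likelihood-ratio tests and AIC between models differing in fixed effects
are valid; k counts fixed effects + variance components + the residual
variance.

The estimator profiles β and σ² out of the likelihood and evaluates the
profiled deviance through the Cholesky factor of the q × q Woodbury
system `I + Λ Z'Z Λ` (q = subjects + words + slope effects), after a
one-time computation of Z'Z, Z'X, Z'y; a Nelder-Mead search over the log
variance ratios (started at log 0.5, tolerances 1e−6/1e−9) finishes the
fit. Each deviance evaluation is O(q³) regardless of the trial count,
which is what makes the 200-replicate calibration batteries feasible.
statsmodels' MixedLM (ML, variance-components formulation, BFGS) is the
independent oracle in the test suite; the two agree in log-likelihood and
coefficients to numerical tolerance on moderate problems but MixedLM is
orders of magnitude slower at the simulation sizes.

Inference on fixed effects uses Satterthwaite-style degrees of freedom:
`df_i = 2c_i²/(g_i' A g_i)` with `c_i` the squared SE as a function of
the variance parameters (log ratios and log σ²), `g_i` its
finite-difference gradient, and `A` twice the inverse finite-difference
Hessian of the −2 log-likelihood. With 12 subjects and a random slope the
normal approximation demonstrably under-covers (≈86% for a nominal 95%
CI in our recovery simulations); the Satterthwaite CIs restore ≈94%
coverage. The normal approximation remains the recorded fallback when the
numeric derivatives fail. Non-convergence triggers a fallback ladder
(drop slopes → intercepts only) recorded in the result.

Model comparison: χ² = 2Δ logLik clipped at zero, df = parameter-count
difference, p from the χ² upper tail; ΔAIC = AIC(smaller) − AIC(larger),
positive favoring the larger model. Nested comparisons hold the random
structure fixed (a random slope may be present without its fixed effect,
so "adding SU" changes exactly one parameter). Benjamini–Hochberg
correction is applied across the cells of one analysis — the predictor
p-values of a table set, all timepoints of a time course, or all
electrode × window cells of a topography.

## Time course and latency

Time-resolved analysis fits one mixed model (same structure, baseline
covariate included) per timepoint of an ROI-averaged signal, or per
50 ms non-overlapping window per electrode for topographies (span
remainders are truncated with a warning; failed cells are excluded from
the FDR family with a log entry). Fractional-area latency treats the
effect curve β(t) as piecewise linear, rectifies it (inserting kinks at
interpolated zero crossings; signed area is available as an option since
the published convention is ambiguous), and returns the earliest time at
which cumulative area reaches the requested fraction, inverting the
within-segment quadratic exactly — this matches dense-grid numerical
integration to well under 1 ms. The default analysis window is 0–650 ms.
Per-subject effect curves drop the subject-level random terms (within one
subject they are constants), reducing each timepoint to OLS across words;
per-subject latencies are compared by a paired two-sided t test, with
undefined latencies excluded and zero-variance differences handled
explicitly.

## Problem sizes and numerical choices

Desk-scale defaults (used throughout the tests and the demo): 400
training sentences, 32/64-unit networks, 40 SG epochs / 15–30 LM epochs,
12 subjects. Calibration batteries use: 50 replicates at 12 × 600 for CI
coverage; 200 replicates at 16 × 150 for LRT size and 50 at 12 × 400 for
power and AIC direction; 100 null replicates at 12 subjects × 80 words ×
2 electrodes for the topographic false-positive rate; 12 seeds for the SU
battery; 5,000 sentences for the bigram-chain LM calibration. These sizes
were chosen once for statistical adequacy at desk-scale runtimes. Further
numerics: probability floor 1e−12 in scoring and Bernoulli losses;
variance ratios bounded in log-space at [−30, 20]; residual sums of
squares floored at 1e−300 so noise-free fits remain finite; forget-gate
bias initialized at 1; Glorot-uniform weight initialization; all
generators and trainers consume `numpy` Generator streams derived from
named seeds (the demo spawns per-stage seeds from one base seed and
writes them to its manifest).

## Known limitations

* Networks are trained per sentence (no cross-sentence context) and at
  desk scale; nothing here estimates how SU behaves after corpus-scale
  training on naturalistic text.
* The LM's internal-update series measures its first word against the
  zero state (sharing the SU convention) rather than against the
  post-start-symbol state; downstream analyses that care can drop
  sentence-initial tokens.
* Random effects are modeled and generated as independent; correlated
  intercept-slope structures are not implemented.
* Satterthwaite df rely on finite-difference curvature of the profiled
  deviance; at variance-boundary optima they can be unstable, in which
  case the code falls back to the normal approximation and says so in the
  result metadata.
* The micro-world's SU–surprisal correlation (~0.6) is much higher than
  in large naturalistic corpora; the demo therefore exhibits stronger
  marginal-vs-joint attenuation than a full-scale study would.
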