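# Methods

## The task being emulated

A two-alternative orientation-averaging judgment. On each trial 30 Gabor
patches are flashed in rapid succession (nominally 16.7 ms each) and the
observer reports whether their overall orientation is tilted left
(counterclockwise, negative angles) or right (clockwise, positive
angles) of vertical. Frame orientations are iid draws from
N(±offset, 22.5²) degrees, truncated to [−45°, 45°]; the signed offset
sets the stimulus category and its magnitude sets the difficulty. Each
session holds 480 trials in 4 runs of 4 blocks of 30; blocks alternate
between *pre-cue* and *post-cue* type. A directional cue (left/right,
valid with probability 2/3) or a neutral cue (25% of trials) is
presented — before the stream in pre blocks, after it in post blocks.
Because the frames mask one another and the post cue arrives well after
stimulus offset, a post cue can only act on the decision stage; a pre
cue could in principle act on sensory processing as well. The analysis
chain is designed around this asymmetry.

## Synthetic-data generator

* **Truncation by rejection.** Out-of-bounds draws are redrawn rather
  than clipped; clipping would put probability atoms on ±45° that the
  modelled distribution does not have.
* **Cue-first construction.** The cue identity is drawn first (uniform
  left/right for predictive trials), then the stimulus category equals
  the cue with probability = validity. This gives exactly the stated
  cue-validity semantics and 50/50 stimulus marginals in expectation.
  By default neutral status and validity are per-trial Bernoulli draws;
  an `allocation="exact"` mode enforces the per-block counts instead.
  Whether the original procedure enforced counts exactly is not
  determinable from its description; neither mode is claimed as the
  original.
* **Per-subject offsets** are drawn from N(7.49°, 3.85°²) truncated to
  (0°, 45°), emulating the spread of staircase outcomes across subjects.
  Half the subjects start with a pre block, half with a post block.
* **Reproducibility.** A single root seed is expanded into independent
  per-subject child streams (`numpy` `SeedSequence.spawn`), so trial
  tables are bit-identical across runs with the same seed and
  per-subject streams do not interact. Orientations are rounded to the
  4-decimal precision of the CSV dialect at generation time, making the
  write→read round trip an exact identity.

### Staircase

The difficulty-setting staircase is 2-down-1-up (converging on ~70.7%
correct): the offset shrinks by the current step after two consecutive
correct responses and grows after every error; the run stops after 10
direction reversals and the threshold is the mean tested offset at the
last 6. Step schedule: 8° initially, halved at each of the first three
reversals (8/4/2/1°), starting offset 20°, offsets clamped to [0°, 40°]
(the ceiling must stay below the 45° stimulus bound). A gentler initial
schedule (4° halved to 0.5°) was tried first and systematically stalled
several degrees above the 70.7% point — the first reversal tends to
happen far from threshold, after which the steps are already too small
to travel the remaining distance within 10 reversals. The 8°-start
schedule tracks a brute-force accuracy sweep of the same observer to
within the 2° tolerance used in the tests. A `max_trials` guard turns
non-convergence (e.g. an observer whose accuracy never crosses the
convergence point) into an explicit error.

## Simulated observers

All three mechanisms are deterministic decision rules over the frame
stream; exact ties at the criterion resolve to "left" so that identical
inputs always produce identical responses. Neutral-cue trials bypass
every cue-dependent transformation.

* **Criterion shift** — respond "right" iff mean(θ₁…θ₃₀) > criterion for
  the trial's (cue time, cue identity) condition; defaults +4/−4/0° for
  pre left/right/neutral and +6/−6/0° for post. Optional internal noise
  (Gaussian, degrees, default 0) is added to the frame average; it is
  used by the study pipeline to obtain a non-degenerate psychometric
  function, while the packaged simulations run noise-free.
* **Early weighting** — frame *i* (1-based) receives weight 8 − *i* for
  *i* ≤ 6 when its orientation sign matches the cued direction, weight 1
  otherwise; the decision compares Σwθ/Σw to 0. A 0° frame carries no
  cue-consistent sign and keeps weight 1. The aggregate's denominator is
  a genuine choice (only the weighting itself is prescribed); Σw is the
  default, Σwθ/n is selectable via `normalize="n"` — the two never
  disagree on the response sign since they differ by a positive factor.
* **Ambiguous bias** — each frame is displaced toward the cue by
  240·φ(θ | 0, 6²) degrees (φ the normal density), so the displacement
  peaks at ≈15.96° at vertical and is negligible beyond ~25°; the
  decision compares the transformed mean to 0.

The parameters of the last two mechanisms are chosen to produce response
bias of roughly the same order as the criterion mechanism, so the three
are distinguished by the *shape* of their reverse-correlation
signatures, not by their overall bias.

## Analysis chain

### Signal detection

The right-tilted stimulus is the target: HR = P(respond right | right),
FAR = P(respond right | left); d′ = Φ⁻¹(HR) − Φ⁻¹(FAR),
c = −½(Φ⁻¹(HR) + Φ⁻¹(FAR)), so positive c is a "left" bias. Boundary
rates (0 or 1) are moved to 1/(2N) and 1 − 1/(2N) — the standard
correction, flagged in the output. The accuracy-maximising criterion is
ln(a)/d′ with a the prior odds of left vs right given the cue (2 at
validity 2/3); cue effects are left-minus-right contrasts, so
Δc_optimal = ln 2/d′_left − ln ½/d′_right. Natural log is used
throughout (the likelihood-ratio convention). The normal quantile comes
from `scipy.stats.norm.ppf` (documented accuracy well below 1e−9).

### Reverse correlation

Every fit is a maximum-likelihood logistic regression with intercept and
a single slope, response coded right = 1, with **no regularisation** —
deliberately, so that perfect separation produces the extreme
coefficients the repair step exists for. Temporal profiles regress the
response on each frame's orientation **in radians** (30 univariate fits;
a single 30-predictor variant is available behind `multivariate=True`
but is not used by the packaged analyses). Feature profiles regress the
response on the per-trial count of frames inside the closed band
[θ − 5°, θ + 5°] for every whole degree θ in [−40°, 40°] (81 fits).
Optimal-usage benchmarks rerun the same regressions on the stimulus
category instead of the response.

Degenerate fits (separation warnings from the fitter, non-finite
estimates, or |β| > 10 per radian/count) are flagged and replaced by the
inverse-distance-weighted mean of the nearest non-flagged β on each side
(one-sided at the array boundary); replacements always draw on original
non-flagged values and every substitution is logged. A profile whose 81
fits are all degenerate raises rather than repairs.

Timecourse smoothing (trailing 2-frame moving average) exists for
display only and is never applied before statistics. Profile slopes are
OLS slopes of β against θ.

One bookkeeping identity worth stating: the feature analysis of a full
study runs 81 regressions × 10 conditions (6 cue-identity: pre/post ×
left/right/neutral; 4 validity: pre/post × valid/invalid, fit on their
own trial subsets, not derived from the identity profiles) × subjects —
24,300 fits for 30 subjects. A related small caveat: the band counts of
one trial sum to 11 × 30 over all θ only when every orientation is a
whole degree (a closed interval of length 10 contains 11 integers only
when centred on one); continuous orientations give 10 × 30. The identity
is therefore exercised on whole-degree streams.

### Reliability

A per-subject effect (by default Δc = c_left − c_right) is recomputed on
the odd- and even-indexed trials of each subject; the Pearson
correlation of the halves across subjects is r_half, projected to full
length by Spearman-Brown (2r/(1+r)). The attenuation ceiling
√(r_full,pre · r_full,post) bounds the observable correlation between
the pre and post effects; the pipeline reports it next to the observed
correlation. Subjects on which the effect is undefined in a half (empty
design cell) are excluded with a warning.

### Model experiment and subject exclusion

The criterion-shift model is run on the trial streams themselves
(deterministically), followed by the full 10-condition feature analysis.
A subject is excluded when more than 5 of its 486 identity-condition
fits (81 × 6) are degenerate — the exclusion threshold is a package
choice, configurable and logged, since only the existence of such an
exclusion rule, not its cutoff, is prescribed by the design. Excluded +
retained always sums to the input subject count.

## Study pipeline observer

For the end-to-end replica the criterion observer gets internal noise of
10° and per-subject criterion magnitudes: base (4° pre / 6° post) + a
*shared* latent jitter (SD 2°, one draw per subject applied to both cue
times) + an independent per-cue-time jitter (SD 1°). The shared
component is what makes the pre and post effects of a subject correlate
— the scenario the reliability analysis is built to quantify; with
purely independent jitter the observed pre/post correlation would be
zero by construction and the attenuation ceiling would have nothing to
bound. With these defaults the observer's sensitivity lands near the
d′ ≈ 1.1 implied by a 70.7%-accuracy staircase.

## Problem sizes

The packaged simulations default to 10⁵ trials per cue (the signature
analyses assert directional contrasts against Monte-Carlo standard
errors, which are comfortably resolved at that size), 30 subjects × 480
trials for the study replica, and 8 staircase runs for the threshold
estimate. All sizes are plain parameters.

## What the generator does and does not emulate

It reproduces the statistical skeleton of the task: stimulus
distributions, cue validity and neutral rates, block alternation, trial
counts, and staircase logic. It does **not** model lapses, sequential
dependencies, learning or fatigue across blocks, reaction times, or any
display/timing physics. Consequently, passing tests demonstrate that the
analysis chain recovers the properties of *known* generative mechanisms
at realistic trial counts — not that any particular mechanism describes
a given real dataset, and real data will show features (e.g. robust
averaging of extreme orientations, recency effects) that the idealised
observers here do not produce unless simulated explicitly.

## Known limitations

* The univariate reading of the per-frame temporal regressions is the
  primary one; with temporally iid stimulus frames the univariate and
  multivariate slopes estimate the same quantity, but they would diverge
  under frame-correlated stimuli.
* The repair of degenerate betas (inverse-distance neighbour weighting)
  is one reasonable interpolation among several; the repair log makes
  every substitution auditable.
* The staircase threshold is a small-sample estimator by design (10
  reversals); its run-to-run SD of 1–2° is inherent, which is why tests
  and the acceptance script average several runs.
* Group-level inference (t-tests, ANOVA) is intentionally left to
  standard statistical packages; the pipeline emits the per-condition
  quantities those tests consume.
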