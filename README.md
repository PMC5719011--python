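# cueshift

Does expecting a stimulus change what we *see*, or only what we *decide*?
`cueshift` is a simulation and analysis toolkit for a cued
orientation-averaging psychophysics design built to answer that question.
In the task it emulates, an observer watches a rapid stream of 30 Gabor
patches (one video frame each) and judges whether their average
orientation tilts left (counterclockwise) or right (clockwise) of
vertical. A probabilistic cue — valid on 66.67% of trials, neutral on
25% — is shown either *before* the stream (a pre cue, which could in
principle bias sensory processing) or *after* it (a post cue, which can
only act on the decision stage). Comparing how the two cue times shape
behaviour separates sensory-signal accounts of expectation from
decision-criterion accounts.

## What's inside

* **`synthetic_data`** — generates complete sessions with the task's
  statistical structure: 480 trials in 4 runs × 4 alternating pre/post
  blocks × 30 trials; frame orientations drawn from a normal with SD
  22.5°, mean ±offset, truncated by rejection to ±45°; per-subject
  offsets from the group distribution N(7.49°, 3.85°²); plus the adaptive
  2-down-1-up staircase (10 reversals, threshold = mean of the last 6)
  that titrates the offset. A bit-exact trial CSV dialect is provided.
* **`observers`** — three candidate expectation mechanisms as
  deterministic decision rules: a **criterion shift** (compare the frame
  average to condition criteria, ±4° pre / ±6° post / 0° neutral), **early
  weighting** (frame *i* ≤ 6 of cue-congruent sign weighted 8 − *i*), and
  an **ambiguous bias** (orientation θ displaced by ±240·φ(θ | 0, 6²)
  toward the cue, i.e. only near-vertical frames move).
* **`sdt`** — signal detection metrics with the right-tilted stimulus as
  target: d′ = Φ⁻¹(HR) − Φ⁻¹(FAR), c = −½(Φ⁻¹(HR) + Φ⁻¹(FAR)), the
  accuracy-maximising criterion ln(a)/d′, and left-minus-right cue
  effects (Δc, Δd′, Δc_optimal).
* **`revcorr`** — psychophysical reverse correlation by maximum-likelihood
  logistic regression: temporal profiles (30 per-frame fits on radians),
  feature profiles (81 fits on counts of frames within ±5° of each whole
  degree in [−40°, 40°]), optimal-usage benchmarks (regressing the
  stimulus instead of the response), perfect-separation detection with
  neighbour-weighted repair, display smoothing and profile slopes.
* **`reliability`** — odd/even split-half reliability of any per-subject
  effect, the Spearman-Brown projection r_full = 2r/(1 + r), and the
  attenuation ceiling r_max = √(r₁·r₂) on the observable pre/post
  correlation.
* **`pipeline` / `cueshift` CLI** — orchestration: mechanism-signature
  simulations, the criterion-shift model experiment with its
  10-condition feature analysis (810 regressions per subject), and the
  full generate → respond → analyse → report chain.

## Worked example

Run the full study replica on 12 simulated subjects (criterion-shift
observers with 10° internal noise and subject-specific criteria):

```python
import json
from cueshift import pipeline

report = pipeline.run_full_analysis(pipeline.StudyConfig(n_subjects=12, seed=7))
print(json.dumps(report["mean_effects"], indent=2, default=float))
print(json.dumps(report["reliability"], indent=2, default=float))
```

prints

```
{
  "post": {
    "delta_c": 1.2119038243102163,
    "delta_dprime": 0.1146552571207277,
    "delta_c_optimal": 1.2544896844191549
  },
  "pre": {
    "delta_c": 0.7715624026529704,
    "delta_dprime": 0.24365546053818002,
    "delta_c_optimal": 1.4722064525527756
  }
}
{
  "r_half_pre": 0.3920663791474334,
  "r_half_post": 0.3949816870212718,
  "r_full_pre": 0.5632869021483777,
  "r_full_post": 0.5662894225725399,
  "r_maximum": 0.5647861671113056,
  "r_observed": 0.5322339267042753,
  "n_subjects": 12
}
```

Reading the numbers: post cues move the decision criterion more than pre
cues (Δc_post ≈ 1.21 > Δc_pre ≈ 0.77 z-units — these observers shift by
6° after the stimulus but only 4° before it), while sensitivity is
essentially unaffected (Δd′ near 0). Both shifts fall short of the
accuracy-maximising shift (Δc_optimal). The split-half reliabilities of
the two effects, projected to full length by Spearman-Brown, cap the
observable pre/post correlation at r_max ≈ 0.56; the correlation actually
observed (≈ 0.53) sits just under that ceiling, as expected when one
shared mechanism drives both effects.

The same chain is scriptable from the shell:

```sh
cueshift simulate --out trials.csv --subjects 12 --seed 7
cueshift respond --in trials.csv --model criterion --out responded.csv
cueshift analyze sdt --in responded.csv --out metrics.csv
cueshift analyze reliability --in responded.csv --out reliability.json
cueshift signatures --trials 100000 --out sigs/     # mechanism signatures
cueshift model-experiment --in responded.csv --out model/
cueshift run --seed 7 --out study/                  # everything above
```

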