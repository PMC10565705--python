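# serialdep

Serial dependence and distractor bias in orientation adjustment
experiments: a tested analysis pipeline for trial-level behavioural data
from interleaved discrimination + adjustment paradigms, with a synthetic
observer model that gives every inference stage a ground truth.

## The problem

In continuous-report ("adjustment") tasks, the orientation a person
reproduces is systematically biased by recently seen orientations — pulled
toward the probe shown on the previous trial (attractive serial
dependence) and, in some conditions, pushed away from task-irrelevant
distractors. Both biases follow the shape of the first derivative of a
Gaussian (DoG) in Δ, the circular difference between the prior orientation
and the current probe. Measuring these effects well requires: strict trial
and participant exclusion rules; a regression family that can express no
effect, a single bias, a mixture of attraction and repulsion, and their
interaction with experimental condition; principled model selection; and a
separate analysis of discrimination reaction times to quantify attentional
capture by the distractor.

`serialdep` implements that chain for experiments of this design: two
sessions of ~1000 trials per observer, a peripheral distractor on 50% of
trials (orientations 0°–160° in 20° steps, probe within ±65° of it), and
blocked *random* vs *fixed* distractor locations.

## The model family

Adjustment errors *y*, pooled over participants, are fit against the DoG
basis f(Δ; w) = Δ·exp(−Δ²/2w²):

| model | mean structure |
|-------|----------------|
| Δ0 | y = a |
| Δ1 | y = a + b·f(Δ; w) |
| Δ2 | y = a + b₁·f(Δ; w₁) + b₂·f(Δ; w₂), w₂ ≥ 2w₁ |
| Δ1×loc | y = a + b₁·f(Δ; w) + b₂·f(Δ; w)·Loc |
| Δ2×loc | y = a + b₁·f(Δ; w₁) + b₂·f(Δ; w₂) + b₃·f(Δ; w₁)·Loc + b₄·f(Δ; w₂)·Loc |

Each width is searched on a 10°–80° grid (1° steps), keeping the
assignment with the highest r²; models are ranked by BIC and reported as
ΔBIC relative to the worst model (larger = better; ≥2 positive, ≥6 strong
evidence). Effect sizes are *peak biases*: the extremum b·w·e^(−½) of a
fitted component, in degrees, positive for attraction. Discrimination RT
is modelled with an inverse-Gaussian mixed model (identity link; fixed
effects location, distractor presence, interaction; participant random
intercept, estimated by adaptive Gauss–Hermite quadrature), and the
capture effect is RT(present) − RT(absent) per condition.

## A worked example

```python
import serialdep as sd

observers = sd.make_cohort(15, seed=1)                     # 1.4° attraction, −0.5° tails
trials = sd.simulate_experiment(sd.DesignParams(), observers, seed=1)
clean, report = sd.preprocess(sd.annotate_trials(trials))

delta, error, loc = sd.prepare_predictor(clean, "distractor")
comparison = sd.compare_models(sd.fit_model_family(delta, error, loc))
print(comparison.table)
```

Running `python examples/simulate_and_fit.py` (which does the above for
both predictors) prints:

```
=== prev_probe (n = 25398) ===
 model       bic  delta_bic evidence
    d0 104730.12       0.00    worst
    d1 104609.23     120.89   strong
    d2 104585.78     144.34   strong
d1xloc 104618.81     111.31   strong
d2xloc 104604.34     125.78   strong
  delta1: peak bias +1.35° at Δ = 23°
  delta2: peak bias -0.52° at Δ = 80°

=== distractor (n = 12801) ===
 model      bic  delta_bic evidence
    d0 52966.87       4.51 positive
    d1 52949.07      22.31   strong
    d2 52953.75      17.63   strong
d1xloc 52958.24      13.14   strong
d2xloc 52971.38       0.00    worst
  delta1: peak bias -0.49° at Δ = 31°
```

Read: errors are pulled ~1.35° toward the previous probe at small Δ with a
weak repulsive tail at large Δ (two-component model wins), and pushed
~0.5° away from the simultaneous distractor (single repulsive component
wins, no location interaction) — the fitted peaks recover the generative
observer within sampling error. The other scripts in `examples/` walk
through the exclusion report, the RT capture analysis, and the
similarity-split interference test; `serialdep --help` exposes the same
stages as a CLI (`simulate`, `preprocess`, `fit`, `rt`, `run`) for use on
trial tables in CSV/TSV form.

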