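"""Attentional capture and the inverse-Gaussian mixed model of RT.

Computes the per-condition capture effect (RT on distractor-present minus
distractor-absent trials) and fits the RT regression: inverse-Gaussian
response, identity link, fixed effects for location condition (random=0),
distractor presence (absent=0) and their interaction, plus a participant
random intercept.
"""

import serialdep as sd

observers = sd.make_cohort(15, seed=3)
trials = sd.simulate_experiment(sd.DesignParams(), observers, seed=3)
clean, _ = sd.preprocess(sd.annotate_trials(trials))

per, group = sd.capture_effect(clean)
print("capture effect, RT(present) − RT(absent):")
print(group.round(1).to_string(index=False), "\n")

result = sd.fit_rt_model(clean)
print(f"mixed model ({result.method}, n = {result.n_obs}, "
      f"{result.n_groups} participants):")
print(result.terms.round(3).to_string(index=False))
print(f"random-intercept SD: {result.sigma_u:.1f} ms; IG shape λ: {result.shape:.0f}")

# A positive distractor effect with a negative interaction reproduces the
# signature pattern: capture is present in both conditions but smaller
# when the distractor's location is fixed, while the positive location
# effect slows even distractor-absent trials in fixed blocks (a cost that
# reads as proactive suppression of the expected location).
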