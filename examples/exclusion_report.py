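"""Apply the trial- and participant-exclusion rules and inspect the report.

Trials fall to three rules (discrimination RT outside 200–1000 ms, a
two-step adjustment-error rule of ±45° then 1.5·IQR fences per
participant, adjustment responses slower than 10 s); participants fall to
three more (>25% flagged trials, circular report/probe correlation < 0.4,
discrimination accuracy or mean RT beyond 3 group SD).
"""

import serialdep as sd

observers = sd.make_cohort(10, seed=7)
trials = sd.simulate_experiment(sd.DesignParams(), observers, seed=7)
annotated = sd.annotate_trials(trials)

clean, report = sd.exclude_trials(annotated)
kept, report = sd.exclude_participants(clean, report)

print("per-criterion trial removals:")
for crit, n in report.counts.items():
    print(f"  {crit:>20s}: {n}")
print(f"retained {report.n_retained}/{report.n_input} trials "
      f"({report.overall_retained_fraction:.1%})")
print(f"participants kept: {len(kept)}; excluded: {report.excluded_participants or 'none'}")

# A trial can carry several flags, so the per-criterion counts may exceed
# the total removals; ~2% removal is typical for this observer model
# (lapses and inverse-Gaussian RT tails drive most of it).
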