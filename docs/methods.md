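# Methods

This note records the statistical model, the generative model used for
validation, and the numerical and design choices that were genuinely open,
in enough detail to re-derive every stage.

## Orientation arithmetic

Orientations live on [0°, 180°); signed differences Δ = prior − current
are wrapped into (−90°, 90°], with the ±90° boundary mapped to +90° by
convention (so `wrap_diff` is antisymmetric everywhere except at exactly
90° apart). Positive Δ with positive error therefore means attraction
toward the prior orientation. Previous-trial linkage never crosses a
session boundary. Annotation is done on the *presented* trial sequence, so
a trial whose response is later excluded still serves as the n−1 context
for its successor — exclusion targets responses, not stimuli. Re-running
`annotate_trials` on a filtered table instead links across retained trials;
the pipeline deliberately annotates before exclusion.

## Exclusion rules

Trial level: (1) discrimination RT outside 200–1000 ms; (2) adjustment
errors in a fixed two-step order — |error| > 45° first, then values beyond
[Q1 − 1.5·IQR, Q3 + 1.5·IQR] among each participant's surviving errors
(quartiles by linear interpolation; per-participant fences, matching the
per-participant 25% criterion below; single pass, never iterated);
(3) adjustment responses slower than 10 s. The three rules are evaluated
independently and any flag removes the trial. Participant level:
>25% flagged trials; circular correlation between reported and presented
orientation below 0.4 (angles doubled to map the 180°-periodic domain onto
the circle, then the sine-deviation circular correlation coefficient —
rotation-invariant, so a constant report offset does not trigger it);
discrimination accuracy or mean RT beyond 3 SD of the group mean (two-
sided, both measures, group statistics over all participants before any
removal at this step). Note the 3-SD screen is structurally inert for
cohorts below ~11 participants: with sample SD the largest attainable
z-score is (n−1)/√n.

Exact idempotence of trial exclusion holds for the RT, ±45° and slow-
adjustment rules; the IQR fence, recomputed on a cleaned table, may
re-flag a sub-percent residue of boundary cases (measured ≈0.08% on
simulated data). The fence is intentionally not iterated to convergence.

## The DoG regression family

The basis is f(Δ; w) = Δ·exp(−Δ²/2w²) — *not* peak-normalised, so
coefficients stay on the regression's natural scale; `peak_bias` converts
a (coefficient, width) pair to degrees via b·w·e^(−½), attained at Δ = w.
"Width" is the Gaussian's σ, searched on a 10°–80° grid in 1° steps (the
grid bounds are the design's stated search range; the step is this
package's choice). Fits are ordinary least squares on pooled single-trial
data; standard errors are unclustered by default (a participant-clustered
option exists). The location dummy is random = 0, fixed = 1, and the
interaction models contain *no* location main effect — condition can scale
the bias amplitude but cannot shift the mean error. Widths are shared
between conditions within a model (the interaction scales amplitude, not
shape).

Two-component fits search width pairs jointly under the constraint
w₂ ≥ 2·w₁. The constraint is an identifiability device, not cosmetics:
nearby-width pairs span nearly collinear columns whose difference mimics a
width-derivative basis, and an unconstrained search routinely returns such
pairs with enormous opposite-signed coefficients — an excellent *curve*
whose per-component "peak biases" are meaningless. Requiring an octave of
scale separation (the repulsive tail lives at distinctly larger Δ than the
attractive core) keeps components interpretable while still nesting every
single-component solution: for any Δ1 width w, the pair (w, 2w) with b₂=0
or (10, w) with b₁=0 reproduces it, so r²(Δ2) ≥ r²(Δ1) ≥ r²(Δ0) holds
exactly. Ties in the width search break toward smaller w₁, then smaller
w₂. The grid search itself runs on precomputed Gram matrices (closed-form
normal equations for every candidate width assignment in one pass over the
data); the winning assignment is refit with statsmodels OLS, which is the
source of all reported coefficients and standard errors. A perfect fit
(RSS = 0) is assigned BIC = −∞ rather than an error, and a zero-variance
response defines r² = 0.

An important caveat established by simulation: with a weak second
component (peak ≈ 0.5° against ≈ 8° response noise at n ≈ 30,000), the
second *width* is intrinsically poorly determined (asymptotic SE ≈ 17°)
even though both *peak biases* are recovered to ~0.1° — peak size and
width trade off along a near-flat likelihood ridge. Downstream analyses
should treat fitted widths as descriptive, peaks as the effect size.

## Model comparison

BIC = n·ln(RSS/n) + k·ln(n), dropping the constant n·(ln 2π + 1) shared by
all models on the same observations; k counts the intercept plus one per
slope term (searched widths are not counted, consistent with reporting the
family as linear regressions). ΔBIC is reported relative to the *largest*
BIC — worst model 0, larger is better — with ≥2 labelled "positive" and ≥6
"strong" evidence. Comparing fits with different n is refused.

## Similarity split and coefficient contrasts

Distractor-present trials are split at |previous probe − distractor| = 45°
(configurable). For the contrast of Δ2 components between halves, the
widths are estimated once on the pooled eligible trials and the per-half
coefficients are refit on that shared basis, so the contrasted
coefficients are commensurate; the z-test is z = (b_a − b_b)/√(SE_a² +
SE_b²) with a two-sided normal p. Alternatives were measured: per-half
width searches leave the contrast unbiased but overdispersed (width
re-estimation noise is invisible to the coefficient SEs), and a joint
similarity-interaction regression performs similarly to the shared-basis
refit. Two caveats: (i) power is modest at realistic effect sizes — for a
0.5° repulsion difference at ~8,000 trials per half and 8° noise, the
expected z is ≈2.3 even with widths known, so single experiments of this
size detect such interference less than ~two-thirds of the time; (ii) in
the *similar* half, Δ to the distractor is correlated with Δ to the
previous probe by construction, so a same-trial distractor kernel leaks
into the previous-probe components there — a genuine confound of the
split design (present in real data too), which the interference
simulations isolate by switching that kernel off.

## RT analyses

The capture effect is each participant's mean RT(present) − RT(absent) per
location condition, on correct trials; the group summary uses a t-based
95% CI. The mixed model is y ~ InverseGaussian(μ, λ) with identity link,
μ = β₀ + β₁·fixed + β₂·present + β₃·fixed·present + u_participant,
u ~ N(0, σᵤ²). No installed Python package estimates this family/link with
a random effect, so the marginal likelihood is maximised directly:
adaptive Gauss–Hermite quadrature (9 nodes) with the conditional mode of
each participant's intercept found by damped Newton (the identity-link
derivatives are ∂logf/∂μ = λ(y−μ)/μ³, ∂²logf/∂μ² = −λ(3y−2μ)/μ⁴; raw
Newton steps from u = 0 can overshoot by orders of magnitude because the
curvature grows like μ⁻⁴, so steps are clipped and μ kept positive).
Adaptivity matters: with ~10³ trials per participant the conditional
posterior of an intercept is a few ms wide, far narrower than its prior,
and fixed-node quadrature biases σᵤ down by a factor ~2. The likelihood
implementation is verified against brute-force numerical integration
(agreement ~3e−7) and, at σᵤ = 0, against the statsmodels inverse-Gaussian
GLM. Optimisation is BFGS on (β, log σᵤ, log λ) with convergence judged by
the scaled gradient (BFGS's own status flag trips on the numeric-gradient
noise floor); standard errors come from the inverse numerical Hessian,
t statistics use residual df = n − 4, and CIs are ±1.96·SE — large-sample
conventions appropriate to five-figure trial counts. Degenerate inputs
short-circuit: constant RT returns the exact least-squares solution;
a single participant drops the random intercept and fits the plain GLM.
A two-stage summary fit (per-participant OLS, averaged) exists as an
explicitly labelled fallback and is never substituted silently.

## The synthetic observer

The generator reproduces the experimental *design* — 2 sessions × 1000
trials, distractor on 50% of trials at 0°–160° in 20° steps at one of 4
locations (one fixed location per participant in fixed blocks), probe
drawn within ±65° of the distractor (sampled directly from the conditional
distribution, which equals rejection sampling of a uniform), each session
split into one random and one fixed block with order counterbalanced
across participants and sessions (block order and size are not dictated by
the design description; equal halves with alternating order is this
package's choice, configurable) — and a response model: report = probe
+ attractive DoG of Δ to the previous probe − repulsive DoG of the same Δ
− repulsive DoG of Δ to the current distractor + N(0, motor σ), wrapped,
replaced by a uniform guess with the lapse probability. Kernel amplitudes
are peak biases in degrees so generative and recovered quantities are
commensurate. Defaults: attraction 1.4° at width 25°, prev-probe repulsion
0.5° at 60°, distractor repulsion 0.5° at 30° (effect sizes anchored to
the magnitudes this literature reports), motor σ 8°, lapse 2% — together
giving mean |error| ≈ 7–9° and a few % trial exclusions. RTs are
inverse-Gaussian (shape λ = 11,700 ms ⇒ within-participant SD ≈ 100 ms at
a 490 ms mean) with additive condition effects (+4.1 location, +18.5
distractor, −11 interaction, in ms) and per-participant baselines drawn
N(490, 50²) by `make_cohort` — the generative random intercept.
Correctness is Bernoulli(0.97). An optional `repulse_boost_similar` adds
repulsion from the previous probe only when the distractor is within 45°
of it, the generative form of the interference effect. Per-(participant,
session) random substreams make tables reproducible and insensitive to
cohort size changes.

What the simulator does **not** emulate: stimulus rendering and contrast/
spatial-frequency manipulations, eye movements, learning or fatigue across
blocks, sequential RT dependencies, and non-DoG bias shapes. Passing
recovery tests therefore demonstrates that the inference chain is correct
*for data of this structure*, not that real data satisfy the model.

## Validation scale

The heavyweight studies run at: 200 replicates each for model-selection
consistency (n = 20,000 null; n = 50,000 two-kernel); 50 seeds of
two-kernel recovery at ~29,000 pooled trials each; 60 interference
replicates at ~7,700 trials per half; 100 RT-coverage replicates of
20-observer, ~18,000-trial experiments. These sizes match the paradigm's
own scale while keeping the full suite in a few minutes of CPU.

## Known limitations

Pooled OLS ignores participant heterogeneity in bias amplitude (only the
RT stage models a random effect); the second DoG width is weakly
identified at realistic effect sizes (see above); the similarity split
inherits the distractor/previous-probe confound of the design; and the
evidence labels attached to ΔBIC are conventional thresholds, not
calibrated error rates.
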