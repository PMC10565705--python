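"""Synthetic observers and experiments: the generative twin of the analysis.

Every inference stage in this package (exclusion rules, DoG-basis model
comparison, RT mixed model) is validated by parameter recovery, so the
simulator is first-class code.  It reproduces the *design* of the
experiment — interleaved discrimination (Landolt C + optional peripheral
Gabor distractor) and central orientation-adjustment tasks, two sessions
of ~1000 trials, distractor on half the trials at one of nine orientations
(0°–160° in 20° steps), probe within ±65° of the distractor, and blocked
random vs. fixed distractor location — together with a parameterised
response model:

* the adjustment report is the probe orientation plus an attractive
  derivative-of-Gaussian (DoG) pull toward the previous trial's probe, a
  repulsive DoG push away from the previous probe at larger orientation
  differences, and a repulsive DoG push away from the current trial's
  distractor, plus Gaussian motor noise and occasional uniform lapses;
* discrimination RT is inverse-Gaussian with an additive (identity-scale)
  mean structure in distractor presence, location condition and their
  interaction, so the RT analysis stage is exactly well-specified;
* discrimination correctness is Bernoulli.

Amplitudes are expressed as *peak* biases in degrees (the extremum of the
bias curve), the quantity the analysis stage reports, so generative and
recovered effect sizes are directly comparable.

No stimulus rendering is modelled: the simulator emits trial tables, not
images.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .orientation import wrap_diff, wrap_orientation
from .trials import TRIAL_COLUMNS

__all__ = [
    "DesignParams",
    "ObserverParams",
    "dog_kernel",
    "simulate_experiment",
    "make_cohort",
    "simulate_dog_dataset",
]


@dataclass(frozen=True)
class DesignParams:
    """Experimental design of a simulated session.

    Defaults follow the target paradigm: 2 sessions × 1000 trials,
    distractor on 50% of trials at orientations 0°–160° in 20° steps and
    at one of 4 peripheral locations, probe within ±65° of the distractor,
    and each session split into one "random" and one "fixed" location
    block of equal size.  ``block_order`` controls which condition comes
    first ("random_first", "fixed_first", or "alternate" to counterbalance
    across participants and sessions).
    """

    n_sessions: int = 2
    trials_per_session: int = 1000
    p_distractor: float = 0.5
    distractor_orientations: tuple = tuple(np.arange(0.0, 180.0, 20.0))
    probe_delta_range: float = 65.0
    n_locations: int = 4
    block_order: str = "alternate"

    def validate(self) -> None:
        if not (0.0 <= self.p_distractor <= 1.0):
            raise ValueError("p_distractor must be in [0, 1]")
        if self.trials_per_session < 1 or self.n_sessions < 1:
            raise ValueError("trials_per_session and n_sessions must be >= 1")
        if self.trials_per_session % 2:
            raise ValueError("trials_per_session must be even (two equal blocks)")
        ori = np.asarray(self.distractor_orientations, dtype=float)
        if ori.size == 0 or np.any((ori < 0) | (ori >= 180)):
            raise ValueError("distractor_orientations must lie in [0, 180)")
        if not (0 < self.probe_delta_range <= 90):
            raise ValueError("probe_delta_range must be in (0, 90]")
        if self.n_locations < 1:
            raise ValueError("n_locations must be >= 1")
        if self.block_order not in ("random_first", "fixed_first", "alternate"):
            raise ValueError("block_order must be random_first|fixed_first|alternate")


@dataclass(frozen=True)
class ObserverParams:
    """Generative parameters of one simulated participant.

    Bias amplitudes are peak biases in degrees; widths are the σ of the
    Gaussian envelope of the DoG kernel.  Repulsive amplitudes are given
    as positive magnitudes and applied with negative sign.  Defaults are
    anchored to effect sizes typical of attended-probe serial dependence
    (attraction peaking ~1.4° at small Δ, a ~0.5° repulsive tail at large
    Δ) and a ~0.5° repulsion from the simultaneous distractor; RT fixed
    effects mirror a ~490 ms baseline with small location/distractor
    effects and a negative interaction.

    ``repulse_boost_similar`` adds extra repulsive prev-probe amplitude on
    trials whose distractor is within ``similarity_threshold`` of the
    previous probe — the interference effect probed by the similarity
    split; default 0 (no interference).
    """

    attract_amp_prev_probe: float = 1.4
    attract_width_prev_probe: float = 25.0
    repulse_amp_prev_probe: float = 0.5
    repulse_width_prev_probe: float = 60.0
    repulse_amp_distractor: float = 0.5
    repulse_width_distractor: float = 30.0
    repulse_boost_similar: float = 0.0
    similarity_threshold: float = 45.0
    motor_noise_sd: float = 8.0
    lapse_rate: float = 0.02
    rt_base: float = 490.0
    rt_distractor_effect: float = 18.5
    rt_location_effect: float = 4.1
    rt_interaction: float = -11.0
    rt_shape: float = 11700.0
    adjustment_rt_mean: float = 1600.0
    adjustment_rt_shape: float = 42600.0
    p_correct_discrimination: float = 0.97

    def validate(self) -> None:
        for name in ("attract_width_prev_probe", "repulse_width_prev_probe",
                     "repulse_width_distractor", "motor_noise_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (0.0 <= self.lapse_rate < 1.0):
            raise ValueError("lapse_rate must be in [0, 1)")
        if self.rt_base <= 0 or self.rt_shape <= 0 or self.adjustment_rt_mean <= 0:
            raise ValueError("RT parameters must be positive")
        if not (0.0 <= self.p_correct_discrimination <= 1.0):
            raise ValueError("p_correct_discrimination must be in [0, 1]")


def dog_kernel(delta, amplitude: float, width: float):
    """Peak-normalised derivative-of-Gaussian bias kernel, in degrees.

    ``amplitude · (Δ/width) · exp(½ − Δ²/(2·width²))`` — an odd function of
    Δ whose extremum equals ±``amplitude`` exactly, attained at Δ = ±width.
    """
    if width <= 0:
        raise ValueError("width must be > 0")
    delta = np.asarray(delta, dtype=float)
    out = amplitude * (delta / width) * np.exp(0.5 - delta**2 / (2.0 * width**2))
    return out if out.ndim else float(out)


def _block_conditions(design: DesignParams, participant: int, session: int) -> np.ndarray:
    half = design.trials_per_session // 2
    if design.block_order == "random_first":
        random_first = True
    elif design.block_order == "fixed_first":
        random_first = False
    else:  # counterbalance across participants and sessions
        random_first = (participant + session) % 2 == 0
    first, second = ("random", "fixed") if random_first else ("fixed", "random")
    return np.array([first] * half + [second] * half)


def _simulate_session(
    design: DesignParams,
    obs: ObserverParams,
    participant: int,
    pid: str,
    session: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    n = design.trials_per_session
    condition = _block_conditions(design, participant, session)
    present = rng.random(n) < design.p_distractor
    ori_set = np.asarray(design.distractor_orientations, dtype=float)
    dori = np.full(n, np.nan)
    dori[present] = rng.choice(ori_set, size=present.sum())

    # fixed blocks use one location per participant; random blocks draw uniformly
    fixed_loc = rng.integers(design.n_locations)
    dloc = np.full(n, np.nan)
    is_fixed = condition == "fixed"
    dloc[present & is_fixed] = fixed_loc
    n_rand = int((present & ~is_fixed).sum())
    dloc[present & ~is_fixed] = rng.integers(design.n_locations, size=n_rand)

    # probe: uniform in [0,180), but within ±probe_delta_range of the
    # distractor when one is shown (drawn directly from the conditional law)
    probe = rng.uniform(0.0, 180.0, size=n)
    r = design.probe_delta_range
    probe[present] = wrap_orientation(
        dori[present] + rng.uniform(-r, r, size=int(present.sum()))
    )

    # response bias from previous probe (within session) and current distractor
    prev_probe = np.roll(probe, 1)
    bias = np.zeros(n)
    d_prev = wrap_diff(prev_probe[1:], probe[1:])
    bias[1:] += dog_kernel(d_prev, obs.attract_amp_prev_probe, obs.attract_width_prev_probe)
    bias[1:] -= dog_kernel(d_prev, obs.repulse_amp_prev_probe, obs.repulse_width_prev_probe)
    if obs.repulse_boost_similar:
        both = present.copy()
        both[0] = False
        sim = np.zeros(n, dtype=bool)
        sim[both] = (
            np.abs(wrap_diff(prev_probe[both], dori[both])) < obs.similarity_threshold
        )
        d_prev_sim = wrap_diff(prev_probe[sim], probe[sim])
        bias[sim] -= dog_kernel(
            d_prev_sim, obs.repulse_boost_similar, obs.repulse_width_prev_probe
        )
    d_dist = wrap_diff(dori[present], probe[present])
    bias[present] -= dog_kernel(d_dist, obs.repulse_amp_distractor, obs.repulse_width_distractor)

    reported = wrap_orientation(probe + bias + rng.normal(0.0, obs.motor_noise_sd, n))
    lapse = rng.random(n) < obs.lapse_rate
    reported[lapse] = rng.uniform(0.0, 180.0, size=int(lapse.sum()))

    rt_mean = (
        obs.rt_base
        + obs.rt_location_effect * is_fixed
        + obs.rt_distractor_effect * present
        + obs.rt_interaction * (is_fixed & present)
    )
    disc_rt = rng.wald(rt_mean, obs.rt_shape)
    adj_rt = rng.wald(obs.adjustment_rt_mean, obs.adjustment_rt_shape, size=n)
    correct = rng.random(n) < obs.p_correct_discrimination

    return pd.DataFrame(
        {
            "participant_id": pid,
            "session": session,
            "trial_index": np.arange(1, n + 1),
            "location_condition": condition,
            "distractor_present": present,
            "distractor_orientation": dori,
            "distractor_location": dloc,
            "probe_orientation": probe,
            "reported_orientation": reported,
            "discrimination_correct": correct,
            "discrimination_rt": disc_rt,
            "adjustment_rt": adj_rt,
        }
    )


def simulate_experiment(
    design: DesignParams,
    observers: list[ObserverParams],
    seed: int,
) -> pd.DataFrame:
    """Simulate a full experiment; same seed → identical table.

    One independent random substream per (participant, session), spawned
    from ``seed``, so adding a participant does not perturb the others'
    draws.
    """
    design.validate()
    if not observers:
        raise ValueError("at least one observer is required")
    for obs in observers:
        obs.validate()
    width = max(2, len(str(len(observers))))
    frames = []
    for p, obs in enumerate(observers):
        pid = f"S{p + 1:0{width}d}"
        for s in range(1, design.n_sessions + 1):
            rng = np.random.default_rng(np.random.SeedSequence([int(seed), p, s]))
            frames.append(_simulate_session(design, obs, p, pid, s, rng))
    out = pd.concat(frames, ignore_index=True)
    return out[TRIAL_COLUMNS]


def make_cohort(
    n_participants: int,
    seed: int,
    rt_base_sd: float = 50.0,
    base: ObserverParams | None = None,
    **overrides,
) -> list[ObserverParams]:
    """A cohort of observers sharing bias parameters but with individual
    RT baselines drawn N(rt_base, rt_base_sd²) — the generative random
    intercept of the RT mixed model."""
    base = replace(base or ObserverParams(), **overrides)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xC0]))
    bases = np.maximum(rng.normal(base.rt_base, rt_base_sd, n_participants), 100.0)
    return [replace(base, rt_base=float(b)) for b in bases]


def simulate_dog_dataset(
    n: int,
    seed: int,
    attract_peak: float = 0.0,
    attract_width: float = 25.0,
    repulse_peak: float = 0.0,
    repulse_width: float = 60.0,
    noise_sd: float = 8.0,
    p_fixed: float = 0.5,
):
    """Regression-stage generator: (delta, error, loc) triples with a known
    bias curve and Gaussian noise.

    Directly generates the quantities the DoG regression consumes (Δ
    uniform on (−90, 90], binary location, error = attractive kernel −
    repulsive kernel + noise), bypassing the trial loop; used for
    model-selection consistency and null-calibration studies where tens of
    thousands of replicated datasets are needed.
    """
    rng = np.random.default_rng(seed)
    delta = rng.uniform(-90.0, 90.0, n)
    loc = (rng.random(n) < p_fixed).astype(int)
    error = rng.normal(0.0, noise_sd, n)
    if attract_peak:
        error += dog_kernel(delta, attract_peak, attract_width)
    if repulse_peak:
        error -= dog_kernel(delta, repulse_peak, repulse_width)
    return delta, error, loc
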