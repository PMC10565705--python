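"""Trial- and participant-level exclusion rules.

Trials are removed when (1) discrimination RT falls outside 200–1000 ms,
(2) the adjustment error is an outlier under a two-step rule — first
|error| > 45°, then, among the surviving errors of the same participant,
values beyond the Tukey fences [Q1 − 1.5·IQR, Q3 + 1.5·IQR] — or (3) the
adjustment response took longer than 10 s.  Participants are removed when
more than 25% of their trials are flagged, when the circular correlation
between reported and presented orientation is below 0.4, or when their
discrimination accuracy or mean RT lies more than 3 SD from the group
mean.

The IQR fence is computed per participant (quartiles by linear
interpolation) and applied in a single pass, never iterated.  The
group-SD screen uses group statistics over *all* participants, before any
removal at that step, and is two-sided on both accuracy and mean RT.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TRIAL_FLAGS",
    "PARTICIPANT_FLAGS",
    "ExclusionReport",
    "exclude_trials",
    "circular_correlation",
    "exclude_participants",
    "preprocess",
]

TRIAL_FLAGS = ["rt_out_of_range", "error_gt_45", "error_iqr_outlier", "adjustment_too_slow"]
PARTICIPANT_FLAGS = ["too_many_outliers", "low_circular_correlation", "discrimination_outlier"]

RT_RANGE_MS = (200.0, 1000.0)
ERROR_CAP_DEG = 45.0
IQR_FACTOR = 1.5
ADJUSTMENT_MAX_MS = 10_000.0
MAX_OUTLIER_FRACTION = 0.25
MIN_CIRCULAR_CORRELATION = 0.4
GROUP_SD_LIMIT = 3.0


@dataclass
class ExclusionReport:
    """Bookkeeping of every removal, attributable flag by flag."""

    trial_flags: pd.DataFrame  # boolean columns TRIAL_FLAGS, aligned to the input index
    n_input: int = 0
    n_retained: int = 0
    counts: dict = field(default_factory=dict)  # per-criterion trial counts
    participant_flags: dict = field(default_factory=dict)  # pid -> list of flags
    flagged_fraction: dict = field(default_factory=dict)  # pid -> fraction flagged
    retained_fraction: dict = field(default_factory=dict)  # pid -> fraction retained
    excluded_participants: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    @property
    def overall_retained_fraction(self) -> float:
        return self.n_retained / self.n_input if self.n_input else float("nan")

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "overall_retained_fraction": self.overall_retained_fraction,
            "trial_criterion_counts": dict(self.counts),
            "participant_flags": {k: list(v) for k, v in self.participant_flags.items()},
            "flagged_fraction": dict(self.flagged_fraction),
            "retained_fraction": dict(self.retained_fraction),
            "excluded_participants": list(self.excluded_participants),
            "warnings": list(self.warnings),
        }


def exclude_trials(trials: pd.DataFrame) -> tuple[pd.DataFrame, ExclusionReport]:
    """Apply the three trial-level criteria; return (clean table, report).

    Requires an annotated table (``adjustment_error`` present).  The three
    criteria are evaluated independently; a trial may carry several flags.
    Within criterion 2 the order is fixed: the ±45° cap strictly precedes
    the IQR fence, and the fence is computed only over each participant's
    surviving (|error| ≤ 45°) trials.
    """
    if trials.empty:
        raise ValueError("cannot run trial exclusion on an empty table")
    if "adjustment_error" not in trials.columns:
        raise ValueError("trials must be annotated (missing adjustment_error)")

    rt = trials["discrimination_rt"].to_numpy(dtype=float)
    err = trials["adjustment_error"].to_numpy(dtype=float)
    adj_rt = trials["adjustment_rt"].to_numpy(dtype=float)

    flags = pd.DataFrame(False, index=trials.index, columns=TRIAL_FLAGS)
    flags["rt_out_of_range"] = (rt < RT_RANGE_MS[0]) | (rt > RT_RANGE_MS[1])
    step1 = np.abs(err) > ERROR_CAP_DEG
    flags["error_gt_45"] = step1
    flags["adjustment_too_slow"] = adj_rt > ADJUSTMENT_MAX_MS

    iqr_flag = np.zeros(len(trials), dtype=bool)
    pids = trials["participant_id"].to_numpy()
    for pid in pd.unique(pids):
        sel = pids == pid
        survivors = sel & ~step1
        if survivors.sum() < 4:
            continue  # too few points for a meaningful fence
        q1, q3 = np.percentile(err[survivors], [25.0, 75.0])  # linear interpolation
        iqr = q3 - q1
        lo, hi = q1 - IQR_FACTOR * iqr, q3 + IQR_FACTOR * iqr
        iqr_flag[survivors] = (err[survivors] < lo) | (err[survivors] > hi)
    flags["error_iqr_outlier"] = iqr_flag

    removed = flags.any(axis=1)
    clean = trials.loc[~removed.to_numpy()].copy()

    report = ExclusionReport(trial_flags=flags)
    report.n_input = len(trials)
    report.n_retained = len(clean)
    report.counts = {c: int(flags[c].sum()) for c in TRIAL_FLAGS}
    report.counts["any"] = int(removed.sum())
    grp = flags.groupby(trials["participant_id"]).apply(lambda f: f.any(axis=1).mean())
    report.flagged_fraction = {str(k): float(v) for k, v in grp.items()}
    report.retained_fraction = {k: 1.0 - v for k, v in report.flagged_fraction.items()}
    for pid, frac in report.retained_fraction.items():
        if frac == 0.0:
            report.warnings.append(f"all trials removed for participant {pid}")
            warnings.warn(f"all trials removed for participant {pid}")
    return clean, report


def circular_correlation(x, y) -> float:
    """Circular correlation between two orientation samples in [0, 180).

    Angles are doubled to map the 180°-periodic orientation domain onto
    the full circle, then the sine-deviation circular correlation
    coefficient is computed:

        r = Σ sin(a − ā)·sin(b − b̄) / √(Σ sin²(a − ā) · Σ sin²(b − b̄))

    with ā, b̄ the circular means.  Invariant under rotation of either
    sample; r = 1 when y = x + const.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("samples must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    a = np.deg2rad(2.0 * x)
    b = np.deg2rad(2.0 * y)
    for name, ang in (("x", a), ("y", b)):
        if np.abs(np.exp(1j * ang).mean()) < 1e-12:
            raise ValueError(f"degenerate sample {name}: zero resultant, circular mean undefined")
    abar = np.angle(np.exp(1j * a).mean())
    bbar = np.angle(np.exp(1j * b).mean())
    sa = np.sin(a - abar)
    sb = np.sin(b - bbar)
    denom = np.sqrt((sa**2).sum() * (sb**2).sum())
    if denom == 0.0:
        raise ValueError("degenerate sample: zero sine dispersion")
    return float((sa * sb).sum() / denom)


def exclude_participants(
    clean: pd.DataFrame, report: ExclusionReport
) -> tuple[list[str], ExclusionReport]:
    """Apply the three participant-level criteria on the trial-cleaned table.

    Returns the kept participant ids and the updated report.  Group mean/SD
    for the accuracy/RT screen are computed over all participants before
    any removal at this step.
    """
    present = [str(p) for p in clean["participant_id"].unique()]
    # participants whose every trial was removed still need a verdict
    pids = sorted(set(present) | set(report.flagged_fraction), key=str)
    flags: dict[str, list[str]] = {p: [] for p in pids}

    for pid, frac in report.flagged_fraction.items():
        if frac > MAX_OUTLIER_FRACTION:
            flags[pid].append("too_many_outliers")

    for pid, grp in clean.groupby("participant_id"):
        r = circular_correlation(
            grp["reported_orientation"].to_numpy(), grp["probe_orientation"].to_numpy()
        )
        if r < MIN_CIRCULAR_CORRELATION:
            flags[str(pid)].append("low_circular_correlation")

    stats = clean.groupby("participant_id").agg(
        accuracy=("discrimination_correct", "mean"), mean_rt=("discrimination_rt", "mean")
    )
    if len(stats) < 2:
        report.warnings.append("fewer than 2 participants: group-SD screen skipped")
        warnings.warn("fewer than 2 participants: group-SD screen skipped")
    else:
        for col in ("accuracy", "mean_rt"):
            v = stats[col].to_numpy(dtype=float)
            mu, sd = v.mean(), v.std(ddof=1)
            if sd == 0.0:
                continue
            for pid, val in zip(stats.index, v):
                if abs(val - mu) > GROUP_SD_LIMIT * sd:
                    if "discrimination_outlier" not in flags[str(pid)]:
                        flags[str(pid)].append("discrimination_outlier")

    kept = [p for p in pids if not flags[p]]
    report.participant_flags = {p: f for p, f in flags.items() if f}
    report.excluded_participants = [p for p in pids if flags[p]]
    return kept, report


def preprocess(annotated: pd.DataFrame) -> tuple[pd.DataFrame, ExclusionReport]:
    """Full exclusion pipeline: trial criteria, then participant criteria."""
    clean, report = exclude_trials(annotated)
    kept, report = exclude_participants(clean, report)
    clean = clean[clean["participant_id"].astype(str).isin(kept)].copy()
    report.n_retained = len(clean)
    return clean, report
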