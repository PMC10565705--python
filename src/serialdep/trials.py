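"""Trial tables: schema, validation, annotation, and delimited-text I/O.

The single currency of every analysis stage is a tidy per-trial table
(one row per trial of the interleaved discrimination + adjustment
experiment).  Tables are plain :class:`pandas.DataFrame` objects with a
fixed set of columns; ``read_trials``/``write_trials`` exchange them as
CSV/TSV with empty fields for absent values (no distractor on this trial,
no previous trial in this session).

Columns
-------
participant_id : str            opaque participant label
session : int ≥ 1               experimental session (separate days)
trial_index : int ≥ 1           chronological within (participant, session)
location_condition : str        "random" or "fixed" distractor location block
distractor_present : bool
distractor_orientation : float  degrees in [0, 180), NaN when absent
distractor_location : float     location code 0..n_locations−1, NaN when absent
probe_orientation : float       degrees in [0, 180)
reported_orientation : float    degrees in [0, 180)
discrimination_correct : bool
discrimination_rt : float       ms, > 0
adjustment_rt : float           ms, > 0

``annotate_trials`` adds the derived circular quantities used by the
serial-dependence stage (adjustment error and the three Δ's).
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .orientation import wrap_diff

__all__ = [
    "TRIAL_COLUMNS",
    "DERIVED_COLUMNS",
    "TrialValidationError",
    "validate_trials",
    "annotate_trials",
    "read_trials",
    "write_trials",
]

TRIAL_COLUMNS = [
    "participant_id",
    "session",
    "trial_index",
    "location_condition",
    "distractor_present",
    "distractor_orientation",
    "distractor_location",
    "probe_orientation",
    "reported_orientation",
    "discrimination_correct",
    "discrimination_rt",
    "adjustment_rt",
]

#: columns appended by :func:`annotate_trials`
DERIVED_COLUMNS = [
    "adjustment_error",
    "delta_prev_probe",
    "delta_distractor",
    "prev_probe_distractor_delta",
]

LOCATION_CONDITIONS = ("random", "fixed")


class TrialValidationError(ValueError):
    """Schema or value violation in a trial table; message lists offending rows."""


def _require_columns(trials: pd.DataFrame, columns) -> None:
    missing = [c for c in columns if c not in trials.columns]
    if missing:
        raise TrialValidationError(f"missing required column(s): {', '.join(missing)}")


def validate_trials(trials: pd.DataFrame) -> None:
    """Check a trial table against the schema; raise listing offending rows.

    Row numbers in messages are 0-based positions in the table.
    """
    _require_columns(trials, TRIAL_COLUMNS)
    problems: list[str] = []

    def flag(mask: np.ndarray, why: str) -> None:
        rows = np.flatnonzero(np.asarray(mask))
        if rows.size:
            shown = ", ".join(map(str, rows[:10])) + ("…" if rows.size > 10 else "")
            problems.append(f"{why} (rows {shown})")

    for col in ("probe_orientation", "reported_orientation"):
        v = trials[col].to_numpy(dtype=float)
        flag(~np.isfinite(v) | (v < 0) | (v >= 180), f"{col} outside [0, 180)")
    present = trials["distractor_present"].to_numpy(dtype=bool)
    dori = trials["distractor_orientation"].to_numpy(dtype=float)
    dloc = trials["distractor_location"].to_numpy(dtype=float)
    flag(present & ~np.isfinite(dori), "distractor_present but distractor_orientation absent")
    flag(present & ~np.isfinite(dloc), "distractor_present but distractor_location absent")
    flag(~present & np.isfinite(dori), "distractor_orientation given on distractor-absent trial")
    flag(~present & np.isfinite(dloc), "distractor_location given on distractor-absent trial")
    flag(np.isfinite(dori) & ((dori < 0) | (dori >= 180)), "distractor_orientation outside [0, 180)")
    for col in ("discrimination_rt", "adjustment_rt"):
        v = trials[col].to_numpy(dtype=float)
        flag(~np.isfinite(v) | (v <= 0), f"{col} not strictly positive")
    bad_cond = ~trials["location_condition"].isin(LOCATION_CONDITIONS).to_numpy()
    flag(bad_cond, "location_condition not in {random, fixed}")

    # trial_index strictly increasing within participant × session
    idx = trials.groupby(["participant_id", "session"], sort=False)["trial_index"].diff()
    flag((idx <= 0).to_numpy(), "trial_index not strictly increasing within session")

    if problems:
        raise TrialValidationError("invalid trial table: " + "; ".join(problems))


def _check_sorted(trials: pd.DataFrame) -> None:
    key = trials[["participant_id", "session", "trial_index"]]
    if not key.equals(key.sort_values(["participant_id", "session", "trial_index"])):
        raise TrialValidationError(
            "trials must be sorted by participant_id, session, trial_index"
        )


def annotate_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Append derived circular quantities to a sorted trial table.

    Adds ``adjustment_error`` (reported − probe, wrapped), ``delta_prev_probe``
    (previous trial's probe − current probe; NaN on the first trial of each
    session), ``delta_distractor`` (current distractor − current probe; NaN
    when no distractor) and ``prev_probe_distractor_delta`` (previous probe −
    current distractor).  Previous-trial linkage uses the immediately
    preceding row within (participant, session) of the table it is given:
    on the raw table this is the preceding *presented* trial regardless of
    any later exclusion; re-annotating a filtered table would instead link
    across the retained trials.

    Deterministic and idempotent: re-annotating an annotated table
    reproduces the same derived columns.
    """
    _require_columns(trials, TRIAL_COLUMNS)
    _check_sorted(trials)
    out = trials.copy()
    probe = out["probe_orientation"].to_numpy(dtype=float)
    reported = out["reported_orientation"].to_numpy(dtype=float)
    out["adjustment_error"] = wrap_diff(reported, probe)

    prev_probe = (
        out.groupby(["participant_id", "session"], sort=False)["probe_orientation"]
        .shift(1)
        .to_numpy(dtype=float)
    )
    has_prev = np.isfinite(prev_probe)
    dpp = np.full(len(out), np.nan)
    dpp[has_prev] = wrap_diff(prev_probe[has_prev], probe[has_prev])
    out["delta_prev_probe"] = dpp

    dori = out["distractor_orientation"].to_numpy(dtype=float)
    has_d = np.isfinite(dori)
    dd = np.full(len(out), np.nan)
    dd[has_d] = wrap_diff(dori[has_d], probe[has_d])
    out["delta_distractor"] = dd

    both = has_prev & has_d
    pdd = np.full(len(out), np.nan)
    pdd[both] = wrap_diff(prev_probe[both], dori[both])
    out["prev_probe_distractor_delta"] = pdd
    return out


def _sep_for(path) -> str:
    return "\t" if os.fspath(path).endswith((".tsv", ".tab")) else ","


def read_trials(path) -> pd.DataFrame:
    """Read and validate a delimited trial table (CSV, or TSV by extension)."""
    df = pd.read_csv(path, sep=_sep_for(path), float_precision="round_trip")
    _require_columns(df, TRIAL_COLUMNS)
    df["participant_id"] = df["participant_id"].astype(str)
    for col in ("distractor_present", "discrimination_correct"):
        if df[col].dtype != bool:
            df[col] = df[col].map(
                {True: True, False: False, "True": True, "False": False}
            )
            if df[col].isna().any():
                raise TrialValidationError(f"{col} must be boolean True/False")
            df[col] = df[col].astype(bool)
    for col in ("distractor_orientation", "distractor_location"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    validate_trials(df)
    return df


def write_trials(trials: pd.DataFrame, path) -> None:
    """Write a trial table as delimited text; absent values become empty fields.

    Floats are written at full round-trip precision, so write→read is
    lossless.
    """
    validate_trials(trials)
    trials.to_csv(path, sep=_sep_for(path), index=False)
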