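"""Reading and writing the canonical delimited-text formats.

trials.csv (comma-delimited, UTF-8): subject_id, group, severity, trial,
s1_choice, s1_rt_ms, transition, s2_state, s2_choice, s2_rt_ms, reward,
missed_stage.  Missing values are empty fields, trial indices are
0-based, transition labels are canonically lower-case {common, rare} but
accepted case-insensitively on input.

subjects.csv: subject_id, group, severity, one column per covariate,
plus true_* parameter columns when the cohort is synthetic.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .agents import TRIAL_COLUMNS
from .cohort import CohortDataset

__all__ = ["read_trials", "write_trials", "read_subjects", "write_subjects",
           "read_cohort", "write_cohort"]

_INT_LIKE = ("s1_choice", "s2_state", "s2_choice", "reward")
_MISSED_VALUES = {"none", "stage1", "stage2"}


def write_trials(cohort: CohortDataset, path: str | Path) -> None:
    df = cohort.trials.copy()
    for c in _INT_LIKE:
        df[c] = df[c].astype("Int64")
    for c in ("s1_rt_ms", "s2_rt_ms"):
        df[c] = df[c].map(lambda v: "" if pd.isna(v) else f"{v:.4f}")
    df.to_csv(path, index=False, columns=TRIAL_COLUMNS)


def write_subjects(cohort: CohortDataset, path: str | Path) -> None:
    cohort.subjects.to_csv(path, index=False, float_format="%.6f")


def _validate_codes(df: pd.DataFrame) -> None:
    for col in _INT_LIKE:
        vals = df[col].dropna()
        bad = vals[~vals.isin([0, 1])]
        if len(bad):
            raise ValueError(
                f"out-of-range value {bad.iloc[0]!r} in column {col!r} "
                f"at row {int(bad.index[0])}"
            )
    trans = df["transition"].dropna()
    bad = trans[~trans.isin(["common", "rare"])]
    if len(bad):
        raise ValueError(
            f"unknown transition value {bad.iloc[0]!r} at row {int(bad.index[0])}"
        )
    missed = df["missed_stage"].dropna()
    bad = missed[~missed.isin(_MISSED_VALUES)]
    if len(bad):
        raise ValueError(
            f"unknown missed_stage value {bad.iloc[0]!r} at row {int(bad.index[0])}"
        )


def read_trials(path: str | Path) -> pd.DataFrame:
    """Read and validate a trial-level table (header must match schema)."""
    df = pd.read_csv(path, dtype={"subject_id": str, "group": str})
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing mandatory column(s): {', '.join(missing)}")
    unknown = [c for c in df.columns if c not in TRIAL_COLUMNS]
    if unknown:
        warnings.warn(f"ignoring unknown column(s): {', '.join(unknown)}")
        df = df[TRIAL_COLUMNS]
    if len(df) == 0:
        return df
    df["transition"] = df["transition"].astype("string").str.lower()
    df["transition"] = df["transition"].astype(object).where(df["transition"].notna(), np.nan)
    df["missed_stage"] = df["missed_stage"].astype("string").str.lower().fillna("none")
    df["missed_stage"] = df["missed_stage"].astype(object)
    for c in _INT_LIKE:
        df[c] = pd.to_numeric(df[c], errors="coerce")
    _validate_codes(df)
    for c in _INT_LIKE:
        df[c] = df[c].astype("Int64").astype(object).where(df[c].notna(), None)
    df["trial"] = df["trial"].astype(int)
    df["severity"] = df["severity"].fillna(0).astype(int)
    return df


def read_subjects(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"subject_id": str, "group": str})
    for col in ("subject_id", "group", "severity"):
        if col not in df.columns:
            raise ValueError(f"missing mandatory column(s): {col}")
    return df


def write_cohort(cohort: CohortDataset, directory: str | Path) -> tuple[Path, Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tpath = directory / "trials.csv"
    spath = directory / "subjects.csv"
    write_trials(cohort, tpath)
    write_subjects(cohort, spath)
    return tpath, spath


def read_cohort(trials_path: str | Path, subjects_path: str | Path | None = None) -> CohortDataset:
    """Load a cohort from trials.csv (+ optional subjects.csv).

    Without a subject table, one is reconstructed from the per-trial
    group/severity columns.
    """
    trials = read_trials(trials_path)
    if subjects_path is not None:
        subjects = read_subjects(subjects_path)
    else:
        subjects = (
            trials.groupby("subject_id", sort=False)[["group", "severity"]]
            .first()
            .reset_index()
        )
    return CohortDataset(subjects=subjects, trials=trials)
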