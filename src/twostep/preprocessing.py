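"""Engagement filters and construction of the lagged stay table.

Subjects are excluded when their behavior suggests disengagement from the
task: repeating a previously rewarded second-stage response less than 50%
of the time, missing the response deadline more than 20 times (counting
stages, since a trial can time out at either stage), or never trying some
response option.  Both thresholds are strict: exactly 50% or exactly 20
misses is retained.

The analysis unit downstream is the lagged row: for each pair of
consecutive fully completed trials, whether the first-stage choice was
repeated ("stay"), together with the previous trial's outcome and
transition type.  Factors are effect-coded +/-1 so that main effects are
averages over the other factors and the outcome x transition interaction
is the model-based signature: o = +1 reward / -1 non-reward, tau = +1
common / -1 rare, g = +1 CP / -1 PG.  Under this coding model-based
behavior produces a positive o x tau coefficient, and in the non-reward
stratum alone a negative tau coefficient (model-based agents switch after
a non-rewarded common transition).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CohortDataset

__all__ = [
    "FilterReport",
    "apply_engagement_filters",
    "build_lagged_table",
    "stay_table",
    "GROUP_CODE",
]

#: Effect codes for the group factor.
GROUP_CODE = {"CP": 1, "PG": -1}

MAX_MISSES = 20  # strict: a subject is removed only above this count
MIN_REWARDED_REPEAT_RATE = 0.50  # strict: removal only below this rate


@dataclass
class FilterReport:
    """Per-subject engagement metrics and exclusion decisions."""

    table: pd.DataFrame  # subject_id, rewarded_repeat_rate, n_missed,
    #                      tried_all_options, excluded, reasons

    @property
    def n_excluded(self) -> int:
        return int(self.table["excluded"].sum())

    def excluded_ids(self) -> list[str]:
        return self.table.loc[self.table["excluded"], "subject_id"].tolist()


def _completed(trials: pd.DataFrame) -> pd.DataFrame:
    return trials[trials["missed_stage"] == "none"]


def _rewarded_repeat_rate(sub: pd.DataFrame) -> float:
    """Rate of repeating the second-stage choice made at the last visit to
    the same second-stage state, among visits where that last visit was
    rewarded.  NaN when no such pair exists."""
    done = _completed(sub).sort_values("trial")
    n_pairs = 0
    n_repeat = 0
    last_visit: dict[int, tuple[int, int]] = {}  # state -> (choice, reward)
    for s2_state, s2_choice, reward in zip(
        done["s2_state"], done["s2_choice"], done["reward"]
    ):
        s2_state = int(s2_state)
        prev = last_visit.get(s2_state)
        if prev is not None and prev[1] == 1:
            n_pairs += 1
            n_repeat += int(int(s2_choice) == prev[0])
        last_visit[s2_state] = (int(s2_choice), int(reward))
    return np.nan if n_pairs == 0 else n_repeat / n_pairs


def _subject_metrics(sub: pd.DataFrame) -> dict:
    done = _completed(sub)
    n_missed = int((sub["missed_stage"] != "none").sum())
    s1_done = sub[sub["s1_choice"].notna()]
    tried_s1 = set(s1_done["s1_choice"].astype(int))
    tried_s2 = set(
        zip(done["s2_state"].astype(int), done["s2_choice"].astype(int))
    )
    tried_all = tried_s1 == {0, 1} and tried_s2 == {(0, 0), (0, 1), (1, 0), (1, 1)}
    return dict(
        rewarded_repeat_rate=_rewarded_repeat_rate(sub),
        n_missed=n_missed,
        tried_all_options=tried_all,
        n_completed=len(done),
    )


def apply_engagement_filters(cohort: CohortDataset) -> tuple[CohortDataset, FilterReport]:
    """Remove disengaged subjects; returns the filtered cohort and a report.

    Rules (a subject is excluded iff at least one fires):

    a. rewarded second-stage repetition rate < 50% (strict),
    b. more than 20 missed stages (strict),
    c. some first-stage option or (state, option) second-stage response
       never tried; a subject with zero completed trials falls here and is
       reported distinctly.
    """
    rows = []
    for sid, sub in cohort.trials.groupby("subject_id", sort=False):
        m = _subject_metrics(sub)
        reasons = []
        rate = m["rewarded_repeat_rate"]
        if np.isfinite(rate) and rate < MIN_REWARDED_REPEAT_RATE:
            reasons.append("low_rewarded_repeat_rate")
        if m["n_missed"] > MAX_MISSES:
            reasons.append("too_many_misses")
        if not m["tried_all_options"]:
            reasons.append(
                "no_completed_trials" if m["n_completed"] == 0 else "untried_options"
            )
        rows.append(
            dict(
                subject_id=sid,
                **m,
                excluded=bool(reasons),
                reasons=";".join(reasons),
            )
        )
    report = FilterReport(table=pd.DataFrame(rows))
    keep = set(report.table.loc[~report.table["excluded"], "subject_id"])
    filtered = CohortDataset(
        subjects=cohort.subjects[cohort.subjects["subject_id"].isin(keep)].reset_index(drop=True),
        trials=cohort.trials[cohort.trials["subject_id"].isin(keep)].reset_index(drop=True),
    )
    return filtered, report


def build_lagged_table(cohort: CohortDataset) -> pd.DataFrame:
    """One row per pair of consecutive fully completed trials per subject.

    The first trial of a subject yields no row, and a missed stage on
    either member of a pair (or a gap in trial indices) drops the pair.
    Columns: subject_id, group, severity, stay, o, tau, g plus any
    covariate columns found in the subject table.
    """
    cov_cols = [
        c
        for c in cohort.subjects.columns
        if c not in ("subject_id", "group", "severity") and not c.startswith("true_")
    ]
    sub_info = cohort.subjects.set_index("subject_id")

    frames = []
    for sid, sub in cohort.trials.groupby("subject_id", sort=False):
        done = _completed(sub).sort_values("trial")
        if len(done) < 2:
            continue
        trial = done["trial"].to_numpy()
        consecutive = np.diff(trial) == 1
        cur = done.iloc[1:][consecutive]
        prev = done.iloc[:-1][consecutive]
        if len(cur) == 0:
            continue
        group = str(sub["group"].iloc[0])
        df = pd.DataFrame(
            dict(
                subject_id=sid,
                group=group,
                severity=int(sub["severity"].iloc[0]),
                trial=cur["trial"].to_numpy(),
                stay=(cur["s1_choice"].to_numpy() == prev["s1_choice"].to_numpy()).astype(int),
                o=np.where(prev["reward"].to_numpy() == 1, 1, -1),
                tau=np.where(prev["transition"].to_numpy() == "common", 1, -1),
                g=GROUP_CODE.get(group, 0),
            )
        )
        for c in cov_cols:
            if sid in sub_info.index:
                df[c] = sub_info.at[sid, c]
        frames.append(df)
    if not frames:
        cols = ["subject_id", "group", "severity", "trial", "stay", "o", "tau", "g"]
        return pd.DataFrame(columns=cols + cov_cols)
    return pd.concat(frames, ignore_index=True)


def stay_table(lagged: pd.DataFrame) -> pd.DataFrame:
    """Per-subject 2x2 p(stay) by previous outcome x previous transition.

    Empty cells are NaN.  Columns are labeled by condition
    (reward/noreward x common/rare) plus matching _n count columns.
    """
    labels = {(1, 1): "reward_common", (1, -1): "reward_rare",
              (-1, 1): "noreward_common", (-1, -1): "noreward_rare"}
    rows = []
    for sid, sub in lagged.groupby("subject_id", sort=False):
        row = dict(subject_id=sid, group=sub["group"].iloc[0])
        for (o, tau), name in labels.items():
            cell = sub[(sub["o"] == o) & (sub["tau"] == tau)]
            row[name] = cell["stay"].mean() if len(cell) else np.nan
            row[f"{name}_n"] = len(cell)
        rows.append(row)
    return pd.DataFrame(rows)
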