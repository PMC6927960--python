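"""Hand-constructed synthetic fixtures for the engagement filters.

The six-subject cohort below is built trial by trial (no randomness) so
that each exclusion rule fires for exactly one subject and each boundary
case is retained:

================  ===========================================  ========
subject           construction                                  outcome
================  ===========================================  ========
clean             rewarded-repeat rate 60%, 0 misses            kept
bound_rate        rewarded-repeat rate exactly 50%              kept
bound_miss        exactly 20 missed stages                      kept
low_rate          rewarded-repeat rate 40%                      removed
many_miss         21 missed stages                              removed
untried           never picks option 1 in state 1               removed
================  ===========================================  ========

All kept aspects of every subject are otherwise clean: both first-stage
options and (unless that is the point) all four second-stage responses
are tried.
"""

from __future__ import annotations

import pandas as pd

from .agents import TRIAL_COLUMNS
from .cohort import CohortDataset

__all__ = ["engagement_filter_fixture", "EXPECTED_EXCLUSIONS"]

#: subject -> expected filter reason ("" means retained)
EXPECTED_EXCLUSIONS = {
    "clean": "",
    "bound_rate": "",
    "bound_miss": "",
    "low_rate": "low_rewarded_repeat_rate",
    "many_miss": "too_many_misses",
    "untried": "untried_options",
}


def _row(sid, trial, s1, s2_state, c2, r, missed="none"):
    common = s2_state == s1  # option 0 leads commonly to state 0, 1 to 1
    if missed == "stage1":
        return dict.fromkeys(TRIAL_COLUMNS) | dict(
            subject_id=sid, group="CP", severity=0, trial=trial, missed_stage="stage1"
        )
    base = dict(
        subject_id=sid,
        group="CP",
        severity=0,
        trial=trial,
        s1_choice=s1,
        s1_rt_ms=500.0,
        transition="common" if common else "rare",
        s2_state=s2_state,
        missed_stage=missed,
    )
    if missed == "stage2":
        return dict.fromkeys(TRIAL_COLUMNS) | base
    return dict.fromkeys(TRIAL_COLUMNS) | base | dict(
        s2_choice=c2, s2_rt_ms=600.0, reward=r, missed_stage="none"
    )


def _coverage_block(sid):
    """Six completed trials: all responses tried, rewarded-repeat rate 2/4."""
    return [
        _row(sid, 0, 0, 0, 0, 1),
        _row(sid, 1, 0, 0, 0, 1),  # state-0 pair after reward: repeat
        _row(sid, 2, 1, 1, 0, 1),
        _row(sid, 3, 1, 1, 0, 1),  # state-1 pair after reward: repeat
        _row(sid, 4, 0, 1, 1, 0),  # state-1 pair after reward: switch
        _row(sid, 5, 1, 0, 1, 0),  # state-0 pair after reward: switch
    ]


def engagement_filter_fixture() -> CohortDataset:
    rows = []

    # kept: rate 3/5 = 60%
    sid = "clean"
    rows += _coverage_block(sid)
    rows += [
        _row(sid, 6, 0, 0, 0, 1),  # previous state-0 visit unrewarded: no pair
        _row(sid, 7, 0, 0, 0, 1),  # rewarded pair: repeat -> 3/5
    ]

    # kept: rate exactly 2/4 = 50% (strict threshold)
    rows += _coverage_block("bound_rate")

    # kept: exactly 20 missed stages (strict threshold)
    sid = "bound_miss"
    rows += _coverage_block(sid)
    rows += [_row(sid, 6 + k, 0, 0, 0, 0, missed="stage1") for k in range(20)]

    # removed: rate 2/5 = 40%
    sid = "low_rate"
    rows += _coverage_block(sid)
    rows += [
        _row(sid, 6, 0, 0, 0, 1),  # previous state-0 visit unrewarded: no pair
        _row(sid, 7, 0, 0, 1, 0),  # rewarded pair: switch -> 2/5
    ]

    # removed: 21 missed stages
    sid = "many_miss"
    rows += _coverage_block(sid)
    rows += [_row(sid, 6 + k, 0, 0, 0, 0, missed="stage1") for k in range(21)]

    # removed: (state 1, option 1) never tried; repeat rate 2/3
    sid = "untried"
    rows += [
        _row(sid, 0, 0, 0, 0, 1),
        _row(sid, 1, 0, 0, 0, 1),  # repeat
        _row(sid, 2, 1, 1, 0, 1),
        _row(sid, 3, 1, 1, 0, 1),  # repeat
        _row(sid, 4, 1, 0, 1, 0),  # rare to state 0; switch
    ]

    trials = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    subjects = pd.DataFrame(
        dict(subject_id=list(EXPECTED_EXCLUSIONS), group="CP", severity=0)
    )
    return CohortDataset(subjects=subjects, trials=trials)
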