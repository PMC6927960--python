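"""Response-time inference: mixed-design ANOVAs and the severity correlation.

Both ANOVAs operate on per-subject cell means (matching the degrees of
freedom a subjects-as-cases analysis reports), with group as the
between-subject factor:

* stage-2 RT by the *current* trial's transition (common vs rare);
* stage-1 RT by the *previous* trial's outcome (reward vs non-reward).

Post-hoc contrasts are a pooled-variance two-sample t on difference
scores (with Cohen's d_s) for between-group comparisons and paired t
tests (with Cohen's d_z = t / sqrt(n)) within groups.  The severity
correlation is the Pearson r between the DSM-style symptom count and the
per-subject post-loss speed-up (mean stage-1 RT after reward minus after
non-reward) among problem gamblers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats

from .cohort import CohortDataset

logger = logging.getLogger(__name__)

__all__ = [
    "rt_cell_means",
    "AnovaResult",
    "rt2_transition_anova",
    "rt1_outcome_anova",
    "severity_rt_correlation",
]


def rt_cell_means(cohort: CohortDataset) -> pd.DataFrame:
    """Per-subject mean RTs by condition.

    Columns: rt2_common / rt2_rare (stage-2 RT by current transition,
    completed trials only), rt1_after_reward / rt1_after_noreward
    (stage-1 RT on trials whose immediately preceding trial was fully
    completed), matching _n cell counts, group and severity.
    """
    info = cohort.subjects.set_index("subject_id")
    rows = []
    for sid, sub in cohort.trials.groupby("subject_id", sort=False):
        sub = sub.sort_values("trial")
        done = sub[sub["missed_stage"] == "none"]
        row: dict = dict(
            subject_id=sid,
            group=info.at[sid, "group"] if sid in info.index else sub["group"].iloc[0],
            severity=int(info.at[sid, "severity"]) if sid in info.index else 0,
        )
        for label in ("common", "rare"):
            cell = done.loc[done["transition"] == label, "s2_rt_ms"]
            row[f"rt2_{label}"] = cell.mean() if len(cell) else np.nan
            row[f"rt2_{label}_n"] = len(cell)

        # stage-1 RT conditioned on the previous trial's outcome
        trial = sub["trial"].to_numpy()
        prev_ok = np.zeros(len(sub), dtype=bool)
        prev_reward = np.zeros(len(sub))
        done_mask = (sub["missed_stage"] == "none").to_numpy()
        reward = sub["reward"].to_numpy()
        for i in range(1, len(sub)):
            if trial[i] - trial[i - 1] == 1 and done_mask[i - 1]:
                prev_ok[i] = True
                prev_reward[i] = reward[i - 1]
        has_rt1 = sub["s1_rt_ms"].notna().to_numpy()
        rt1 = sub["s1_rt_ms"].to_numpy(dtype=float)
        for value, label in ((1, "after_reward"), (0, "after_noreward")):
            m = prev_ok & has_rt1 & (prev_reward == value)
            row[f"rt1_{label}"] = rt1[m].mean() if m.any() else np.nan
            row[f"rt1_{label}_n"] = int(m.sum())
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class AnovaResult:
    """2x2 mixed-design ANOVA table with post-hoc contrasts."""

    effects: pd.DataFrame  # effect, F, df1, df2, p, eta_p2
    posthoc: pd.DataFrame  # contrast, t, df, p, d, kind
    cell_means: pd.DataFrame
    dropped_subjects: list[str] = field(default_factory=list)

    def effect(self, name: str) -> pd.Series:
        row = self.effects[self.effects["effect"] == name]
        if row.empty:
            raise KeyError(name)
        return row.iloc[0]


def _cohens_ds(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    return float((a.mean() - b.mean()) / np.sqrt(sp2)) if sp2 > 0 else np.inf


def _mixed_anova(
    cells: pd.DataFrame,
    col_a: str,
    col_b: str,
    within_name: str,
    level_a: str,
    level_b: str,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Run the 2x2 mixed ANOVA on a wide per-subject cell-mean table."""
    complete = cells[[col_a, col_b]].notna().all(axis=1)
    dropped = cells.loc[~complete, "subject_id"].tolist()
    if dropped:
        logger.info("dropping %d subject(s) with empty RT cells: %s", len(dropped), dropped)
    work = cells[complete]
    for g, sub in work.groupby("group"):
        if len(sub) < 2:
            raise ValueError(f"group {g!r} reduced below 2 subjects with complete cells")

    long = work.melt(
        id_vars=["subject_id", "group"],
        value_vars=[col_a, col_b],
        var_name=within_name,
        value_name="rt",
    )
    long[within_name] = long[within_name].map({col_a: level_a, col_b: level_b})
    aov = pg.mixed_anova(
        data=long,
        dv="rt",
        within=within_name,
        subject="subject_id",
        between="group",
        correction=False,
    )
    effects = pd.DataFrame(
        dict(
            effect=["group", within_name, f"{within_name}:group"],
            F=aov["F"].to_numpy(),
            df1=aov["DF1"].to_numpy(),
            df2=aov["DF2"].to_numpy(),
            p=aov["p_unc"].to_numpy(),
            eta_p2=aov["np2"].to_numpy(),
        )
    )
    return effects, work, dropped


def rt2_transition_anova(cohort: CohortDataset, welch: bool = False) -> AnovaResult:
    """Mixed ANOVA: stage-2 RT by current transition (within) x group.

    Post-hoc: two-sample t between groups on per-subject (rare - common)
    difference scores, with Cohen's d_s (pooled variance by default;
    ``welch=True`` switches the t test to the Welch form).
    """
    cells = rt_cell_means(cohort)
    effects, work, dropped = _mixed_anova(
        cells, "rt2_common", "rt2_rare", "transition", "common", "rare"
    )
    diff = work["rt2_rare"] - work["rt2_common"]
    groups = sorted(work["group"].unique())
    post_rows = []
    if len(groups) == 2:
        a = diff[work["group"] == groups[0]].to_numpy()
        b = diff[work["group"] == groups[1]].to_numpy()
        t, p = stats.ttest_ind(a, b, equal_var=not welch)
        df = (len(a) + len(b) - 2) if not welch else np.nan
        post_rows.append(
            dict(
                contrast=f"rare-common: {groups[0]} vs {groups[1]}",
                t=float(t),
                df=df,
                p=float(p),
                d=_cohens_ds(a, b),
                kind="between (d_s)",
            )
        )
        for g in groups:
            v = diff[work["group"] == g].to_numpy()
            post_rows.append(_paired_row(f"rare vs common within {g}", v))
    return AnovaResult(
        effects=effects,
        posthoc=pd.DataFrame(post_rows),
        cell_means=work,
        dropped_subjects=dropped,
    )


def _paired_row(label: str, diff: np.ndarray) -> dict:
    n = len(diff)
    sd = diff.std(ddof=1)
    if sd == 0:
        logger.warning("paired contrast %r has zero variance; t degenerate", label)
        return dict(contrast=label, t=np.inf if diff.mean() != 0 else 0.0,
                    df=n - 1, p=0.0 if diff.mean() != 0 else 1.0,
                    d=np.inf if diff.mean() != 0 else 0.0, kind="paired (d_z, degenerate)")
    t, p = stats.ttest_1samp(diff, 0.0)
    return dict(
        contrast=label, t=float(t), df=n - 1, p=float(p),
        d=float(t / np.sqrt(n)), kind="paired (d_z)",
    )


def rt1_outcome_anova(cohort: CohortDataset) -> AnovaResult:
    """Mixed ANOVA: stage-1 RT by previous outcome (within) x group.

    Post-hoc: paired t within each group (after reward vs after
    non-reward) with Cohen's d_z.
    """
    cells = rt_cell_means(cohort)
    effects, work, dropped = _mixed_anova(
        cells, "rt1_after_reward", "rt1_after_noreward", "prev_outcome",
        "reward", "noreward",
    )
    post_rows = []
    for g, sub in work.groupby("group"):
        diff = (sub["rt1_after_reward"] - sub["rt1_after_noreward"]).to_numpy()
        post_rows.append(_paired_row(f"after reward vs after non-reward within {g}", diff))
    return AnovaResult(
        effects=effects,
        posthoc=pd.DataFrame(post_rows),
        cell_means=work,
        dropped_subjects=dropped,
    )


def severity_rt_correlation(
    cohort: CohortDataset, group: str = "PG"
) -> tuple[float, float, int]:
    """Pearson r between symptom count and the post-loss RT1 speed-up.

    The speed-up is mean stage-1 RT after a reward minus after a
    non-reward, so a positive value means faster responding after losses.
    Returns ``(r, two-sided p, n)``.
    """
    cells = rt_cell_means(cohort)
    sub = cells[
        (cells["group"] == group)
        & cells[["rt1_after_reward", "rt1_after_noreward"]].notna().all(axis=1)
    ]
    if len(sub) < 3:
        raise ValueError(f"need >= 3 {group} subjects with defined cells, got {len(sub)}")
    diff = (sub["rt1_after_reward"] - sub["rt1_after_noreward"]).to_numpy()
    sev = sub["severity"].to_numpy(dtype=float)
    if diff.std(ddof=1) == 0 or sev.std(ddof=1) == 0:
        raise ValueError("zero variance in severity or RT difference")
    r, p = stats.pearsonr(sev, diff)
    return float(r), float(p), int(len(sub))
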