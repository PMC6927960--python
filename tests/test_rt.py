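"""Response-time ANOVAs against closed-form sums-of-squares oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import twostep as ts
from twostep.agents import TRIAL_COLUMNS
from twostep.cohort import CohortDataset


def _rt2_subject(sid, group, common_mean, rare_mean, n_per_cell=2):
    """Completed trials whose stage-2 cell means are exact by construction."""
    rows = []
    t = 0
    for rt, label, state in ((common_mean, "common", 0), (rare_mean, "rare", 1)):
        for _ in range(n_per_cell):
            rows.append(dict.fromkeys(TRIAL_COLUMNS) | dict(
                subject_id=sid, group=group, severity=0, trial=t,
                s1_choice=0, s1_rt_ms=400.0, transition=label, s2_state=state,
                s2_choice=0, s2_rt_ms=float(rt), reward=1, missed_stage="none",
            ))
            t += 1
    return rows


def _rt1_subject(sid, group, speedup, severity=0, base=430.0, noise=None):
    """Rewards alternate; stage-1 RT drops by `speedup` after a non-reward."""
    rows = []
    prev_reward = None
    rng_noise = iter(noise) if noise is not None else None
    for t in range(41):
        reward = t % 2  # 0, 1, 0, 1, ...
        rt1 = base
        if prev_reward == 0:
            rt1 -= speedup
        if rng_noise is not None:
            rt1 += next(rng_noise)
        rows.append(dict.fromkeys(TRIAL_COLUMNS) | dict(
            subject_id=sid, group=group, severity=severity, trial=t,
            s1_choice=0, s1_rt_ms=float(rt1), transition="common", s2_state=0,
            s2_choice=0, s2_rt_ms=600.0, reward=reward, missed_stage="none",
        ))
        prev_reward = reward
    return rows


def _cohort(rows):
    trials = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    subjects = (
        trials.groupby("subject_id", sort=False)[["group", "severity"]].first().reset_index()
    )
    return CohortDataset(subjects=subjects, trials=trials)


def _mixed_anova_oracle(Y, groups):
    """Textbook SS decomposition for a balanced 2-level mixed design.

    Y: (n_subjects, 2) cell means; groups: label per subject.
    Returns (F, eta_p2) dicts keyed by between/within/interaction.
    """
    Y = np.asarray(Y, dtype=float)
    groups = np.asarray(groups)
    labels = sorted(set(groups))
    N, C = Y.shape
    G = len(labels)
    gm = Y.mean()
    subj_means = Y.mean(axis=1)
    group_means = {g: Y[groups == g].mean() for g in labels}
    col_means = Y.mean(axis=0)

    ss_a = C * sum((groups == g).sum() * (group_means[g] - gm) ** 2 for g in labels)
    ss_s = C * sum(
        (subj_means[i] - group_means[groups[i]]) ** 2 for i in range(N)
    )
    ss_b = N * ((col_means - gm) ** 2).sum()
    ss_ab = sum(
        (groups == g).sum() * (Y[groups == g][:, c].mean() - group_means[g]
                               - col_means[c] + gm) ** 2
        for g in labels for c in range(C)
    )
    ss_bs = sum(
        (Y[i, c] - subj_means[i] - Y[groups == groups[i]][:, c].mean()
         + group_means[groups[i]]) ** 2
        for i in range(N) for c in range(C)
    )
    df_a, df_s = G - 1, N - G
    df_b, df_bs = C - 1, (N - G) * (C - 1)
    F = {
        "between": (ss_a / df_a) / (ss_s / df_s),
        "within": (ss_b / df_b) / (ss_bs / df_bs),
        "interaction": (ss_ab / (df_a * df_b)) / (ss_bs / df_bs),
    }
    eta = {
        "between": ss_a / (ss_a + ss_s),
        "within": ss_b / (ss_b + ss_bs),
        "interaction": ss_ab / (ss_ab + ss_bs),
    }
    return F, eta


@pytest.fixture()
def four_subject_cohort():
    rows = []
    rows += _rt2_subject("a1", "CP", 500, 540)
    rows += _rt2_subject("a2", "CP", 520, 556)
    rows += _rt2_subject("b1", "PG", 510, 530)
    rows += _rt2_subject("b2", "PG", 530, 546)
    return _cohort(rows)


class TestTransitionAnova:
    def test_matches_hand_sums_of_squares(self, four_subject_cohort):
        res = ts.rt2_transition_anova(four_subject_cohort)
        Y = [[500, 540], [520, 556], [510, 530], [530, 546]]
        F, eta = _mixed_anova_oracle(Y, ["CP", "CP", "PG", "PG"])
        assert res.effect("group")["F"] == pytest.approx(F["between"], rel=1e-9)
        assert res.effect("transition")["F"] == pytest.approx(F["within"], rel=1e-9)
        assert res.effect("transition:group")["F"] == pytest.approx(
            F["interaction"], rel=1e-9
        )
        for name, key in (("group", "between"), ("transition", "within"),
                          ("transition:group", "interaction")):
            assert res.effect(name)["eta_p2"] == pytest.approx(eta[key], rel=1e-9)

    def test_degrees_of_freedom(self, four_subject_cohort):
        res = ts.rt2_transition_anova(four_subject_cohort)
        assert (res.effect("transition")["df1"], res.effect("transition")["df2"]) == (1, 2)

    def test_zero_within_effect_gives_zero_f(self):
        # difference scores cancel (+10, -10 in each group): the transition
        # main effect and interaction are exactly zero with nonzero error
        means = [("CP", 500, 510), ("CP", 520, 510), ("PG", 510, 520), ("PG", 530, 520)]
        rows = []
        for i, (g, c, r) in enumerate(means):
            rows += _rt2_subject(f"s{i}", g, c, r)
        res = ts.rt2_transition_anova(_cohort(rows))
        assert res.effect("transition")["F"] == pytest.approx(0.0, abs=1e-12)
        assert res.effect("transition:group")["F"] == pytest.approx(0.0, abs=1e-12)

    def test_scale_equivariance(self, four_subject_cohort):
        res = ts.rt2_transition_anova(four_subject_cohort)
        shifted = four_subject_cohort.trials.copy()
        shifted["s2_rt_ms"] = shifted["s2_rt_ms"] + 250.0
        res2 = ts.rt2_transition_anova(
            CohortDataset(subjects=four_subject_cohort.subjects, trials=shifted)
        )
        pd.testing.assert_frame_equal(res.effects, res2.effects)

    def test_between_f_equals_squared_t_on_grand_means(self, four_subject_cohort):
        res = ts.rt2_transition_anova(four_subject_cohort)
        cm = res.cell_means
        grand = (cm["rt2_common"] + cm["rt2_rare"]) / 2
        t, _ = stats.ttest_ind(grand[cm["group"] == "CP"], grand[cm["group"] == "PG"])
        assert res.effect("group")["F"] == pytest.approx(t**2, rel=1e-9)

    def test_interaction_f_equals_squared_t_on_difference_scores(self):
        # with a 2-level within factor, the interaction F is exactly the
        # squared pooled two-sample t on per-subject difference scores,
        # which is the post-hoc contrast this module reports
        rows = []
        rng = np.random.default_rng(1)
        for i, g in enumerate(["CP"] * 4 + ["PG"] * 4):
            c = 500 + rng.normal(0, 20)
            shift = 40 if g == "CP" else 20
            rows += _rt2_subject(f"s{i}", g, c, c + shift + rng.normal(0, 10))
        res = ts.rt2_transition_anova(_cohort(rows))
        t = res.posthoc.set_index("contrast").at["rare-common: CP vs PG", "t"]
        assert res.effect("transition:group")["F"] == pytest.approx(t**2, rel=1e-9)

    def test_empty_cell_subject_dropped(self, four_subject_cohort):
        extra = pd.DataFrame(
            _rt2_subject("only_common", "CP", 505, 0, n_per_cell=2)[:2]
        )
        trials = pd.concat([four_subject_cohort.trials, extra], ignore_index=True)
        subjects = pd.concat(
            [four_subject_cohort.subjects,
             pd.DataFrame([dict(subject_id="only_common", group="CP", severity=0)])],
            ignore_index=True,
        )
        res = ts.rt2_transition_anova(CohortDataset(subjects=subjects, trials=trials))
        assert res.dropped_subjects == ["only_common"]


class TestOutcomeAnova:
    def test_noiseless_speedup_degenerate_paired_t(self):
        rows = []
        for i in range(3):
            rows += _rt1_subject(f"pg{i}", "PG", speedup=30.0)
        for i in range(3):
            rows += _rt1_subject(f"cp{i}", "CP", speedup=0.0)
        res = ts.rt1_outcome_anova(_cohort(rows))
        ph = res.posthoc.set_index("contrast")
        row = ph.loc["after reward vs after non-reward within PG"]
        assert "degenerate" in row["kind"]
        assert np.isinf(row["t"])

    def test_noisy_speedup_large_positive_dz(self):
        rng = np.random.default_rng(2)
        rows = []
        for i in range(8):
            rows += _rt1_subject(f"pg{i}", "PG", speedup=30.0,
                                 noise=rng.normal(0, 3, 41))
        for i in range(8):
            rows += _rt1_subject(f"cp{i}", "CP", speedup=0.0,
                                 noise=rng.normal(0, 3, 41))
        res = ts.rt1_outcome_anova(_cohort(rows))
        ph = res.posthoc.set_index("contrast")
        pg_row = ph.loc["after reward vs after non-reward within PG"]
        cp_row = ph.loc["after reward vs after non-reward within CP"]
        assert pg_row["d"] > 2 and pg_row["p"] < 0.001
        assert abs(cp_row["d"]) < 1
        # d_z definition: paired t / sqrt(n)
        assert pg_row["d"] == pytest.approx(pg_row["t"] / np.sqrt(8), rel=1e-9)

    def test_default_cohort_pattern(self, filtered_cohort):
        res = ts.rt1_outcome_anova(filtered_cohort)
        assert res.effect("prev_outcome")["p"] < 0.01
        assert res.effect("prev_outcome:group")["p"] < 0.05
        ph = res.posthoc.set_index("contrast")
        assert ph.loc["after reward vs after non-reward within PG", "p"] < 0.001
        assert ph.loc["after reward vs after non-reward within PG", "t"] > 0


class TestSeverityCorrelation:
    def test_four_point_textbook_value(self):
        rows = []
        for sid, sev, diff in (("p1", 3, 10), ("p2", 5, 20), ("p3", 7, 30), ("p4", 9, 20)):
            rows += _rt1_subject(sid, "PG", speedup=float(diff), severity=sev)
        r, p, n = ts.severity_rt_correlation(_cohort(rows))
        # r = 40 / sqrt(20 * 200) = 2 / sqrt(10)
        assert r == pytest.approx(2 / np.sqrt(10), abs=1e-9)
        assert n == 4
        t = r * np.sqrt((n - 2) / (1 - r**2))
        assert p == pytest.approx(2 * stats.t.sf(abs(t), n - 2), rel=1e-6)

    def test_perfectly_linear_gives_r_one(self):
        rows = []
        for i, sev in enumerate((3, 5, 7, 9)):
            rows += _rt1_subject(f"p{i}", "PG", speedup=10.0 * sev, severity=sev)
        r, _, _ = ts.severity_rt_correlation(_cohort(rows))
        assert r == pytest.approx(1.0, abs=1e-9)

    def test_zero_variance_rejected(self):
        rows = []
        for i in range(4):
            rows += _rt1_subject(f"p{i}", "PG", speedup=20.0, severity=5)
        with pytest.raises(ValueError, match="zero variance"):
            ts.severity_rt_correlation(_cohort(rows))

    def test_too_few_subjects_rejected(self):
        rows = _rt1_subject("p0", "PG", 10.0, severity=4) + _rt1_subject(
            "p1", "PG", 20.0, severity=6
        )
        with pytest.raises(ValueError, match=">= 3"):
            ts.severity_rt_correlation(_cohort(rows))

    def test_default_cohort_positive(self, filtered_cohort):
        r, p, n = ts.severity_rt_correlation(filtered_cohort)
        assert r > 0 and n >= 40
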