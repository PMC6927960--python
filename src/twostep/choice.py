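"""Choice-behavior inference: stay regressions and the reward-rate test.

All regressions model the stay indicator with effect-coded (+/-1)
predictors (see :mod:`twostep.preprocessing` for the coding):

* full model: stay ~ g * o * tau with per-subject random effects,
* valence split: stay ~ g * tau fit separately on trials following a
  reward and following a non-reward,
* covariate model: a standardized clinical score replaces the group code.

Under the documented coding a positive ``o`` main effect is the
model-free signature, a positive ``o:tau`` interaction the model-based
one, and a positive ``g:o:tau`` term means the model-based signature is
larger in controls than in gamblers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortDataset
from .mixedlogit import MixedLogitResult, fit_fixed_logit, fit_mixed_logit

logger = logging.getLogger(__name__)

__all__ = [
    "RegressionSpec",
    "RegressionResult",
    "fit_stay_regression",
    "fit_valence_split",
    "fit_covariate_regression",
    "RewardRateResult",
    "reward_rate_comparison",
]

RegressionResult = MixedLogitResult

FULL_TERMS = ["g", "o", "tau", "g:o", "g:tau", "o:tau", "g:o:tau"]
SPLIT_TERMS = ["g", "tau", "g:tau"]

#: base columns that vary within subject, hence eligible as random slopes
_WITHIN = {"o", "tau"}


@dataclass(frozen=True)
class RegressionSpec:
    """Fixed terms and random-effects structure of a stay regression.

    ``random_effects`` is one of "slopes" (per-subject intercept plus
    slopes for every within-subject term; the default), "intercept", or
    "none" (plain logistic regression).  On non-convergence the fit falls
    down this ladder automatically, logging each step.
    """

    terms: tuple[str, ...] = tuple(FULL_TERMS)
    random_effects: str = "slopes"
    sd_init: float = 0.3
    xtol: float = 1e-3
    max_fev: int = 600

    def __post_init__(self) -> None:
        if self.random_effects not in ("slopes", "intercept", "none"):
            raise ValueError(f"unknown random_effects: {self.random_effects}")


def _term_column(lagged: pd.DataFrame, term: str) -> np.ndarray:
    col = np.ones(len(lagged))
    for factor in term.split(":"):
        if factor not in lagged.columns:
            raise ValueError(f"term factor {factor!r} not in table")
        col = col * lagged[factor].to_numpy(dtype=float)
    return col


def _design(lagged: pd.DataFrame, terms: tuple[str, ...]):
    X = np.column_stack(
        [np.ones(len(lagged))] + [_term_column(lagged, t) for t in terms]
    )
    names = ["(Intercept)"] + list(terms)
    return X, names


def _within_terms(terms: tuple[str, ...]) -> list[str]:
    return [t for t in terms if set(t.split(":")) <= _WITHIN]


def _check_estimable(lagged: pd.DataFrame, terms: tuple[str, ...]) -> None:
    if len(lagged) == 0:
        raise ValueError("empty lagged table")
    X, names = _design(lagged, terms)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(f"design matrix is rank-deficient for terms {names}")


def fit_stay_regression(
    lagged: pd.DataFrame,
    spec: RegressionSpec | None = None,
) -> RegressionResult:
    """Hierarchical logistic regression of stay on the requested terms.

    Falls back from random slopes to random intercept to fixed effects on
    non-convergence, flagging the step taken in ``result.warnings``.
    """
    spec = spec or RegressionSpec()
    _check_estimable(lagged, spec.terms)
    y = lagged["stay"].to_numpy(dtype=float)
    X, names = _design(lagged, spec.terms)
    groups = lagged["subject_id"].to_numpy()
    n_subjects = lagged["subject_id"].nunique()

    ladder: list[str] = []
    if n_subjects >= 2:
        if spec.random_effects == "slopes":
            ladder = ["slopes", "intercept", "none"]
        elif spec.random_effects == "intercept":
            ladder = ["intercept", "none"]
        else:
            ladder = ["none"]
    else:
        ladder = ["none"]

    notes: list[str] = []
    if n_subjects < 2 and spec.random_effects != "none":
        notes.append("single subject: random effects degenerate to fixed effects")

    result: RegressionResult | None = None
    for level in ladder:
        try:
            if level == "none":
                result = fit_fixed_logit(y, X, names)
            else:
                if level == "slopes":
                    within = _within_terms(spec.terms)
                    z_cols = [np.ones(len(lagged))] + [
                        _term_column(lagged, t) for t in within
                    ]
                    re_names = ["(Intercept)"] + within
                else:
                    z_cols = [np.ones(len(lagged))]
                    re_names = ["(Intercept)"]
                result = fit_mixed_logit(
                    y,
                    X,
                    groups,
                    np.column_stack(z_cols),
                    terms=names,
                    re_names=re_names,
                    sd_init=spec.sd_init,
                    xtol=spec.xtol,
                    max_fev=spec.max_fev,
                )
        except Exception as exc:  # pragma: no cover - defensive ladder
            logger.warning("stay regression at level %r failed: %s", level, exc)
            notes.append(f"level {level} failed: {exc}")
            result = None
            continue
        if result.converged:
            break
        logger.warning("stay regression at level %r did not converge", level)
        notes.append(f"level {level} did not converge; falling back")
    if result is None:
        raise RuntimeError("all estimation levels failed")
    result.warnings = notes + result.warnings
    return result


def fit_valence_split(
    lagged: pd.DataFrame,
    spec: RegressionSpec | None = None,
) -> tuple[RegressionResult, RegressionResult]:
    """Fit stay ~ g * tau separately after rewarded and unrewarded trials.

    Returns ``(rewarded, unrewarded)`` results.
    """
    base = spec or RegressionSpec()
    split_spec = RegressionSpec(
        terms=tuple(SPLIT_TERMS),
        random_effects=base.random_effects,
        sd_init=base.sd_init,
        xtol=base.xtol,
        max_fev=base.max_fev,
    )
    out = []
    for o_code, label in ((1, "rewarded"), (-1, "unrewarded")):
        stratum = lagged[lagged["o"] == o_code]
        if stratum.empty:
            raise ValueError(f"empty {label} stratum")
        out.append(fit_stay_regression(stratum, split_spec))
    return out[0], out[1]


def fit_covariate_regression(
    lagged: pd.DataFrame,
    covariate: str,
    spec: RegressionSpec | None = None,
) -> RegressionResult:
    """Stay regression with a standardized clinical score in place of group."""
    if covariate not in lagged.columns:
        raise ValueError(f"covariate {covariate!r} not in table")
    per_subject = lagged.groupby("subject_id")[covariate].first()
    if per_subject.isna().any():
        raise ValueError(f"covariate {covariate!r} missing for some subjects")
    sd = per_subject.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise ValueError(f"covariate {covariate!r} has zero variance")
    zmap = (per_subject - per_subject.mean()) / sd
    work = lagged.copy()
    work["c"] = work["subject_id"].map(zmap)

    base = spec or RegressionSpec()
    cov_spec = RegressionSpec(
        terms=("c", "o", "tau", "c:o", "c:tau", "o:tau", "c:o:tau"),
        random_effects=base.random_effects,
        sd_init=base.sd_init,
        xtol=base.xtol,
        max_fev=base.max_fev,
    )
    return fit_stay_regression(work, cov_spec)


@dataclass
class RewardRateResult:
    """Between-group one-way ANOVA on per-subject reward rates."""

    group_means: dict[str, float]
    group_ns: dict[str, int]
    F: float
    df1: int
    df2: int
    p: float
    eta_p2: float
    degenerate: bool = False  # zero within-group variance


def reward_rate_comparison(cohort: CohortDataset) -> RewardRateResult:
    """Compare per-subject reward rates (rewarded / completed trials)."""
    done = cohort.trials[cohort.trials["missed_stage"] == "none"]
    rates = done.groupby("subject_id")["reward"].mean()
    groups = cohort.subjects.set_index("subject_id")["group"]
    by_group = {
        g: rates.loc[[s for s in idx if s in rates.index]].to_numpy()
        for g, idx in groups.groupby(groups).groups.items()
    }
    for g, vals in by_group.items():
        if len(vals) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 subjects with trials")

    samples = list(by_group.values())
    grand = np.concatenate(samples)
    ss_between = sum(len(v) * (v.mean() - grand.mean()) ** 2 for v in samples)
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in samples)
    df1 = len(samples) - 1
    df2 = len(grand) - len(samples)
    degenerate = bool(ss_within == 0)
    if degenerate:
        F = np.inf if ss_between > 0 else 0.0
        p = 0.0 if ss_between > 0 else 1.0
    else:
        F = (ss_between / df1) / (ss_within / df2)
        p = float(stats.f.sf(F, df1, df2))
    eta = ss_between / (ss_between + ss_within) if (ss_between + ss_within) > 0 else 0.0
    return RewardRateResult(
        group_means={g: float(v.mean()) for g, v in by_group.items()},
        group_ns={g: int(len(v)) for g, v in by_group.items()},
        F=float(F),
        df1=df1,
        df2=df2,
        p=p,
        eta_p2=float(eta),
        degenerate=degenerate,
    )
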