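"""Simulated decision-makers for the two-step task.

The learner is the canonical hybrid for this paradigm: a delta rule at the
second stage, SARSA(lambda) at the first stage, a model-based planner that
combines second-stage values through the known transition matrix, and a
softmax choice rule with a perseveration bonus.  The model-based weight is
allowed to depend on the valence of the previous outcome (``w_pos`` after
a reward, ``w_neg`` after a non-reward), which is the mechanism this
package uses to generate cohorts whose goal-directed control breaks down
specifically after losses.  A lognormal response-time layer adds the two
latency signatures of interest: slowing on rare transitions (scaled by the
agent's effective model-based weight) and first-stage speeding after a
non-rewarded trial.

The agents are data generators, not estimators: no routine here fits
parameters to observed behavior.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .task import (
    TaskConfig,
    TransitionStructure,
    RewardWalkSet,
    init_walks,
    step_walks,
    sample_transition,
    sample_reward,
    subject_streams,
)

__all__ = [
    "RTParams",
    "AgentParams",
    "ValueState",
    "mb_values",
    "td_update",
    "choose",
    "effective_w",
    "generate_rts",
    "simulate_subject",
    "TRIAL_COLUMNS",
]

#: Canonical column order of the trial-level table.
TRIAL_COLUMNS = [
    "subject_id",
    "group",
    "severity",
    "trial",
    "s1_choice",
    "s1_rt_ms",
    "transition",
    "s2_state",
    "s2_choice",
    "s2_rt_ms",
    "reward",
    "missed_stage",
]


@dataclass(frozen=True)
class RTParams:
    """Parameters of the generative response-time layer (milliseconds).

    RTs are ``rt_floor + Lognormal`` with the lognormal median shifted
    additively by the experimental condition: the stage-1 median drops by
    ``delta_loss`` after a non-rewarded trial, and the stage-2 median rises
    by ``delta_rare * w_eff`` on rare transitions, where ``w_eff`` is the
    agent's current effective model-based weight (slowing on rare
    transitions is a model-based phenomenon, so purely model-free agents
    show none).
    """

    mu1: float = 330.0
    delta_loss: float = 0.0
    mu2: float = 495.0
    delta_rare: float = 60.0
    sigma_rt: float = 0.22
    rt_floor: float = 100.0

    def __post_init__(self) -> None:
        if self.rt_floor < 0:
            raise ValueError("rt_floor must be >= 0")
        if self.mu1 <= 0 or self.mu2 <= 0:
            raise ValueError("mu1 and mu2 must be positive")
        if self.sigma_rt < 0:
            raise ValueError("sigma_rt must be >= 0")


@dataclass(frozen=True)
class AgentParams:
    """Learning, choice and response-time parameters of one agent.

    ``w_pos = w_neg = 0`` gives a pure model-free agent, ``w_pos = w_neg = 1``
    a pure model-based agent.
    """

    alpha: float = 0.6
    lam: float = 0.6
    beta1: float = 4.5
    beta2: float = 3.5
    w_pos: float = 0.7
    w_neg: float = 0.7
    persev: float = 0.2
    p_miss: float = 0.0
    rt: RTParams = field(default_factory=RTParams)

    def __post_init__(self) -> None:
        for name in ("alpha", "lam", "w_pos", "w_neg"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.beta1 < 0 or self.beta2 < 0:
            raise ValueError("inverse temperatures must be >= 0")
        if not 0.0 <= self.p_miss < 1.0:
            raise ValueError(f"p_miss must be in [0, 1), got {self.p_miss}")


@dataclass
class ValueState:
    """Learner state: second-stage values plus stage-1 MF/MB values."""

    q2: np.ndarray  # (2 states, 2 options)
    q_mf: np.ndarray  # (2 first-stage options,)

    @classmethod
    def initial(cls, value: float = 0.5) -> "ValueState":
        # Rewards are 0/1 with probabilities bounded away from the extremes,
        # so the midpoint is the natural agnostic starting value.
        return cls(q2=np.full((2, 2), value), q_mf=np.full(2, value))


def mb_values(q2: np.ndarray, structure: TransitionStructure) -> np.ndarray:
    """Model-based first-stage values from prospective planning.

    q_mb(a) = p_common * max_o q2(common(a), o)
            + (1 - p_common) * max_o q2(other(a), o)
    """
    state_max = np.max(q2, axis=1)  # best attainable value in each state
    p = structure.p_common
    return np.array(
        [
            p * state_max[structure.common_state(a)]
            + (1.0 - p) * state_max[structure.other_state(a)]
            for a in (0, 1)
        ]
    )


def td_update(
    state: ValueState,
    s1_choice: int,
    s2_state: int,
    s2_choice: int,
    reward: float,
    params: AgentParams,
) -> ValueState:
    """SARSA(lambda)-style update after a completed trial.

    The second-stage value moves toward the reward by a delta rule; the
    first-stage model-free value moves toward the *pre-update* second-stage
    value, plus an eligibility-trace shortcut that passes the reward
    prediction error back one stage with gain ``lam``.
    """
    a, l = params.alpha, params.lam
    q2_old = state.q2[s2_state, s2_choice]
    q2 = state.q2.copy()
    q_mf = state.q_mf.copy()
    q2[s2_state, s2_choice] = q2_old + a * (reward - q2_old)
    q_mf[s1_choice] = (
        q_mf[s1_choice] + a * (q2_old - q_mf[s1_choice]) + a * l * (reward - q2_old)
    )
    return ValueState(q2=q2, q_mf=q_mf)


def choose(
    values: np.ndarray,
    beta: float,
    rng: np.random.Generator,
    persev: float = 0.0,
    prev_choice: int | None = None,
) -> int:
    """Softmax choice: P(a) proportional to exp(beta*v(a) + persev*[a == prev])."""
    z = beta * np.asarray(values, dtype=float)
    if prev_choice is not None:
        z = z.copy()
        z[prev_choice] += persev
    z -= z.max()  # shift invariance, avoids overflow
    p = np.exp(z)
    p /= p.sum()
    return int(rng.random() >= p[0])  # binary: index 1 iff u >= P(0)


def choice_probabilities(
    values: np.ndarray,
    beta: float,
    persev: float = 0.0,
    prev_choice: int | None = None,
) -> np.ndarray:
    """Softmax probabilities themselves (used by tests and diagnostics)."""
    z = beta * np.asarray(values, dtype=float)
    if prev_choice is not None:
        z = z.copy()
        z[prev_choice] += persev
    z -= z.max()
    p = np.exp(z)
    return p / p.sum()


def effective_w(prev_outcome: int | None, params: AgentParams) -> float:
    """Valence-dependent model-based weight.

    ``w_pos`` after a rewarded trial, ``w_neg`` after a non-rewarded one,
    and their midpoint when there is no previous outcome (first trial).
    """
    if prev_outcome is None:
        return 0.5 * (params.w_pos + params.w_neg)
    return params.w_pos if prev_outcome else params.w_neg


def _lognormal_rt(median: float, sigma: float, floor: float, rng: np.random.Generator) -> float:
    med = max(median, 1.0)  # keep the log defined if deltas push the median low
    return floor + math.exp(rng.normal(math.log(med), sigma))


def generate_rts(
    prev_outcome: int | None,
    transition: str,
    w_eff: float,
    params: AgentParams,
    config: TaskConfig,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Draw stage-1 and stage-2 response times for one trial (ms).

    Stage-1 median: mu1 - delta_loss after a previous non-reward.
    Stage-2 median: mu2 + delta_rare * w_eff on rare transitions.
    """
    rt = params.rt
    med1 = rt.mu1 - (rt.delta_loss if prev_outcome == 0 else 0.0)
    med2 = rt.mu2 + (rt.delta_rare * w_eff if transition == "rare" else 0.0)
    rt1 = _lognormal_rt(med1, rt.sigma_rt, rt.rt_floor, rng)
    rt2 = _lognormal_rt(med2, rt.sigma_rt, rt.rt_floor, rng)
    return rt1, rt2


def simulate_subject(
    params: AgentParams,
    config: TaskConfig,
    seed: int | np.random.SeedSequence,
    subject_id: str = "sim",
    group: str = "",
    severity: int = 0,
) -> pd.DataFrame:
    """Simulate one subject's full session; returns a trial-level table.

    Per trial: effective weight -> stage-1 softmax -> transition -> stage-2
    softmax -> reward -> RTs -> value update -> walk step.  A stage is
    missed with probability ``p_miss`` (or when its drawn RT exceeds the
    deadline); a missed stage aborts the trial with no reward and no value
    update.  The reward walks advance every trial regardless, since they
    model drift in the environment, not in the agent.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    streams = subject_streams(ss)
    structure = TransitionStructure(p_common=config.p_common)
    walks = init_walks(config, streams["walks"])
    state = ValueState.initial()
    deadline_ms = config.choice_deadline * 1000.0

    prev_outcome: int | None = None
    prev_choice: int | None = None
    rows = []
    for t in range(config.n_trials):
        w = effective_w(prev_outcome, params)
        q_mb = mb_values(state.q2, structure)
        q_net = w * q_mb + (1.0 - w) * state.q_mf

        row = dict.fromkeys(TRIAL_COLUMNS)
        row.update(subject_id=subject_id, group=group, severity=severity, trial=t)

        miss1 = streams["rts"].random() < params.p_miss
        if miss1:
            row["missed_stage"] = "stage1"
            rows.append(row)
            walks = step_walks(walks, config, streams["walks"])
            continue

        c1 = choose(q_net, params.beta1, streams["choices"], params.persev, prev_choice)
        s2_state, transition = sample_transition(c1, structure, streams["transitions"])
        rt1, rt2 = generate_rts(prev_outcome, transition, w, params, config, streams["rts"])
        if rt1 > deadline_ms:
            row.update(missed_stage="stage1")
            rows.append(row)
            walks = step_walks(walks, config, streams["walks"])
            continue
        row.update(s1_choice=c1, s1_rt_ms=rt1, transition=transition, s2_state=s2_state)

        miss2 = streams["rts"].random() < params.p_miss or rt2 > deadline_ms
        if miss2:
            row["missed_stage"] = "stage2"
            rows.append(row)
            prev_choice = c1
            walks = step_walks(walks, config, streams["walks"])
            continue

        c2 = choose(state.q2[s2_state], params.beta2, streams["choices"])
        r = sample_reward(s2_state, c2, walks, streams["rewards"])
        row.update(s2_choice=c2, s2_rt_ms=rt2, reward=r, missed_stage="none")
        rows.append(row)

        state = td_update(state, c1, s2_state, c2, r, params)
        prev_outcome = r
        prev_choice = c1
        walks = step_walks(walks, config, streams["walks"])

    df = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    return df
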