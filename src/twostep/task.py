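"""Generative model of the two-step task environment.

A first-stage choice between two options leads probabilistically (common
70% / rare 30%) to one of two second-stage states; each second-stage
option pays a unit reward with a probability that drifts across trials as
a bounded Gaussian random walk.  The walk keeps reward contingencies
non-stationary so that agents must keep learning throughout the session.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TaskConfig",
    "TransitionStructure",
    "RewardWalkSet",
    "init_walks",
    "step_walks",
    "sample_transition",
    "sample_reward",
    "subject_streams",
    "walk_trajectory",
]

#: Names of the independent random substreams a simulated subject consumes.
STREAM_ROLES = ("walks", "transitions", "rewards", "choices", "rts")


@dataclass(frozen=True)
class TaskConfig:
    """Constants of the two-step task.

    Defaults follow the standard laboratory version: 200 trials, 70/30
    transition structure, reward-probability random walks with increment
    SD 0.025 reflected at [0.25, 0.75], and 3-s choice deadlines.
    """

    n_trials: int = 200
    p_common: float = 0.70
    walk_sd: float = 0.025
    walk_lower: float = 0.25
    walk_upper: float = 0.75
    choice_deadline: float = 3.0
    feedback_duration: float = 1.0
    inter_stage_interval: float = 1.0
    inter_trial_interval: float = 1.0
    reward_magnitude: float = 0.10

    def __post_init__(self) -> None:
        if not 0.0 < self.p_common < 1.0:
            raise ValueError(f"p_common must be in (0, 1), got {self.p_common}")
        if not 0.0 <= self.walk_lower <= self.walk_upper <= 1.0:
            raise ValueError(
                f"walk bounds must satisfy 0 <= lower <= upper <= 1, "
                f"got [{self.walk_lower}, {self.walk_upper}]"
            )
        if self.walk_sd < 0:
            raise ValueError(f"walk_sd must be >= 0, got {self.walk_sd}")
        if self.n_trials < 2:
            raise ValueError(f"n_trials must be >= 2, got {self.n_trials}")


@dataclass(frozen=True)
class TransitionStructure:
    """Fixed mapping from first-stage options to their common states.

    Option 0 leads commonly to state 0, option 1 to state 1; the mapping
    is constant across trials (participants are instructed that it is).
    """

    p_common: float = 0.70

    def common_state(self, s1_choice: int) -> int:
        return int(s1_choice)

    def other_state(self, s1_choice: int) -> int:
        return 1 - int(s1_choice)


@dataclass
class RewardWalkSet:
    """Reward probabilities for the 2 states x 2 options, one walk each."""

    p: np.ndarray  # shape (2, 2): [state, option]
    trial_index: int = 0


def subject_streams(seed_seq: np.random.SeedSequence) -> dict[str, np.random.Generator]:
    """Split a subject-level seed into one named substream per role.

    Separate streams for walks, transitions, rewards, choices and RTs keep
    each stochastic component reproducible in isolation: changing e.g. the
    choice rule never perturbs the reward-walk trajectory.
    """
    children = seed_seq.spawn(len(STREAM_ROLES))
    return {role: np.random.default_rng(child) for role, child in zip(STREAM_ROLES, children)}


def init_walks(config: TaskConfig, rng: np.random.Generator) -> RewardWalkSet:
    """Draw the four starting reward probabilities uniformly within bounds."""
    p = rng.uniform(config.walk_lower, config.walk_upper, size=(2, 2))
    return RewardWalkSet(p=p, trial_index=0)


def _reflect(p: np.ndarray, lower: float, upper: float) -> np.ndarray:
    # One reflection suffices for |increment| < (upper - lower); loop for safety.
    p = np.asarray(p, dtype=float).copy()
    for _ in range(100):
        over = p > upper
        under = p < lower
        if not (over.any() or under.any()):
            break
        p[over] = 2.0 * upper - p[over]
        p[under] = 2.0 * lower - p[under]
    return np.clip(p, lower, upper)


def step_walks(
    walks: RewardWalkSet,
    config: TaskConfig,
    rng: np.random.Generator,
    return_increments: bool = False,
):
    """Advance all four walks by one Gaussian step, reflecting at the bounds.

    A raw value crossing a bound is folded back (p' = 2*bound - p_raw), so
    the stationary distribution stays uniform-ish within the bounds rather
    than piling up at them.  ``return_increments`` exposes the raw
    pre-reflection Gaussian increments for diagnostics.
    """
    eps = rng.normal(0.0, config.walk_sd, size=(2, 2))
    p_new = _reflect(walks.p + eps, config.walk_lower, config.walk_upper)
    out = RewardWalkSet(p=p_new, trial_index=walks.trial_index + 1)
    if return_increments:
        return out, eps
    return out


def sample_transition(
    s1_choice: int,
    structure: TransitionStructure,
    rng: np.random.Generator,
) -> tuple[int, str]:
    """Sample the second-stage state for a first-stage choice.

    Returns ``(s2_state, label)`` where the label is "common" when the
    state is the choice's frequent destination and "rare" otherwise.
    """
    if s1_choice not in (0, 1):
        raise ValueError(f"s1_choice must be 0 or 1, got {s1_choice}")
    if rng.random() < structure.p_common:
        return structure.common_state(s1_choice), "common"
    return structure.other_state(s1_choice), "rare"


def walk_trajectory(
    config: TaskConfig,
    seed: int | np.random.SeedSequence = 0,
    n_trials: int | None = None,
):
    """Simulate one walk set and return its trajectory as a table.

    Columns: trial, p_s0_o0, p_s0_o1, p_s1_o0, p_s1_o1 — exportable as
    delimited text for inspection or plotting.
    """
    import pandas as pd

    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    n = config.n_trials if n_trials is None else n_trials
    walks = init_walks(config, rng)
    rows = [walks.p.ravel().copy()]
    for _ in range(n - 1):
        walks = step_walks(walks, config, rng)
        rows.append(walks.p.ravel().copy())
    df = pd.DataFrame(rows, columns=["p_s0_o0", "p_s0_o1", "p_s1_o0", "p_s1_o1"])
    df.insert(0, "trial", range(n))
    return df


def sample_reward(
    s2_state: int,
    s2_choice: int,
    walks: RewardWalkSet,
    rng: np.random.Generator,
) -> int:
    """Bernoulli reward with the current walk probability of the chosen option."""
    if s2_state not in (0, 1) or s2_choice not in (0, 1):
        raise ValueError(f"state/choice out of range: ({s2_state}, {s2_choice})")
    return int(rng.random() < walks.p[s2_state, s2_choice])
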