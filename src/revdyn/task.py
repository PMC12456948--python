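"""Probabilistic reversal-learning task simulator.

A block consists of ``T`` trials with two options, A and B. One option is
"high-value" and yields reward with probability ``p`` when its rewarded-choice
indicator comes up; at a scheduled reversal trial, drawn uniformly from a
window around the block midpoint, the high-value option switches to the other
one. An agent (a policy, an RNN, or a Bayesian model follower) chooses on each
trial, is compared against the stochastically drawn rewarded choice, and
receives one of four feedback types encoding (its choice, reward bit).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CHOICES",
    "CHOICE_TO_INT",
    "opposite",
    "TaskConfig",
    "BlockSchedule",
    "TrialRecord",
    "BlockRecord",
    "sample_schedule",
    "sample_rewarded_choice",
    "feedback_for",
    "run_block_with_policy",
    "blocks_to_frame",
]

#: Choice labels; A maps to 0 and B to 1 wherever an integer code is needed.
CHOICES = ("A", "B")
CHOICE_TO_INT = {"A": 0, "B": 1}
INT_TO_CHOICE = {0: "A", 1: "B"}

#: feedback_type keyed by (choice, rewarded_choice)
_FEEDBACK_TABLE = {
    ("A", "A"): ("A1", 1),
    ("A", "B"): ("A0", 0),
    ("B", "A"): ("B0", 0),
    ("B", "B"): ("B1", 1),
}

FEEDBACK_TYPES = ("A1", "A0", "B0", "B1")


def opposite(choice: str) -> str:
    """Return the other option label."""
    if choice == "A":
        return "B"
    if choice == "B":
        return "A"
    raise ValueError(f"invalid choice label {choice!r}")


@dataclass(frozen=True)
class TaskConfig:
    """Parameters of the reversal-learning block.

    Parameters
    ----------
    n_trials
        Trials per block, ``T``. Training blocks default to 24 and testing
        blocks to 36 elsewhere in the package; this type carries whatever is
        simulated.
    reward_prob
        Probability ``p`` that the current high-value option is the rewarded
        choice on a trial. The low-value option is rewarded with ``1 - p``.
    reversal_halfwidth
        Half-width ``h`` of the uniform scheduled-reversal window
        ``[T/2 - h, T/2 + h]`` (inclusive; 2h+1 candidate trials).
    seed
        Default seed for convenience constructors; operations take explicit
        generators so the config itself is stateless.
    """

    n_trials: int = 24
    reward_prob: float = 0.7
    reversal_halfwidth: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials % 2 != 0:
            raise ValueError("n_trials must be even")
        if self.reversal_halfwidth < 0:
            raise ValueError("reversal_halfwidth must be nonnegative")
        if self.n_trials < 2 * self.reversal_halfwidth + 2:
            raise ValueError(
                "n_trials must be at least 2*reversal_halfwidth + 2 so the "
                "reversal window stays inside the block"
            )
        if not (0.0 < self.reward_prob <= 1.0):
            raise ValueError("reward_prob must lie in (0, 1]")
        mid = self.n_trials // 2
        if mid - self.reversal_halfwidth < 2 or mid + self.reversal_halfwidth > self.n_trials - 1:
            raise ValueError("reversal window extends outside trials [2, T-1]")


@dataclass(frozen=True)
class BlockSchedule:
    """Scheduled reversal trial (1-based) and the initial high-value option."""

    scheduled_reversal: int
    initial_high_value: str

    def high_value_at(self, k: int) -> str:
        """High-value option on 1-based trial ``k``."""
        if k < self.scheduled_reversal:
            return self.initial_high_value
        return opposite(self.initial_high_value)


@dataclass(frozen=True)
class TrialRecord:
    trial: int  # 1-based index k
    choice: str
    rewarded_choice: str
    reward: int
    feedback_type: str


@dataclass
class BlockRecord:
    """One completed block: its schedule and the per-trial records."""

    schedule: BlockSchedule
    trials: list[TrialRecord] = field(default_factory=list)
    behavioral_reversal: Optional[int] = None  # filled by the bayes module

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def choices(self) -> list[str]:
        return [t.choice for t in self.trials]

    @property
    def rewards(self) -> np.ndarray:
        return np.array([t.reward for t in self.trials], dtype=int)

    @property
    def reward_rate(self) -> float:
        return float(self.rewards.mean())


def sample_schedule(config: TaskConfig, rng: np.random.Generator) -> BlockSchedule:
    """Draw a block schedule: uniform reversal trial and random initial option.

    The scheduled reversal is uniform over the inclusive integer interval
    ``[T/2 - h, T/2 + h]`` and the initial high-value option is uniform over
    {A, B}.
    """
    mid = config.n_trials // 2
    h = config.reversal_halfwidth
    r = int(rng.integers(mid - h, mid + h + 1))
    initial = CHOICES[int(rng.integers(0, 2))]
    return BlockSchedule(scheduled_reversal=r, initial_high_value=initial)


def sample_rewarded_choice(
    schedule: BlockSchedule, k: int, p: float, rng: np.random.Generator
) -> str:
    """Draw the rewarded choice on trial ``k``.

    Before the scheduled reversal the initial high-value option is rewarded
    with probability ``p``; from the reversal trial onward with ``1 - p``.
    """
    q = p if k < schedule.scheduled_reversal else 1.0 - p
    if rng.random() < q:
        return schedule.initial_high_value
    return opposite(schedule.initial_high_value)


def feedback_for(choice: str, rewarded_choice: str) -> tuple[str, int]:
    """Map (choice, rewarded choice) to the feedback type and reward bit.

    The four feedback types encode the chosen option and whether it matched
    the rewarded choice: A1/B1 rewarded, A0/B0 unrewarded.
    """
    try:
        return _FEEDBACK_TABLE[(choice, rewarded_choice)]
    except KeyError:
        raise ValueError(
            f"invalid choice labels ({choice!r}, {rewarded_choice!r}); expected 'A' or 'B'"
        ) from None


Policy = Callable[[Sequence[TrialRecord]], str]


def run_block_with_policy(
    schedule: BlockSchedule,
    policy: Policy,
    config: TaskConfig,
    rng: np.random.Generator,
) -> BlockRecord:
    """Roll out one block under a history-dependent choice policy.

    ``policy`` receives the list of completed TrialRecords (length 0..T-1) and
    must return 'A' or 'B'. Rewarded choices are drawn independently per trial
    from the schedule; everything is deterministic given the generator state.
    """
    trials: list[TrialRecord] = []
    for k in range(1, config.n_trials + 1):
        choice = policy(trials)
        if choice not in CHOICES:
            raise ValueError(f"policy returned invalid label {choice!r} on trial {k}")
        rewarded = sample_rewarded_choice(schedule, k, config.reward_prob, rng)
        ftype, reward = feedback_for(choice, rewarded)
        trials.append(
            TrialRecord(
                trial=k,
                choice=choice,
                rewarded_choice=rewarded,
                reward=reward,
                feedback_type=ftype,
            )
        )
    return BlockRecord(schedule=schedule, trials=trials)


def blocks_to_frame(blocks: Sequence[BlockRecord]) -> pd.DataFrame:
    """Serialize blocks to a tidy frame, one row per trial."""
    rows = []
    for b, block in enumerate(blocks):
        for t in block.trials:
            rows.append(
                {
                    "block_id": b,
                    "trial": t.trial,
                    "choice": t.choice,
                    "rewarded_choice": t.rewarded_choice,
                    "reward": t.reward,
                    "feedback_type": t.feedback_type,
                    "scheduled_reversal": block.schedule.scheduled_reversal,
                    "initial_high_value": block.schedule.initial_high_value,
                    "behavioral_reversal": block.behavioral_reversal,
                }
            )
    return pd.DataFrame(rows)
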