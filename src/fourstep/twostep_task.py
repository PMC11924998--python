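"""Two-Step task simulator with block-stationary reward probabilities.

Each trial has two stages: a binary Step-1 choice between two colors,
which leads to one of two Step-2 states ("A" or "B") — the commonly
associated state with probability ``p_common`` = 0.75, the other state
otherwise — followed by a binary choice between the two shapes offered
in that state. Exactly one of the four shapes pays out with high
probability (0.8); the other three pay out rarely (1/12 = 8.3%). The
high shape is constant for a 32-trial block and switches to a different
shape at every block boundary; a session is 9 blocks = 288 trials.

Coding conventions: states are 0 (Step 1), 1 (A), 2 (B); shapes carry
global ids 0..3 with shapes (0, 1) offered in state A and (2, 3) in
state B; ``choice2`` indexes the shape within the realized state
(global shape id = 2 * (state2 - 1) + choice2). The fixed common
mapping sends Step-1 action 0 to state A and action 1 to state B.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

STATE_A = 1
STATE_B = 2
COMMON = "common"
RARE = "rare"

TRIAL_COLUMNS = [
    "subject_id", "trial", "choice1", "transition", "state2",
    "choice2", "reward", "rt2_ms", "high_shape",
]


@dataclass(frozen=True)
class TaskConfig:
    n_blocks: int = 9
    block_len: int = 32
    p_common: float = 0.75
    p_high: float = 0.8
    p_low: float = 1.0 / 12.0

    def __post_init__(self):
        for name in ("p_common", "p_high", "p_low"):
            if not 0 < getattr(self, name) < 1:
                raise ValueError(f"{name} must be in (0, 1)")
        if self.p_common <= 0.5:
            raise ValueError("p_common must exceed 0.5 (it defines 'common')")
        if self.n_blocks < 1 or self.block_len < 1:
            raise ValueError("n_blocks and block_len must be positive")

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.block_len


@dataclass
class Schedule:
    """Per-trial identity of the high-reward shape (global id 0..3)."""

    config: TaskConfig
    high_shape: np.ndarray  # int array, length n_trials

    def __post_init__(self):
        if len(self.high_shape) != self.config.n_trials:
            raise ValueError("high_shape length must equal n_trials")

    @property
    def n_trials(self) -> int:
        return self.config.n_trials

    def high_state(self, t: int) -> int:
        """The Step-2 state (1 or 2) containing the high shape at trial t."""
        return int(self.high_shape[t]) // 2 + 1


@dataclass(frozen=True)
class TwoStepTrial:
    trial: int
    choice1: int
    transition: str
    state2: int
    choice2: int
    reward: int
    rt2_ms: float = math.nan
    high_shape: int = -1


def common_state(choice1: int) -> int:
    """The Step-2 state commonly reached from a Step-1 action."""
    return STATE_A if choice1 == 0 else STATE_B


def generate_schedule(config: TaskConfig, rng: np.random.Generator) -> Schedule:
    """Draw the block sequence of high shapes: first block uniform over
    the 4 shapes, each later block uniform over the other 3."""
    highs = np.empty(config.n_trials, dtype=np.int64)
    current = int(rng.integers(4))
    for b in range(config.n_blocks):
        if b > 0:
            current = int(rng.choice([s for s in range(4) if s != current]))
        highs[b * config.block_len:(b + 1) * config.block_len] = current
    return Schedule(config=config, high_shape=highs)


def run_trial(
    schedule: Schedule,
    t: int,
    choice1: int,
    choice2: int,
    rng: np.random.Generator,
) -> TwoStepTrial:
    """Realize one trial given both choices: draw the transition, map to
    the Step-2 state, and draw the reward of the chosen shape."""
    if not 0 <= t < schedule.n_trials:
        raise IndexError(f"trial {t} outside schedule of {schedule.n_trials}")
    cfg = schedule.config
    is_common = rng.random() < cfg.p_common
    state2 = common_state(choice1) if is_common else (
        STATE_B if common_state(choice1) == STATE_A else STATE_A
    )
    shape = 2 * (state2 - 1) + choice2
    p_reward = cfg.p_high if shape == schedule.high_shape[t] else cfg.p_low
    reward = int(rng.random() < p_reward)
    return TwoStepTrial(
        trial=t,
        choice1=choice1,
        transition=COMMON if is_common else RARE,
        state2=state2,
        choice2=choice2,
        reward=reward,
        high_shape=int(schedule.high_shape[t]),
    )


def trials_to_frame(trials, subject_id: str = "s0") -> pd.DataFrame:
    """Trial list -> the canonical trial-table DataFrame."""
    return pd.DataFrame(
        {
            "subject_id": subject_id,
            "trial": [t.trial for t in trials],
            "choice1": [t.choice1 for t in trials],
            "transition": [t.transition for t in trials],
            "state2": [t.state2 for t in trials],
            "choice2": [t.choice2 for t in trials],
            "reward": [t.reward for t in trials],
            "rt2_ms": [t.rt2_ms for t in trials],
            "high_shape": [t.high_shape for t in trials],
        }
    )
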