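"""Tracking-error scores and motor-learning rates.

The adjustability-for-grasping (AGF) score of a trial half is the mean
absolute difference between target and measured grip force over the 100
samples of that half; block scores average the 5 trials of a block, and
the learning rate is the percent reduction of the mean AGF from block 1
to block 10, computed separately for the random half (external attention)
and the repeat half (internal attention).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .tasks import N1, N, N_SAMPLES, TaskSpec

__all__ = [
    "TrialRecord",
    "TrialScore",
    "BlockScore",
    "LearningRates",
    "UndefinedLearningRateError",
    "agf_random",
    "agf_repeat",
    "score_trial",
    "block_means",
    "learning_rates",
    "score_participant",
]

DEVICE_MIN = 0.0  # kg
DEVICE_MAX = 0.5  # kg

_RAN = slice(N1, N1 + N)  # 0-based random half, k = N1+1 .. N1+N
_REP = slice(N1 + N, N1 + 2 * N)  # 0-based repeat half


class UndefinedLearningRateError(ZeroDivisionError):
    """Raised when a block-10 mean AGF is zero (degenerate perfect tracking)."""


@dataclass(frozen=True)
class TrialRecord:
    """One measured participant-trial aligned to its task."""

    participant_id: str
    group: str  # "NC" | "MCI"
    trial_index: int  # 1..50
    task_id: int  # 1..5
    measured: np.ndarray  # force in kg, shape (230,)

    def __post_init__(self) -> None:
        measured = np.asarray(self.measured, dtype=float)
        object.__setattr__(self, "measured", measured)
        if measured.shape != (N_SAMPLES,):
            raise ValueError(f"expected {N_SAMPLES} samples, got {measured.shape}")
        if np.any(np.isnan(measured)):
            raise ValueError("trial contains missing samples; trials are not imputed")
        if measured.min() < DEVICE_MIN or measured.max() > DEVICE_MAX:
            raise ValueError("measured force outside the device range [0, 0.5] kg")
        if not 1 <= self.trial_index <= 50:
            raise ValueError("trial_index must lie in 1..50")
        if self.task_id not in (1, 2, 3, 4, 5):
            raise ValueError("task_id must lie in 1..5")

    @property
    def block_index(self) -> int:
        """1..10; block j covers trials 5(j-1)+1 .. 5j."""
        return (self.trial_index - 1) // 5 + 1


@dataclass(frozen=True)
class TrialScore:
    trial_index: int
    task_id: int
    agf_ran: float  # kg
    agf_rep: float  # kg


@dataclass(frozen=True)
class BlockScore:
    block_index: int  # 1..10
    mean_agf_ran: float  # kg
    mean_agf_rep: float  # kg


@dataclass(frozen=True)
class LearningRates:
    lr_ran: float  # percent
    lr_rep: float  # percent


def _check_pair(trial: TrialRecord, spec: TaskSpec) -> None:
    if trial.task_id != spec.task_id:
        raise ValueError(
            f"trial is task {trial.task_id} but spec is task {spec.task_id}"
        )


def agf_random(trial: TrialRecord, spec: TaskSpec) -> float:
    """Mean |target - measured| in kg over the 100 random-half samples."""
    _check_pair(trial, spec)
    return float(np.mean(np.abs(spec.samples[_RAN] - trial.measured[_RAN])))


def agf_repeat(trial: TrialRecord, spec: TaskSpec) -> float:
    """Mean |target - measured| in kg over the 100 repeat-half samples."""
    _check_pair(trial, spec)
    return float(np.mean(np.abs(spec.samples[_REP] - trial.measured[_REP])))


def score_trial(trial: TrialRecord, spec: TaskSpec) -> TrialScore:
    return TrialScore(
        trial_index=trial.trial_index,
        task_id=trial.task_id,
        agf_ran=agf_random(trial, spec),
        agf_rep=agf_repeat(trial, spec),
    )


def block_means(scores: Sequence[TrialScore]) -> list[BlockScore]:
    """Average the 50 trial scores into 10 block scores of 5 trials each."""
    if len(scores) != 50:
        raise ValueError(f"expected exactly 50 trial scores, got {len(scores)}")
    idx = [s.trial_index for s in scores]
    if sorted(idx) != list(range(1, 51)):
        raise ValueError("trial indices must be exactly 1..50 with no gaps")
    ordered = sorted(scores, key=lambda s: s.trial_index)
    out = []
    for j in range(1, 11):
        chunk = ordered[5 * (j - 1) : 5 * j]
        out.append(
            BlockScore(
                block_index=j,
                mean_agf_ran=float(np.mean([s.agf_ran for s in chunk])),
                mean_agf_rep=float(np.mean([s.agf_rep for s in chunk])),
            )
        )
    return out


def learning_rates(blocks: Sequence[BlockScore]) -> LearningRates:
    """Percent AGF reduction from block 1 to block 10, per task half.

    Positive values indicate a learning effect (block-10 error below
    block-1 error); negative values (worsening) are allowed.
    """
    if len(blocks) != 10 or [b.block_index for b in blocks] != list(range(1, 11)):
        raise ValueError("expected blocks 1..10 in order")
    b1, b10 = blocks[0], blocks[-1]
    if b10.mean_agf_ran == 0.0 or b10.mean_agf_rep == 0.0:
        raise UndefinedLearningRateError(
            "block-10 mean AGF is zero; learning rate undefined for a perfect tracker"
        )
    return LearningRates(
        lr_ran=(b1.mean_agf_ran - b10.mean_agf_ran) / b10.mean_agf_ran * 100.0,
        lr_rep=(b1.mean_agf_rep - b10.mean_agf_rep) / b10.mean_agf_rep * 100.0,
    )


def score_participant(
    trials: Sequence[TrialRecord], specs: Sequence[TaskSpec]
) -> tuple[list[TrialScore], list[BlockScore], LearningRates]:
    """Score a complete 50-trial participant against the five-task set."""
    if len(trials) != 50:
        raise ValueError(f"expected 50 trials, got {len(trials)}")
    by_task = {s.task_id: s for s in specs}
    scores = [score_trial(t, by_task[t.task_id]) for t in trials]
    blocks = block_means(scores)
    return scores, blocks, learning_rates(blocks)
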