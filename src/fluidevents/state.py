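"""Per-participant evolving state of the sequential model."""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import List, Optional


@dataclass(frozen=True)
class Observation:
    """One time bin as observed: the action taken, an optional performance
    score in [0, 1], and a nonnegative environmental-change magnitude."""

    action: str
    score: Optional[float]
    env_change: float

    def __post_init__(self) -> None:
        if not str(self.action):
            raise ValueError("action label must be non-empty")
        if self.score is not None and not (0.0 <= self.score <= 1.0):
            raise ValueError(f"score must be in [0, 1], got {self.score}")
        if not (self.env_change >= 0.0):  # also rejects NaN
            raise ValueError(f"env_change must be finite and >= 0, got {self.env_change}")


@dataclass
class ParticipantState:
    """The model's memory for one participant.

    Cumulative experience (``flexibility``, shift count ``n_shifts``, trial
    count ``n_trials``) spans the whole task and, by default, carries across
    conditions. The sequential context (previous action/score/prediction,
    bins since the last shift, the recent-score window) is local to the
    current stream and is cleared by :meth:`start_stream`.
    """

    flexibility: float = 0.0
    n_shifts: int = 0
    n_trials: int = 0
    bins_since_shift: Optional[int] = None
    score_history: List[Optional[float]] = field(default_factory=list)
    prev_action: Optional[str] = None
    prev_prediction: Optional[float] = None
    prev_shift: Optional[int] = None
    bins_in_stream: int = 0
    history_limit: int = 11  # recent_window + 1 scores retained

    def start_stream(self) -> None:
        """Begin a new stream (condition): clear the sequential context while
        keeping cumulative experience."""
        self.bins_since_shift = None
        self.score_history = []
        self.prev_action = None
        self.prev_prediction = None
        self.prev_shift = None
        self.bins_in_stream = 0

    def copy(self) -> "ParticipantState":
        return copy.deepcopy(self)

    def _check(self) -> None:
        assert self.n_shifts <= self.n_trials
        assert self.bins_since_shift is None or self.bins_since_shift >= 1
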