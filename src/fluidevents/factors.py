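"""Closed-form factor functions of the switch-probability model.

Each factor maps a facet of the task or of the person's running experience
onto an additive contribution to the probability of abandoning the current
action. The event-structure factors (environmental change, time on task)
depend on the task; the experience factors (just shifted, number of shifts,
performance dip, bad shift, flexibility) depend on the person's history.

All functions accept scalars or numpy arrays and evaluate element-wise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from .constants import ModelConstants

ArrayLike = Union[int, float, np.ndarray]

#: Factor names in canonical (trace-column) order.
FACTOR_NAMES = (
    "env_change",
    "time_on_task",
    "just_shifted",
    "num_shifts",
    "performance_dip",
    "bad_shift",
    "flexibility",
)


def _check_integer(value: ArrayLike, name: str) -> None:
    arr = np.asarray(value)
    if not np.all(np.equal(np.mod(arr, 1), 0)):
        raise ValueError(f"{name} must be an integer count, got {value!r}")


def time_on_task_factor(n_trials: ArrayLike, base: float = 1.001) -> ArrayLike:
    """Drive toward switching that grows slowly with cumulative trials.

    Computed as ``1 - base**(-(A + 1))`` for trial count ``A``; strictly
    increasing in ``A`` and approaching 1 from below. Always active.
    """
    _check_integer(n_trials, "n_trials")
    if np.any(np.asarray(n_trials) < 1):
        raise ValueError("n_trials must be >= 1")
    return 1.0 - base ** (-(np.asarray(n_trials, dtype=float) + 1.0)) \
        if isinstance(n_trials, np.ndarray) else 1.0 - base ** (-(n_trials + 1))


def num_shifts_factor(n_shifts: ArrayLike, base: float = 1.001) -> ArrayLike:
    """Inhibition that accumulates with the number of past action shifts.

    Computed as ``base**(-S) - 1``: zero at ``S = 0`` and strictly
    decreasing (more negative) as shifts accumulate. Active once S >= 1.
    """
    _check_integer(n_shifts, "n_shifts")
    if np.any(np.asarray(n_shifts) < 0):
        raise ValueError("n_shifts must be >= 0")
    return base ** (-np.asarray(n_shifts, dtype=float)) - 1.0 \
        if isinstance(n_shifts, np.ndarray) else base ** (-n_shifts) - 1.0


def just_shifted_factor(bins_since_shift: ArrayLike, scale: float = 0.01) -> ArrayLike:
    """Short-lived inhibition right after an action shift.

    Computed as ``-scale * R**(-(R + 1))`` for ``R`` bins since the last
    shift: a fast-decaying negative term (-0.01 at R=1, -0.00125 at R=2,
    ~-0.0001 at R=3) that gives a newly adopted action a chance to work.
    Only applies in the absence of an environmental change.
    """
    _check_integer(bins_since_shift, "bins_since_shift")
    if np.any(np.asarray(bins_since_shift) < 1):
        raise ValueError("bins_since_shift must be >= 1")
    r = np.asarray(bins_since_shift, dtype=float)
    out = -scale * r ** (-(r + 1.0))
    return out if isinstance(bins_since_shift, np.ndarray) else float(out)


def performance_dip_factor(decrease: ArrayLike, base: float = 1.1) -> ArrayLike:
    """Drive toward switching after a recent drop in performance.

    Computed as ``1 - base**(-(C + 1))`` for dip magnitude ``C >= 0``;
    strictly increasing in ``C``. Note the function is evaluated only when a
    dip is detected: activity is decided by :func:`dip_magnitude`, not by
    this value being nonzero.
    """
    if np.any(np.asarray(decrease) < 0):
        raise ValueError("decrease must be >= 0")
    c = np.asarray(decrease, dtype=float)
    out = 1.0 - base ** (-(c + 1.0))
    return out if isinstance(decrease, np.ndarray) else float(out)


def bad_shift_factor(dip: float, prev_was_shift: bool) -> float:
    """Duplicate the dip term when the dip immediately followed a shift.

    A performance drop right after an action change suggests the new action
    is a poor fit, doubling the pressure to abandon it. Realized as an
    additive copy of the active dip contribution.
    """
    if dip < 0:
        raise ValueError("dip must be >= 0")
    return dip if (prev_was_shift and dip > 0) else 0.0


def update_flexibility(flexibility: float, prev_shift: int,
                       prev_prediction: float, learning_rate: float = 0.1) -> float:
    """Delta-rule update of the person's running switch bias.

    ``F <- F + eta * (H - P)`` where ``H`` is whether a shift actually
    occurred on the previous bin and ``P`` was the model's prediction for
    it. Under-predicted shifts raise flexibility; over-predictions lower it.
    """
    if not 0.0 <= prev_prediction <= 1.0:
        raise ValueError("prev_prediction must be a probability")
    if prev_shift not in (0, 1):
        raise ValueError("prev_shift must be 0 or 1")
    return flexibility + learning_rate * (prev_shift - prev_prediction)


def dip_magnitude(scores: Sequence[float], mode: str = "raw_decrease",
                  window: int = 10) -> Optional[float]:
    """Magnitude C of a recent performance dip, or ``None`` when inactive.

    ``scores`` is the performance history up to and including the previous
    bin (most recent last). In ``raw_decrease`` mode, C is the lag-1 drop
    ``scores[-2] - scores[-1]`` when positive. In ``normalized_window``
    mode, C is how far the previous score fell below the minimum of the up
    to ``window`` scores preceding it, normalized by the range of that
    window; inactive when the previous score is within the recent range or
    the window is degenerate (zero range or too short).
    """
    if len(scores) < 2:
        return None
    prev = scores[-1]
    if prev is None or scores[-2] is None:
        return None
    if mode == "raw_decrease":
        drop = scores[-2] - prev
        return drop if drop > 0 else None
    if mode == "normalized_window":
        recent = [s for s in scores[-(window + 1):-1] if s is not None]
        if not recent:
            return None
        s_min, s_max = min(recent), max(recent)
        if s_max == s_min or prev >= s_min:
            return None
        return (s_min - prev) / (s_max - s_min)
    raise ValueError(f"unknown dip mode: {mode!r}")


@dataclass(frozen=True)
class FactorVector:
    """Per-bin factor values plus which factors are active.

    Inactive factors carry the value 0.0; ``active`` records which factors'
    triggering conditions held (a factor counts as active even when its
    value rounds to zero). Time on task and flexibility are always active.
    """

    env_change: float
    time_on_task: float
    just_shifted: float
    num_shifts: float
    performance_dip: float
    bad_shift: float
    flexibility: float
    active: frozenset

    @property
    def active_count(self) -> int:
        return len(self.active)

    @property
    def total(self) -> float:
        """Unclamped sum of the active factor contributions."""
        return math.fsum(getattr(self, name) for name in self.active)

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in FACTOR_NAMES}
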