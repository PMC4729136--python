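"""Model constants and run configuration.

The switch-probability model is deliberately parameter-light: a handful of
fixed constants shared across every task, never refit per dataset. The
defaults here are those fixed values; they are exposed so that sensitivity
analyses can perturb them, not because the model is meant to be tuned.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Literal

DipMode = Literal["raw_decrease", "normalized_window"]


@dataclass(frozen=True)
class ModelConstants:
    """Fixed numeric constants of the switch-probability model.

    Attributes
    ----------
    learning_rate
        Step size of the delta-rule flexibility update, in (0, 1].
    time_base
        Base of the time-on-task power function (> 1); values barely above 1
        make time-on-task a slow-moving factor.
    shift_count_base
        Base of the shift-count power function (> 1), likewise slow-moving.
    dip_base
        Base of the performance-dip power function (> 1); larger than the
        time bases so dips act quickly.
    just_shifted_scale
        Magnitude scale of the just-shifted inhibition (probability units).
    recent_window
        Number of preceding scores defining "recent performance" for the
        normalized dip mode.
    env_increment
        Probability added per changed situational dimension when coding
        environmental change from dimension counts.
    """

    learning_rate: float = 0.1
    time_base: float = 1.001
    shift_count_base: float = 1.001
    dip_base: float = 1.1
    just_shifted_scale: float = 0.01
    recent_window: int = 10
    env_increment: float = 0.1

    def __post_init__(self) -> None:
        for name in ("learning_rate", "time_base", "shift_count_base",
                     "dip_base", "just_shifted_scale", "env_increment"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not (0 < self.learning_rate <= 1):
            raise ValueError("learning_rate must be in (0, 1]")
        if self.time_base <= 1 or self.shift_count_base <= 1 or self.dip_base <= 1:
            raise ValueError("power-function bases must exceed 1")
        if self.recent_window < 1:
            raise ValueError("recent_window must be >= 1")


@dataclass(frozen=True)
class ModelConfig:
    """Constants plus the behavioural switches of a model run.

    ``dip_mode`` selects how the magnitude of a performance dip is measured:
    ``raw_decrease`` (the lag-1 score drop; the default, which reproduces the
    published worked example) or ``normalized_window`` (drop below the recent
    minimum, normalized by the recent range). ``reset_between_conditions``
    controls whether cumulative experience (flexibility, shift and trial
    counts) carries across a participant's conditions; by default it carries.
    ``clamp`` bounds the summed prediction to [0, 1].
    """

    constants: ModelConstants = ModelConstants()
    dip_mode: DipMode = "raw_decrease"
    reset_between_conditions: bool = False
    clamp: bool = True

    def __post_init__(self) -> None:
        if self.dip_mode not in ("raw_decrease", "normalized_window"):
            raise ValueError(f"unknown dip_mode: {self.dip_mode!r}")

    def to_dict(self) -> dict[str, Any]:
        return {
            "constants": dataclasses.asdict(self.constants),
            "dip_mode": self.dip_mode,
            "reset_between_conditions": self.reset_between_conditions,
            "clamp": self.clamp,
        }

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "ModelConfig":
        data = dict(data)
        constants = ModelConstants(**data.pop("constants", {}))
        return cls(constants=constants, **data)


def load_config(path: str | Path) -> ModelConfig:
    """Load a :class:`ModelConfig` from a JSON key-value file."""
    with open(path, encoding="utf-8") as fh:
        return ModelConfig.from_dict(json.load(fh))


def save_config(config: ModelConfig, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(config.to_dict(), fh, indent=2)
        fh.write("\n")
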