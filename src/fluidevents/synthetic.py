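"""Seeded synthetic event-stream cohorts with known structure.

Real deployments of the switch model consume behavioural streams (game
telemetry, reading times) that cannot be redistributed, so this module
generates statistical stand-ins: a bounded random-walk performance score,
sparse environmental changes drawn from a band mixture matching the
pooled distribution observed across tasks, and switch decisions sampled
from a known policy. Under the ``model_driven`` policy each bin's switch is
a Bernoulli draw from the model's own prediction, which makes the cohort
perfectly calibrated by construction — the strongest available ground
truth for the evaluation pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np

from .constants import ModelConfig
from .model import FluidEventsModel
from .state import Observation
from .streams import EventStream, TimeBin


@dataclass(frozen=True)
class EnvChangeMixture:
    """Mixture over environmental-change magnitudes: a point mass at zero
    plus uniform bands ``(low, high, mass)``. Unassigned mass sits at zero
    (most bins carry no situational change)."""

    bands: Tuple[Tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        total = sum(m for _, _, m in self.bands)
        if total > 1 + 1e-12:
            raise ValueError("band masses exceed 1")
        for low, high, mass in self.bands:
            if not (0 <= low < high) or mass < 0:
                raise ValueError(f"invalid band {(low, high, mass)}")

    @property
    def zero_mass(self) -> float:
        return 1.0 - sum(m for _, _, m in self.bands)

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        masses = [self.zero_mass] + [m for _, _, m in self.bands]
        choice = rng.choice(len(masses), size=size, p=masses)
        out = np.zeros(size)
        for k, (low, high, _) in enumerate(self.bands, start=1):
            sel = choice == k
            out[sel] = rng.uniform(low, high, size=int(sel.sum()))
        return out


#: Pooled-across-tasks default: 38% of bins carry a small change (under 0.1),
#: 10% a moderate one (0.4-0.5), 1% a large one (above 0.6), the rest none.
DEFAULT_ENV_MIXTURE = EnvChangeMixture(
    bands=((0.0, 0.1, 0.38), (0.4, 0.5, 0.10), (0.6, 0.8, 0.01)),
)


@dataclass(frozen=True)
class ModelDrivenPolicy:
    """Switch with probability equal to the generating model's own
    prediction for the bin."""

    initial_flexibility: float = 0.0
    config: ModelConfig = ModelConfig()


@dataclass(frozen=True)
class BernoulliPolicy:
    """Switch with a fixed per-bin probability, independent of history."""

    rate: float

    def __post_init__(self) -> None:
        if not 0 <= self.rate <= 1:
            raise ValueError("rate must be a probability")


@dataclass(frozen=True)
class CalibrationPolicy:
    """Switch with known per-bin probabilities cycled over the stream;
    useful for exercising calibration analyses against explicit truth."""

    probabilities: Tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.probabilities:
            raise ValueError("need at least one probability")
        if any(not 0 <= p <= 1 for p in self.probabilities):
            raise ValueError("probabilities must be in [0, 1]")


Policy = Union[ModelDrivenPolicy, BernoulliPolicy, CalibrationPolicy]


@dataclass(frozen=True)
class GeneratorParams:
    """Cohort recipe. Defaults mirror a continuous-game study arm: 15
    participants, 1360 five-second bins each, three actions, a 0.1-step
    score walk from 0.5, the pooled environmental-change mixture, and
    model-driven switching starting from zero flexibility."""

    n_participants: int = 15
    bins_per_stream: int = 1360
    actions: Tuple[str, ...] = ("1", "2", "3")
    env_mixture: EnvChangeMixture = DEFAULT_ENV_MIXTURE
    score_step: float = 0.1
    score_start: float = 0.5
    with_scores: bool = True
    policy: Policy = ModelDrivenPolicy()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bins_per_stream < 2:
            raise ValueError("bins_per_stream must be >= 2")
        if self.n_participants < 0:
            raise ValueError("n_participants must be >= 0")
        if len(self.actions) < 2:
            raise ValueError("need at least two actions")
        if not 0 <= self.score_start <= 1 or not 0 < self.score_step <= 1:
            raise ValueError("score walk parameters out of range")


def _reflect(x: float) -> float:
    # reflect a walk proposal back into [0, 1]
    while x < 0 or x > 1:
        x = -x if x < 0 else 2 - x
    return x


def generate_stream(params: GeneratorParams, participant: str,
                    condition: str = "c1",
                    rng: Optional[np.random.Generator] = None) -> EventStream:
    """Generate one stream. With no explicit ``rng``, the stream is a pure
    function of ``params.seed`` and the identifiers."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    env = params.env_mixture.sample(rng, params.bins_per_stream)

    model: Optional[FluidEventsModel] = None
    state = None
    if isinstance(params.policy, ModelDrivenPolicy):
        model = FluidEventsModel(params.policy.config)
        state = model.new_state(params.policy.initial_flexibility)
        state.start_stream()

    bins: List[TimeBin] = []
    score = params.score_start
    action = str(rng.choice(params.actions))
    for t in range(1, params.bins_per_stream + 1):
        if t > 1:
            step = params.score_step if rng.random() < 0.5 else -params.score_step
            score = _reflect(score + step)
        score_obs = round(float(score), 12) if params.with_scores else None

        if model is not None:
            p, _ = model.predict(state, env[t - 1])
        elif isinstance(params.policy, BernoulliPolicy):
            p = 0.0 if t == 1 else params.policy.rate
        else:
            probs = params.policy.probabilities
            p = 0.0 if t == 1 else probs[(t - 2) % len(probs)]

        if t > 1 and rng.random() < p:
            others = [a for a in params.actions if a != action]
            action = str(others[rng.integers(len(others))])

        bins.append(TimeBin(participant, condition, t, action, score_obs,
                            float(env[t - 1])))
        if model is not None:
            model.advance(state, Observation(action, score_obs, float(env[t - 1])), p)
    return EventStream(participant, condition, bins, task="synthetic")


def generate_cohort(params: GeneratorParams) -> List[EventStream]:
    """Generate ``n_participants`` independent streams from per-participant
    seeds derived from the master seed; deterministic given the master."""
    children = np.random.SeedSequence(params.seed).spawn(params.n_participants)
    streams = []
    width = max(2, len(str(max(params.n_participants, 1))))
    for i, child in enumerate(children, start=1):
        pid = f"p{i:0{width}d}"
        streams.append(generate_stream(params, pid,
                                       rng=np.random.default_rng(child)))
    return streams
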