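"""The sequential switch-probability state machine.

One participant is stepped bin by bin. At each bin the model (1) detects
whether the observed action differs from the previous one, (2) folds the
previous bin's prediction error into the running flexibility term, (3)
assembles the active factors from the pre-bin state and the current
environmental change, (4) emits the switch probability as the clamped sum
of the active factors, and (5) commits the observation into the state.

The first bin of a stream is forced to probability zero: with no prior
action there is no basis for a prediction, and no shift is scored there.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, List, Optional, Sequence

import pandas as pd

from .constants import ModelConfig
from .factors import (
    FactorVector,
    bad_shift_factor,
    dip_magnitude,
    just_shifted_factor,
    num_shifts_factor,
    performance_dip_factor,
    time_on_task_factor,
)
from .state import Observation, ParticipantState
from .streams import EventStream

#: Column layout of a diagnostic trace, matching the published worked table.
TRACE_COLUMNS = (
    "Time bin", "Score", "Prediction", "Switch", "Action",
    "Environmental change", "Time on task", "Just shifted",
    "No. of actions shifts", "Performance dip", "Bad shift",
    "Flexibility", "No. Components",
)

_FACTOR_TRACE_COLUMNS = (
    "Environmental change", "Time on task", "Just shifted",
    "No. of actions shifts", "Performance dip", "Bad shift", "Flexibility",
)


def round_half_up(value: float, ndigits: int) -> float:
    """Round to ``ndigits`` decimals with ties going away from zero,
    matching how the reference trace prints its values."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class StepResult:
    prediction: float
    factors: FactorVector
    shift: int


class FluidEventsModel:
    """Factor-summing predictor of per-bin action-switch probability."""

    def __init__(self, config: Optional[ModelConfig] = None):
        self.config = config or ModelConfig()

    # -- state construction -------------------------------------------------

    def new_state(self, flexibility: float = 0.0) -> ParticipantState:
        """Fresh participant state. ``flexibility`` seeds the running switch
        bias; zero for a person with no prior experience of the task."""
        return ParticipantState(
            flexibility=flexibility,
            history_limit=self.config.constants.recent_window + 1,
        )

    # -- one bin ------------------------------------------------------------

    def predict(self, state: ParticipantState, env_change: float) -> tuple[float, FactorVector]:
        """Assemble factors and emit the switch probability for the current
        bin, updating flexibility from the previous bin's prediction error.

        Mutates ``state`` (the flexibility update); must be followed by
        exactly one :meth:`advance` with the realized observation. Use
        :meth:`step` unless the switch decision itself depends on the
        prediction (as in model-driven simulation).
        """
        cfg = self.config
        k = cfg.constants

        # Delta-rule flexibility update from the previous bin's error. The
        # update entering the second bin would use the forced-zero first-bin
        # prediction and the undefined-hence-zero first-bin shift, so the
        # stream's flexibility first moves at its third bin.
        if state.bins_in_stream >= 2 and state.prev_prediction is not None:
            # same arithmetic as update_flexibility, but tolerant of
            # out-of-range previous predictions when clamping is disabled
            state.flexibility += k.learning_rate * (
                state.prev_shift - state.prev_prediction)

        n_trials_now = state.n_trials + 1  # count includes the current bin
        active = {"time_on_task", "flexibility"}
        tot = time_on_task_factor(n_trials_now, k.time_base)

        env = float(env_change)
        if env > 0:
            active.add("env_change")

        just = 0.0
        if state.bins_since_shift is not None and env == 0:
            just = just_shifted_factor(state.bins_since_shift, k.just_shifted_scale)
            active.add("just_shifted")

        shifts = 0.0
        if state.n_shifts >= 1:
            shifts = num_shifts_factor(state.n_shifts, k.shift_count_base)
            active.add("num_shifts")

        dip = 0.0
        bad = 0.0
        c = dip_magnitude(state.score_history, cfg.dip_mode, k.recent_window)
        if c is not None:
            dip = performance_dip_factor(c, k.dip_base)
            active.add("performance_dip")
            bad = bad_shift_factor(dip, state.prev_shift == 1)
            if bad:
                active.add("bad_shift")

        fv = FactorVector(
            env_change=env if env > 0 else 0.0,
            time_on_task=tot,
            just_shifted=just,
            num_shifts=shifts,
            performance_dip=dip,
            bad_shift=bad,
            flexibility=state.flexibility,
            active=frozenset(active),
        )

        if state.bins_in_stream == 0:
            prediction = 0.0  # no information yet at the stream's first bin
        else:
            prediction = fv.total
            if cfg.clamp:
                prediction = min(1.0, max(0.0, prediction))
        return prediction, fv

    def advance(self, state: ParticipantState, obs: Observation,
                prediction: float) -> int:
        """Commit the realized observation after :meth:`predict`; returns the
        detected shift indicator for this bin."""
        shift = 0 if state.prev_action is None else int(obs.action != state.prev_action)

        state.n_trials += 1
        if shift:
            state.n_shifts += 1
            state.bins_since_shift = 1
        elif state.bins_since_shift is not None:
            state.bins_since_shift += 1

        if obs.score is not None:
            state.score_history.append(obs.score)
            del state.score_history[:-state.history_limit]

        state.prev_action = obs.action
        state.prev_prediction = prediction
        state.prev_shift = shift
        state.bins_in_stream += 1
        return shift

    def step(self, state: ParticipantState, obs: Observation) -> StepResult:
        """Process one bin: predict, then commit the observation."""
        prediction, fv = self.predict(state, obs.env_change)
        shift = self.advance(state, obs, prediction)
        return StepResult(prediction=prediction, factors=fv, shift=shift)

    # -- whole streams ------------------------------------------------------

    def run_stream(self, stream: EventStream,
                   state: Optional[ParticipantState] = None,
                   initial_flexibility: float = 0.0) -> pd.DataFrame:
        """Replay one stream and return a full-precision diagnostic trace
        with the canonical column layout (:data:`TRACE_COLUMNS`)."""
        if state is None:
            state = self.new_state(initial_flexibility)
        state.start_stream()
        rows = []
        for tb in stream.bins:
            obs = Observation(action=tb.action, score=tb.score,
                              env_change=tb.env_change)
            res = self.step(state, obs)
            fv = res.factors
            rows.append({
                "Time bin": tb.bin_index,
                "Score": tb.score,
                "Prediction": res.prediction,
                "Switch": res.shift,
                "Action": tb.action,
                "Environmental change": tb.env_change,
                "Time on task": fv.time_on_task,
                "Just shifted": fv.just_shifted,
                "No. of actions shifts": fv.num_shifts,
                "Performance dip": fv.performance_dip,
                "Bad shift": fv.bad_shift,
                "Flexibility": fv.flexibility,
                "No. Components": fv.active_count,
            })
        return pd.DataFrame(rows, columns=list(TRACE_COLUMNS))

    def run_cohort(self, streams: Sequence[EventStream],
                   initial_flexibility: float = 0.0) -> pd.DataFrame:
        """Run every stream, carrying each participant's cumulative state
        across their conditions (unless configured to reset), and return one
        prediction record per bin for downstream evaluation.

        Columns: participant, condition, bin, trial_number, p_sum (the summed
        prediction), shift, and the seven factor values.
        """
        ordered = sorted(streams, key=lambda s: (str(s.participant), str(s.condition)))
        states: dict[str, ParticipantState] = {}
        rows = []
        for stream in ordered:
            pid = str(stream.participant)
            if self.config.reset_between_conditions or pid not in states:
                states[pid] = self.new_state(initial_flexibility)
            state = states[pid]
            state.start_stream()
            for tb in stream.bins:
                obs = Observation(action=tb.action, score=tb.score,
                                  env_change=tb.env_change)
                res = self.step(state, obs)
                row = {
                    "participant": pid,
                    "condition": str(stream.condition),
                    "bin": tb.bin_index,
                    "trial_number": state.n_trials,
                    "p_sum": res.prediction,
                    "shift": res.shift,
                }
                row.update(res.factors.as_dict())
                rows.append(row)
        return pd.DataFrame(rows)


def printed_trace(trace: pd.DataFrame, ndigits: int = 4) -> pd.DataFrame:
    """Render a full-precision trace the way the reference table prints it.

    Each factor column is rounded half-up to ``ndigits`` decimals and the
    prediction is recomputed as the clamped, rounded sum of those rounded
    entries (inactive factors contribute exact zeros, so no activity
    bookkeeping is needed). The first bin keeps its forced zero. This is the
    layout against which printed traces are compared, since a table printed
    to four decimals is only consistent with sums of its own rounded cells.
    """
    out = trace.copy()
    for col in _FACTOR_TRACE_COLUMNS:
        out[col] = [round_half_up(v, ndigits) for v in out[col]]
    preds = []
    for pos, (_, row) in enumerate(out.iterrows()):
        if pos == 0:
            preds.append(0.0)  # the stream's first bin keeps its forced zero
            continue
        total = sum(row[col] for col in _FACTOR_TRACE_COLUMNS)
        preds.append(round_half_up(min(1.0, max(0.0, total)), ndigits))
    out["Prediction"] = preds
    return out


def write_trace(traces: Iterable[pd.DataFrame], path) -> None:
    """Write one or more traces to CSV, consecutive blocks sharing a header."""
    frames: List[pd.DataFrame] = list(traces)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
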