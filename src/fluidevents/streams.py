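"""Event-stream data model, file I/O, and raw-measurement adapters.

An event stream is one participant's ordered sequence of time bins within
one condition. Each bin carries a categorical action label, an optional
performance score in [0, 1], and a nonnegative environmental-change
magnitude. Adapters turn raw per-clause reading times into fast/normal/slow
"actions" and counts of changed situational dimensions into
environmental-change magnitudes, so covert comprehension tasks feed the
same machinery as interactive ones.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

CSV_FIELDS = ("participant", "condition", "bin", "action", "score", "env_change")


class StreamSchemaError(ValueError):
    """A stream file violated the documented schema; carries the offending
    row number where applicable."""

    def __init__(self, message: str, row: Optional[int] = None):
        self.row = row
        super().__init__(message if row is None else f"row {row}: {message}")


@dataclass(frozen=True)
class TimeBin:
    participant: str
    condition: str
    bin_index: int
    action: str
    score: Optional[float]
    env_change: float

    def __post_init__(self) -> None:
        if not str(self.action):
            raise ValueError("action label must be non-empty")
        if self.score is not None and not (0.0 <= self.score <= 1.0):
            raise ValueError(f"score must be in [0, 1], got {self.score}")
        if not (self.env_change >= 0.0 and math.isfinite(self.env_change)):
            raise ValueError(f"env_change must be finite and >= 0, got {self.env_change}")


@dataclass
class EventStream:
    """Ordered time bins of one participant in one condition."""

    participant: str
    condition: str
    bins: List[TimeBin]
    task: Optional[str] = None
    bin_duration_s: Optional[float] = None

    def __post_init__(self) -> None:
        for tb in self.bins:
            if (tb.participant, tb.condition) != (self.participant, self.condition):
                raise ValueError("all bins must belong to the stream's participant/condition")
        idx = [tb.bin_index for tb in self.bins]
        if any(b >= a for a, b in zip(idx[1:], idx)):
            raise ValueError("bin_index must be strictly increasing")

    def __len__(self) -> int:
        return len(self.bins)

    @property
    def actions(self) -> List[str]:
        return [tb.action for tb in self.bins]

    @property
    def scores(self) -> List[Optional[float]]:
        return [tb.score for tb in self.bins]

    @property
    def env_changes(self) -> List[float]:
        return [tb.env_change for tb in self.bins]


# ---------------------------------------------------------------------------
# file I/O

def _parse_row(raw: Dict[str, str], rownum: int) -> TimeBin:
    for key in CSV_FIELDS:
        if raw.get(key) is None and key != "score":
            raise StreamSchemaError(f"missing column or value for {key!r}", rownum)
    try:
        bin_index = int(raw["bin"])
    except ValueError:
        raise StreamSchemaError(f"non-integer bin index {raw['bin']!r}", rownum) from None
    score_text = (raw.get("score") or "").strip()
    if score_text == "":
        score: Optional[float] = None
    else:
        try:
            score = float(score_text)
        except ValueError:
            raise StreamSchemaError(f"non-numeric score {score_text!r}", rownum) from None
    try:
        env = float(raw["env_change"])
    except ValueError:
        raise StreamSchemaError(f"non-numeric env_change {raw['env_change']!r}", rownum) from None
    try:
        return TimeBin(str(raw["participant"]), str(raw["condition"]), bin_index,
                       str(raw["action"]), score, env)
    except ValueError as exc:
        raise StreamSchemaError(str(exc), rownum) from None


def _group(bins_with_rows: List[Tuple[TimeBin, int]]) -> List[EventStream]:
    groups: Dict[Tuple[str, str], List[Tuple[TimeBin, int]]] = {}
    for tb, rownum in bins_with_rows:
        groups.setdefault((tb.participant, tb.condition), []).append((tb, rownum))
    streams = []
    for (pid, cond), members in sorted(groups.items()):
        members.sort(key=lambda m: m[0].bin_index)
        seen: Dict[int, int] = {}
        for tb, rownum in members:
            if tb.bin_index in seen:
                raise StreamSchemaError(
                    f"duplicate bin {tb.bin_index} for participant {pid!r}, "
                    f"condition {cond!r} (first at row {seen[tb.bin_index]})", rownum)
            seen[tb.bin_index] = rownum
        streams.append(EventStream(pid, cond, [m[0] for m in members]))
    return streams


def read_streams(path: str | Path, fmt: Optional[str] = None) -> List[EventStream]:
    """Load event streams from CSV or JSON, grouped by (participant,
    condition) and ordered by bin index. Schema violations raise
    :class:`StreamSchemaError` with the offending row number."""
    path = Path(path)
    if fmt is None:
        fmt = "json" if path.suffix.lower() == ".json" else "csv"
    if fmt == "csv":
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None:
                return []
            missing = [c for c in CSV_FIELDS if c not in reader.fieldnames]
            if missing:
                raise StreamSchemaError(f"missing columns: {', '.join(missing)}")
            rows = [(_parse_row(raw, i), i) for i, raw in enumerate(reader, start=2)]
        return _group(rows)
    if fmt == "json":
        with open(path, encoding="utf-8") as fh:
            data = json.load(fh)
        rows = []
        for i, raw in enumerate(data, start=1):
            raw = {k: ("" if v is None else str(v)) for k, v in raw.items()}
            rows.append((_parse_row(raw, i), i))
        return _group(rows)
    raise ValueError(f"unknown format {fmt!r}")


def write_streams(streams: Sequence[EventStream], path: str | Path,
                  fmt: Optional[str] = None) -> None:
    """Write streams to the CSV or JSON schema. Numeric fields are written
    with ``repr`` so a read/write cycle round-trips exactly."""
    path = Path(path)
    if fmt is None:
        fmt = "json" if path.suffix.lower() == ".json" else "csv"
    records = [
        {"participant": tb.participant, "condition": tb.condition,
         "bin": tb.bin_index, "action": tb.action,
         "score": tb.score, "env_change": tb.env_change}
        for s in streams for tb in s.bins
    ]
    if fmt == "csv":
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(CSV_FIELDS)
            for r in records:
                writer.writerow([
                    r["participant"], r["condition"], r["bin"], r["action"],
                    "" if r["score"] is None else repr(float(r["score"])),
                    repr(float(r["env_change"])),
                ])
    elif fmt == "json":
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(records, fh, indent=1)
            fh.write("\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")


# ---------------------------------------------------------------------------
# derived sequences and adapters

def detect_shifts(stream: EventStream) -> np.ndarray:
    """0/1 shift indicator per bin: 1 where the action differs from the
    previous bin's, 0 at the first bin (no prior action to compare)."""
    if len(stream) == 0:
        raise ValueError("stream is empty")
    actions = stream.actions
    out = np.zeros(len(actions), dtype=int)
    for i in range(1, len(actions)):
        out[i] = int(actions[i] != actions[i - 1])
    return out


def discretize_reading_times(times: Sequence[float]) -> List[str]:
    """Classify per-clause reading times into ``fast``/``normal``/``slow``.

    The person's mean and (population) standard deviation are computed over
    their full series; a time within one SD of the mean is ``normal``
    (boundary inclusive), above it ``slow``, below it ``fast``. A constant
    series has zero SD and is all ``normal``.
    """
    arr = np.asarray(times, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least two reading times")
    if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
        raise ValueError("reading times must be finite and positive")
    mu = arr.mean()
    sigma = arr.std(ddof=0)
    labels = []
    for t in arr:
        if abs(t - mu) <= sigma:
            labels.append("normal")
        elif t > mu:
            labels.append("slow")
        else:
            labels.append("fast")
    return labels


def code_env_change(n_changed_dimensions: int, increment: float = 0.1) -> float:
    """Code a count of changed situational dimensions (new entities, time,
    location, goals, ...) as an environmental-change magnitude: each changed
    dimension adds ``increment`` to the switch probability."""
    if n_changed_dimensions < 0:
        raise ValueError("n_changed_dimensions must be >= 0")
    if increment <= 0:
        raise ValueError("increment must be > 0")
    return n_changed_dimensions * increment


def reading_times_to_stream(participant: str, condition: str,
                            times: Sequence[float],
                            dimension_changes: Optional[Sequence[int]] = None,
                            increment: float = 0.1) -> EventStream:
    """Build a model-ready stream from raw per-clause reading times and
    (optionally) per-clause counts of changed situational dimensions.

    Scores are omitted: comprehension performance is not measured, so the
    performance-dip and bad-shift factors stay inactive.
    """
    labels = discretize_reading_times(times)
    if dimension_changes is None:
        dimension_changes = [0] * len(labels)
    if len(dimension_changes) != len(labels):
        raise ValueError("dimension_changes must match times in length")
    bins = [
        TimeBin(participant, condition, i, label, None,
                code_env_change(n, increment))
        for i, (label, n) in enumerate(zip(labels, dimension_changes), start=1)
    ]
    return EventStream(participant, condition, bins)
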