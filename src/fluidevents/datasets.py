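"""Bundled demonstration data.

The aerial-combat demo is a 20-bin excerpt of one player's session in a
WWI flight-combat video game: per 5-second window, the action taken
(1 = flying, 2 = shooting, 3 = dropping bombs), a performance score
(0.5 start; hits taken lower it, targets destroyed raise it), and an
environmental-change magnitude from terrain and entity changes. The player
had flown earlier missions, so their running flexibility enters at 0.16
rather than 0. This excerpt is the package's regression fixture: the
reference trace below lists, to four decimals, the factor values and
predictions the model must reproduce bin by bin.
"""

from __future__ import annotations

from typing import List, Tuple

import pandas as pd

from .streams import EventStream, TimeBin

#: Initial flexibility for the demo participant (carried in from earlier play).
AERIAL_COMBAT_F0 = 0.16

# (score, action, env_change) per 5 s window
_AERIAL_BINS: List[Tuple[float, str, float]] = [
    (0.5, "1", 0.05), (0.6, "3", 0.1), (0.5, "1", 0.0), (0.5, "2", 0.1),
    (0.5, "2", 0.0), (0.6, "1", 0.15), (0.5, "1", 0.05), (0.5, "2", 0.0),
    (0.5, "1", 0.0), (0.4, "1", 0.05), (0.5, "1", 0.0), (0.5, "1", 0.0),
    (0.4, "1", 0.05), (0.4, "2", 0.1), (0.5, "2", 0.0), (0.5, "1", 0.0),
    (0.5, "1", 0.0), (0.5, "1", 0.0), (0.3, "2", 0.15), (0.2, "1", 0.15),
]

# Reference trace printed to four decimals:
# (prediction, switch, time_on_task, just_shifted, num_shifts,
#  performance_dip, bad_shift, flexibility, n_components)
_AERIAL_REFERENCE = [
    (0.0,    0, 0.0020,  0.0,     0.0,    0.0,    0.0,    0.1600, 3),
    (0.2630, 1, 0.0030,  0.0,     0.0,    0.0,    0.0,    0.1600, 3),
    (0.2267, 1, 0.0040, -0.01,   -0.001,  0.0,    0.0,    0.2337, 4),
    (0.6131, 1, 0.0050,  0.0,    -0.002,  0.0995, 0.0995, 0.3110, 6),
    (0.3427, 0, 0.0060, -0.01,   -0.003,  0.0,    0.0,    0.3497, 4),
    (0.4694, 1, 0.0070,  0.0,    -0.003,  0.0,    0.0,    0.3155, 4),
    (0.4225, 0, 0.0080,  0.0,    -0.004,  0.0,    0.0,    0.3685, 4),
    (0.4295, 1, 0.0090, -0.0013, -0.004,  0.0995, 0.0,    0.3263, 5),
    (0.3782, 1, 0.0099, -0.01,   -0.005,  0.0,    0.0,    0.3833, 4),
    (0.5004, 0, 0.0109,  0.0,    -0.006,  0.0,    0.0,    0.4455, 4),
    (0.4995, 0, 0.0119, -0.0013, -0.006,  0.0995, 0.0,    0.3954, 5),
    (0.3523, 0, 0.0129, -0.0001, -0.006,  0.0,    0.0,    0.3455, 4),
    (0.3682, 0, 0.0139,  0.0,    -0.006,  0.0,    0.0,    0.3103, 4),
    (0.4818, 1, 0.0149,  0.0,    -0.006,  0.0995, 0.0,    0.2734, 5),
    (0.3241, 0, 0.0159, -0.01,   -0.007,  0.0,    0.0,    0.3252, 4),
    (0.3013, 1, 0.0168, -0.0013, -0.007,  0.0,    0.0,    0.2928, 4),
    (0.3625, 0, 0.0178, -0.01,   -0.008,  0.0,    0.0,    0.3627, 4),
    (0.3359, 0, 0.0188, -0.0013, -0.008,  0.0,    0.0,    0.3264, 4),
    (0.4546, 1, 0.0198,  0.0,    -0.008,  0.0,    0.0,    0.2928, 4),
    (0.7253, 1, 0.0208,  0.0,    -0.009,  0.1081, 0.1081, 0.3474, 6),
]


def aerial_combat_demo() -> EventStream:
    """The 20-bin aerial-combat demo stream (one participant, one sortie)."""
    bins = [
        TimeBin("demo", "sortie1", i, action, score, env)
        for i, (score, action, env) in enumerate(_AERIAL_BINS, start=1)
    ]
    return EventStream("demo", "sortie1", bins, task="aerial_combat",
                       bin_duration_s=5.0)


def aerial_combat_reference_trace() -> pd.DataFrame:
    """The reference trace for the demo stream, in the canonical trace
    column layout, with values printed to four decimal places."""
    rows = []
    for i, ((score, action, env), ref) in enumerate(zip(_AERIAL_BINS, _AERIAL_REFERENCE), 1):
        pred, switch, tot, just, shifts, dip, bad, flex, ncomp = ref
        rows.append({
            "Time bin": i, "Score": score, "Prediction": pred,
            "Switch": switch, "Action": action, "Environmental change": env,
            "Time on task": tot, "Just shifted": just,
            "No. of actions shifts": shifts, "Performance dip": dip,
            "Bad shift": bad, "Flexibility": flex, "No. Components": ncomp,
        })
    return pd.DataFrame(rows)
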