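"""Replay the bundled aerial-combat demo and print its diagnostic trace.

The demo is a 20-bin excerpt of one player's session in a WWI flight-combat
game (actions: 1 = flying, 2 = shooting, 3 = dropping bombs). The model is
stepped bin by bin and the trace shows, for each bin, every factor's
contribution, how many factors were active, the summed switch probability,
and whether the player actually switched actions.
"""

from fluidevents import FluidEventsModel, printed_trace
from fluidevents.datasets import AERIAL_COMBAT_F0, aerial_combat_demo

model = FluidEventsModel()
trace = model.run_stream(aerial_combat_demo(),
                         initial_flexibility=AERIAL_COMBAT_F0)
print(printed_trace(trace).to_string(index=False))
print()
print("Each 'Prediction' is the clamped sum of the active factor columns;")
print("'Switch' marks where the player actually changed actions. Note bin 4:")
print("an environmental change plus a performance dip doubled by the")
print("bad-shift rule push the probability to 0.613, and a switch follows.")
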