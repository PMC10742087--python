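"""The biofeedback gauge mapping: measured frequency to needle position.

The needle is linear in the relative error from the goal cue frequency,
exactly zero at the goal (goal range centered), and saturates at ±1 for
errors beyond half the goal frequency.
"""

from tremorkit import gauge_position

goal = 4.0  # Hz
print(f"goal frequency {goal:.1f} Hz, goal range ±10%, full scale ±50%\n")
print(f"{'measured (Hz)':>14} {'needle':>8} {'in goal':>8}")
for measured in (None, 1.5, 3.2, 3.7, 4.0, 4.3, 4.8, 8.0):
    r = gauge_position(measured, goal)
    label = "  none" if measured is None else f"{measured:6.1f}"
    print(f"{label:>14} {r.needle:8.2f} {str(r.in_goal):>8}")
# needle 0.00 means the user matches the cue exactly; ±1.00 is a pegged
# needle (including 'no significant movement detected', shown pegged low).
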