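"""Simulate one Trail-Making trial and compute its eight test scores.

Generates a 25-target TMT-A layout, simulates a trial under accuracy
emphasis (searching fixations, guiding fixations held until each click),
and prints the per-trial score row.
"""

from tmtgaze import generate_layout, score_trial, simulate_trial

layout = generate_layout("A", seed=11)
trial = simulate_trial(layout, subject="demo", instruction="accuracy", seed=42)
row = score_trial(trial)

print(f"trial duration        {row.trial_duration:8.2f} s")
print(f"mean fixation duration{row.mean_fixation_duration:8.1f} ms")
print(f"mean saccade amplitude{row.mean_saccade_amplitude:8.2f} deg")
print(f"n fixations           {row.n_fixations:5d}")
print(f"n guiding             {row.n_guiding:5d}")
print(f"n searching           {row.n_searching:5d}")
print(f"mean eye-hand span    {row.mean_eye_hand_span:8.2f} s")
print(f"scanpath length       {row.scanpath_length:8.1f} deg")
# Guiding fixations sit on the target about to be clicked; the eye-hand span
# is the time the eyes lead the hand on each target.
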