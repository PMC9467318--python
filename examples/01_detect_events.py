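"""Detect saccades and fixations in a synthetic gaze trace.

Builds a 1000 Hz trace with two steady fixation periods joined by a
6-degree, 20 ms saccade (300 deg/s), runs the velocity+acceleration
detector and prints the events it finds.
"""

import numpy as np

from tmtgaze import PAPER_GEOMETRY, DetectionParams, deg_to_px, detect_events, samples_frame

# piecewise-linear trajectory in degrees of visual angle
key_t = np.array([0.0, 200.0, 220.0, 420.0])
key_x = np.array([-3.0, -3.0, 3.0, 3.0])
t = np.arange(0.0, 420.0 + 0.5)
deg = np.column_stack([np.interp(t, key_t, key_x), np.zeros_like(t)])
px = deg_to_px(deg, PAPER_GEOMETRY)
trace = samples_frame(t, px[:, 0], px[:, 1])

fixations, saccades, blinks = detect_events(trace, DetectionParams(), PAPER_GEOMETRY)

print(f"{len(fixations)} fixations, {len(saccades)} saccades, {len(blinks)} blinks")
for f in fixations:
    print(f"  fixation {f.onset:6.0f}-{f.offset:6.0f} ms at ({f.centroid[0]:+.2f}, "
          f"{f.centroid[1]:+.2f}) deg")
for s in saccades:
    print(f"  saccade  {s.onset:6.0f}-{s.offset:6.0f} ms, amplitude {s.amplitude:.2f} deg, "
          f"peak {s.peak_velocity:.0f} deg/s")
# The saccade amplitude recovers the 6-deg step; the two fixations cover the
# steady periods on either side.
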