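"""Event detection against analytic traces and a brute-force scanner."""

import numpy as np
import pytest

from tmtgaze import (
    PAPER_GEOMETRY,
    DetectionParams,
    FixationEvent,
    SaccadeEvent,
    detect_events,
    deg_to_px,
    merge_fixations,
    px_to_deg,
    samples_frame,
)


# ---------------------------------------------------------------- trace tools
def trace_from_keyframes(keyframes, rate_hz=1000.0):
    """Sample a piecewise-linear deg-space trajectory at rate_hz -> gaze frame."""
    kt = np.array([k[0] for k in keyframes], dtype=float)
    kp = np.array([[k[1], k[2]] for k in keyframes], dtype=float)
    t = np.arange(kt[0], kt[-1] + 0.5, 1000.0 / rate_hz)
    deg = np.column_stack([np.interp(t, kt, kp[:, 0]), np.interp(t, kt, kp[:, 1])])
    px = deg_to_px(deg, PAPER_GEOMETRY)
    return samples_frame(t, px[:, 0], px[:, 1])


from oracles import oracle_scanner


# ------------------------------------------------------------------ detection
def test_constant_position_is_one_fixation(geom, det_params):
    trace = trace_from_keyframes([(0, 1.0, -2.0), (300, 1.0, -2.0)])
    fx, sc, blinks = detect_events(trace, det_params, geom)
    assert len(fx) == 1 and len(sc) == 0 and len(blinks) == 0
    assert fx[0].duration == pytest.approx(300, abs=2)
    assert np.allclose(fx[0].centroid, (1.0, -2.0), atol=1e-6)


def test_six_degree_ramp_is_one_saccade(geom, det_params):
    # 200 ms steady, 20 ms linear 6-deg ramp (300 deg/s), 200 ms steady
    trace = trace_from_keyframes([(0, -3.0, 0.0), (200, -3.0, 0.0),
                                  (220, 3.0, 0.0), (420, 3.0, 0.0)])
    fx, sc, _ = detect_events(trace, det_params, geom)
    assert len(sc) == 1 and len(fx) == 2
    assert sc[0].amplitude == pytest.approx(6.0, abs=0.1)
    assert sc[0].peak_velocity == pytest.approx(300.0, rel=0.05)


def test_slow_drift_stays_one_fixation(geom, det_params):
    # 10 deg/s drift is well below the 30 deg/s threshold
    trace = trace_from_keyframes([(0, 0.0, 0.0), (500, 5.0, 0.0)])
    deg = px_to_deg(trace[["x_px", "y_px"]].to_numpy(), geom)
    v = np.linalg.norm(np.diff(deg, axis=0), axis=1) * 1000.0
    assert v.max() < det_params.vel_thresh  # velocity oracle: sub-threshold everywhere
    fx, sc, _ = detect_events(trace, det_params, geom)
    assert len(sc) == 0 and len(fx) == 1


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_detector_matches_brute_force_scanner(geom, det_params, seed):
    """Vectorized detector and sample-by-sample scanner give identical boundaries."""
    rng = np.random.default_rng(seed)
    keyframes = [(0.0, 0.0, 0.0)]
    t = 0.0
    pos = np.zeros(2)
    for _ in range(6):
        t += rng.uniform(80, 250)
        keyframes.append((t, *pos))
        step = rng.uniform(-5, 5, size=2)
        dur = max(2.0, np.linalg.norm(step) / 0.3)
        t += dur
        pos = pos + step
        keyframes.append((t, *pos))
    t += 150
    keyframes.append((t, *pos))
    trace = trace_from_keyframes(keyframes)
    fx, sc, _ = detect_events(trace, det_params, geom)
    got = sorted(
        [("fixation", f.onset, f.offset) for f in fx]
        + [("saccade", s.onset, s.offset) for s in sc],
        key=lambda e: e[1],
    )
    expected = oracle_scanner(trace, det_params, geom)
    assert got == expected


def test_event_durations_partition_valid_span(geom, det_params):
    trace = trace_from_keyframes([(0, 0, 0), (100, 0, 0), (110, 4, 0),
                                  (300, 4, 0), (312, -2, 3), (500, -2, 3)])
    fx, sc, _ = detect_events(trace, det_params, geom)
    total = sum(f.duration for f in fx) + sum(s.duration for s in sc)
    span = trace["t_ms"].iloc[-1] - trace["t_ms"].iloc[0]
    assert abs(total - span) <= 1.0  # within one sample


def test_raising_velocity_threshold_never_adds_saccades(geom, rng):
    keyframes = [(0, 0, 0)]
    t, pos = 0.0, np.zeros(2)
    for _ in range(8):
        t += rng.uniform(50, 150)
        keyframes.append((t, *pos))
        pos = pos + rng.uniform(-4, 4, size=2)
        t += rng.uniform(5, 40)
        keyframes.append((t, *pos))
    trace = trace_from_keyframes(keyframes)
    counts = []
    for vt in [10, 20, 30, 60, 120, 400]:
        p = DetectionParams(vel_thresh=vt, acc_thresh=1e12)
        _, sc, _ = detect_events(trace, p, geom)
        counts.append(len(sc))
    assert counts == sorted(counts, reverse=True)


# --------------------------------------------------------------------- blinks
def test_blink_run_splits_events_and_single_dropout_does_not(geom, det_params):
    trace = trace_from_keyframes([(0, 0, 0), (400, 0, 0)])
    valid = trace["valid"].to_numpy()
    valid[200:210] = False  # 10-sample blink
    trace["valid"] = valid
    fx, sc, blinks = detect_events(trace, det_params, geom)
    assert len(blinks) == 1 and len(fx) == 2 and len(sc) == 0

    trace2 = trace_from_keyframes([(0, 0, 0), (400, 0, 0)])
    valid = trace2["valid"].to_numpy()
    valid[200] = False  # isolated dropout is bridged
    trace2["valid"] = valid
    fx, sc, blinks = detect_events(trace2, det_params, geom)
    assert len(blinks) == 0 and len(fx) == 1


def test_degenerate_streams(geom, det_params):
    trace = trace_from_keyframes([(0, 0, 0), (100, 0, 0)])
    trace["valid"] = False
    with pytest.warns(UserWarning):
        fx, sc, blinks = detect_events(trace, det_params, geom)
    assert fx == [] and sc == []

    bad = trace_from_keyframes([(0, 0, 0), (50, 0, 0)])
    bad.loc[10, "t_ms"] = 5.0  # non-monotone
    with pytest.raises(ValueError):
        detect_events(bad, det_params, geom)


# -------------------------------------------------------------------- merging
def _fx(onset, offset, x, y=0.0):
    return FixationEvent(onset=onset, offset=offset, centroid=(x, y))


def test_close_fixations_merge_with_weighted_centroid(det_params):
    merged = merge_fixations([_fx(0, 100, 0.0), _fx(120, 220, 0.4)], det_params)
    assert len(merged) == 1
    assert merged[0].onset == 0 and merged[0].offset == 220
    assert merged[0].centroid[0] == pytest.approx(0.2)  # equal durations
    assert 0.0 < merged[0].centroid[0] < 0.4


def test_distant_fixations_unchanged(det_params):
    fx = [_fx(0, 100, 0.0), _fx(120, 220, 2.0)]
    assert merge_fixations(fx, det_params) == fx


def test_iterative_merge_uses_merged_centroid(det_params):
    # equal durations: (0 + 0.6)/2 = 0.3, then |0.3 - 1.2| = 0.9 < 1 -> all merge
    all_merge = merge_fixations(
        [_fx(0, 100, 0.0), _fx(110, 210, 0.6), _fx(220, 320, 1.2)], det_params
    )
    assert len(all_merge) == 1
    # heavy first fixation pulls the merged centroid to 0.15 -> 1.05 >= 1 -> stop
    two_stay = merge_fixations(
        [_fx(0, 300, 0.0), _fx(310, 410, 0.6), _fx(420, 520, 1.2)], det_params
    )
    assert len(two_stay) == 2
    assert two_stay[0].centroid[0] == pytest.approx(0.15)


def test_merge_absorbs_intervening_saccade(det_params):
    fx = [_fx(0, 100, 0.0), _fx(110, 210, 0.4)]
    sc = [SaccadeEvent(onset=100, offset=110, amplitude=0.4, peak_velocity=50.0)]
    merged_fx, kept_sc = merge_fixations(fx, det_params, sc)
    assert len(merged_fx) == 1 and kept_sc == []


def test_empty_list_is_noop(det_params):
    assert merge_fixations([], det_params) == []
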