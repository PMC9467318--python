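"""Saccade / fixation / blink detection from raw gaze samples.

Detection mirrors the classic velocity+acceleration parser used by
desktop video eye trackers: gaze positions are converted to degrees of
visual angle, angular velocity is computed by central differences over a
small window, and a sample belongs to a saccade whenever its velocity
OR its acceleration exceeds the respective threshold (defaults
30 deg/s and 8000 deg/s^2). Maximal runs of sub-threshold samples are
fixations. Runs of >= 2 invalid samples are blinks and split the
surrounding events; an isolated invalid sample is bridged by linear
interpolation. Fixations closer than a merge distance (default 1 deg)
are merged, absorbing the intervening saccade.

The online parser of commercial trackers is proprietary; this detector
is threshold-faithful to the published rules but not guaranteed
sample-identical to any vendor's output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .geometry import ScreenGeometry, px_to_deg

__all__ = [
    "GazeSample",
    "FixationEvent",
    "SaccadeEvent",
    "DetectionParams",
    "detect_events",
    "merge_fixations",
    "samples_frame",
]


class GazeSample(NamedTuple):
    """One gaze measurement: time (ms), position (px, origin top-left), validity."""

    t: float
    x: float
    y: float
    valid: bool = True


@dataclass(frozen=True)
class FixationEvent:
    """Interval of stable gaze.

    ``centroid`` is the mean angular position (deg va, screen-center
    origin) of the samples in the interval; ``duration = offset - onset``
    in ms.
    """

    onset: float
    offset: float
    centroid: tuple[float, float]

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass(frozen=True)
class SaccadeEvent:
    """Rapid gaze shift: amplitude is the angular start->end distance (deg va)."""

    onset: float
    offset: float
    amplitude: float
    peak_velocity: float

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass(frozen=True)
class DetectionParams:
    """Thresholds for event detection.

    vel_thresh : deg/s, saccade velocity threshold (default 30).
    acc_thresh : deg/s^2, saccade acceleration threshold (default 8000).
    merge_dist : deg, fixations closer than this are merged (default 1.0).
    min_fix_dur : ms, fixations shorter than this are discarded (default 0).
    vel_window : samples, width of the central-difference window (odd, default 3).
    """

    vel_thresh: float = 30.0
    acc_thresh: float = 8000.0
    merge_dist: float = 1.0
    min_fix_dur: float = 0.0
    vel_window: int = 3

    def __post_init__(self) -> None:
        for name in ("vel_thresh", "acc_thresh", "merge_dist", "min_fix_dur"):
            if getattr(self, name) < 0:
                raise ValueError(f"DetectionParams.{name} must be >= 0")
        if self.vel_window < 3 or self.vel_window % 2 == 0:
            raise ValueError("vel_window must be an odd integer >= 3")


def samples_frame(t, x, y, valid=None) -> pd.DataFrame:
    """Assemble a gaze-sample table with the canonical columns."""
    t = np.asarray(t, dtype=float)
    if valid is None:
        valid = np.ones(t.shape, dtype=bool)
    return pd.DataFrame(
        {
            "t_ms": t,
            "x_px": np.asarray(x, dtype=float),
            "y_px": np.asarray(y, dtype=float),
            "valid": np.asarray(valid, dtype=bool),
        }
    )


def _as_arrays(samples) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if isinstance(samples, pd.DataFrame):
        t = samples["t_ms"].to_numpy(dtype=float)
        xy = samples[["x_px", "y_px"]].to_numpy(dtype=float)
        valid = samples["valid"].to_numpy(dtype=bool)
    else:
        rows = [GazeSample(*s) if not isinstance(s, GazeSample) else s for s in samples]
        t = np.array([s.t for s in rows], dtype=float)
        xy = np.array([[s.x, s.y] for s in rows], dtype=float)
        valid = np.array([s.valid for s in rows], dtype=bool)
    return t, xy, valid


def speed_profile(
    t_ms: np.ndarray, deg: np.ndarray, window: int = 3
) -> tuple[np.ndarray, np.ndarray]:
    """Angular speed (deg/s) and its rate of change (deg/s^2) per sample.

    Central differences over ``window`` samples ((window-1)/2 on each
    side); edge samples copy the nearest interior value so every sample
    has a defined speed. Acceleration is the central difference of the
    scalar speed.
    """
    n = len(t_ms)
    k = (window - 1) // 2
    speed = np.zeros(n)
    if n >= 2:
        kk = min(k, (n - 1) // 2) or 1
        if n > 2 * kk:
            hi = np.arange(2 * kk, n)
            lo = np.arange(0, n - 2 * kk)
            dt_s = (t_ms[hi] - t_ms[lo]) / 1000.0
            disp = np.linalg.norm(deg[hi] - deg[lo], axis=1)
            speed[kk : n - kk] = disp / dt_s
            speed[:kk] = speed[kk]
            speed[n - kk :] = speed[n - kk - 1]
        else:
            dt_s = (t_ms[-1] - t_ms[0]) / 1000.0
            speed[:] = np.linalg.norm(deg[-1] - deg[0]) / dt_s
    accel = np.zeros(n)
    if n >= 3:
        dt_s = (t_ms[2:] - t_ms[:-2]) / 1000.0
        accel[1:-1] = (speed[2:] - speed[:-2]) / dt_s
        accel[0] = accel[1]
        accel[-1] = accel[-2]
    return speed, accel


def _runs(mask: np.ndarray) -> list[tuple[int, int, bool]]:
    """Maximal constant runs of a boolean array as (start, stop, value)."""
    out = []
    i = 0
    n = len(mask)
    while i < n:
        j = i
        while j + 1 < n and mask[j + 1] == mask[i]:
            j += 1
        out.append((i, j + 1, bool(mask[i])))
        i = j + 1
    return out


def detect_events(
    samples,
    params: DetectionParams | None = None,
    geom: ScreenGeometry | None = None,
) -> tuple[list[FixationEvent], list[SaccadeEvent], list[tuple[float, float]]]:
    """Segment a gaze-sample stream into fixations, saccades and blinks.

    Parameters
    ----------
    samples : DataFrame (columns t_ms, x_px, y_px, valid) or sequence of GazeSample
    params : DetectionParams, defaults to the standard thresholds
    geom : ScreenGeometry, required to convert pixels to visual angle

    Returns
    -------
    (fixations, saccades, blinks) — fixations/saccades ordered by onset,
    blinks as (onset_ms, offset_ms) intervals.

    Every valid sample belongs to exactly one fixation or saccade (or is
    adjacent to a blink gap); within each valid segment the event
    offsets abut the next event's onset, so durations partition the
    segment span exactly.
    """
    if params is None:
        params = DetectionParams()
    if geom is None:
        raise ValueError("detect_events requires a ScreenGeometry")
    t, xy, valid = _as_arrays(samples)
    if len(t) >= 2 and np.any(np.diff(t) <= 0):
        raise ValueError("gaze-sample timestamps must be strictly increasing")
    if valid.sum() < 2:
        warnings.warn("gaze stream has < 2 valid samples; no events detected", stacklevel=2)
        blinks = [
            (t[i], t[j - 1]) for i, j, bad in _runs(~valid) if bad and j - i >= 2
        ] if len(t) else []
        return [], [], blinks

    # blink splitting: invalid runs of >= 2 samples; single invalid samples interpolated
    blinks: list[tuple[float, float]] = []
    segments: list[np.ndarray] = []
    seg_start = 0
    for i, j, bad in _runs(~valid):
        if bad and j - i >= 2:
            blinks.append((t[i], t[j - 1]))
            if i > seg_start:
                segments.append(np.arange(seg_start, i))
            seg_start = j
    if seg_start < len(t):
        segments.append(np.arange(seg_start, len(t)))

    fixations: list[FixationEvent] = []
    saccades: list[SaccadeEvent] = []
    for idx in segments:
        ts = t[idx]
        pos = xy[idx].copy()
        v = valid[idx]
        if v.sum() < 2:
            continue
        # bridge isolated invalid samples
        if not v.all():
            for ax in range(2):
                pos[:, ax] = np.interp(ts, ts[v], pos[v, ax])
        deg = px_to_deg(pos, geom)
        speed, accel = speed_profile(ts, deg, params.vel_window)
        sacc_mask = (speed > params.vel_thresh) | (np.abs(accel) > params.acc_thresh)
        for i, j, is_sacc in _runs(sacc_mask):
            onset = ts[i]
            offset = ts[j] if j < len(ts) else ts[-1]
            if offset <= onset:
                continue  # zero-length trailing run
            if is_sacc:
                saccades.append(
                    SaccadeEvent(
                        onset=onset,
                        offset=offset,
                        amplitude=float(np.linalg.norm(deg[j - 1] - deg[i])),
                        peak_velocity=float(speed[i:j].max()),
                    )
                )
            else:
                if offset - onset < params.min_fix_dur:
                    continue
                c = deg[i:j].mean(axis=0)
                fixations.append(
                    FixationEvent(onset=onset, offset=offset, centroid=(float(c[0]), float(c[1])))
                )
    fixations.sort(key=lambda f: f.onset)
    saccades.sort(key=lambda s: s.onset)
    return fixations, saccades, blinks


def merge_fixations(
    fixations: Sequence[FixationEvent],
    params: DetectionParams | None = None,
    saccades: Sequence[SaccadeEvent] | None = None,
):
    """Merge consecutive fixations whose centroids are closer than merge_dist.

    The merged fixation spans the first onset to the second offset with a
    duration-weighted mean centroid; merging is applied iteratively
    left-to-right (the merged centroid is re-checked against the next
    fixation) until stable. Saccades falling inside a merged span are
    absorbed (removed) when a saccade list is supplied.

    Returns the merged fixation list, or ``(fixations, saccades)`` when
    ``saccades`` is given.
    """
    if params is None:
        params = DetectionParams()
    fx = list(fixations)
    i = 0
    while i < len(fx) - 1:
        a, b = fx[i], fx[i + 1]
        d = float(np.hypot(a.centroid[0] - b.centroid[0], a.centroid[1] - b.centroid[1]))
        if d < params.merge_dist:
            wa, wb = max(a.duration, 0.0), max(b.duration, 0.0)
            if wa + wb == 0:
                wa = wb = 1.0
            cx = (a.centroid[0] * wa + b.centroid[0] * wb) / (wa + wb)
            cy = (a.centroid[1] * wa + b.centroid[1] * wb) / (wa + wb)
            fx[i : i + 2] = [FixationEvent(onset=a.onset, offset=b.offset, centroid=(cx, cy))]
            # stay at i: merged centroid must be re-checked against the next one
        else:
            i += 1
    if saccades is None:
        return fx
    spans = [(f.onset, f.offset) for f in fx]
    kept = [
        s
        for s in saccades
        if not any(on < s.onset and s.offset < off for on, off in spans)
    ]
    return fx, kept
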