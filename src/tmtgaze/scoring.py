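"""Trial scoring: the eight Trail-Making-Test measures.

A trial is one completed TMT sequence (25 targets, or 8 in training)
under one instruction (speed or accuracy). From the detected fixations,
the click log and the target layout this module computes, per trial:

- trial_duration (s): start signal to the final hit
- mean_fixation_duration (ms), mean_saccade_amplitude (deg va), n_fixations
- n_guiding / n_searching: fixations inside the 3.25 deg va AOI circle
  of the current target vs. any other target
- mean_eye_hand_span (s): first guiding fixation on a target to the
  click that hits it (eyes leading the hand)
- scanpath_length (deg va): summed angular distance between consecutive
  fixation centroids

Fixations outside every AOI are "unassigned": counted in n_fixations but
in neither subtype. The target that counts as "current" for a fixation
is the one pending at the fixation's onset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .events import FixationEvent, SaccadeEvent
from .geometry import ScreenGeometry, px_to_deg

__all__ = [
    "TargetLayout",
    "ClickEvent",
    "TrialRecord",
    "ScoreRow",
    "SCORE_COLUMNS",
    "version_labels",
    "classify_fixation",
    "eye_hand_span",
    "scanpath_length",
    "score_trial",
    "scores_to_frame",
]

#: TMT circle diameter around each number/letter (deg va).
TARGET_CIRCLE_DIAMETER = 1.35
#: Classification circle (AOI) diameter around each target center (deg va).
AOI_DIAMETER = 3.25

SCORE_COLUMNS = [
    "subject",
    "test_type",
    "instruction",
    "trial_duration",
    "mean_fixation_duration",
    "mean_saccade_amplitude",
    "n_fixations",
    "n_guiding",
    "n_searching",
    "mean_eye_hand_span",
    "scanpath_length",
]


def version_labels(version: str, n_targets: int = 25) -> list[str]:
    """Target labels in click order: A = "1".."25"; B = "1","A","2","B",...,"13"."""
    if version == "A":
        return [str(i + 1) for i in range(n_targets)]
    if version == "B":
        letters = "ABCDEFGHIJKL"
        seq: list[str] = []
        for i in range(13):
            seq.append(str(i + 1))
            if i < 12:
                seq.append(letters[i])
        return seq[:n_targets]
    raise ValueError(f"unknown TMT version {version!r}")


@dataclass(frozen=True)
class TargetLayout:
    """Ordered target positions for one TMT display.

    ``centers_px`` are screen-pixel centers in click order; ``geom`` fixes
    the pixel-to-angle mapping used for AOI classification.
    """

    version: Literal["A", "B"]
    labels: tuple[str, ...]
    centers_px: np.ndarray  # (n, 2)
    geom: ScreenGeometry
    circle_diameter: float = TARGET_CIRCLE_DIAMETER
    aoi_diameter: float = AOI_DIAMETER

    def __post_init__(self) -> None:
        object.__setattr__(self, "centers_px", np.asarray(self.centers_px, dtype=float))
        if self.centers_px.shape != (len(self.labels), 2):
            raise ValueError("centers_px must be (n_targets, 2)")
        if self.aoi_diameter <= self.circle_diameter:
            raise ValueError("AOI diameter must exceed the target circle diameter")
        x, y = self.centers_px[:, 0], self.centers_px[:, 1]
        if (x < 0).any() or (x > self.geom.res_x_px).any() or (y < 0).any() or (
            y > self.geom.res_y_px
        ).any():
            raise ValueError("target centers must lie on-screen")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def centers_deg(self) -> np.ndarray:
        return px_to_deg(self.centers_px, self.geom)


@dataclass(frozen=True)
class ClickEvent:
    """One mouse click: hit iff inside the current target's circle."""

    t: float
    position: tuple[float, float]
    hit: bool
    target_index: int


@dataclass
class TrialRecord:
    """One completed TMT trial with its events, clicks and layout."""

    subject: str
    test_type: Literal["A", "B"]
    instruction: Literal["speed", "accuracy"]
    start_t: float
    end_t: float
    fixations: list[FixationEvent]
    saccades: list[SaccadeEvent]
    clicks: list[ClickEvent]
    layout: TargetLayout
    truth_roles: list[str] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not self.start_t < self.end_t:
            raise ValueError("trial start_t must precede end_t")


class TrialIntegrityError(ValueError):
    """Raised when a trial is incomplete or internally inconsistent."""


def classify_fixation(
    f: FixationEvent, layout: TargetLayout, current_index: int
) -> Literal["guiding", "searching", "unassigned"]:
    """Label a fixation by the AOI it falls in relative to the current target.

    guiding: within aoi_diameter/2 of the current target's center;
    searching: within that radius of any other (past or future) target;
    unassigned: outside every AOI. When inside several AOIs the nearest
    center wins, ties going to the current target.
    """
    if not 0 <= current_index < len(layout):
        raise IndexError(f"current_index {current_index} out of range")
    d = np.linalg.norm(layout.centers_deg - np.asarray(f.centroid), axis=1)
    radius = layout.aoi_diameter / 2.0
    inside = d <= radius
    if not inside.any():
        return "unassigned"
    if inside[current_index] and d[current_index] <= d[inside].min() + 1e-12:
        return "guiding"
    return "searching"


def _current_index_at(t: float, clicks: Sequence[ClickEvent], n_targets: int) -> int:
    """Index of the target pending at time t (number of hits strictly before t)."""
    n_hits = sum(1 for c in clicks if c.hit and c.t < t)
    return min(n_hits, n_targets - 1)


def eye_hand_span(trial: TrialRecord) -> list[float]:
    """Per-target spans (s): hit-click time minus first guiding-fixation onset.

    For each target k the qualifying fixation is the first guiding
    fixation on k that begins after k becomes current and before k's hit
    click. Targets never fixated this way contribute no span; the result
    may therefore be shorter than the target list (and empty).
    """
    hits = [c for c in trial.clicks if c.hit]
    spans: list[float] = []
    for k, click in enumerate(hits):
        became_current = trial.start_t if k == 0 else hits[k - 1].t
        for f in trial.fixations:
            if f.onset < became_current or f.onset >= click.t:
                continue
            if classify_fixation(f, trial.layout, k) == "guiding":
                spans.append((click.t - f.onset) / 1000.0)
                break
    return spans


def scanpath_length(fixations: Sequence[FixationEvent]) -> float:
    """Total angular distance (deg va) along consecutive fixation centroids."""
    if len(fixations) < 2:
        return 0.0
    c = np.array([f.centroid for f in fixations], dtype=float)
    return float(np.linalg.norm(np.diff(c, axis=0), axis=1).sum())


@dataclass(frozen=True)
class ScoreRow:
    """The eight per-trial measures (one row of the long-format score table)."""

    subject: str
    test_type: str
    instruction: str
    trial_duration: float
    mean_fixation_duration: float
    mean_saccade_amplitude: float
    n_fixations: int
    n_guiding: int
    n_searching: int
    mean_eye_hand_span: float  # NaN when no target had a guiding fixation
    scanpath_length: float


def score_trial(trial: TrialRecord, count_unassigned: bool = True) -> ScoreRow:
    """Compute the eight measures for one completed trial.

    ``count_unassigned=False`` restricts n_fixations to AOI-classified
    fixations (the default includes every merged fixation).
    """
    hits = [c for c in trial.clicks if c.hit]
    if len(hits) != len(trial.layout):
        raise TrialIntegrityError(
            f"trial has {len(hits)} hits for {len(trial.layout)} targets; "
            "every target must be hit exactly once"
        )
    if hits and abs(hits[-1].t - trial.end_t) > 1e-9:
        raise TrialIntegrityError("trial end_t must equal the final hit time")
    for ev in trial.fixations + trial.saccades:
        if ev.onset < trial.start_t - 1e-6 or ev.offset > trial.end_t + 1e-6:
            raise TrialIntegrityError("event outside the trial window")

    n_guiding = n_searching = n_unassigned = 0
    for f in trial.fixations:
        k = _current_index_at(f.onset, trial.clicks, len(trial.layout))
        role = classify_fixation(f, trial.layout, k)
        if role == "guiding":
            n_guiding += 1
        elif role == "searching":
            n_searching += 1
        else:
            n_unassigned += 1
    spans = eye_hand_span(trial)
    n_fix = len(trial.fixations) if count_unassigned else n_guiding + n_searching
    return ScoreRow(
        subject=trial.subject,
        test_type=trial.test_type,
        instruction=trial.instruction,
        trial_duration=(trial.end_t - trial.start_t) / 1000.0,
        mean_fixation_duration=(
            float(np.mean([f.duration for f in trial.fixations])) if trial.fixations else math.nan
        ),
        mean_saccade_amplitude=(
            float(np.mean([s.amplitude for s in trial.saccades])) if trial.saccades else math.nan
        ),
        n_fixations=n_fix,
        n_guiding=n_guiding,
        n_searching=n_searching,
        mean_eye_hand_span=float(np.mean(spans)) if spans else math.nan,
        scanpath_length=scanpath_length(trial.fixations),
    )


def scores_to_frame(rows: Sequence[ScoreRow]) -> pd.DataFrame:
    """Long-format score table, one row per subject x test_type x instruction.

    Repeated trials of a subject in the same design cell are averaged.
    """
    df = pd.DataFrame([r.__dict__ for r in rows], columns=SCORE_COLUMNS)
    keys = ["subject", "test_type", "instruction"]
    if df.duplicated(keys).any():
        df = df.groupby(keys, as_index=False, sort=False).mean(numeric_only=True)
    return df[SCORE_COLUMNS]
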