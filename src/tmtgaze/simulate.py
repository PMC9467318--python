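"""Synthetic Trail-Making-Test data with the structure the analysis assumes.

Three levels of generation:

``generate_layout``
    Target positions scattered around the centers of a 5x5 screen grid
    (25 experimental targets, 8 for training), rejection-sampled to a
    minimum pairwise separation.

``simulate_trial``
    Event-level trials: for every target in sequence, a Poisson number
    of searching fixations on other targets, one guiding fixation on the
    current target held until the click, and a click that must land
    inside the 1.35 deg target circle to advance. Condition multipliers
    encode the speed-accuracy trade-off (fewer searching fixations and
    shorter eye-hand spans under speed emphasis). Trials can be rendered
    to raw 1000 Hz gaze samples whose detection recovers the events.

``simulate_scores``
    Score-level tables straight from the random-intercept model
    y_ij = X beta + u_j + eps_ij for the 2 (test half) x 2 (instruction)
    within-subject design, for testing the mixed-model machinery.

All generative choices here are test scaffolding with the qualitative
structure of the task, not claims about any particular dataset. Fixation
landing scatter is truncated (at 3 SD, and always inside the AOI and
within half the minimum target separation) so that the emitted
ground-truth fixation roles are exactly recoverable by AOI
classification.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .events import FixationEvent, SaccadeEvent, samples_frame
from .geometry import PAPER_GEOMETRY, ScreenGeometry, deg_to_px, px_to_deg
from .scoring import (
    AOI_DIAMETER,
    TARGET_CIRCLE_DIAMETER,
    ClickEvent,
    TargetLayout,
    TrialRecord,
    version_labels,
)

__all__ = [
    "LayoutConfig",
    "BehaviorParams",
    "ScoreSimConfig",
    "LayoutError",
    "generate_layout",
    "simulate_trial",
    "render_gaze_samples",
    "simulate_scores",
    "simulate_study",
]


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


class LayoutError(RuntimeError):
    """Raised when no layout satisfies the separation constraint."""


@dataclass(frozen=True)
class LayoutConfig:
    """Geometry of target placement.

    jitter_deg: max per-axis displacement of a target from its grid-field
    center (deg va). min_sep: minimum pairwise target distance (deg va);
    must be at least the target circle diameter so hits are unambiguous.
    """

    grid: tuple[int, int] = (5, 5)
    jitter_deg: float = 1.0
    min_sep: float = 2.0
    n_targets: int = 25
    geom: ScreenGeometry = PAPER_GEOMETRY
    circle_diameter: float = TARGET_CIRCLE_DIAMETER
    aoi_diameter: float = AOI_DIAMETER
    max_tries: int = 1000

    def __post_init__(self) -> None:
        if self.min_sep < self.circle_diameter:
            raise ValueError("min_sep must be >= the target circle diameter")
        if self.n_targets > self.grid[0] * self.grid[1]:
            raise ValueError("more targets than grid fields")


TRAINING_N_TARGETS = 8


def generate_layout(version: str, cfg: LayoutConfig | None = None, seed=None) -> TargetLayout:
    """Place targets on distinct grid fields with uniform jitter.

    Each target is assigned a distinct field of the grid and displaced by
    a uniform per-axis jitter; the whole placement is re-drawn until all
    pairwise distances reach ``min_sep`` (LayoutError after max_tries).
    """
    cfg = cfg or LayoutConfig()
    rng = _rng(seed)
    g = cfg.geom
    nx, ny = cfg.grid
    fx = (np.arange(nx) + 0.5) * g.res_x_px / nx
    fy = (np.arange(ny) + 0.5) * g.res_y_px / ny
    centers_px = np.array([(x, y) for y in fy for x in fx])
    centers_deg = px_to_deg(centers_px, g)
    labels = tuple(version_labels(version, cfg.n_targets))
    for _ in range(cfg.max_tries):
        fields = rng.choice(len(centers_deg), size=cfg.n_targets, replace=False)
        pos = centers_deg[fields] + rng.uniform(
            -cfg.jitter_deg, cfg.jitter_deg, size=(cfg.n_targets, 2)
        )
        d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        if d.min() >= cfg.min_sep:
            return TargetLayout(
                version=version,  # type: ignore[arg-type]
                labels=labels,
                centers_px=deg_to_px(pos, g),
                geom=g,
                circle_diameter=cfg.circle_diameter,
                aoi_diameter=cfg.aoi_diameter,
            )
    raise LayoutError(
        f"no layout with min_sep={cfg.min_sep} deg found in {cfg.max_tries} tries"
    )


@dataclass(frozen=True)
class BehaviorParams:
    """Subject- and condition-level parameters of the trial generator.

    Durations in ms, spans in s, scatter in deg va, click precision in
    px. The speed multipliers (< 1) encode the trade-off: fewer
    searching fixations and shorter eye-hand spans under speed emphasis,
    at the cost of less precise (occasionally missing) clicks.
    """

    fixation_dur_ms: float = 160.0      # median searching-fixation duration
    fixation_dur_sigma: float = 0.25    # lognormal sigma on the log scale
    span_s: float = 1.95                # median eye-hand span, accuracy emphasis
    span_sigma: float = 0.20
    span_extra_B_s: float = 0.30        # additive span increment in test half B
    search_rate: float = 2.0            # mean searching fixations per target, accuracy/A
    search_mult_speed: float = 0.65
    search_mult_B: float = 1.5
    span_mult_speed: float = 1.35 / 1.95
    click_sd_px_accuracy: float = 4.0
    click_sd_px_speed: float = 12.0
    reclick_delay_ms: float = 250.0
    start_latency_ms: float = 200.0
    fixation_scatter_sd: float = 0.3    # deg va
    refix_rate: float = 1.0             # guiding re-fixations per second of hold
    min_fix_ms: float = 50.0            # shortest emitted fixation
    saccade_velocity: float = 300.0     # deg/s, raw-sample rendering

    def __post_init__(self) -> None:
        for name in ("fixation_dur_ms", "span_s", "search_rate", "saccade_velocity"):
            if getattr(self, name) <= 0:
                raise ValueError(f"BehaviorParams.{name} must be > 0")
        if self.search_mult_speed > 1.0:
            raise ValueError("speed multiplier for searching fixations must be <= 1")


def _condition_mults(p: BehaviorParams, test_type: str, instruction: str):
    search = p.search_rate
    span = p.span_s
    if test_type == "B":
        search *= p.search_mult_B
        span += p.span_extra_B_s
    if instruction == "speed":
        search *= p.search_mult_speed
        span *= p.span_mult_speed
    click_sd = p.click_sd_px_speed if instruction == "speed" else p.click_sd_px_accuracy
    return search, span, click_sd


def _truncated_offset(rng, sd: float, max_r: float) -> np.ndarray:
    """Bivariate normal offset with the radius capped (keeps AOI roles exact)."""
    if sd <= 0:
        return np.zeros(2)
    off = rng.normal(0.0, sd, size=2)
    r = np.linalg.norm(off)
    cap = min(3.0 * sd, max_r)
    if r > cap:
        off *= cap / r
    return off


def _place(rng, center, sd, max_r, prev, min_gap: float = 1.05):
    """Landing position near ``center``, kept beyond the merge distance from
    the previous fixation when the scatter allows it."""
    cand = center + _truncated_offset(rng, sd, max_r)
    if prev is None:
        return cand
    for _ in range(100):
        if np.linalg.norm(cand - prev) >= min_gap:
            return cand
        cand = center + _truncated_offset(rng, sd, max_r)
    return cand


def simulate_trial(
    layout: TargetLayout,
    params: BehaviorParams | None = None,
    subject: str = "s01",
    instruction: str = "accuracy",
    seed=None,
    start_t: float = 0.0,
) -> TrialRecord:
    """Generate one event-level trial.

    Per target: a Poisson number of searching fixations on other
    targets, then one guiding fixation on the current target that is
    held until the hit click (so the recorded span is the time the eyes
    lead the hand). Clicks are drawn around the target center with
    condition-dependent precision; misses are re-clicked after a delay
    and do not advance the sequence. Ground-truth fixation roles are
    stored on the returned record (``truth_roles``).
    """
    params = params or BehaviorParams()
    rng = _rng(seed)
    search_mean, span_med, click_sd = _condition_mults(
        params, layout.version, instruction
    )
    centers_deg = layout.centers_deg
    max_off = min(0.95 * layout.aoi_diameter / 2.0, 0.475 * _min_sep(centers_deg))
    hit_radius_px = _deg_len_to_px(layout.circle_diameter / 2.0, layout.geom)

    fixations: list[FixationEvent] = []
    saccades: list[SaccadeEvent] = []
    clicks: list[ClickEvent] = []
    roles: list[str] = []
    t = start_t + params.start_latency_ms
    prev_centroid: np.ndarray | None = None
    prev_target: int | None = None

    def add_fixation(centroid: np.ndarray, duration: float, role: str) -> float:
        nonlocal t, prev_centroid
        if prev_centroid is not None:
            amp = float(np.linalg.norm(centroid - prev_centroid))
            sdur = max(2.0, amp / params.saccade_velocity * 1000.0)
            saccades.append(
                SaccadeEvent(
                    onset=t, offset=t + sdur, amplitude=amp,
                    peak_velocity=params.saccade_velocity,
                )
            )
            t += sdur
        onset = t
        fixations.append(
            FixationEvent(onset=onset, offset=onset + duration,
                          centroid=(float(centroid[0]), float(centroid[1])))
        )
        roles.append(role)
        prev_centroid = centroid
        t = onset + duration
        return onset

    for k in range(len(layout)):
        n_search = rng.poisson(search_mean)
        for _ in range(n_search):
            choices = [j for j in range(len(layout)) if j != k and j != prev_target]
            j = int(rng.choice(choices))
            centroid = _place(rng, centers_deg[j], params.fixation_scatter_sd,
                              max_off, prev_centroid)
            dur = params.fixation_dur_ms * np.exp(
                rng.normal(0.0, params.fixation_dur_sigma)
            )
            add_fixation(centroid, dur, "searching")
            prev_target = j
        span_ms = span_med * 1000.0 * np.exp(rng.normal(0.0, params.span_sigma))
        # the target is held until the click; longer holds produce re-fixations
        # (placed beyond the merge distance so they survive event merging)
        positions = [_place(rng, centers_deg[k], params.fixation_scatter_sd,
                            max_off, prev_centroid)]
        n_guide = 1 + rng.poisson(params.refix_rate * span_ms / 1000.0)
        while len(positions) < n_guide:
            for _ in range(50):
                cand = centers_deg[k] + _truncated_offset(
                    rng, params.fixation_scatter_sd, max_off
                )
                if np.linalg.norm(cand - positions[-1]) >= 1.05:
                    positions.append(cand)
                    break
            else:
                break  # too little scatter to separate re-fixations
        gaps = [
            max(2.0, np.linalg.norm(b - a) / params.saccade_velocity * 1000.0)
            for a, b in zip(positions, positions[1:])
        ]
        while len(positions) > 1 and (
            span_ms - sum(gaps) < params.min_fix_ms * len(positions)
        ):
            positions.pop()
            gaps = gaps[: len(positions) - 1]
        free = span_ms - sum(gaps) - params.min_fix_ms * len(positions)
        weights = rng.dirichlet(np.ones(len(positions))) if len(positions) > 1 else [1.0]
        durs = [params.min_fix_ms + w * free for w in weights]
        guide_onset = add_fixation(positions[0], durs[0], "guiding")
        for pos, dur in zip(positions[1:], durs[1:]):
            add_fixation(pos, dur, "guiding")
        prev_target = k
        # click attempts around the target center
        t_click = guide_onset + span_ms
        while True:
            pos = layout.centers_px[k] + rng.normal(0.0, click_sd, size=2)
            hit = np.linalg.norm(pos - layout.centers_px[k]) <= hit_radius_px
            clicks.append(
                ClickEvent(t=t_click, position=(float(pos[0]), float(pos[1])),
                           hit=bool(hit), target_index=k)
            )
            if hit:
                break
            t_click += params.reclick_delay_ms
        # the hold ends exactly at the hit (misses extend it)
        f = fixations[-1]
        fixations[-1] = FixationEvent(onset=f.onset, offset=t_click, centroid=f.centroid)
        t = t_click

    return TrialRecord(
        subject=subject,
        test_type=layout.version,
        instruction=instruction,  # type: ignore[arg-type]
        start_t=start_t,
        end_t=t,
        fixations=fixations,
        saccades=saccades,
        clicks=clicks,
        layout=layout,
        truth_roles=roles,
    )


def _min_sep(centers_deg: np.ndarray) -> float:
    d = np.linalg.norm(centers_deg[:, None, :] - centers_deg[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    return float(d.min())


def _deg_len_to_px(deg: float, geom: ScreenGeometry) -> float:
    """Length of a small central angular extent in pixels (x axis)."""
    return float(
        np.tan(np.radians(deg)) * geom.distance_cm / geom.pitch_x_cm
    )


def render_gaze_samples(trial: TrialRecord, rate_hz: float = 1000.0) -> pd.DataFrame:
    """Render a trial to raw gaze samples (default 1000 Hz).

    Gaze holds at each fixation centroid and moves linearly between
    consecutive centroids during the inter-fixation interval, so the
    ramp velocity (~300 deg/s at the default saccade speed) exceeds the
    detection threshold while fixations stay still. Running
    ``detect_events`` + ``merge_fixations`` on the output recovers the
    simulated fixation count.
    """
    dt = 1000.0 / rate_hz
    t_grid = np.arange(trial.start_t, trial.end_t + 1e-9, dt)  # never past end_t
    key_t: list[float] = []
    key_pos: list[np.ndarray] = []
    for f in trial.fixations:
        c = np.asarray(f.centroid)
        key_t.extend([f.onset, f.offset])
        key_pos.extend([c, c])
    if not key_t:
        raise ValueError("cannot render a trial without fixations")
    key_t = [trial.start_t] + key_t + [trial.end_t]
    key_pos = [key_pos[0]] + key_pos + [key_pos[-1]]
    kt = np.asarray(key_t)
    kp = np.vstack(key_pos)
    deg = np.column_stack(
        [np.interp(t_grid, kt, kp[:, 0]), np.interp(t_grid, kt, kp[:, 1])]
    )
    px = deg_to_px(deg, trial.layout.geom)
    return samples_frame(t_grid, px[:, 0], px[:, 1])


@dataclass(frozen=True)
class ScoreSimConfig:
    """Score-level generator: y_ij = X beta + u_j + eps_ij.

    ``betas`` are on the response scale in dummy coding with reference
    levels test half A and accuracy instruction: (intercept, test_type B,
    instruction speed, interaction). Defaults reproduce the structure of
    a trial-duration analysis in seconds.
    """

    betas: tuple[float, float, float, float] = (72.55, 22.97, -28.18, 14.20)
    sd_subject: float = 17.22
    sd_resid: float = 20.9
    n_subjects: int = 58
    response: str = "trial_duration"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.sd_subject < 0 or self.sd_resid < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")


def design_matrix(test_type: np.ndarray, instruction: np.ndarray) -> np.ndarray:
    """Dummy-coded 2x2 design (reference levels: test half A, accuracy)."""
    b = (np.asarray(test_type) == "B").astype(float)
    s = (np.asarray(instruction) == "speed").astype(float)
    return np.column_stack([np.ones_like(b), b, s, b * s])


def simulate_scores(cfg: ScoreSimConfig | None = None, seed=None) -> pd.DataFrame:
    """Draw one long-format score table (n_subjects x 4 rows)."""
    cfg = cfg or ScoreSimConfig()
    rng = _rng(cfg.seed if seed is None else seed)
    cells = [("A", "accuracy"), ("A", "speed"), ("B", "accuracy"), ("B", "speed")]
    subj = [f"s{i + 1:03d}" for i in range(cfg.n_subjects)]
    rows = []
    u = rng.normal(0.0, cfg.sd_subject, size=cfg.n_subjects)
    for i, s in enumerate(subj):
        for tt, ins in cells:
            rows.append((s, tt, ins))
    df = pd.DataFrame(rows, columns=["subject", "test_type", "instruction"])
    X = design_matrix(df["test_type"].to_numpy(), df["instruction"].to_numpy())
    eps = rng.normal(0.0, cfg.sd_resid, size=len(df))
    df[cfg.response] = X @ np.asarray(cfg.betas) + np.repeat(u, 4) + eps
    return df


def simulate_study(
    n_subjects: int = 8,
    params: BehaviorParams | None = None,
    cfg: LayoutConfig | None = None,
    seed=None,
    match_layouts: bool = False,
) -> list[TrialRecord]:
    """Event-level study: every subject completes the 2x2 design.

    One layout per test half, shared across subjects (as in the task,
    where all participants see the same arrangements). ``match_layouts``
    reuses the A arrangement for B, for studying the layout confound.
    """
    ss = np.random.SeedSequence(seed if seed is not None else 0)
    lay_seed, trial_seed = ss.spawn(2)
    lay_rng = np.random.default_rng(lay_seed)
    layout_a = generate_layout("A", cfg, lay_rng)
    if match_layouts:
        layout_b = replace(layout_a, version="B",
                           labels=tuple(version_labels("B", len(layout_a))))
    else:
        layout_b = generate_layout("B", cfg, lay_rng)
    trial_rng = np.random.default_rng(trial_seed)
    trials = []
    for i in range(n_subjects):
        for layout in (layout_a, layout_b):
            for instruction in ("accuracy", "speed"):
                trials.append(
                    simulate_trial(
                        layout,
                        params,
                        subject=f"s{i + 1:03d}",
                        instruction=instruction,
                        seed=trial_rng,
                    )
                )
    return trials
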