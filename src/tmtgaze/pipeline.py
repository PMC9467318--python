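"""End-to-end orchestration: data in, Table-style reports out.

``run_study`` drives the full analysis for the 2 (test half) x 2
(instruction) within-subject design:

1. obtain a long-format score table (simulate event-level trials, score
   supplied raw gaze / event files via a manifest, or load a ready
   score table),
2. fit the random-intercept mixed model for each of the eight measures
   (log-transforming the count/span/path measures),
3. run the dominance analysis (Bayes-factor quotient + R^2 with
   bootstrap CIs) per measure and test half,
4. write everything as TSV plus a YAML run log with seeds and resolved
   parameters.

Identical config and seed give byte-identical outputs.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as tio
from .dominance import BfPriorSpec, dominance_analysis
from .events import DetectionParams, detect_events, merge_fixations
from .geometry import PAPER_GEOMETRY, ScreenGeometry
from .lmm import LOG_TRANSFORMED_DVS, ModelSpec, fit_lmm
from .scoring import TrialRecord, score_trial, scores_to_frame
from .simulate import (
    BehaviorParams,
    LayoutConfig,
    ScoreSimConfig,
    generate_layout,
    render_gaze_samples,
    simulate_scores,
    simulate_study,
)

__all__ = ["RunConfig", "run_study", "make_fixture", "MEASURES"]

MEASURES = [
    "trial_duration",
    "mean_fixation_duration",
    "mean_saccade_amplitude",
    "n_fixations",
    "n_guiding",
    "n_searching",
    "mean_eye_hand_span",
    "scanpath_length",
]


@dataclass
class RunConfig:
    """Resolved parameters of one analysis run."""

    input_mode: str = "simulate"  # simulate | raw | events | scores
    scores_path: str | None = None
    manifest_path: str | None = None
    geometry: ScreenGeometry = PAPER_GEOMETRY
    detection: DetectionParams = dc_field(default_factory=DetectionParams)
    behavior: BehaviorParams = dc_field(default_factory=BehaviorParams)
    layout: LayoutConfig = dc_field(default_factory=LayoutConfig)
    n_subjects: int = 58
    seed: int = 0
    bootstrap_b: int = 1000
    priors: BfPriorSpec = dc_field(default_factory=BfPriorSpec)
    measures: list[str] = dc_field(default_factory=lambda: list(MEASURES))
    out_dir: str = "tmtgaze_out"

    def __post_init__(self) -> None:
        modes = {"simulate", "raw", "events", "scores"}
        if self.input_mode not in modes:
            raise ValueError(f"input_mode must be one of {sorted(modes)}")
        if self.input_mode == "scores" and not self.scores_path:
            raise ValueError("scores mode needs scores_path")
        if self.input_mode in ("raw", "events") and not self.manifest_path:
            raise ValueError(f"{self.input_mode} mode needs manifest_path")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and record."""


def _scores_from_manifest(cfg: RunConfig) -> pd.DataFrame:
    manifest = pd.read_csv(cfg.manifest_path, sep="\t", dtype={"subject": str})
    base = Path(cfg.manifest_path).parent
    rows = []
    for rec in manifest.itertuples(index=False):
        try:
            layout = tio.read_layout(base / rec.layout_file, cfg.geometry)
            clicks = tio.read_clicks(base / rec.clicks_file)
            if cfg.input_mode == "raw":
                gaze = tio.read_gaze(base / rec.gaze_file)
                fixations, saccades, _ = detect_events(gaze, cfg.detection, cfg.geometry)
                fixations, saccades = merge_fixations(fixations, cfg.detection, saccades)
            else:
                fixations, saccades = tio.read_events(base / rec.events_file)
            trial = TrialRecord(
                subject=rec.subject,
                test_type=rec.test_type,
                instruction=rec.instruction,
                start_t=float(rec.start_ms),
                end_t=float(rec.end_ms),
                fixations=fixations,
                saccades=saccades,
                clicks=clicks,
                layout=layout,
            )
            rows.append(score_trial(trial))
        except Exception as err:
            raise StageError(
                f"scoring failed for {rec.subject}/{rec.test_type}/{rec.instruction}: {err}"
            ) from err
    return scores_to_frame(rows)


def _score_table(cfg: RunConfig) -> pd.DataFrame:
    if cfg.input_mode == "scores":
        return tio.read_scores(cfg.scores_path)
    if cfg.input_mode in ("raw", "events"):
        return _scores_from_manifest(cfg)
    trials = simulate_study(cfg.n_subjects, cfg.behavior, cfg.layout, seed=cfg.seed)
    return scores_to_frame([score_trial(t) for t in trials])


def _fit_report(scores: pd.DataFrame, measures: list[str]) -> tuple[pd.DataFrame, dict]:
    rows = []
    meta = {}
    for dv in measures:
        log_it = dv in LOG_TRANSFORMED_DVS
        table = scores.copy()
        if log_it:
            table.loc[table[dv] <= 0, dv] = np.nan
        try:
            fit = fit_lmm(table, ModelSpec(response=dv, log_transform=log_it))
        except Exception as err:
            raise StageError(f"mixed-model fit failed for {dv}: {err}") from err
        s = fit.summary()
        s.insert(0, "dv", dv)
        s["log_transformed"] = int(log_it)
        s["n_groups"] = fit.n_groups
        s["n_obs"] = fit.n_obs
        s["sd_intercept"] = fit.sd_intercept
        s["sd_resid"] = fit.sd_resid
        rows.append(s)
        meta[dv] = {"n_groups": fit.n_groups, "n_obs": fit.n_obs}
    return pd.concat(rows, ignore_index=True), meta


def _dominance_report(
    scores: pd.DataFrame, measures: list[str], cfg: RunConfig
) -> pd.DataFrame:
    rows = []
    rng = np.random.SeedSequence(cfg.seed).spawn(len(measures) * 2)
    i = 0
    for dv in measures:
        log_it = dv in LOG_TRANSFORMED_DVS
        table = scores.copy()
        if log_it:
            table.loc[table[dv] <= 0, dv] = np.nan
        for half in ("A", "B"):
            try:
                res = dominance_analysis(
                    table, dv, half, priors=cfg.priors, log_transform=log_it,
                    B=cfg.bootstrap_b, seed=np.random.default_rng(rng[i]),
                )
            except Exception as err:
                raise StageError(f"dominance failed for {dv}/TMT-{half}: {err}") from err
            i += 1
            rows.append(
                {
                    "dv": dv,
                    "test_type": half,
                    "bf_fixed": res.bf_fixed,
                    "bf_random": res.bf_random,
                    "quotient": res.quotient,
                    "r2m": res.r2_marginal,
                    "r2m_lo": res.ci_r2m[0],
                    "r2m_hi": res.ci_r2m[1],
                    "r2c": res.r2_conditional,
                    "r2c_lo": res.ci_r2c[0],
                    "r2c_hi": res.ci_r2c[1],
                    "verdict": res.verdict,
                }
            )
    return pd.DataFrame(rows)


def run_study(cfg: RunConfig) -> dict:
    """Run the full pipeline; returns paths and in-memory tables."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {"seed": cfg.seed, "input_mode": cfg.input_mode, "stages": {}}

    t0 = time.perf_counter()
    scores = _score_table(cfg)
    log["stages"]["scores"] = {"n_rows": int(len(scores)),
                               "seconds": round(time.perf_counter() - t0, 3)}
    tio.write_scores(scores, out / "scores.tsv")

    t0 = time.perf_counter()
    lmm_report, lmm_meta = _fit_report(scores, cfg.measures)
    log["stages"]["lmm"] = {"per_dv": lmm_meta,
                            "seconds": round(time.perf_counter() - t0, 3)}
    lmm_report.to_csv(out / "lmm_report.tsv", sep="\t", index=False, float_format="%.10g")

    t0 = time.perf_counter()
    dom_report = _dominance_report(scores, cfg.measures, cfg)
    log["stages"]["dominance"] = {"bootstrap_b": cfg.bootstrap_b,
                                  "seconds": round(time.perf_counter() - t0, 3)}
    dom_report.to_csv(out / "dominance_report.tsv", sep="\t", index=False,
                      float_format="%.10g")

    log["parameters"] = {
        "geometry": cfg.geometry.__dict__,
        "detection": cfg.detection.__dict__,
        "priors": {"rscale_fixed": cfg.priors.rscale_fixed,
                   "rscale_random": cfg.priors.rscale_random},
        "n_subjects": cfg.n_subjects,
        "measures": cfg.measures,
    }
    with open(out / "run_log.yaml", "w") as fh:
        yaml.safe_dump(log, fh, sort_keys=True)
    return {"scores": scores, "lmm_report": lmm_report,
            "dominance_report": dom_report, "out_dir": str(out), "log": log}


def make_fixture(kind: str, seed: int, out_dir) -> dict:
    """Write a small deterministic dataset with ground-truth sidecars.

    kind="event-level": 8 subjects' trials as raw gaze + click + layout
    files with a manifest and a fixation-role sidecar. kind="score-level":
    a 58-subject score table drawn from the trial-duration mixed model,
    with the generating parameters recorded alongside.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if kind == "score-level":
        cfg = ScoreSimConfig(seed=seed)
        scores = simulate_scores(cfg)
        # embed the single simulated measure in a full score-table shape
        full = scores.rename(columns={cfg.response: cfg.response})
        for dv in MEASURES:
            if dv not in full.columns:
                full[dv] = np.nan
        tio.write_scores(full, out / "scores.tsv")
        with open(out / "truth.yaml", "w") as fh:
            yaml.safe_dump(
                {"betas": list(cfg.betas), "sd_subject": cfg.sd_subject,
                 "sd_resid": cfg.sd_resid, "n_subjects": cfg.n_subjects,
                 "response": cfg.response, "seed": seed},
                fh, sort_keys=True,
            )
        return {"out_dir": str(out), "n_rows": len(full)}
    if kind == "event-level":
        trials = simulate_study(8, seed=seed)
        manifest = []
        truth_rows = []
        layouts_written = set()
        for i, tr in enumerate(trials):
            stem = f"trial_{i:03d}"
            gaze = render_gaze_samples(tr)
            tio.write_gaze(gaze, out / f"{stem}_gaze.tsv")
            tio.write_clicks(tr.clicks, out / f"{stem}_clicks.tsv")
            lay_name = f"layout_{tr.test_type}.tsv"
            if lay_name not in layouts_written:
                tio.write_layout(tr.layout, out / lay_name)
                layouts_written.add(lay_name)
            manifest.append(
                {"subject": tr.subject, "test_type": tr.test_type,
                 "instruction": tr.instruction, "start_ms": tr.start_t,
                 "end_ms": tr.end_t, "gaze_file": f"{stem}_gaze.tsv",
                 "clicks_file": f"{stem}_clicks.tsv", "layout_file": lay_name}
            )
            for j, role in enumerate(tr.truth_roles or []):
                truth_rows.append({"trial": stem, "fixation_index": j, "role": role})
        pd.DataFrame(manifest).to_csv(out / "manifest.tsv", sep="\t", index=False,
                                      float_format="%.10g")
        pd.DataFrame(truth_rows).to_csv(out / "truth_roles.tsv", sep="\t", index=False)
        return {"out_dir": str(out), "n_trials": len(trials)}
    raise ValueError("kind must be 'event-level' or 'score-level'")
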