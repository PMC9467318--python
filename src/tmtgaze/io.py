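"""Delimited-text IO for every table the pipeline reads or writes.

All formats are TSV with headers; configuration is YAML. Gaze samples
use the canonical columns t_ms, x_px, y_px, valid.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import yaml

from .events import DetectionParams, FixationEvent, SaccadeEvent
from .geometry import ScreenGeometry
from .scoring import SCORE_COLUMNS, ClickEvent, TargetLayout

__all__ = [
    "read_gaze",
    "write_gaze",
    "write_events",
    "read_events",
    "read_layout",
    "write_layout",
    "read_clicks",
    "write_clicks",
    "read_scores",
    "write_scores",
    "load_config",
]

_FLOAT_FMT = "%.10g"


def read_gaze(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"t_ms", "x_px", "y_px", "valid"} - set(df.columns)
    if missing:
        raise ValueError(f"gaze file {path} missing columns {sorted(missing)}")
    df["valid"] = df["valid"].astype(bool)
    return df


def write_gaze(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["valid"] = out["valid"].astype(int)
    out.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def write_events(fixations, saccades, path) -> None:
    rows = []
    for f in fixations:
        rows.append(
            ("fixation", f.onset, f.offset, f.centroid[0], f.centroid[1], np.nan, np.nan)
        )
    for s in saccades:
        rows.append(("saccade", s.onset, s.offset, np.nan, np.nan, s.amplitude, s.peak_velocity))
    df = pd.DataFrame(
        rows,
        columns=["event", "onset_ms", "offset_ms", "centroid_x_deg", "centroid_y_deg",
                 "amplitude_deg", "peak_velocity_deg_s"],
    ).sort_values("onset_ms", kind="stable")
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_events(path) -> tuple[list[FixationEvent], list[SaccadeEvent]]:
    df = pd.read_csv(path, sep="\t")
    fixations, saccades = [], []
    for row in df.itertuples(index=False):
        if row.event == "fixation":
            fixations.append(
                FixationEvent(
                    onset=row.onset_ms, offset=row.offset_ms,
                    centroid=(row.centroid_x_deg, row.centroid_y_deg),
                )
            )
        else:
            saccades.append(
                SaccadeEvent(
                    onset=row.onset_ms, offset=row.offset_ms,
                    amplitude=row.amplitude_deg, peak_velocity=row.peak_velocity_deg_s,
                )
            )
    return fixations, saccades


def write_layout(layout: TargetLayout, path) -> None:
    pd.DataFrame(
        {
            "order": np.arange(len(layout)),
            "label": list(layout.labels),
            "x_px": layout.centers_px[:, 0],
            "y_px": layout.centers_px[:, 1],
            "version": layout.version,
        }
    ).to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_layout(path, geom: ScreenGeometry) -> TargetLayout:
    df = pd.read_csv(path, sep="\t", dtype={"label": str}).sort_values("order")
    return TargetLayout(
        version=df["version"].iloc[0],
        labels=tuple(df["label"]),
        centers_px=df[["x_px", "y_px"]].to_numpy(dtype=float),
        geom=geom,
    )


def write_clicks(clicks, path) -> None:
    pd.DataFrame(
        {
            "t_ms": [c.t for c in clicks],
            "x_px": [c.position[0] for c in clicks],
            "y_px": [c.position[1] for c in clicks],
            "hit": [int(c.hit) for c in clicks],
            "target_index": [c.target_index for c in clicks],
        }
    ).to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_clicks(path) -> list[ClickEvent]:
    df = pd.read_csv(path, sep="\t")
    return [
        ClickEvent(t=r.t_ms, position=(r.x_px, r.y_px), hit=bool(r.hit),
                   target_index=int(r.target_index))
        for r in df.itertuples(index=False)
    ]


def write_scores(df: pd.DataFrame, path) -> None:
    df[SCORE_COLUMNS].to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_scores(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"subject": str})
    missing = set(SCORE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"score file {path} missing columns {sorted(missing)}")
    return df


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    return cfg


def geometry_from_config(cfg: dict) -> ScreenGeometry:
    return ScreenGeometry(**cfg)


def detection_from_config(cfg: dict) -> DetectionParams:
    return DetectionParams(**cfg)
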