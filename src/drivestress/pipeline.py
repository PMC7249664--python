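"""End-to-end helpers wiring the processing stages together.

These functions take generated or loaded sessions through fusion,
normalization, feature extraction, classification and the HR statistics, and
are shared by the command-line interface and the analysis scripts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import blocks_features as bf
from . import ecg_hr
from .core import Channel, SessionRecording
from .ma_removal import FusionParams, fuse_spr

__all__ = [
    "fused_spr",
    "cohort_feature_table",
    "cohort_hr_table",
]


def fused_spr(rec: SessionRecording, fusion: FusionParams | None = None) -> Channel:
    return fuse_spr(rec.spr_left, rec.spr_right, fusion)


def cohort_feature_table(
    sessions: list[SessionRecording],
    fusion: FusionParams | None = None,
    block_s: float = bf.DEFAULT_BLOCK_S,
    stride_s: float = bf.DEFAULT_STRIDE_S,
) -> pd.DataFrame:
    """Fuse, normalize and featurize every session of a cohort.

    Normalization uses each track's own mean and, for subjects recorded in
    both scenarios, the standard deviation of that subject's *manual* track,
    so manual and autonomous blocks of one subject share a scale.  Subjects
    with no manual session fall back to the track's own std.
    """
    fused = {id(rec): fused_spr(rec, fusion) for rec in sessions}
    manual_std: dict[str, float] = {}
    for rec in sessions:
        if rec.scenario == "manual":
            manual_std[rec.subject_id] = float(np.std(fused[id(rec)].samples))
    tables = []
    for rec in sessions:
        ch = fused[id(rec)]
        std = manual_std.get(rec.subject_id, float(np.std(ch.samples)))
        stats = bf.NormalizationStats(float(np.mean(ch.samples)), std, "manual" if rec.subject_id in manual_std else rec.scenario)
        norm = bf.normalize_track(ch, stats)
        tables.append(
            bf.session_feature_table(norm, rec.schedule, rec.subject_id, rec.scenario, block_s, stride_s)
        )
    return pd.concat(tables, ignore_index=True)


def cohort_hr_table(sessions: list[SessionRecording]) -> pd.DataFrame:
    """Mean HR per interval class for every session with ECG channels.

    Selects the best derivation, detects R peaks, interpolates instantaneous
    HR to 1 Hz and averages per task, outside tasks and over the whole
    track.  One tidy row per (subject, scenario, interval class).
    """
    rows = []
    for rec in sessions:
        if not rec.ecg:
            continue
        best = ecg_hr.choose_derivation(rec.ecg)
        beats = ecg_hr.detect_r_peaks(rec.ecg[best])
        hr = ecg_hr.instantaneous_hr(beats, duration_s=rec.duration_s)
        for label, value in ecg_hr.mean_hr_by_interval(hr, rec.schedule).items():
            rows.append(
                {
                    "subject_id": rec.subject_id,
                    "scenario": rec.scenario,
                    "interval": label,
                    "mean_hr_bpm": value,
                }
            )
    return pd.DataFrame(rows)
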