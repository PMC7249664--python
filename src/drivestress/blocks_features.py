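"""Per-track normalization, block segmentation, feature extraction and labels.

The fused SPR is normalized per track (subtract the track mean, divide by a
track standard deviation), cut into 15 s blocks advanced every 5 s, and each
block is summarized by five statistics: variance, energy, mean absolute
value, mean absolute derivative and maximum absolute derivative.  A block is
labeled "stress" (1) when its time interval intersects any task interval of
the schedule, "no stress" (0) otherwise.

For cross-scenario comparisons the standard deviation comes from the same
subject's *manual* track, so the two scenarios of one subject live on a
common scale; the mean is always the track's own.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import Channel, EventSchedule

__all__ = [
    "FEATURE_NAMES",
    "NormalizationStats",
    "fit_normalization",
    "normalize_track",
    "segment_blocks",
    "extract_features",
    "label_blocks",
    "fit_feature_scaler",
    "apply_feature_scaler",
    "session_feature_table",
]

FEATURE_NAMES = ["variance", "energy", "mean_abs", "mean_abs_deriv", "max_abs_deriv"]

DEFAULT_BLOCK_S = 15.0
DEFAULT_STRIDE_S = 5.0


@dataclass(frozen=True)
class NormalizationStats:
    mean_mV: float
    std_mV: float
    std_source_scenario: str

    def __post_init__(self) -> None:
        if self.std_mV <= 0:
            raise ValueError("zero standard deviation")


def fit_normalization(spr: Channel, scenario: str) -> NormalizationStats:
    """Whole-track mean and standard deviation of an SPR signal."""
    std = float(np.std(spr.samples))
    if std == 0.0:
        raise ValueError("zero standard deviation")
    return NormalizationStats(float(np.mean(spr.samples)), std, scenario)


def normalize_track(spr: Channel, stats: NormalizationStats) -> Channel:
    """Apply ``(x - mean) / std``; self-fit stats yield a zero-mean,
    unit-std track."""
    return spr.copy_with((spr.samples - stats.mean_mV) / stats.std_mV, name=f"{spr.name}_norm")


def segment_blocks(
    duration_s: float, block_s: float = DEFAULT_BLOCK_S, stride_s: float = DEFAULT_STRIDE_S
) -> list[tuple[float, float]]:
    """Half-open block intervals ``[t, t + block_s)`` starting at 0 with the
    given stride; only full blocks are kept."""
    if block_s <= 0 or stride_s <= 0:
        raise ValueError("block_s and stride_s must be > 0")
    if duration_s < block_s:
        raise ValueError("duration shorter than one block")
    n_blocks = int(np.floor((duration_s - block_s) / stride_s)) + 1
    return [(i * stride_s, i * stride_s + block_s) for i in range(n_blocks)]


def extract_features(samples: np.ndarray, fs: float) -> np.ndarray:
    """The five block statistics, in :data:`FEATURE_NAMES` order.

    Variance and energy are population moments (energy = mean of squares, so
    ``energy - variance = mean**2``); the derivative is the first difference
    scaled by the sampling rate, giving units of (normalized units)/s.
    """
    x = np.asarray(samples, dtype=float)
    if x.size == 0:
        raise ValueError("empty block")
    d = np.abs(np.diff(x) * fs) if x.size > 1 else np.zeros(1)
    return np.array(
        [np.var(x), np.mean(x**2), np.mean(np.abs(x)), np.mean(d), np.max(d)]
    )


def label_blocks(blocks: list[tuple[float, float]], schedule: EventSchedule) -> np.ndarray:
    """1 for every block whose interval has non-empty overlap with any task
    interval (half-open semantics: a shared endpoint is not an overlap)."""
    tasks = schedule.task_intervals_s()
    labels = np.zeros(len(blocks), dtype=int)
    for i, (t0, t1) in enumerate(blocks):
        if any(t0 < b and a < t1 for _, a, b in tasks):
            labels[i] = 1
    return labels


def fit_feature_scaler(features: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature (min, max) over the training rows."""
    x = np.asarray(features, dtype=float)
    lo, hi = x.min(axis=0), x.max(axis=0)
    if np.any(hi <= lo):
        bad = [FEATURE_NAMES[i] for i in np.flatnonzero(hi <= lo)]
        raise ValueError(f"degenerate feature range (max = min) for: {', '.join(bad)}")
    return lo, hi


def apply_feature_scaler(features: np.ndarray, scaler: tuple[np.ndarray, np.ndarray]) -> np.ndarray:
    """Map to [0, 1] on the training range; out-of-range test values clip."""
    lo, hi = scaler
    return np.clip((np.asarray(features, float) - lo) / (hi - lo), 0.0, 1.0)


def session_feature_table(
    spr_norm: Channel,
    schedule: EventSchedule,
    subject_id: str,
    scenario: str,
    block_s: float = DEFAULT_BLOCK_S,
    stride_s: float = DEFAULT_STRIDE_S,
) -> pd.DataFrame:
    """One row per block: metadata, the five raw (unscaled) features and the
    truth label from the schedule."""
    blocks = segment_blocks(spr_norm.duration_s, block_s, stride_s)
    labels = label_blocks(blocks, schedule)
    fs = spr_norm.fs_hz
    rows = []
    for (t0, t1), lab in zip(blocks, labels):
        seg = spr_norm.samples[int(round(t0 * fs)) : int(round(t1 * fs))]
        feats = extract_features(seg, fs)
        rows.append([subject_id, scenario, t0, t1, *feats, lab])
    return pd.DataFrame(
        rows,
        columns=["subject_id", "scenario", "t_start_s", "t_end_s", *FEATURE_NAMES, "truth_label"],
    )
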