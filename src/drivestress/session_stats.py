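"""Cohort summary statistics and report tables.

Covers the task-level SPR statistics (per-task RMS normalized by the
whole-track RMS, the in-task / out-of-task standard-deviation ratio, local
RMS traces), paired t-tests across subjects, stress-interval percentages
from classifier timelines, and the assembly of the report tables.  The
published per-subject stress-percentage and mean-HR tables are packaged as
fixtures and can be reloaded to recompute their row means.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .core import Channel, EventSchedule

__all__ = [
    "local_rms",
    "task_normalized_rms",
    "std_ratio",
    "paired_ttest",
    "stress_percentages",
    "load_stress_pct_table",
    "load_mean_hr_table",
    "table_row_means",
    "build_report",
]


def _truncated_moving_average(x: np.ndarray, win: int) -> np.ndarray:
    ones = np.ones(win)
    return np.convolve(x, ones, mode="same") / np.convolve(np.ones_like(x), ones, mode="same")


def local_rms(x: Channel, window_s: float) -> Channel:
    """Moving RMS: square root of the moving mean of squares."""
    if window_s <= 0:
        raise ValueError("window_s must be > 0")
    win = int(round(window_s * x.fs_hz))
    if win < 1:
        raise ValueError("window shorter than one sample")
    return x.copy_with(np.sqrt(_truncated_moving_average(x.samples**2, win)), name=f"{x.name}_rms")


def _interval_samples(x: Channel, intervals: list[tuple[float, float]]) -> np.ndarray:
    fs = x.fs_hz
    parts = [x.samples[int(round(a * fs)) : int(round(b * fs))] for a, b in intervals]
    return np.concatenate(parts) if parts else np.empty(0)


def task_normalized_rms(spr: Channel, schedule: EventSchedule) -> dict[str, float]:
    """Per-task RMS of the SPR divided by the RMS over the whole track."""
    whole = float(np.sqrt(np.mean(spr.samples**2)))
    if whole == 0.0:
        raise ValueError("zero whole-track RMS")
    out = {}
    for name, a, b in schedule.task_intervals_s():
        seg = _interval_samples(spr, [(a, b)])
        if seg.size == 0:
            raise ValueError(f"task {name!r} contains no samples")
        out[name] = float(np.sqrt(np.mean(seg**2))) / whole
    return out


def std_ratio(spr: Channel, schedule: EventSchedule) -> float:
    """Std of the SPR over concatenated task samples divided by the std over
    concatenated non-task samples."""
    mask = schedule.in_task(spr.t_s)
    inside, outside = spr.samples[mask], spr.samples[~mask]
    if inside.size == 0 or outside.size == 0:
        raise ValueError("both interval classes must be non-empty")
    denom = float(np.std(outside))
    if denom == 0.0:
        raise ValueError("zero out-of-task standard deviation")
    return float(np.std(inside)) / denom


def paired_ttest(a: np.ndarray, b: np.ndarray) -> dict[str, float]:
    """Two-sided paired t-test on per-subject values.

    Returns the t statistic, df = n - 1 and the two-sided p-value.  Raises on
    zero-variance differences, where the statistic is undefined.
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.size != b.size or a.size < 2:
        raise ValueError("paired samples must have equal length >= 2")
    if np.std(a - b) == 0.0:
        raise ValueError("zero-variance differences")
    res = sstats.ttest_rel(a, b)
    return {"t": float(res.statistic), "df": float(a.size - 1), "p": float(res.pvalue)}


def stress_percentages(timeline: pd.DataFrame, schedule: EventSchedule | None = None) -> pd.DataFrame:
    """Percentage of blocks labeled "stress" per subject and scenario.

    Uses the post-relabel predictions.  One row per (subject, scenario) with
    the whole-track percentage; when a schedule is given, adds one column per
    task with the percentage among blocks intersecting that task.
    """
    if timeline.empty:
        raise ValueError("empty timeline")
    label_col = "relabeled_label" if "relabeled_label" in timeline.columns else "predicted_label"
    rows = []
    for (subj, sc), grp in timeline.groupby(["subject_id", "scenario"], sort=False):
        row: dict[str, object] = {"subject_id": subj, "scenario": sc}
        row["stress_pct"] = 100.0 * float(grp[label_col].mean())
        if schedule is not None:
            for name, a, b in schedule.task_intervals_s():
                in_task = grp[(grp["t_start_s"] < b) & (grp["t_end_s"] > a)]
                row[f"stress_pct_{name}"] = (
                    100.0 * float(in_task[label_col].mean()) if len(in_task) else np.nan
                )
        rows.append(row)
    return pd.DataFrame(rows)


def _load_fixture(name: str) -> pd.DataFrame:
    with resources.files("drivestress.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_stress_pct_table() -> pd.DataFrame:
    """Published per-subject whole-track stress percentages (13 subjects,
    manual and autonomous scenarios), as printed."""
    return _load_fixture("stress_pct_published.csv")


def load_mean_hr_table() -> pd.DataFrame:
    """Published per-subject mean HR by interval class, as printed.

    The printed table carries two known quirks, preserved verbatim: the
    manual block labels one row "task 4" twice (``row_index`` disambiguates)
    and one manual task-2 entry is inconsistent with its printed row mean.
    ``consistent`` flags the rows whose printed mean matches the arithmetic
    mean of the printed per-subject entries.
    """
    return _load_fixture("mean_hr_published.csv")


def table_row_means(table: pd.DataFrame, value_col: str, by: list[str]) -> pd.DataFrame:
    """Arithmetic mean of the per-subject entries for each table row."""
    return table.groupby(by, sort=False)[value_col].mean().reset_index(name="mean")


def build_report(
    timelines: pd.DataFrame | None = None,
    hr_means: pd.DataFrame | None = None,
    task_rms: pd.DataFrame | None = None,
    schedule: EventSchedule | None = None,
) -> dict[str, pd.DataFrame]:
    """Assemble the report tables from cohort results.

    Returns a dict of tidy tables: ``stress_pct`` (per subject/scenario),
    ``hr_by_interval`` and ``task_rms`` when the corresponding inputs are
    given, plus recomputed row means of the packaged published tables
    (``published_stress_means``, ``published_hr_means``) for regression
    checks.
    """
    out: dict[str, pd.DataFrame] = {}
    if timelines is not None:
        if timelines.empty:
            raise ValueError("empty cohort timeline")
        out["stress_pct"] = stress_percentages(timelines, schedule)
    if hr_means is not None:
        out["hr_by_interval"] = hr_means
    if task_rms is not None:
        out["task_rms"] = task_rms
    pub_stress = load_stress_pct_table()
    out["published_stress_means"] = table_row_means(pub_stress, "stress_pct", ["scenario"])
    pub_hr = load_mean_hr_table()
    out["published_hr_means"] = table_row_means(pub_hr, "hr_bpm", ["scenario", "row_index", "row_label"])
    return out
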