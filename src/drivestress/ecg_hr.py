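"""R-peak detection, instantaneous heart rate and interval-class averages.

The detector follows the classic Pan–Tompkins stages: band-pass filtering in
the QRS band, differentiation, squaring, moving-window integration, an
adaptive (per-segment) threshold and a 250 ms refractory period.  When more
than one ECG derivation is available the one with the highest QRS-band
signal-to-noise ratio is analyzed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .core import Channel, EventSchedule

__all__ = [
    "HRSeries",
    "choose_derivation",
    "detect_r_peaks",
    "instantaneous_hr",
    "mean_hr_by_interval",
]

QRS_BAND_HZ = (5.0, 25.0)
REFRACTORY_S = 0.25
#: physiologic gating bounds for instantaneous HR, bpm
HR_GATE_BPM = (20.0, 250.0)


@dataclass
class HRSeries:
    """Beat times plus instantaneous HR interpolated onto a 1 Hz grid."""

    beat_times_s: np.ndarray
    t_s: np.ndarray
    hr_bpm: np.ndarray


def _band_power_ratio(x: np.ndarray, fs: float) -> float:
    f, pxx = sps.welch(x, fs=fs, nperseg=min(x.size, int(4 * fs)))
    band = (f >= QRS_BAND_HZ[0]) & (f <= QRS_BAND_HZ[1])
    p_in = float(np.trapezoid(pxx[band], f[band]))
    p_out = float(np.trapezoid(pxx[~band], f[~band]))
    return p_in / max(p_out, 1e-30)


def choose_derivation(ecg_channels: list[Channel]) -> int:
    """Index of the channel with the highest QRS-band SNR (power in the
    5–25 Hz band over power outside it).  Ties break to the lowest index."""
    if not ecg_channels:
        raise ValueError("no ECG channels")
    scores = [_band_power_ratio(ch.samples, ch.fs_hz) for ch in ecg_channels]
    return int(np.argmax(scores))


def detect_r_peaks(ecg: Channel, segment_s: float = 10.0, rel_threshold: float = 0.3) -> np.ndarray:
    """Detect R-peak times (seconds) in a single ECG channel.

    Requires fs >= 100 Sa/s.  The adaptive threshold is ``rel_threshold``
    times the maximum of the integrated signal within each ``segment_s``
    segment; detected peaks are refined to the local band-passed maximum and
    deduplicated under the 250 ms refractory period.
    """
    fs = ecg.fs_hz
    if fs < 100:
        raise ValueError("R-peak detection requires fs >= 100 Sa/s")
    x = ecg.samples - np.mean(ecg.samples)
    sos = sps.butter(2, QRS_BAND_HZ, btype="bandpass", fs=fs, output="sos")
    bp = sps.sosfiltfilt(sos, x)
    sq = np.gradient(bp) ** 2
    win = max(int(round(0.15 * fs)), 1)
    integ = np.convolve(sq, np.ones(win) / win, mode="same")

    # per-segment adaptive threshold
    seg_len = max(int(round(segment_s * fs)), win)
    thresh = np.empty_like(integ)
    for start in range(0, integ.size, seg_len):
        seg = integ[start : start + seg_len]
        thresh[start : start + seg_len] = rel_threshold * seg.max()
    peaks, _ = sps.find_peaks(integ, height=thresh, distance=int(round(REFRACTORY_S * fs)))

    # refine each detection to the nearest band-passed maximum (R apex)
    half = int(round(0.1 * fs))
    refined = []
    for p in peaks:
        a, b = max(p - half, 0), min(p + half + 1, bp.size)
        refined.append(a + int(np.argmax(bp[a:b])))
    refined = np.unique(refined)
    if refined.size:
        keep = [refined[0]]
        for r in refined[1:]:
            if (r - keep[-1]) / fs >= REFRACTORY_S:
                keep.append(r)
        refined = np.asarray(keep)
    return refined / fs


def instantaneous_hr(beat_times_s: np.ndarray, duration_s: float | None = None) -> HRSeries:
    """Instantaneous HR = 60/RR assigned at the later beat of each pair,
    physiologically gated to (20, 250) bpm, then linearly interpolated onto a
    1 Hz grid covering the session."""
    bt = np.asarray(beat_times_s, dtype=float)
    if bt.size < 2:
        raise ValueError("need at least 2 beats")
    rr = np.diff(bt)
    hr = 60.0 / rr
    t_hr = bt[1:]
    ok = (hr > HR_GATE_BPM[0]) & (hr < HR_GATE_BPM[1])
    if not np.any(ok):
        raise ValueError("no physiologically plausible RR intervals")
    t_hr, hr = t_hr[ok], hr[ok]
    end = duration_s if duration_s is not None else bt[-1]
    grid = np.arange(0.0, np.floor(end) + 1.0)
    return HRSeries(beat_times_s=bt, t_s=grid, hr_bpm=np.interp(grid, t_hr, hr))


def mean_hr_by_interval(hr: HRSeries, schedule: EventSchedule) -> dict[str, float]:
    """Arithmetic mean of the 1 Hz HR samples per interval class: one entry
    per task, plus 'no tasks' and 'whole track'."""
    out: dict[str, float] = {}
    in_any = np.zeros(hr.t_s.size, dtype=bool)
    for name, a, b in schedule.task_intervals_s():
        mask = (hr.t_s >= a) & (hr.t_s < b)
        if not np.any(mask):
            raise ValueError(f"no HR samples in task {name!r}")
        out[name] = float(np.mean(hr.hr_bpm[mask]))
        in_any |= mask
    track_mask = hr.t_s < schedule.duration_s
    no_task = ~in_any & track_mask
    if not np.any(no_task):
        raise ValueError("no HR samples outside tasks")
    out["no tasks"] = float(np.mean(hr.hr_bpm[no_task]))
    out["whole track"] = float(np.mean(hr.hr_bpm[track_mask]))
    return out
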