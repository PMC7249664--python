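"""Seeded synthetic driving-session generator.

Emulates the statistical structure of skin-potential-response (SPR) and ECG
recordings taken while driving on a fixed highway track with four
stress-inducing tasks, in a manual and an autonomous scenario:

* a slow tonic SPR baseline with drift,
* event-evoked phasic transients (biexponential kinetics) whose rate is
  higher inside task intervals, amplitudes drawn per event,
* single-hand motion-artifact bursts added to the hand channels (hands on
  the steering wheel engage one hand at a time),
* an ECG beat train whose instantaneous rate rises inside tasks.

The manual scenario defaults produce frequent, moderate-amplitude phasic
peaks with motion artifacts; the autonomous defaults produce sparse,
higher-amplitude peaks and no artifacts (hands rest on the knees).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .core import Channel, EventSchedule, SessionRecording, SessionTruth, TrackEvent

__all__ = [
    "EventSchedule",
    "TrackEvent",
    "SessionTruth",
    "SprGenParams",
    "EcgGenParams",
    "RandomEffects",
    "make_default_track",
    "make_warmup_schedule",
    "default_spr_params",
    "default_ecg_params",
    "generate_session",
    "generate_cohort",
]

#: Per-channel (gain, noise sd in mV) for the three simulated ECG derivations.
#: The middle derivation is the cleanest, mirroring a chest-vest montage where
#: one lead usually has the best signal-to-noise ratio.
ECG_DERIVATION_QUALITY = ((0.7, 0.06), (1.0, 0.02), (0.8, 0.04))


@dataclass(frozen=True)
class SprGenParams:
    """Parameters of the synthetic SPR process (amplitudes in mV, rates per
    minute, time constants in seconds)."""

    tonic_level_mV: float = 1.0
    tonic_drift_mV_per_min: float = 0.05
    evoked_rate_in_task_per_min: float = 6.0
    evoked_rate_out_task_per_min: float = 2.0
    evoked_amp_mean_mV: float = 0.8
    evoked_amp_sd_mV: float = 0.25
    rise_tau_s: float = 0.5
    decay_tau_s: float = 3.0
    noise_sd_mV: float = 0.05
    artifact_rate_per_min: float = 1.5
    artifact_amp_mV: float = 2.0
    artifact_dur_s: float = 0.6
    simultaneous_artifact_prob: float = 0.05

    def __post_init__(self) -> None:
        for name in (
            "evoked_rate_in_task_per_min",
            "evoked_rate_out_task_per_min",
            "evoked_amp_sd_mV",
            "rise_tau_s",
            "decay_tau_s",
            "noise_sd_mV",
            "artifact_rate_per_min",
            "artifact_dur_s",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.simultaneous_artifact_prob <= 1.0:
            raise ValueError("simultaneous_artifact_prob must be in [0, 1]")


@dataclass(frozen=True)
class EcgGenParams:
    """Parameters of the synthetic ECG beat train."""

    baseline_hr_bpm: float = 80.0
    task_hr_increment_bpm: float = 4.0
    hr_jitter_sd_bpm: float = 2.0
    noise_sd_mV: float = 0.02
    #: beat template: (amplitude mV, offset from R in s, width sd in s) per wave
    beat_template: tuple[tuple[float, float, float], ...] = (
        (-0.10, -0.040, 0.010),  # Q
        (1.00, 0.000, 0.012),  # R
        (-0.15, 0.030, 0.010),  # S
        (0.20, 0.250, 0.050),  # T
    )

    def __post_init__(self) -> None:
        if not 20.0 < self.baseline_hr_bpm < 220.0:
            raise ValueError("baseline_hr_bpm must be in (20, 220)")
        if self.hr_jitter_sd_bpm < 0:
            raise ValueError("hr_jitter_sd_bpm must be >= 0")


@dataclass(frozen=True)
class RandomEffects:
    """Between-subject variability applied on top of the scenario defaults."""

    baseline_hr_sd_bpm: float = 8.0
    tonic_scale_sd_log: float = 0.2
    evoked_amp_scale_sd_log: float = 0.25


def default_spr_params(scenario: str) -> SprGenParams:
    """Scenario-specific SPR defaults.

    Manual driving shows frequent evoked peaks of moderate amplitude plus
    steering-wheel motion artifacts; autonomous driving shows sparse but
    larger peaks concentrated in the tasks and artifact-free hands.
    """
    if scenario == "manual":
        return SprGenParams()
    if scenario == "autonomous":
        return SprGenParams(
            evoked_rate_in_task_per_min=2.5,
            evoked_rate_out_task_per_min=0.3,
            evoked_amp_mean_mV=1.6,
            evoked_amp_sd_mV=0.4,
            artifact_rate_per_min=0.0,
        )
    if scenario == "warmup":
        return SprGenParams(
            evoked_rate_in_task_per_min=2.0,
            evoked_rate_out_task_per_min=2.0,
            artifact_rate_per_min=0.5,
        )
    raise ValueError(f"unknown scenario tag {scenario!r}")


def default_ecg_params(scenario: str) -> EcgGenParams:
    """Scenario-specific heart-rate defaults: manual driving carries a higher
    baseline rate and a larger in-task increment than autonomous driving."""
    if scenario == "manual":
        return EcgGenParams(baseline_hr_bpm=83.0, task_hr_increment_bpm=4.0)
    if scenario == "autonomous":
        return EcgGenParams(baseline_hr_bpm=75.5, task_hr_increment_bpm=0.5)
    if scenario == "warmup":
        return EcgGenParams(baseline_hr_bpm=75.0, task_hr_increment_bpm=0.0)
    raise ValueError(f"unknown scenario tag {scenario!r}")


def make_default_track(speed_kmh: float = 120.0) -> EventSchedule:
    """The default 40 km highway track with its four tasks.

    Task lengths are 3.5 km (overtake), 2.5 km (trucks), 1 km (narrow) and
    5 km (wind) — 12 km of tasks in total, 30% of the track.  At the default
    120 km/h cruise speed the track takes 20 minutes.  Task positions along
    the track are a package choice (spread out with recovery gaps between
    them) and can be overridden by building an :class:`EventSchedule`
    directly.
    """
    events = [
        TrackEvent("overtake", 5.0, 8.5),
        TrackEvent("trucks", 13.0, 15.5),
        TrackEvent("narrow", 20.0, 21.0),
        TrackEvent("wind", 27.0, 32.0),
    ]
    return EventSchedule(track_length_km=40.0, speed_kmh=speed_kmh, events=events)


def make_warmup_schedule(speed_kmh: float = 120.0, length_km: float = 10.0) -> EventSchedule:
    """A short task-free stretch used for the familiarization phase."""
    return EventSchedule(track_length_km=length_km, speed_kmh=speed_kmh, events=[])


def _biexp_kernel(rise_tau_s: float, decay_tau_s: float, fs: float) -> np.ndarray:
    """Unit-peak biexponential transient exp(-t/td) - exp(-t/tr)."""
    t = np.arange(0.0, 6.0 * decay_tau_s, 1.0 / fs)
    k = np.exp(-t / decay_tau_s) - np.exp(-t / rise_tau_s)
    peak = k.max()
    if peak <= 0:
        raise ValueError("decay_tau_s must exceed rise_tau_s")
    return k / peak


def _add_at(signal: np.ndarray, kernel: np.ndarray, idx: int) -> None:
    stop = min(idx + kernel.size, signal.size)
    if stop > idx >= 0:
        signal[idx:stop] += kernel[: stop - idx]


def _poisson_times(rng: np.random.Generator, intervals: list[tuple[float, float]], rate_per_min: float) -> np.ndarray:
    """Homogeneous Poisson event times within a union of intervals."""
    times: list[np.ndarray] = []
    for a, b in intervals:
        n = rng.poisson(rate_per_min * (b - a) / 60.0)
        times.append(rng.uniform(a, b, size=n))
    out = np.concatenate(times) if times else np.empty(0)
    return np.sort(out)


def _artifact_burst(rng: np.random.Generator, n: int, amp: float) -> np.ndarray:
    """A pressure/movement burst: white noise under a Hann envelope, so it
    carries high first-difference energy against the slow SPR background."""
    env = np.hanning(max(n, 3))[:n]
    return amp * env * rng.standard_normal(n)


def generate_session(
    subject_id: str,
    scenario: str,
    schedule: EventSchedule,
    spr_params: SprGenParams | None = None,
    ecg_params: EcgGenParams | None = None,
    fs: float = 250.0,
    seed: int = 0,
    n_ecg: int = 3,
) -> tuple[SessionRecording, SessionTruth]:
    """Generate one synthetic session with ground truth.

    Identical ``(seed, params)`` produce bit-identical output.  ``n_ecg=0``
    skips ECG synthesis (useful with low sampling rates where R-peak
    detection would not be meaningful anyway).
    """
    if scenario not in ("manual", "autonomous", "warmup"):
        raise ValueError(f"unknown scenario tag {scenario!r}")
    if fs <= 0:
        raise ValueError("fs must be > 0")
    spr_params = spr_params if spr_params is not None else default_spr_params(scenario)
    ecg_params = ecg_params if ecg_params is not None else default_ecg_params(scenario)

    rng = np.random.default_rng(seed)
    duration = schedule.duration_s
    n = int(round(duration * fs))
    t = np.arange(n) / fs

    # --- clean SPR: tonic + evoked transients + measurement noise
    tonic = spr_params.tonic_level_mV + spr_params.tonic_drift_mV_per_min * t / 60.0
    task_iv = [(a, b) for _, a, b in schedule.task_intervals_s()]
    out_iv = _complement_intervals(task_iv, duration)
    evoked_times = np.sort(
        np.concatenate(
            [
                _poisson_times(rng, task_iv, spr_params.evoked_rate_in_task_per_min),
                _poisson_times(rng, out_iv, spr_params.evoked_rate_out_task_per_min),
            ]
        )
    )
    phasic = np.zeros(n)
    kernel = _biexp_kernel(spr_params.rise_tau_s, spr_params.decay_tau_s, fs)
    amps = rng.normal(spr_params.evoked_amp_mean_mV, spr_params.evoked_amp_sd_mV, size=evoked_times.size)
    amps = np.clip(amps, 0.0, None)
    for tt, a in zip(evoked_times, amps):
        _add_at(phasic, a * kernel, int(round(tt * fs)))
    clean = tonic + phasic + rng.normal(0.0, spr_params.noise_sd_mV, size=n)

    # --- hand channels: clean + independent noise + artifact bursts
    left = clean + rng.normal(0.0, spr_params.noise_sd_mV, size=n)
    right = clean + rng.normal(0.0, spr_params.noise_sd_mV, size=n)
    art_left: list[tuple[float, float]] = []
    art_right: list[tuple[float, float]] = []
    n_art = rng.poisson(spr_params.artifact_rate_per_min * duration / 60.0)
    burst_len = max(int(round(spr_params.artifact_dur_s * fs)), 1)
    prev_end = -np.inf
    for t0 in np.sort(rng.uniform(0.0, max(duration - spr_params.artifact_dur_s, 0.0), size=n_art)):
        if t0 < prev_end:  # one hand moves at a time: bursts never overlap
            continue
        prev_end = t0 + spr_params.artifact_dur_s
        idx = int(round(t0 * fs))
        interval = (t0, t0 + spr_params.artifact_dur_s)
        both = rng.random() < spr_params.simultaneous_artifact_prob
        hands = ("left", "right") if both else (("left",) if rng.random() < 0.5 else ("right",))
        for hand in hands:
            burst = _artifact_burst(rng, burst_len, spr_params.artifact_amp_mV)
            if hand == "left":
                _add_at(left, burst, idx)
                art_left.append(interval)
            else:
                _add_at(right, burst, idx)
                art_right.append(interval)

    # --- ECG beat train
    beat_times = _beat_times(rng, schedule, ecg_params, duration)
    ecg_channels: list[Channel] = []
    if n_ecg > 0:
        base = _ecg_waveform(beat_times, ecg_params, n, fs)
        for i in range(min(n_ecg, len(ECG_DERIVATION_QUALITY))):
            gain, noise_sd = ECG_DERIVATION_QUALITY[i]
            samples = gain * base + rng.normal(0.0, max(noise_sd, ecg_params.noise_sd_mV), size=n)
            ecg_channels.append(Channel(f"ecg_{i}", "mV", fs, samples))

    rec = SessionRecording(
        subject_id=subject_id,
        scenario=scenario,
        spr_left=Channel("spr_left", "mV", fs, left),
        spr_right=Channel("spr_right", "mV", fs, right),
        ecg=ecg_channels,
        schedule=schedule,
    )
    truth = SessionTruth(
        clean_spr=Channel("spr_clean", "mV", fs, clean),
        artifact_intervals_left=art_left,
        artifact_intervals_right=art_right,
        evoked_times_s=evoked_times,
        beat_times_s=beat_times,
    )
    return rec, truth


def _complement_intervals(intervals: list[tuple[float, float]], duration: float) -> list[tuple[float, float]]:
    out = []
    cursor = 0.0
    for a, b in intervals:
        if a > cursor:
            out.append((cursor, a))
        cursor = max(cursor, b)
    if cursor < duration:
        out.append((cursor, duration))
    return out


def _beat_times(
    rng: np.random.Generator, schedule: EventSchedule, p: EcgGenParams, duration: float
) -> np.ndarray:
    times = []
    t = float(rng.uniform(0.2, 1.0))
    while t < duration:
        hr = p.baseline_hr_bpm + p.task_hr_increment_bpm * float(schedule.in_task(np.array([t]))[0])
        hr += rng.normal(0.0, p.hr_jitter_sd_bpm)
        hr = max(hr, 25.0)
        times.append(t)
        t += 60.0 / hr
    return np.asarray(times)


def _ecg_waveform(beat_times: np.ndarray, p: EcgGenParams, n: int, fs: float) -> np.ndarray:
    sig = np.zeros(n)
    # render one template at the beat sampling grid, widest wave defines span
    span = max(abs(off) + 4 * sd for _, off, sd in p.beat_template)
    tk = np.arange(-span, span, 1.0 / fs)
    template = np.zeros(tk.size)
    for amp, off, sd in p.beat_template:
        template += amp * np.exp(-0.5 * ((tk - off) / sd) ** 2)
    lead = int(round(span * fs))
    for bt in beat_times:
        _add_at(sig, template, int(round(bt * fs)) - lead)
    return sig


def cohort_subject_effects(
    n_subjects: int, seed: int, random_effects: RandomEffects | None = None
) -> list[dict]:
    """Per-subject random effects for a cohort seed.

    Deterministic in ``(n_subjects, seed, random_effects)`` and used by
    :func:`generate_cohort` itself, so analyses can recover the programmed
    per-subject parameters (e.g. the heart-rate offset) without regenerating
    the signals.
    """
    re = random_effects if random_effects is not None else RandomEffects()
    rng = np.random.default_rng([seed, 1])
    effects = []
    for i in range(n_subjects):
        effects.append(
            {
                "subject_id": f"s{i + 1:02d}",
                "hr_offset_bpm": rng.normal(0.0, re.baseline_hr_sd_bpm) if re.baseline_hr_sd_bpm > 0 else 0.0,
                "tonic_scale": float(np.exp(rng.normal(0.0, re.tonic_scale_sd_log))) if re.tonic_scale_sd_log > 0 else 1.0,
                "evoked_amp_scale": float(np.exp(rng.normal(0.0, re.evoked_amp_scale_sd_log))) if re.evoked_amp_scale_sd_log > 0 else 1.0,
            }
        )
    return effects


def generate_cohort(
    n_subjects: int,
    scenarios: tuple[str, ...] = ("manual", "autonomous"),
    schedule: EventSchedule | None = None,
    spr_params: dict[str, SprGenParams] | None = None,
    ecg_params: dict[str, EcgGenParams] | None = None,
    random_effects: RandomEffects | None = None,
    fs: float = 250.0,
    seed: int = 0,
    n_ecg: int = 3,
) -> list[tuple[SessionRecording, SessionTruth]]:
    """Generate a cohort with per-subject random effects.

    Each subject receives a heart-rate offset and log-normal scale factors on
    tonic level and evoked amplitude, shared across that subject's scenarios
    (so within-subject scenario contrasts remain paired).  Scenario order
    alternates across subjects: odd-numbered subjects drive the first
    scenario first, even-numbered the reverse.  Sessions are returned in the
    order they were "performed".
    """
    if n_subjects < 2:
        raise ValueError("a cohort needs at least 2 subjects")
    schedule = schedule if schedule is not None else make_default_track()
    spr_params = spr_params or {sc: default_spr_params(sc) for sc in scenarios}
    ecg_params = ecg_params or {sc: default_ecg_params(sc) for sc in scenarios}
    effects = cohort_subject_effects(n_subjects, seed, random_effects)

    seed_rng = np.random.default_rng([seed, 2])
    sessions: list[tuple[SessionRecording, SessionTruth]] = []
    for i, eff in enumerate(effects):
        order = list(scenarios) if i % 2 == 0 else list(scenarios)[::-1]
        for sc in order:
            sp = spr_params[sc]
            sp = replace(
                sp,
                tonic_level_mV=sp.tonic_level_mV * eff["tonic_scale"],
                evoked_amp_mean_mV=sp.evoked_amp_mean_mV * eff["evoked_amp_scale"],
                evoked_amp_sd_mV=sp.evoked_amp_sd_mV * eff["evoked_amp_scale"],
            )
            ep = ecg_params[sc]
            new_hr = float(np.clip(ep.baseline_hr_bpm + eff["hr_offset_bpm"], 40.0, 180.0))
            ep = replace(ep, baseline_hr_bpm=new_hr)
            session_seed = int(seed_rng.integers(0, 2**31 - 1))
            sessions.append(
                generate_session(
                    eff["subject_id"], sc, schedule, sp, ep, fs=fs, seed=session_seed, n_ecg=n_ecg
                )
            )
    return sessions
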