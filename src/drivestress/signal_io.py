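"""Session file I/O, cohort manifests and configuration loading.

A session is stored as a single delimited-text file: a ``#``-prefixed header
block with the metadata (subject, scenario, sampling rate, units, the track
schedule as JSON) followed by one CSV column per channel.  Floats are
written at full precision so a write/read round trip is lossless.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import Channel, EventSchedule, SessionRecording

__all__ = [
    "Channel",
    "SessionRecording",
    "write_session",
    "read_session",
    "write_manifest",
    "read_manifest",
    "load_sessions",
    "load_config",
    "DEFAULT_CONFIG",
]

_MAGIC = "drivestress-session v1"


def write_session(rec: SessionRecording, path: str | Path) -> None:
    path = Path(path)
    chans = rec.channels
    header = [
        f"# {_MAGIC}",
        f"# subject_id: {rec.subject_id}",
        f"# scenario: {rec.scenario}",
        f"# fs_hz: {rec.fs_hz!r}",
        f"# units: {','.join(c.unit for c in chans)}",
        f"# schedule: {json.dumps(rec.schedule.to_dict())}",
    ]
    data = pd.DataFrame({c.name: c.samples for c in chans})
    with path.open("w") as fh:
        fh.write("\n".join(header) + "\n")
        data.to_csv(fh, index=False, float_format="%.17g")


def read_session(path: str | Path) -> SessionRecording:
    path = Path(path)
    meta: dict[str, str] = {}
    with path.open() as fh:
        first = fh.readline().strip()
        if first != f"# {_MAGIC}":
            raise ValueError(f"{path} is not a session file")
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("# "):
            key, _, value = line[2:].partition(": ")
            meta[key.strip()] = value.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        data = pd.read_csv(fh, float_precision="round_trip")
    for key in ("subject_id", "scenario", "fs_hz", "units", "schedule"):
        if key not in meta:
            raise ValueError(f"session file missing header field {key!r}")
    fs = float(meta["fs_hz"])
    units = meta["units"].split(",")
    if len(units) != data.shape[1]:
        raise ValueError("units header does not match channel count")
    channels = {
        name: Channel(name, unit, fs, data[name].to_numpy())
        for name, unit in zip(data.columns, units)
    }
    for required in ("spr_left", "spr_right"):
        if required not in channels:
            raise ValueError(f"missing channel {required!r}")
    ecg = [channels[c] for c in data.columns if c.startswith("ecg")]
    return SessionRecording(
        subject_id=meta["subject_id"],
        scenario=meta["scenario"],
        spr_left=channels["spr_left"],
        spr_right=channels["spr_right"],
        ecg=ecg,
        schedule=EventSchedule.from_dict(json.loads(meta["schedule"])),
    )


def write_manifest(entries: list[dict], path: str | Path) -> None:
    """Cohort manifest: one row per session with subject, scenario, relative
    file path and the generation seed."""
    pd.DataFrame(entries, columns=["subject_id", "scenario", "path", "seed"]).to_csv(path, index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def load_sessions(manifest_path: str | Path) -> list[SessionRecording]:
    """Load every session a manifest references (paths are relative to the
    manifest's directory)."""
    manifest_path = Path(manifest_path)
    manifest = read_manifest(manifest_path)
    return [read_session(manifest_path.parent / p) for p in manifest["path"]]


DEFAULT_CONFIG: dict = {
    "fs_hz": 250.0,
    "block_s": 15.0,
    "stride_s": 5.0,
    "fusion": {"energy_window_s": 2.0, "sharpening_exponent": 2.0, "epsilon": 1e-12},
    "relabel_max_run": 1,
    "svm": {"cv_folds": 5},
    "spr": {
        "noise_sd_mV": 0.05,
        "artifact_rate_per_min": 1.5,
        "artifact_amp_mV": 2.0,
        "artifact_dur_s": 0.6,
        "simultaneous_artifact_prob": 0.05,
    },
    "ecg": {"hr_jitter_sd_bpm": 2.0, "noise_sd_mV": 0.02},
}

#: key -> (predicate, human-readable constraint)
_VALIDATORS: dict[str, tuple] = {
    "fs_hz": (lambda v: v > 0, "must be > 0"),
    "block_s": (lambda v: v > 0, "must be > 0"),
    "stride_s": (lambda v: v > 0, "must be > 0"),
    "relabel_max_run": (lambda v: v >= 0, "must be >= 0"),
    "fusion.energy_window_s": (lambda v: v > 0, "must be > 0"),
    "fusion.sharpening_exponent": (lambda v: v >= 0, "must be >= 0"),
    "fusion.epsilon": (lambda v: v > 0, "must be > 0"),
    "svm.cv_folds": (lambda v: v >= 2, "must be >= 2"),
    "spr.noise_sd_mV": (lambda v: v >= 0, "must be >= 0"),
    "spr.artifact_rate_per_min": (lambda v: v >= 0, "must be >= 0"),
    "spr.artifact_amp_mV": (lambda v: v >= 0, "must be >= 0"),
    "spr.artifact_dur_s": (lambda v: v >= 0, "must be >= 0"),
    "spr.simultaneous_artifact_prob": (lambda v: 0 <= v <= 1, "must be in [0, 1]"),
    "ecg.hr_jitter_sd_bpm": (lambda v: v >= 0, "must be >= 0"),
    "ecg.noise_sd_mV": (lambda v: v >= 0, "must be >= 0"),
}


def _merge(base: dict, override: dict, prefix: str = "") -> dict:
    out = dict(base)
    for key, value in override.items():
        dotted = f"{prefix}{key}"
        if isinstance(value, dict) and isinstance(base.get(key), dict):
            out[key] = _merge(base[key], value, prefix=f"{dotted}.")
        else:
            out[key] = value
    return out


def _validate(cfg: dict, prefix: str = "") -> None:
    for key, value in cfg.items():
        dotted = f"{prefix}{key}"
        if isinstance(value, dict):
            _validate(value, prefix=f"{dotted}.")
        elif dotted in _VALIDATORS:
            pred, msg = _VALIDATORS[dotted]
            if not pred(value):
                raise ValueError(f"invalid value for '{dotted}': {value} ({msg})")


def load_config(path: str | Path | None = None) -> dict:
    """Load a YAML config, apply defaults for absent keys, validate values.

    ``None`` or an empty file yields the full default set.  Invalid values
    raise with the offending dotted key named.
    """
    override: dict = {}
    if path is not None:
        with Path(path).open() as fh:
            override = yaml.safe_load(fh) or {}
        if not isinstance(override, dict):
            raise ValueError("config root must be a mapping")
    cfg = _merge(DEFAULT_CONFIG, override)
    _validate(cfg)
    return cfg
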