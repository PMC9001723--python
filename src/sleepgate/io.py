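"""Readers and writers for recordings, hypnograms, schedules and power tables.

Recordings interchange as classic EDF (16-bit, the field standard for
polysomnography); triggers travel in a CSV sidecar (columns time_s,
sound_id).  The EDF writer here encodes the minimal continuous-recording
subset of the format; reading goes through MNE, which also serves as an
independent check of the writer in the test suite.
"""

from __future__ import annotations

import hashlib
import json
import struct
from datetime import datetime
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .synth import EEGRecording, Hypnogram

VALID_STATES = {"WAKE", "NREM", "REM", "UNKNOWN"}


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def _pad(text: str, n: int) -> bytes:
    b = text.encode("ascii", "replace")[:n]
    return b + b" " * (n - len(b))


def write_edf(path: str | Path, rec: EEGRecording) -> Path:
    """Write channels as classic EDF with physical units µV.

    One data record per second; each channel's physical range is its actual
    min/max (quantization error <= range/2^16).  The sampling rate must be an
    integer.  Triggers, if any, go to a ``<stem>.triggers.csv`` sidecar.
    """
    path = Path(path)
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF export requires an integer sampling rate")
    fs = int(round(fs))
    names = list(rec.channels)
    n_sig = len(names)
    # truncate to whole seconds (EDF records are fixed-duration)
    n_rec = rec.n_samples // fs
    if n_rec == 0:
        raise ValueError("recording shorter than one EDF record (1 s)")
    data = {k: np.asarray(v[: n_rec * fs], float) for k, v in rec.channels.items()}
    phys = {}
    digital_min, digital_max = -32768, 32767
    for k, v in data.items():
        lo, hi = float(np.min(v)), float(np.max(v))
        if hi - lo < 1e-9:
            lo, hi = lo - 1.0, hi + 1.0
        phys[k] = (lo, hi)

    header = b""
    header += _pad("0", 8)
    header += _pad("X X X X", 80)  # local patient id
    header += _pad("Startdate X X X X", 80)
    now = datetime(2000, 1, 1)
    header += _pad(now.strftime("%d.%m.%y"), 8)
    header += _pad(now.strftime("%H.%M.%S"), 8)
    header += _pad(str(256 * (1 + n_sig)), 8)
    header += _pad("", 44)
    header += _pad(str(n_rec), 8)
    header += _pad("1", 8)  # record duration, s
    header += _pad(str(n_sig), 4)

    def field(fmt, width):
        return b"".join(_pad(fmt(k), width) for k in names)

    header += field(lambda k: k[:16], 16)
    header += field(lambda k: "", 80)  # transducer
    header += field(lambda k: "uV", 8)
    header += field(lambda k: f"{phys[k][0]:.8g}"[:8], 8)
    header += field(lambda k: f"{phys[k][1]:.8g}"[:8], 8)
    header += field(lambda k: str(digital_min), 8)
    header += field(lambda k: str(digital_max), 8)
    header += field(lambda k: "", 80)  # prefiltering
    header += field(lambda k: str(fs), 8)
    header += field(lambda k: "", 32)

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_rec):
            for k in names:
                seg = data[k][r * fs : (r + 1) * fs]
                lo, hi = phys[k]
                scaled = (seg - lo) / (hi - lo) * (digital_max - digital_min) + digital_min
                ints = np.clip(np.round(scaled), digital_min, digital_max).astype("<i2")
                fh.write(ints.tobytes())
    if rec.triggers:
        write_triggers_csv(path.with_suffix(".triggers.csv"), rec.triggers)
    return path


def read_edf(path: str | Path) -> EEGRecording:
    """Read an EDF recording via MNE; channels returned in µV.

    A ``<stem>.triggers.csv`` sidecar, if present, populates the triggers.
    """
    import mne

    path = Path(path)
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    channels = {
        name: raw.get_data(picks=[name])[0] * 1e6 for name in raw.ch_names
    }
    triggers = []
    sidecar = path.with_suffix(".triggers.csv")
    if sidecar.exists():
        triggers = read_triggers_csv(sidecar)
    return EEGRecording(channels=channels, fs=float(raw.info["sfreq"]), triggers=triggers)


def write_triggers_csv(path: str | Path, triggers: list) -> Path:
    path = Path(path)
    pd.DataFrame(triggers, columns=["time_s", "sound_id"]).to_csv(path, index=False)
    return path


def read_triggers_csv(path: str | Path) -> list:
    df = pd.read_csv(path)
    return [(float(t), str(s)) for t, s in zip(df["time_s"], df["sound_id"])]


# ---------------------------------------------------------------------------
# Hypnogram / schedule / power tables
# ---------------------------------------------------------------------------

def write_hypnogram_csv(path: str | Path, hyp: Hypnogram) -> Path:
    path = Path(path)
    hyp.epochs[["start_s", "end_s", "state"]].to_csv(path, index=False)
    return path


def read_hypnogram_csv(path: str | Path) -> Hypnogram:
    """Read and validate a hypnogram CSV (start_s, end_s, state).

    Overlapping epochs or unknown state labels are rejected.
    """
    df = pd.read_csv(path)
    missing = {"start_s", "end_s", "state"} - set(df.columns)
    if missing:
        raise ValueError(f"hypnogram CSV missing columns: {missing}")
    bad = set(df["state"]) - VALID_STATES
    if bad:
        raise ValueError(f"unknown state labels: {bad}")
    return Hypnogram(df[["start_s", "end_s", "state"]])


def write_schedule_csv(path: str | Path, schedule) -> Path:
    path = Path(path)
    schedule.to_frame().to_csv(path, index=False)
    return path


def write_long_power_csv(path: str | Path, table: pd.DataFrame) -> Path:
    path = Path(path)
    table.to_csv(path, index=False)
    return path


def read_long_power_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"normalized_power", "block", "time", "sound_type", "phase",
                "animal_id", "session_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"power table missing columns: {missing}")
    return df


# ---------------------------------------------------------------------------
# Config and run log
# ---------------------------------------------------------------------------

DEFAULT_CONFIG = {
    "fs": 1000.0,
    "scoring": {"ratio_cut": 1.0, "emg_cut": 400.0, "window_s": 4.0},
    "bands": {"delta": [0.0, 4.0], "theta": [6.0, 10.0]},
    "ramp": {"min_db": 24.6, "max_db": 73.5, "n_blocks": 8, "pulses_per_block": 3},
    "cohort": "learner",
}


def load_config(path: str | Path | None = None) -> dict:
    """Defaults merged (shallow per section) with an optional YAML file."""
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for key, val in user.items():
            if isinstance(val, dict) and isinstance(cfg.get(key), dict):
                cfg[key].update(val)
            else:
                cfg[key] = val
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]


def write_run_log(path: str | Path, seed: int | None, cfg: dict, **extra) -> Path:
    """Machine-readable provenance record for a CLI run."""
    from . import __version__

    path = Path(path)
    payload = {
        "seed": seed,
        "config_hash": config_hash(cfg),
        "config": cfg,
        "versions": {
            "sleepgate": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        **extra,
    }
    path.write_text(json.dumps(payload, indent=2, default=str))
    return path
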