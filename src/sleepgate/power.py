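"""Sound-locked normalized band-power time courses.

For every sound presentation falling in a known sleep state, the
state-dependent band power (delta 0-4 Hz in NREM, theta 6-10 Hz in REM) is
computed in 24 consecutive non-overlapping 1-s windows: 8 s before sound
onset (block 1, baseline), 8 s during the rising-intensity presentation
(block 2) and 8 s after offset (block 3).  Each epoch is normalized by its
own baseline mean, then aggregated in two stages — over all presentations of
each animal first, then unweighted over animals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from .scoring import DELTA_BAND, THETA_BAND, ScoringThresholds, bandpower, score_state_at
from .synth import EEGRecording, PresentationEpoch

N_SECONDS = 24
BLOCK1 = slice(0, 8)   # pre (baseline)
BLOCK2 = slice(8, 16)  # during sound
BLOCK3 = slice(16, 24)  # post

#: seconds of the during-sound window regarded as the suppression plateau
#: (the gain has settled once the ramp has passed its low-intensity onset).
PLATEAU_SKIP_S = 3

STATE_BAND = {"NREM": DELTA_BAND, "REM": THETA_BAND}
STATE_BAND_NAME = {"NREM": "delta", "REM": "theta"}


@dataclass
class EpochPower:
    """24-element per-second band-power vector around one presentation."""

    values: np.ndarray
    normalized: np.ndarray
    band: str
    state: str
    sound_type: str = "unknown"
    animal_id: str = "m01"
    session_id: str = "s0001"
    day: int = 1
    excluded: bool = False
    meta: dict = field(default_factory=dict)

    def block_mean(self, block: slice) -> float:
        return float(np.mean(self.normalized[block]))

    def plateau_mean(self, skip_s: int = PLATEAU_SKIP_S) -> float:
        """Mean normalized power over the settled tail of the sound window."""
        return float(np.mean(self.normalized[BLOCK2][skip_s:]))


def normalize_to_baseline(values: np.ndarray, rel_tol: float = 1e-9) -> np.ndarray:
    """Divide a 24-element power vector by the mean of its first 8 values."""
    values = np.asarray(values, dtype=float)
    baseline = float(np.mean(values[BLOCK1]))
    if baseline <= rel_tol * max(float(np.max(values)), 1.0):
        raise ZeroDivisionError("zero or near-zero baseline power")
    return values / baseline


def extract_epoch_power(
    rec: EEGRecording,
    onset_s: float,
    state: str,
    window_s: float = 1.0,
    **meta,
) -> EpochPower:
    """24 onset-locked 1-s band powers with baseline normalization.

    The band follows the state (delta for NREM, theta for REM); windows are
    aligned to the sound onset, not to absolute time.  Epochs with
    unusable (zero) baselines are flagged ``excluded`` rather than clamped.
    """
    if state not in STATE_BAND:
        raise ValueError(f"state must be NREM or REM, got {state!r}")
    fs = rec.fs
    i0 = int(round((onset_s - 8.0) * fs))
    i1 = int(round((onset_s + 16.0) * fs))
    if i0 < 0 or i1 > rec.n_samples:
        raise ValueError("epoch window [-8 s, +16 s] extends past the recording")
    band = STATE_BAND[state]
    eeg = rec.channels["eeg_parietal"]
    n_win = int(round(window_s * fs))
    values = np.array(
        [
            bandpower(eeg[i0 + k * n_win : i0 + (k + 1) * n_win], fs, *band)
            for k in range(N_SECONDS)
        ]
    )
    try:
        normalized = normalize_to_baseline(values)
        excluded = False
    except ZeroDivisionError:
        warnings.warn("epoch excluded: zero baseline power", stacklevel=2)
        normalized = np.full(N_SECONDS, np.nan)
        excluded = True
    fields = {"sound_type", "animal_id", "session_id", "day"}
    known = {k: v for k, v in meta.items() if k in fields}
    extra = {k: v for k, v in meta.items() if k not in fields}
    return EpochPower(
        values=values,
        normalized=normalized,
        band=STATE_BAND_NAME[state],
        state=state,
        excluded=excluded,
        meta=extra,
        **known,
    )


def epochs_to_frame(epochs: list[EpochPower]) -> pd.DataFrame:
    """Wide table: one row per epoch, second-wise normalized power columns."""
    rows = []
    for ep in epochs:
        if ep.excluded:
            continue
        row = {
            "animal_id": ep.animal_id,
            "session_id": ep.session_id,
            "day": ep.day,
            "sound_type": ep.sound_type,
            "state": ep.state,
            "band": ep.band,
        }
        row.update({f"t{k + 1:02d}": ep.normalized[k] for k in range(N_SECONDS)})
        rows.append(row)
    return pd.DataFrame(rows)


_TCOLS = [f"t{k + 1:02d}" for k in range(N_SECONDS)]


def aggregate(
    epochs: list[EpochPower],
    by: tuple[str, ...] = ("sound_type", "state"),
) -> pd.DataFrame:
    """Two-stage mean time courses: sessions within animal, then animals.

    Every animal contributes with equal weight to the grand mean regardless
    of how many presentations it has.  Returns one row per group with the 24
    per-second means and the contributing animal count; empty groups are
    simply absent (with a warning if all epochs were excluded).
    """
    frame = epochs_to_frame(epochs)
    if frame.empty:
        warnings.warn("no usable epochs to aggregate", stacklevel=2)
        return pd.DataFrame(columns=[*by, "n_animals", *_TCOLS])
    per_animal = frame.groupby([*by, "animal_id"], as_index=False)[_TCOLS].mean()
    grand = per_animal.groupby(list(by), as_index=False)[_TCOLS].mean()
    grand.insert(
        len(by),
        "n_animals",
        per_animal.groupby(list(by)).size().values,
    )
    return grand


def aggregate_daily(epochs: list[EpochPower]) -> pd.DataFrame:
    """Per-day two-stage mean time courses (day-wise effect tracking)."""
    return aggregate(epochs, by=("sound_type", "state", "day"))


def to_long_table(epochs: list[EpochPower]) -> pd.DataFrame:
    """Long-format table for the block-wise mixed models.

    One row per (epoch, second): normalized_power, block in {1,2,3}, time
    1-8 within block, sound_type, phase (sleep state), day, animal_id,
    session_id.
    """
    rows = []
    for ep in epochs:
        if ep.excluded:
            continue
        for k in range(N_SECONDS):
            rows.append(
                {
                    "normalized_power": ep.normalized[k],
                    "block": k // 8 + 1,
                    "time": k % 8 + 1,
                    "sound_type": ep.sound_type,
                    "phase": ep.state,
                    "day": ep.day,
                    "animal_id": ep.animal_id,
                    "session_id": ep.session_id,
                }
            )
    return pd.DataFrame(rows)


def downsample(rec: EEGRecording, target_fs: float = 1000.0) -> EEGRecording:
    """Anti-aliased decimation to the analysis rate.

    A zero-phase low-pass at 0.4 x target_fs precedes decimation; the
    original rate must be an integer multiple of the target.  Trigger times
    are in seconds and carry over unchanged.
    """
    if target_fs > rec.fs:
        raise ValueError("target_fs exceeds the recording rate")
    if rec.fs == target_fs:
        return rec
    q = rec.fs / target_fs
    if abs(q - round(q)) > 1e-9:
        raise ValueError("fs must be an integer multiple of target_fs")
    q = int(round(q))
    sos = sp_signal.butter(8, 0.4 * target_fs / (rec.fs / 2), btype="low", output="sos")
    channels = {
        name: sp_signal.sosfiltfilt(sos, x)[::q] for name, x in rec.channels.items()
    }
    return EEGRecording(channels=channels, fs=target_fs, triggers=list(rec.triggers))


def run_pipeline(
    epochs: list[PresentationEpoch],
    thresholds: ScoringThresholds | None = None,
    use_scored_state: bool = True,
) -> list[EpochPower]:
    """Score state at onset, then extract normalized epoch powers.

    The full per-presentation path: classify the sleep state from the
    undisturbed pre-onset baseline (or trust the simulation's label when
    ``use_scored_state`` is False), then compute the 24-s normalized
    band-power vector.  Presentations scored WAKE/UNKNOWN are dropped.
    """
    out = []
    for ep in epochs:
        state = (
            score_state_at(ep.recording, ep.onset_s, thresholds)
            if use_scored_state
            else ep.state
        )
        if state not in STATE_BAND:
            continue
        out.append(
            extract_epoch_power(
                ep.recording,
                ep.onset_s,
                state,
                sound_type=ep.sound_type,
                animal_id=ep.animal_id,
                session_id=ep.session_id,
                day=ep.day,
            )
        )
    return out
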