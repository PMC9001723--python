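"""Auditory stimulus synthesis: pure tones, logarithmic FM chirps, tone clouds,
and the fixed rising-intensity presentation scheme.

All waveforms are generated at 200 kHz (ultrasonic speaker rates) with peak
amplitude 1 before intensity calibration.  The presentation scheme plays a
sound as short pulses, three per one-second intensity block, over eight blocks
of strictly increasing level (24.6 to 73.5 dB SPL), preceded by one block of
three zero-amplitude pulses that controls for speaker switching artefacts.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_FS = 200_000.0

#: dB SPL endpoints of the eight-step intensity ramp.
RAMP_MIN_DB = 24.6
RAMP_MAX_DB = 73.5
N_BLOCKS = 8
PULSES_PER_BLOCK = 3

#: within-block pulse timing (seconds); three 0.25-s pulses with 83-ms gaps,
#: left-aligned in each 1-s block.
BLOCK_S = 1.0
PULSE_S = 0.25
PULSE_GAP_S = 0.083

RAMP_S = 0.005  # raised-cosine on/off ramp applied to every pulse / tone segment


@dataclass
class SoundWaveform:
    """A synthesized sound: samples in [-1, 1] at sampling rate ``fs``."""

    samples: np.ndarray
    fs: float
    kind: str
    freq_meta: dict = field(default_factory=dict)

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.size == 0:
            raise ValueError("waveform must have positive duration")
        peak = np.max(np.abs(self.samples))
        if peak > 1.0 + 1e-12:
            raise ValueError(f"samples exceed full scale (peak {peak:.3g})")


@dataclass
class CloudSpec:
    """Frequency window and subrange layout of a tone cloud.

    The window [f_low_hz, f_high_hz] is partitioned into ``n_subranges``
    contiguous bands; ``tones_per_subrange`` tones are drawn from each.
    """

    f_low_hz: float
    f_high_hz: float
    n_subranges: int = 3
    tones_per_subrange: int = 2
    duration_s: float = PULSE_S

    def __post_init__(self) -> None:
        if not self.f_low_hz < self.f_high_hz:
            raise ValueError("f_low_hz must be < f_high_hz")
        if self.n_subranges < 1 or self.tones_per_subrange < 1:
            raise ValueError("subrange layout must be positive")

    @property
    def subrange_edges(self) -> np.ndarray:
        return np.linspace(self.f_low_hz, self.f_high_hz, self.n_subranges + 1)


#: cloud frequency windows (Hz) used in the generalization experiment,
#: ranked by distance from the conditioned window.
CLOUD_WINDOWS = {
    "pre_control": (3000.0, 4662.0),
    "post_control_1": (4811.0, 7478.0),
    "post_control_2": (7718.0, 11995.0),
    "post_control_3": (12379.0, 19240.0),
    "conditioned": (12379.0, 19240.0),
}


@dataclass
class StimulusSchedule:
    """Ordered pulse list realizing one rising-intensity presentation.

    Onsets are in seconds relative to the start of the eight nonzero
    intensity blocks (t = 0); the zero-amplitude control block sits at
    negative times.
    """

    pulses: pd.DataFrame  # columns: onset_s, duration_s, intensity_dbspl, is_zero
    sound_id: str
    total_ramp_duration_s: float = 8.0

    def validate(self) -> None:
        p = self.pulses
        if not p["onset_s"].is_monotonic_increasing or p["onset_s"].duplicated().any():
            raise ValueError("pulse onsets must be strictly increasing")
        nz = p[~p["is_zero"]]
        levels = np.sort(nz["intensity_dbspl"].unique())
        if len(levels) != N_BLOCKS:
            raise ValueError(f"expected {N_BLOCKS} distinct nonzero intensity levels")
        if len(nz) != N_BLOCKS * PULSES_PER_BLOCK:
            raise ValueError("expected 24 nonzero pulses")
        if not nz["intensity_dbspl"].is_monotonic_increasing:
            raise ValueError("intensities must be nondecreasing across blocks")
        zeros = p[p["is_zero"]]
        if len(zeros) != PULSES_PER_BLOCK:
            raise ValueError("expected 3 zero-amplitude pulses")
        if zeros["onset_s"].max() >= nz["onset_s"].min():
            raise ValueError("zero-amplitude pulses must precede all nonzero pulses")

    @property
    def sound_onset_s(self) -> float:
        """Start of the nonzero-intensity ramp (t = 0 by construction)."""
        return float(self.pulses.loc[~self.pulses["is_zero"], "onset_s"].min())

    @property
    def sound_offset_s(self) -> float:
        last = self.pulses[~self.pulses["is_zero"]].iloc[-1]
        return float(last["onset_s"] + last["duration_s"])

    def shifted(self, t0: float) -> "StimulusSchedule":
        """Schedule with all onsets moved by ``t0`` (absolute placement)."""
        p = self.pulses.copy()
        p["onset_s"] = p["onset_s"] + t0
        return StimulusSchedule(p, self.sound_id, self.total_ramp_duration_s)

    def to_frame(self) -> pd.DataFrame:
        out = self.pulses.copy()
        out["sound_id"] = self.sound_id
        return out


def _cosine_ramps(n: int, fs: float, ramp_s: float = RAMP_S) -> np.ndarray:
    """Raised-cosine on/off envelope of length n (avoids spectral splatter)."""
    nr = min(int(round(ramp_s * fs)), n // 2)
    env = np.ones(n)
    if nr > 0:
        r = 0.5 * (1 - np.cos(np.pi * np.arange(nr) / nr))
        env[:nr] = r
        env[-nr:] = r[::-1]
    return env


def make_pure_tone(
    freq_hz: float, duration_s: float, fs: float = DEFAULT_FS
) -> SoundWaveform:
    """Pure tone at ``freq_hz`` with raised-cosine onset/offset ramps, peak 1."""
    if not 0 < freq_hz < fs / 2:
        raise ValueError(
            f"tone frequency {freq_hz} Hz outside (0, Nyquist={fs / 2:g}) Hz"
        )
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    x = np.sin(2 * np.pi * freq_hz * t) * _cosine_ramps(n, fs)
    return SoundWaveform(x, fs, "pure_tone", {"freq_hz": float(freq_hz)})


def make_chirp(
    start_hz: float,
    octave_span: float = 2.0,
    rate_oct_per_s: float = 50.0,
    direction: str = "up",
    fs: float = DEFAULT_FS,
) -> SoundWaveform:
    """Logarithmic FM sweep: f(t) = start_hz * 2**(±rate*t).

    The sweep covers ``octave_span`` octaves at ``rate_oct_per_s``, so its
    duration is span/rate.  ``direction='down'`` descends from ``start_hz``
    (the mirror image used as the neutral novel sound).
    """
    if octave_span <= 0 or rate_oct_per_s <= 0:
        raise ValueError("octave_span and rate must be positive")
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    sgn = 1.0 if direction == "up" else -1.0
    end_hz = start_hz * 2.0 ** (sgn * octave_span)
    f_hi, f_lo = max(start_hz, end_hz), min(start_hz, end_hz)
    if f_hi >= fs / 2:
        raise ValueError(f"sweep reaches {f_hi:g} Hz, above Nyquist {fs / 2:g} Hz")
    if f_lo < 20.0:
        raise ValueError(f"sweep reaches {f_lo:g} Hz, below 20 Hz")
    duration_s = octave_span / rate_oct_per_s
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    # phase = 2*pi * integral of start * 2**(sgn*rate*t)
    k = sgn * rate_oct_per_s * np.log(2.0)
    phase = 2 * np.pi * start_hz * (np.exp(k * t) - 1.0) / k
    x = np.sin(phase) * _cosine_ramps(n, fs)
    kind = "chirp_up" if direction == "up" else "chirp_down"
    meta = {
        "start_hz": float(start_hz),
        "octave_span": float(octave_span),
        "rate_oct_per_s": float(rate_oct_per_s),
        "direction": direction,
        "end_hz": float(end_hz),
    }
    return SoundWaveform(x, fs, kind, meta)


def _cloud_subrange_order(rng: np.random.Generator, n: int, max_tries: int = 1000):
    """Two permutations of the n subranges with no repeat across the boundary.

    Each half of the tone sequence visits every subrange once; rejection
    sampling enforces that consecutive tones (including across the half
    boundary) never share a subrange.
    """
    for _ in range(max_tries):
        first = rng.permutation(n)
        second = rng.permutation(n)
        if second[0] != first[-1]:
            return np.concatenate([first, second])
    raise RuntimeError("could not satisfy cloud ordering constraint")


def plan_cloud_tones(
    spec: CloudSpec, rng: np.random.Generator | int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Tone frequencies and subrange indices for one cloud realization.

    Two tones fall in each subrange; the sequence splits into two halves,
    each visiting every subrange once, with no consecutive tones (including
    across the half boundary) sharing a subrange.
    """
    rng = np.random.default_rng(rng)
    order = _cloud_subrange_order(rng, spec.n_subranges)
    edges = spec.subrange_edges
    freqs = np.array([rng.uniform(edges[i], edges[i + 1]) for i in order])
    return freqs, order


def make_sound_cloud(
    spec: CloudSpec, rng: np.random.Generator | int | None = None, fs: float = DEFAULT_FS
) -> SoundWaveform:
    """Concatenation of six pure tones drawn pseudo-randomly from the cloud window.

    The tone sequence follows ``plan_cloud_tones``; each segment carries its
    own raised-cosine on/off ramps.
    """
    freqs, order = plan_cloud_tones(spec, rng)
    if np.any(freqs >= fs / 2):
        raise ValueError("cloud tone above Nyquist")
    n_tones = spec.n_subranges * spec.tones_per_subrange
    tone_s = spec.duration_s / n_tones
    n = int(round(tone_s * fs))
    segs = []
    for f in freqs:
        t = np.arange(n) / fs
        segs.append(np.sin(2 * np.pi * f * t) * _cosine_ramps(n, fs))
    meta = {
        "tone_freqs_hz": freqs.tolist(),
        "subranges": order.tolist(),
        "f_low_hz": spec.f_low_hz,
        "f_high_hz": spec.f_high_hz,
    }
    return SoundWaveform(np.concatenate(segs), fs, "cloud", meta)


def db_to_amplitude(db_spl: float, calibration_const: float) -> float:
    """Linear gain for a level in dB SPL: gain = c * 10**(db/20)."""
    if calibration_const <= 0:
        raise ValueError("calibration_const must be positive")
    return calibration_const * 10.0 ** (np.asarray(db_spl, dtype=float) / 20.0)


def calibration_for(db_ref: float = RAMP_MAX_DB, amplitude: float = 1.0) -> float:
    """Calibration constant mapping ``db_ref`` dB SPL to the given peak amplitude."""
    return amplitude / 10.0 ** (db_ref / 20.0)


def make_ramp_schedule(
    sound_id: str = "sound",
    min_db: float = RAMP_MIN_DB,
    max_db: float = RAMP_MAX_DB,
    n_blocks: int = N_BLOCKS,
    pulses_per_block: int = PULSES_PER_BLOCK,
    pulse_s: float = PULSE_S,
    block_s: float = BLOCK_S,
    gap_s: float = PULSE_GAP_S,
) -> StimulusSchedule:
    """Pulse schedule of the rising-intensity scheme (no audio rendering).

    Intensity levels are equally spaced in dB between ``min_db`` and
    ``max_db``; the zero-amplitude control block occupies [-1, 0) s.
    """
    if pulses_per_block * pulse_s + (pulses_per_block - 1) * gap_s > block_s + 1e-9:
        raise ValueError("pulses do not fit in the block")
    levels = np.linspace(min_db, max_db, n_blocks)
    rows = []
    # leading zero-amplitude block
    for i in range(pulses_per_block):
        rows.append((-block_s + i * (pulse_s + gap_s), pulse_s, 0.0, True))
    for b, db in enumerate(levels):
        for i in range(pulses_per_block):
            rows.append((b * block_s + i * (pulse_s + gap_s), pulse_s, float(db), False))
    pulses = pd.DataFrame(
        rows, columns=["onset_s", "duration_s", "intensity_dbspl", "is_zero"]
    )
    sched = StimulusSchedule(pulses, sound_id, total_ramp_duration_s=n_blocks * block_s)
    sched.validate()
    return sched


def build_intensity_ramp(
    wave: SoundWaveform,
    min_db: float = RAMP_MIN_DB,
    max_db: float = RAMP_MAX_DB,
    n_blocks: int = N_BLOCKS,
    pulses_per_block: int = PULSES_PER_BLOCK,
    calibration_const: float | None = None,
) -> tuple[StimulusSchedule, np.ndarray]:
    """Render one full presentation of ``wave`` under the rising-intensity scheme.

    Returns the schedule and the rendered sample array covering
    [-1 s, +8 s] around the nonzero-ramp onset.  Each pulse is the input
    waveform scaled by ``db_to_amplitude``; by default the loudest level maps
    to peak amplitude 1.
    """
    if wave.duration > PULSE_S + 1e-9:
        raise ValueError(
            f"waveform of {wave.duration:.3f} s does not fit the {PULSE_S} s pulse slot"
        )
    if calibration_const is None:
        calibration_const = calibration_for(max_db)
    sched = make_ramp_schedule(
        sound_id=wave.kind, min_db=min_db, max_db=max_db,
        n_blocks=n_blocks, pulses_per_block=pulses_per_block,
        pulse_s=wave.duration,
    )
    fs = wave.fs
    t_start = -BLOCK_S
    n_total = int(round((n_blocks * BLOCK_S + BLOCK_S) * fs))
    out = np.zeros(n_total)
    for _, row in sched.pulses.iterrows():
        if row["is_zero"]:
            continue
        gain = db_to_amplitude(row["intensity_dbspl"], calibration_const)
        i0 = int(round((row["onset_s"] - t_start) * fs))
        out[i0 : i0 + len(wave.samples)] += gain * wave.samples
    return sched, out


def waveform_digest(wave: SoundWaveform) -> str:
    """SHA-256 of the sample bytes — bit-exact reproducibility fingerprint."""
    return hashlib.sha256(np.ascontiguousarray(wave.samples).tobytes()).hexdigest()
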