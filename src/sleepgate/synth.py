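"""Synthetic sleep electrophysiology with sound-evoked power suppression.

The generator produces parietal EEG + nuchal EMG sessions with known
vigilance-state structure.  Each state contributes a narrowband oscillation
(band-limited Gaussian noise) modulated by a slow log-normal envelope whose
coefficient of variation sets the amplitude "irregularity", plus broadband
1/f background noise.  NREM is delta-dominant (high amplitude, irregular),
REM theta-dominant (low amplitude, regular), mirroring the spectral and
peak-to-peak signatures that separate the two states in feature space.

Sound presentations suppress the state oscillation multiplicatively: from the
first pulse exceeding an intensity threshold, the oscillation amplitude
relaxes toward sqrt(g) (so that band *power* scales by the gain g), and after
sound offset recovers to baseline over a few seconds.  Learner-calibrated
defaults reproduce the conditioned-sound drops to ~35% of baseline delta
power in NREM and ~60% of theta power in REM, without any state transition
(no awakening).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from .stimuli import StimulusSchedule, make_ramp_schedule

STATES = ("WAKE", "NREM", "REM")
SOUND_TYPES = ("pre_control", "conditioned", "post_control")


@dataclass
class OscillationParams:
    """Per-state signal parameters (amplitudes in µV RMS).

    ``carrier_sine_frac`` is the fraction of oscillation power carried by a
    deterministic sinusoid at band center; the remainder is band-limited
    Gaussian noise.  A high fraction gives the regular, nearly sinusoidal
    rhythm of REM theta; a lower one the irregular waveform of NREM delta.
    """

    band_hz: tuple[float, float]
    osc_amplitude_uv: float
    amplitude_irregularity: float  # CV of the slow amplitude envelope
    broadband_noise_uv: float
    emg_tone_uv: float
    carrier_sine_frac: float = 0.6


@dataclass
class StateParams:
    """Signal model parameters for all vigilance states."""

    states: dict = field(default_factory=lambda: dict(DEFAULT_STATE_PARAMS))

    def __getitem__(self, state: str) -> OscillationParams:
        return self.states[state]

    def validate(self) -> None:
        nrem, rem, wake = self["NREM"], self["REM"], self["WAKE"]
        if not (0.0 <= nrem.band_hz[0] and nrem.band_hz[1] <= 4.0):
            raise ValueError("NREM band must lie within 0-4 Hz")
        if not (6.0 <= rem.band_hz[0] and rem.band_hz[1] <= 10.0):
            raise ValueError("REM band must lie within 6-10 Hz")
        if not nrem.amplitude_irregularity > rem.amplitude_irregularity:
            raise ValueError("NREM envelope must be more irregular than REM")
        if not (wake.emg_tone_uv > nrem.emg_tone_uv and wake.emg_tone_uv > rem.emg_tone_uv):
            raise ValueError("WAKE muscle tone must exceed sleep tone")


DEFAULT_STATE_PARAMS = {
    "NREM": OscillationParams((0.5, 4.0), 200.0, 0.30, 15.0, 8.0, 0.8),
    "REM": OscillationParams((6.0, 10.0), 55.0, 0.15, 15.0, 4.0, 0.9),
    "WAKE": OscillationParams((5.0, 15.0), 30.0, 0.25, 20.0, 40.0, 0.3),
}


@dataclass
class SuppressionProfile:
    """Sound-evoked multiplicative gain on the state-band oscillation power.

    ``asymptotic_gain`` g in (0, 1] is the plateau band-power fraction of
    baseline; the oscillation amplitude is scaled by sqrt(gain) so power
    scales by g.  Suppression engages at the first pulse at or above
    ``onset_intensity_threshold_dbspl`` with exponential time constant
    ``onset_latency_s``, and decays back to baseline linearly over
    ``recovery_duration_s`` after sound offset.
    """

    asymptotic_gain: float = 1.0
    onset_latency_s: float = 0.4
    onset_intensity_threshold_dbspl: float = 30.0
    recovery_duration_s: float = 6.0
    emg_twitch_uv: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.asymptotic_gain <= 1.0:
            raise ValueError("asymptotic_gain must be in (0, 1]")
        if self.recovery_duration_s <= 0:
            raise ValueError("recovery_duration_s must be positive")


def default_profiles(cohort: str = "learner") -> dict[tuple[str, str], SuppressionProfile]:
    """Suppression profiles per (sound_type, state), calibrated per cohort.

    Learners: conditioned sound drops NREM delta power to 0.35 and REM theta
    power to 0.60 of baseline from low intensities (30 dB SPL); the neutral
    novel (post-control) sound generalizes in NREM only, with a later onset;
    the pre-exposure control barely moves power except at the loudest levels.
    Non-learners: no clear effect for any sound.
    """
    if cohort == "learner":
        return {
            ("conditioned", "NREM"): SuppressionProfile(0.35, 0.4, 30.0, 6.0, 20.0),
            ("conditioned", "REM"): SuppressionProfile(0.60, 0.4, 30.0, 6.0, 10.0),
            ("post_control", "NREM"): SuppressionProfile(0.45, 0.6, 45.0, 5.0, 10.0),
            ("post_control", "REM"): SuppressionProfile(1.0, 0.6, 45.0, 5.0),
            ("pre_control", "NREM"): SuppressionProfile(0.85, 0.6, 65.0, 4.0),
            ("pre_control", "REM"): SuppressionProfile(0.95, 0.6, 65.0, 4.0),
        }
    if cohort == "nonlearner":
        return {
            (snd, st): SuppressionProfile(0.95, 0.8, 65.0, 4.0)
            for snd in SOUND_TYPES
            for st in ("NREM", "REM")
        }
    raise ValueError(f"unknown cohort {cohort!r}")


@dataclass
class Hypnogram:
    """Contiguous, non-overlapping vigilance-state epochs."""

    epochs: pd.DataFrame  # columns: start_s, end_s, state

    def __post_init__(self) -> None:
        e = self.epochs.reset_index(drop=True)
        if len(e) == 0:
            raise ValueError("hypnogram must contain at least one epoch")
        if not set(e["state"]).issubset({"WAKE", "NREM", "REM", "UNKNOWN"}):
            bad = set(e["state"]) - {"WAKE", "NREM", "REM", "UNKNOWN"}
            raise ValueError(f"unknown state labels: {bad}")
        if (e["end_s"] <= e["start_s"]).any():
            raise ValueError("epoch end must exceed start")
        if (e["start_s"].values[1:] < e["end_s"].values[:-1] - 1e-9).any():
            raise ValueError("epochs overlap")
        self.epochs = e

    @classmethod
    def from_bouts(cls, bouts: list[tuple[float, str]]) -> "Hypnogram":
        """Build from (duration_s, state) bouts starting at t = 0."""
        rows, t = [], 0.0
        for dur, state in bouts:
            rows.append((t, t + dur, state))
            t += dur
        return cls(pd.DataFrame(rows, columns=["start_s", "end_s", "state"]))

    @property
    def duration_s(self) -> float:
        return float(self.epochs["end_s"].iloc[-1])

    def state_at(self, t: float) -> str:
        e = self.epochs
        hit = e[(e["start_s"] <= t) & (t < e["end_s"])]
        if len(hit) == 0:
            return "UNKNOWN"
        return str(hit.iloc[0]["state"])


@dataclass
class EEGRecording:
    """Multichannel recording (µV) with sample rate and sound triggers.

    ``components`` optionally carries the generative decomposition of the EEG
    (state oscillation vs broadband background), which lets sound responses
    act on the oscillation alone, as the signal model specifies.
    """

    channels: dict[str, np.ndarray]
    fs: float
    triggers: list = field(default_factory=list)  # (time_s, sound_id)
    components: dict | None = None

    def __post_init__(self) -> None:
        lens = {len(v) for v in self.channels.values()}
        if len(lens) != 1:
            raise ValueError("all channels must have equal length")

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


def _bandlimited_noise(n: int, fs: float, band: tuple[float, float],
                       rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS Gaussian noise band-passed to ``band``."""
    lo, hi = band
    nyq = fs / 2
    x = rng.standard_normal(n)
    if lo <= 0:
        sos = sp_signal.butter(4, hi / nyq, btype="low", output="sos")
    else:
        sos = sp_signal.butter(4, [lo / nyq, hi / nyq], btype="band", output="sos")
    y = sp_signal.sosfiltfilt(sos, x)
    rms = np.sqrt(np.mean(y**2))
    return y / max(rms, 1e-12)


def _mixed_carrier(n: int, fs: float, band: tuple[float, float],
                   sine_frac: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS oscillation carrier: sinusoid at band center + band noise."""
    t = np.arange(n) / fs
    fc = 0.5 * (band[0] + band[1])
    sine = np.sqrt(2.0) * np.sin(2 * np.pi * fc * t + rng.uniform(0, 2 * np.pi))
    noise = _bandlimited_noise(n, fs, band, rng)
    return np.sqrt(sine_frac) * sine + np.sqrt(1.0 - sine_frac) * noise


def _slow_lognormal_envelope(n: int, fs: float, cv: float,
                             rng: np.random.Generator,
                             knot_spacing_s: float = 10.0,
                             within_frac: float = 0.05) -> np.ndarray:
    """Mean-1 log-normal amplitude envelope with overall CV ``cv``.

    The log-envelope is a per-bout random level (the dominant component)
    plus a slowly varying within-bout modulation carrying ``within_frac`` of
    the log-amplitude SD, built by smoothstep interpolation of independent
    knots every ``knot_spacing_s`` (marginal variance renormalized to 1).
    Keeping most variance at the bout level mirrors the amplitude waxing and
    waning of real sleep, and means an epoch's baseline normalization
    removes the bulk of the slow amplitude fluctuation.
    """
    if cv <= 0:
        return np.ones(n)
    sigma = np.sqrt(np.log(1 + cv**2))
    sigma_within = sigma * within_frac
    sigma_level = sigma * np.sqrt(1 - within_frac**2)
    n_knots = int(np.ceil(n / (knot_spacing_s * fs))) + 1
    knots = rng.standard_normal(n_knots)
    pos = np.arange(n) / (knot_spacing_s * fs)
    idx = np.minimum(pos.astype(int), n_knots - 2)
    w = pos - idx
    w = 3 * w**2 - 2 * w**3  # smoothstep between knots
    z = (1 - w) * knots[idx] + w * knots[idx + 1]
    z /= np.sqrt((1 - w) ** 2 + w**2)
    level = rng.standard_normal()
    return np.exp(sigma_level * level + sigma_within * z - sigma**2 / 2)


def _pink_noise(n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS 1/f (power) background noise via spectral shaping."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1 / fs)
    shaping = np.ones_like(f)
    nzi = f > 0
    shaping[nzi] = 1.0 / np.sqrt(f[nzi])
    shaping[0] = 0.0
    y = np.fft.irfft(spec * shaping, n)
    return y / max(np.sqrt(np.mean(y**2)), 1e-12)


def simulate_session(
    bout_plan: Hypnogram,
    params: StateParams | None = None,
    fs: float = 1000.0,
    rng: np.random.Generator | int | None = None,
) -> tuple[EEGRecording, Hypnogram]:
    """Simulate an EEG/EMG session following the given state-bout plan.

    Returns the recording (with its generative components) and the
    ground-truth hypnogram.  Per-bout seeds are derived deterministically
    from the supplied generator, so identical seeds give identical samples.
    """
    params = params or StateParams()
    params.validate()
    rng = np.random.default_rng(rng)
    max_band = max(p.band_hz[1] for p in params.states.values())
    if fs < 2 * max_band:
        raise ValueError("fs must be at least twice the highest band edge")
    n_total = int(round(bout_plan.duration_s * fs))
    osc = np.zeros(n_total)
    background = np.zeros(n_total)
    emg = np.zeros(n_total)
    for _, bout in bout_plan.epochs.iterrows():
        i0 = int(round(bout["start_s"] * fs))
        i1 = int(round(bout["end_s"] * fs))
        n = i1 - i0
        if n <= 0:
            continue
        p = params[bout["state"]]
        carrier = _mixed_carrier(n, fs, p.band_hz, p.carrier_sine_frac, rng)
        env = _slow_lognormal_envelope(n, fs, p.amplitude_irregularity, rng)
        osc[i0:i1] = p.osc_amplitude_uv * carrier * env
        background[i0:i1] = p.broadband_noise_uv * _pink_noise(n, fs, rng)
        emg[i0:i1] = p.emg_tone_uv * rng.standard_normal(n)
    rec = EEGRecording(
        channels={"eeg_parietal": osc + background, "emg": emg},
        fs=fs,
        components={"oscillation": osc, "background": background},
    )
    return rec, bout_plan


def suppression_gain_curve(
    times_s: np.ndarray, schedule: StimulusSchedule, profile: SuppressionProfile
) -> np.ndarray:
    """Band-power gain g(t) implied by a schedule and suppression profile.

    1 before the first suprathreshold pulse; exponential approach to the
    asymptotic gain during the sound; linear recovery to 1 after offset.
    """
    g = np.ones_like(times_s, dtype=float)
    nz = schedule.pulses[~schedule.pulses["is_zero"]]
    supra = nz[nz["intensity_dbspl"] >= profile.onset_intensity_threshold_dbspl]
    if len(supra) == 0 or profile.asymptotic_gain >= 1.0:
        return g
    t_on = float(supra["onset_s"].min())
    t_off = schedule.sound_offset_s
    ga = profile.asymptotic_gain
    tau = max(profile.onset_latency_s, 1e-6)
    during = (times_s >= t_on) & (times_s <= t_off)
    g[during] = 1 + (ga - 1) * (1 - np.exp(-(times_s[during] - t_on) / tau))
    g_off = 1 + (ga - 1) * (1 - np.exp(-(t_off - t_on) / tau))
    after = times_s > t_off
    frac = np.clip((times_s[after] - t_off) / profile.recovery_duration_s, 0, 1)
    g[after] = g_off + (1 - g_off) * frac
    return g


def apply_sound_response(
    rec: EEGRecording,
    schedule: StimulusSchedule,
    profile: SuppressionProfile,
    state_at_onset: str,
    rng: np.random.Generator | int | None = None,
) -> EEGRecording:
    """Apply sound-evoked oscillation suppression to a simulated recording.

    The schedule must be placed in absolute recording time (see
    ``StimulusSchedule.shifted``).  The state oscillation amplitude is scaled
    by sqrt(g(t)); broadband background and the vigilance state itself are
    untouched (suppression without awakening).  An optional brief EMG twitch
    marks suppression onset.
    """
    if state_at_onset not in ("NREM", "REM"):
        raise ValueError("state_at_onset must be NREM or REM")
    if rec.components is None:
        raise ValueError("recording lacks generative components")
    if schedule.sound_offset_s > rec.duration_s or schedule.pulses["onset_s"].min() < 0:
        raise ValueError("schedule extends beyond the recording")
    t = np.arange(rec.n_samples) / rec.fs
    g = suppression_gain_curve(t, schedule, profile)
    osc = rec.components["oscillation"] * np.sqrt(g)
    background = rec.components["background"]
    emg = rec.channels["emg"].copy()
    if profile.emg_twitch_uv > 0 and g.min() < 1:
        rng = np.random.default_rng(rng)
        t_on = t[np.argmax(g < 1)]
        i0 = int(round(t_on * rec.fs))
        n_tw = int(round(0.05 * rec.fs))
        emg[i0 : i0 + n_tw] += profile.emg_twitch_uv * rng.standard_normal(
            min(n_tw, len(emg) - i0)
        )
    return EEGRecording(
        channels={"eeg_parietal": osc + background, "emg": emg},
        fs=rec.fs,
        triggers=list(rec.triggers) + [(schedule.sound_onset_s, schedule.sound_id)],
        components={"oscillation": osc, "background": background},
    )


@dataclass
class PresentationEpoch:
    """One simulated sound presentation with its metadata."""

    recording: EEGRecording
    onset_s: float
    state: str
    sound_type: str
    animal_id: str
    session_id: str
    day: int


def simulate_presentation_epochs(
    n_epochs: int,
    state: str,
    sound_type: str,
    cohort: str = "learner",
    seed: int | np.random.SeedSequence = 0,
    n_animals: int = 6,
    n_days: int = 4,
    params: StateParams | None = None,
    profiles: dict | None = None,
    fs: float = 1000.0,
    pad_s: float = 2.0,
) -> list[PresentationEpoch]:
    """Simulate independent sound-presentation epochs for one condition.

    Each epoch is a single-state bout long enough for the 8 s pre / 8 s
    during / 8 s post analysis window plus padding, with one rising-intensity
    presentation whose suppression follows the cohort's profile for
    (sound_type, state).  Epochs are distributed round-robin over
    ``n_animals`` pseudo-animals and cyclically over ``n_days`` days; each
    epoch is its own session (one presentation per session).
    """
    profiles = profiles or default_profiles(cohort)
    profile = profiles[(sound_type, state)]
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(int(seed))
    )
    children = ss.spawn(n_epochs)
    onset = 8.0 + pad_s + 1.0  # leave room for the zero-amplitude lead-in block
    total_s = onset + 16.0 + pad_s
    out = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        plan = Hypnogram.from_bouts([(total_s, state)])
        rec, _ = simulate_session(plan, params, fs=fs, rng=rng)
        sched = make_ramp_schedule(sound_id=sound_type).shifted(onset)
        rec = apply_sound_response(rec, sched, profile, state, rng=rng)
        out.append(
            PresentationEpoch(
                recording=rec,
                onset_s=onset,
                state=state,
                sound_type=sound_type,
                animal_id=f"m{i % n_animals + 1:02d}",
                session_id=f"s{i + 1:04d}",
                day=(i // n_animals) % n_days + 1,
            )
        )
    return out


def simulate_state_snippets(
    n_nrem: int = 246,
    n_rem: int = 228,
    n_animals: int = 11,
    snippet_s: float = 8.0,
    params: StateParams | None = None,
    fs: float = 1000.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Short undisturbed single-state snippets for scoring validation.

    Mirrors a manual-scoring validation set: 8-s NREM and REM sleep sections
    drawn from several animals.  Returns one row per snippet with the raw
    EEG/EMG arrays and the ground-truth state.
    """
    ss = np.random.SeedSequence(int(seed))
    children = ss.spawn(n_nrem + n_rem)
    rows = []
    labels = ["NREM"] * n_nrem + ["REM"] * n_rem
    for i, (state, child) in enumerate(zip(labels, children)):
        rng = np.random.default_rng(child)
        plan = Hypnogram.from_bouts([(snippet_s, state)])
        rec, _ = simulate_session(plan, params, fs=fs, rng=rng)
        rows.append(
            {
                "state": state,
                "animal_id": f"m{i % n_animals + 1:02d}",
                "eeg": rec.channels["eeg_parietal"],
                "emg": rec.channels["emg"],
                "fs": fs,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Synthetic behavior: terrace conditioning trials and Audiobox visits
# ---------------------------------------------------------------------------

def simulate_terrace_trials(
    n_animals: int = 9,
    n_learners: int = 6,
    n_days: int = 4,
    trials_per_day: int = 15,
    learner_day2_avoidance: float = 0.95,
    nonlearner_day2_avoidance: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Avoidance-conditioning trial table (one row per trial).

    Learners ramp from chance to high avoidance by day 2; non-learners stay
    near their day-2 level.  Columns: animal_id, day, trial_index, avoided.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for a in range(n_animals):
        learner = a < n_learners
        p2 = learner_day2_avoidance if learner else nonlearner_day2_avoidance
        for day in range(1, n_days + 1):
            p = min(p2, 0.4 + (p2 - 0.4) * (day - 1)) if day <= 2 else p2
            for k in range(trials_per_day):
                rows.append(
                    {
                        "animal_id": f"m{a + 1:02d}",
                        "day": day,
                        "trial_index": k + 1,
                        "avoided": bool(rng.random() < p),
                    }
                )
    return pd.DataFrame(rows)


#: nose-poke probability per sound for the discrimination simulation, graded
#: by frequency distance from the conditioned cloud (safe sound ≈ always
#: poked, conditioned ≈ always avoided).
AUDIOBOX_POKE_PROBS = {
    "safe": {"early": 0.70, "late": 0.70},
    "novel1": {"early": 0.65, "late": 0.72},
    "novel2": {"early": 0.25, "late": 0.45},
    "novel3": {"early": 0.15, "late": 0.18},
    "cond": {"early": 0.05, "late": 0.05},
}


def simulate_audiobox_visits(
    n_animals: int = 6,
    n_days: int = 6,
    visits_per_day: int = 40,
    poke_probs: dict | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Audiobox visit table (one row per corner visit).

    Safe visits dominate; conditioned and the three novel clouds each occupy
    20% of the non-safe share per the staged protocol.  Columns: animal_id,
    day, visit_time, sound, nosepoked.
    """
    poke_probs = poke_probs or AUDIOBOX_POKE_PROBS
    rng = np.random.default_rng(seed)
    sounds = list(poke_probs)
    probs = np.array([0.4, 0.15, 0.15, 0.15, 0.15])
    rows = []
    for a in range(n_animals):
        for day in range(1, n_days + 1):
            phase = "early" if day <= 2 else "late"
            for v in range(visits_per_day):
                snd = sounds[rng.choice(len(sounds), p=probs)]
                rows.append(
                    {
                        "animal_id": f"m{a + 1:02d}",
                        "day": day,
                        "visit_time": day * 86400.0 + v * 600.0,
                        "sound": snd,
                        "nosepoked": bool(rng.random() < poke_probs[snd][phase]),
                    }
                )
    return pd.DataFrame(rows)
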