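"""Sleep-state scoring from EEG/EMG spectral and amplitude features.

Vigilance states are separated in a two-dimensional feature space computed in
non-overlapping 4-s windows: the theta/delta band-power ratio
(6-10 Hz / 0-4 Hz) and the peak-to-peak variability (standard deviation of
absolute local-extremum amplitudes of the raw trace).  NREM sleep shows low
ratio and high peak-to-peak SD; REM the converse; wakefulness is flagged by
muscle tone on the EMG channel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from .synth import EEGRecording, Hypnogram

DELTA_BAND = (0.0, 4.0)
THETA_BAND = (6.0, 10.0)


def bandpower(
    x: np.ndarray, fs: float, f_lo: float, f_hi: float, window: str = "hann"
) -> float:
    """Band power (µV²) of a signal over the half-open band [f_lo, f_hi).

    One Hann-tapered periodogram per call (mean removed); the power is the
    PSD integrated over the band, so summing over a partition of
    [0, fs/2) approximately recovers the time-domain variance.
    """
    x = np.asarray(x, dtype=float)
    if not (0 <= f_lo < f_hi <= fs / 2):
        raise ValueError("need 0 <= f_lo < f_hi <= fs/2")
    if len(x) < fs:
        raise ValueError("signal shorter than 1 s")
    if f_lo > 0 and len(x) / fs < 1.0 / f_lo:
        warnings.warn("window shorter than one cycle of f_lo", stacklevel=2)
    freqs, psd = sp_signal.periodogram(x, fs=fs, window=window, detrend="constant")
    df = freqs[1] - freqs[0]
    mask = (freqs >= f_lo) & (freqs < f_hi)
    return float(np.sum(psd[mask]) * df)


def _peak_indices(x: np.ndarray) -> np.ndarray:
    """Indices of local extrema (both signs); plateaus count once at center."""
    d = np.diff(x)
    nz = np.flatnonzero(d)
    if len(nz) < 2:
        return np.array([], dtype=int)
    s = np.sign(d[nz])
    change = np.flatnonzero(s[:-1] != s[1:])
    left = nz[change] + 1
    right = nz[change + 1]
    return (left + right) // 2


def peak_to_peak_sd(x: np.ndarray) -> float:
    """Population SD of absolute local-extremum amplitudes (µV).

    High for irregular high-amplitude activity (NREM delta), low for regular
    oscillations (REM theta).  Fewer than two peaks returns 0 with a warning.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 samples")
    peaks = _peak_indices(x)
    if len(peaks) < 2:
        warnings.warn("fewer than two peaks found; returning 0", stacklevel=2)
        return 0.0
    return float(np.std(np.abs(x[peaks])))


def compute_features(rec: EEGRecording, window_s: float = 4.0) -> pd.DataFrame:
    """Per-window scoring features tiling the recording without overlap.

    Columns: window_start_s, theta_delta_ratio, p2p_sd, emg_power (µV²,
    variance of the EMG window; NaN if no EMG channel).
    """
    eeg = rec.channels["eeg_parietal"]
    emg = rec.channels.get("emg")
    n_win = int(window_s * rec.fs)
    n_windows = len(eeg) // n_win
    if n_windows == 0:
        raise ValueError("recording shorter than one scoring window")
    rows = []
    for w in range(n_windows):
        seg = eeg[w * n_win : (w + 1) * n_win]
        delta = bandpower(seg, rec.fs, *DELTA_BAND)
        theta = bandpower(seg, rec.fs, *THETA_BAND)
        ratio = theta / delta if delta > 0 else np.inf
        emg_power = (
            float(np.var(emg[w * n_win : (w + 1) * n_win])) if emg is not None else np.nan
        )
        rows.append(
            {
                "window_start_s": w * window_s,
                "theta_delta_ratio": ratio,
                "p2p_sd": peak_to_peak_sd(seg),
                "emg_power": emg_power,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class ScoringThresholds:
    """Decision cuts for the rule-based epoch classifier.

    ``emg_cut`` (µV²) flags wakefulness by muscle tone; among sleep windows,
    ``ratio_cut`` splits REM (above) from NREM (below).  An optional
    ``p2p_cut`` (µV) additionally requires high peak-to-peak SD for NREM.
    Defaults match the synthetic generator's µV scaling.
    """

    ratio_cut: float = 1.0
    emg_cut: float = 400.0
    p2p_cut: float | None = None


def _classify_window(row: pd.Series, thr: ScoringThresholds) -> str:
    if not np.isfinite(row["theta_delta_ratio"]) and np.isnan(row["theta_delta_ratio"]):
        return "UNKNOWN"
    if np.isfinite(row["emg_power"]) and row["emg_power"] > thr.emg_cut:
        return "WAKE"
    if row["theta_delta_ratio"] > thr.ratio_cut:
        return "REM"
    if thr.p2p_cut is not None and row["p2p_sd"] < thr.p2p_cut:
        return "UNKNOWN"
    return "NREM"


def _smooth_labels(labels: list[str]) -> list[str]:
    """Majority vote over a 3-window neighborhood (ties keep the center)."""
    out = list(labels)
    for i in range(1, len(labels) - 1):
        trio = labels[i - 1 : i + 2]
        for lab in set(trio):
            if trio.count(lab) >= 2:
                out[i] = lab
                break
    return out


def classify_epochs(
    features: pd.DataFrame,
    thresholds: ScoringThresholds | None = None,
    window_s: float = 4.0,
    smooth: bool = True,
) -> Hypnogram:
    """Rule-based vigilance-state classification of feature windows.

    WAKE if EMG power exceeds the muscle-tone cut; otherwise REM if the
    theta/delta ratio exceeds the ratio cut, else NREM.  Optional 3-window
    majority smoothing removes isolated misclassified windows.
    """
    thr = thresholds or ScoringThresholds()
    labels = [_classify_window(row, thr) for _, row in features.iterrows()]
    if smooth and len(labels) >= 3:
        labels = _smooth_labels(labels)
    rows = [
        (start, start + window_s, lab)
        for start, lab in zip(features["window_start_s"], labels)
    ]
    return Hypnogram(pd.DataFrame(rows, columns=["start_s", "end_s", "state"]))


def score_state_at(
    rec: EEGRecording,
    onset_s: float,
    thresholds: ScoringThresholds | None = None,
    baseline_s: float = 8.0,
    window_s: float = 4.0,
) -> str:
    """State at a sound onset, scored from the undisturbed pre-onset baseline.

    Features are computed on the ``baseline_s`` seconds preceding the onset
    and the majority label returned (ties favour the last window).
    """
    i0 = int(round((onset_s - baseline_s) * rec.fs))
    i1 = int(round(onset_s * rec.fs))
    if i0 < 0:
        raise ValueError("baseline extends before the recording")
    sub = EEGRecording(
        channels={k: v[i0:i1] for k, v in rec.channels.items()}, fs=rec.fs
    )
    feats = compute_features(sub, window_s=window_s)
    hyp = classify_epochs(feats, thresholds, window_s=window_s, smooth=False)
    states = list(hyp.epochs["state"])
    counts = {s: states.count(s) for s in set(states)}
    best = max(counts.values())
    for s in reversed(states):
        if counts[s] == best:
            return s
    return "UNKNOWN"


def hypnogram_accuracy(predicted: Hypnogram, truth: Hypnogram, step_s: float = 1.0) -> float:
    """Fraction of time (sampled every ``step_s``) with matching state labels."""
    t_end = min(predicted.duration_s, truth.duration_s)
    times = np.arange(step_s / 2, t_end, step_s)
    hits = sum(predicted.state_at(t) == truth.state_at(t) for t in times)
    return hits / len(times)


def cluster_overlap_1d(a: np.ndarray, b: np.ndarray) -> float:
    """Minimum achievable misclassification of two samples by one threshold.

    Scans all cut points on the pooled values (both polarities) and returns
    the best error rate — a scale-free measure of 1-D cluster overlap.
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    pooled = np.sort(np.unique(np.concatenate([a, b])))
    cuts = np.concatenate([[-np.inf], (pooled[:-1] + pooled[1:]) / 2, [np.inf]])
    n = len(a) + len(b)
    best = 1.0
    for c in cuts:
        err_lo = (np.sum(a >= c) + np.sum(b < c)) / n  # a below, b above
        err_hi = (np.sum(a < c) + np.sum(b >= c)) / n  # a above, b below
        best = min(best, err_lo, err_hi)
    return float(best)
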