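"""Figure helpers: feature scatter, power time courses, day-wise curves,
avoidance generalization."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

STATE_COLORS = {"NREM": "tab:orange", "REM": "purple", "WAKE": "0.6"}
SOUND_COLORS = {
    "pre_control": "0.5",
    "post_control": "tab:green",
    "conditioned": "tab:red",
}


def plot_feature_scatter(features: pd.DataFrame, ax=None):
    """Theta/delta ratio vs peak-to-peak SD, colored by state label."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    for state, grp in features.groupby("state"):
        ax.scatter(
            grp["theta_delta_ratio"], grp["p2p_sd"], s=8, alpha=0.6,
            color=STATE_COLORS.get(state, "k"), label=state,
        )
    ax.set_xscale("log")
    ax.set_xlabel("theta/delta power ratio")
    ax.set_ylabel("peak-to-peak SD (µV)")
    ax.legend(frameon=False)
    return ax


def plot_power_timecourse(agg: pd.DataFrame, state: str, ax=None):
    """Mean normalized band power over the 24-s window per sound type."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    tcols = [c for c in agg.columns if c.startswith("t") and c[1:].isdigit()]
    t = np.arange(1, len(tcols) + 1) - 8.5  # onset at 0
    ax.axvspan(0, 8, color="gold", alpha=0.2)
    for _, row in agg[agg["state"] == state].iterrows():
        ax.plot(
            t, row[tcols].to_numpy(float),
            color=SOUND_COLORS.get(row["sound_type"], "k"),
            label=row["sound_type"],
        )
    ax.axhline(1.0, color="0.8", lw=0.8)
    band = "delta" if state == "NREM" else "theta"
    ax.set_xlabel("time from sound onset (s)")
    ax.set_ylabel(f"normalized {band} power")
    ax.set_title(state)
    ax.legend(frameon=False, fontsize=8)
    return ax


def plot_daily_timecourses(daily: pd.DataFrame, state: str, sound_type: str, ax=None):
    """Day-by-day mean time courses with fading color."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    tcols = [c for c in daily.columns if c.startswith("t") and c[1:].isdigit()]
    t = np.arange(1, len(tcols) + 1) - 8.5
    sel = daily[(daily["state"] == state) & (daily["sound_type"] == sound_type)]
    days = sorted(sel["day"].unique())
    base = SOUND_COLORS.get(sound_type, "k")
    for i, day in enumerate(days):
        row = sel[sel["day"] == day].iloc[0]
        ax.plot(
            t, row[tcols].to_numpy(float), color=base,
            alpha=max(0.15, 1.0 - 0.12 * i), label=f"day {day}",
        )
    ax.axvspan(0, 8, color="gold", alpha=0.2)
    ax.set_xlabel("time from sound onset (s)")
    ax.set_ylabel("normalized power")
    ax.set_title(f"{state} / {sound_type}")
    ax.legend(frameon=False, fontsize=7)
    return ax


def plot_avoidance_generalization(avoid: pd.DataFrame, fits: dict | None = None, ax=None):
    """Per-sound avoidance with optional sigmoid fits per phase."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    order = sorted(avoid["sound"].unique())
    ranks = {s: i + 1 for i, s in enumerate(order)}
    for phase, color in (("early", "k"), ("late", "0.6")):
        sel = avoid[avoid["phase"] == phase]
        if sel.empty:
            continue
        means = sel.groupby("sound")["avoidance_pct"].mean()
        x = [ranks[s] for s in means.index]
        ax.plot(x, means.to_numpy(), "o", color=color, label=phase)
        if fits and phase in fits:
            xs = np.linspace(min(x), max(x), 100)
            ax.plot(xs, fits[phase].predict(xs), "-", color=color, lw=1)
    ax.set_xticks(list(ranks.values()), list(ranks.keys()), rotation=30, fontsize=7)
    ax.set_ylabel("avoidance (%)")
    ax.legend(frameon=False)
    return ax
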