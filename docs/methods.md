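# Methods

This note documents the models, parameter choices and numerical conventions
behind `sleepgate`, and what the synthetic generator does and does not claim
about real recordings.

## Stimuli

All waveforms are synthesized at 200 kHz with peak amplitude 1 before
intensity calibration, and every pulse or tone segment carries 5-ms
raised-cosine on/off ramps to avoid spectral splatter.

**Chirps.** Frequency-modulated sweeps follow a log-linear trajectory
`f(t) = f₀·2^(±rt)` with the phase computed as the exact integral of `f(t)`
(no cumulative-sum drift). Defaults: 2-octave span at 50 octaves/s
(duration 40 ms); the downward sweep is the mirror image used as the
neutral novel sound. Sweeps ending above Nyquist or below 20 Hz are
rejected.

**Tone clouds.** A cloud's frequency window is split into three equal
contiguous subranges; six tones are drawn uniformly, two per subrange. The
six-tone sequence is built as two halves of three, each half a permutation
of the three subranges, with rejection sampling on the half boundary so no
consecutive tones share a subrange. The published ordering rule ("within
each half, no tone is in the same frequency range as the one previously")
is ambiguous about the boundary; we adopt the strictest reading
(one-per-subrange per half *and* no consecutive repeats anywhere), which
implies every weaker reading. Total cloud duration equals the 0.25-s pulse
slot (≈41.7 ms per tone), keeping clouds interchangeable with chirps in the
scheduler.

**Presentation scheme.** Eight 1-s intensity blocks from 24.6 to 73.5 dB
SPL, equally spaced in dB (the field convention for "eight steps" between
stated endpoints), three 0.25-s pulses per block left-aligned with 83-ms
gaps. The within-block pulse timing is not published; these values fit
three pulses per 1-s block. A block of three zero-amplitude pulses occupies
[−1, 0) s so that the analysis timeline (8 s pre / during / post) is
unaffected by the speaker-artefact control. `db_to_amplitude` maps level to
linear gain with a calibration constant anchoring 73.5 dB to full scale by
default.

## Synthetic electrophysiology

Each vigilance state contributes, per bout:

```
EEG(t) = A_state · carrier(t) · envelope(t) + background(t)
EMG(t) = tone_state · white noise (+ optional twitch transients)
```

- **Carrier**: unit-RMS mixture `√s·sin(2πf_c t+φ) + √(1−s)·bandnoise`, with
  `f_c` the state band center and `s` the deterministic (sinusoidal)
  power fraction — NREM 0.8, REM 0.9, WAKE 0.3. The mixture realizes the
  regularity contrast between states (REM theta nearly sinusoidal, NREM
  delta visibly irregular) while keeping per-second band-power estimates
  stable enough for second-resolution statistics; a pure band-noise
  carrier has a 1-s power CV near 0.5, which would swamp within-window
  time trends that second-scale mixed models are meant to detect.
- **Envelope**: mean-1 log-normal with state CV (NREM 0.30 > REM 0.15,
  the amplitude-irregularity ordering of the two states). Its log-SD is
  split into a per-bout level (95 %) and a slow within-bout modulation
  (5 %, smoothstep interpolation of independent knots every 10 s). The
  bout-level component cancels exactly in each epoch's baseline
  normalization. This split matters numerically: a slow envelope that is
  only *partially* correlated across a 24-s epoch inflates
  baseline-normalized power by `exp(4σ²(1−ρ))` (log-normal ratio bias) —
  early versions with filtered-noise envelopes showed null post-sound
  means as high as 1.3 from this effect alone.
- **Background**: unit-RMS 1/f (power) noise at 15 µV, plus state-specific
  EMG tone (WAKE 40 µV ≫ NREM 8 µV > REM 4 µV).

Default amplitudes (NREM 200 µV, REM 55 µV, WAKE 30 µV RMS) are
field-realistic for parietal screw EEG in mice and give cleanly separated
feature clusters at validation scale.

**Sound response.** Suppression is multiplicative on the state oscillation
only: from the first pulse at or above the profile's intensity threshold,
the oscillation amplitude relaxes toward `√g` with a 0.4-s time constant
(so band *power* relaxes to the gain `g`), then returns to baseline
linearly over the recovery duration (default 6 s, within the observed
4–8 s range). Broadband background, EMG tone and the vigilance state are
untouched — suppression without awakening; an optional brief EMG twitch
marks onset. Learner defaults: conditioned `g` = 0.35 (NREM) / 0.60 (REM)
engaging at 30 dB SPL; post-control `g` = 0.45 in NREM only, engaging at
45 dB (later, weaker generalization); pre-control `g` = 0.85/0.95 engaging
only at 65 dB (loudest blocks). Non-learners: `g` = 0.95 everywhere.

**Seeding.** One master seed; per-epoch child seeds via
`numpy.random.SeedSequence.spawn`, so multi-animal simulations are
reproducible sample-for-sample.

## Scoring

Features per non-overlapping 4-s window: theta/delta band-power ratio
(6–10 Hz / 0–4 Hz), peak-to-peak SD, EMG power. Band power is one
Hann-tapered periodogram per window (mean removed), integrated over the
half-open band `[lo, hi)` — half-open edges avoid double counting the 4-Hz
bin, and the 4–6 Hz gap belongs to neither band. Peak-to-peak SD is the
*population* SD of absolute local-extremum amplitudes; plateaus of equal
samples count once at their center. Classification is rule-based: WAKE if
EMG power exceeds the muscle-tone cut (default 400 µV²), else REM if the
ratio exceeds 1, else NREM; a 3-window majority vote removes isolated
windows. The thresholds are defaults for the generator's µV scaling, not
universal constants; on real data they should be set from the feature
scatter.

## Power pipeline

Per presentation: 24 consecutive 1-s band powers aligned to sound onset
(8 pre / 8 during / 8 post), band chosen by state (delta in NREM, theta in
REM), each epoch divided by its own 8-s baseline mean (block-1 normalized
mean is exactly 1 by construction). Epochs with zero/near-zero baselines
are flagged and excluded rather than clamped. Aggregation is two-stage —
mean over each animal's presentations, then unweighted mean over animals —
so animals with few sessions are not down-weighted. The "suppression
plateau" statistic is the mean normalized power over seconds 4–8 of the
sound window, where the gain has settled past the low-intensity onset of
the ramp. Decimation to the 1000-Hz analysis rate applies a zero-phase
8th-order Butterworth low-pass at 0.4× the target rate before taking every
q-th sample.

## Statistics

**Block models.** `BlockPowerModel` fits, per block, a linear mixed model
of the long table (one row per epoch-second): fixed effects sound type,
time (1–8 s, linear) and their interaction (plus sleep phase when both
states are present); random intercepts for animal and for session nested
in animal (statsmodels `MixedLM` with a session variance component), REML
by default. Per-term F statistics come from Wald chi-square tests of the
term's coefficient block divided by its df, with a residual-style
denominator df (n − rank X); at the designs used here (≈1000 rows) this is
indistinguishable from a Satterthwaite approximation, which `MixedLM` does
not provide. The random-effects LRT refits both the mixed model and the
fixed-effects-only OLS by ML; its χ² df is the number of variance
parameters the fitted structure actually removes (2 here: animal +
session), not a hard-coded constant. Significance conventions follow
0.05/0.01/0.001 with no correction across blocks. Factor terms with a
single observed level are dropped from the formula rather than fitted as
empty contrasts.

Calibration measured on the default generator (6 animals, NREM): type-I
error of the block-2 sound × time interaction 0.04–0.06 over 200 null
replicates; detection of the learner conditioned-sound effect in 12/12
replicates at the 6 × ~7-session design scale; null block-2/3 normalized
means 1.017 (the small excess over 1 is the unavoidable `E[1/x̄]` bias of
ratio normalization with an 8-sample baseline, shared with any analysis
that normalizes by a finite baseline mean).

**Behavior.** The learner rule is strict as stated: avoidance strictly
above 80 % on conditioning day 2 *and* at least 15 conditioning trials
accumulated by the end of day 2. Audiobox avoidance is
100 × (visits without nose poke)/visits per animal and sound; the
early/late split keeps the first/last two training days present in the
table. Generalization curves are least-squares 4-parameter logistic fits
(floor, ceiling, midpoint, slope) over sound-frequency rank, with bounded
`curve_fit` and a flat fallback reported as non-converged. Group
comparisons use one-way ANOVA plus Tukey–Kramer adjusted pairwise p values
(studentized-range based; valid for unequal group sizes).

## I/O conventions

Recordings interchange as classic EDF (16-bit, 1-s records, physical units
µV, per-channel physical range set to the data extremes so quantization
error is ≤ range/2¹⁶). Triggers travel in a `<stem>.triggers.csv` sidecar
(`time_s, sound_id`) rather than an EDF+ annotations stream; the reader
(MNE-based) picks the sidecar up automatically. Hypnograms and long power
tables are plain CSV with validated columns; every CLI run writes a
`run_log.json` with the seed, a config hash and package versions.

## What the generator does and does not show

The synthetic sessions reproduce the *statistical signatures* the analysis
depends on: state-banded spectra, amplitude regularity contrast, EMG tone,
intensity-gated multiplicative suppression with post-offset recovery, and
repeated-measures structure over animals/sessions/days. They do not
reproduce waveform-level features of real murine EEG (spindles, slow-wave
morphology, state transitions' gradual character, movement or electrical
artifacts), and scoring thresholds that are trivially separable here
require tuning on real data. Passing tests therefore validate the
*pipeline* — that it recovers known ground truth, invents no effects under
a null generator, and detects calibrated effects at the study's design
scale — not any biological claim about new recordings.

## Problem sizes

Test and acceptance runs use 50 epochs per recovery condition, 200 null
replicates for type-I calibration (24 presentations per sound each), 12
replicates for detection power, and a 246 + 228-snippet validation set for
state separability — the design scales of the paradigm the package models.
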