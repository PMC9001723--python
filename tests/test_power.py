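"""Sound-locked band-power extraction, normalization, aggregation, decimation."""

import numpy as np
import pytest

from sleepgate import power
from sleepgate.power import (
    BLOCK1,
    BLOCK2,
    EpochPower,
    aggregate,
    downsample,
    extract_epoch_power,
    normalize_to_baseline,
    to_long_table,
)
from sleepgate.synth import (
    EEGRecording,
    Hypnogram,
    SuppressionProfile,
    apply_sound_response,
    simulate_session,
)
from sleepgate.stimuli import make_ramp_schedule


class TestNormalization:
    def test_constant_vector_maps_to_ones(self):
        assert np.allclose(normalize_to_baseline(np.full(24, 3.7)), 1.0)

    def test_during_over_baseline_arithmetic(self):
        values = np.r_[np.full(8, 2.0), np.full(8, 0.7), np.full(8, 2.0)]
        assert np.allclose(normalize_to_baseline(values)[BLOCK2], 0.35)

    def test_zero_baseline_raises(self):
        values = np.r_[np.zeros(8), np.ones(16)]
        with pytest.raises(ZeroDivisionError):
            normalize_to_baseline(values)

    def test_block1_mean_is_exactly_one(self):
        rng = np.random.default_rng(0)
        values = rng.gamma(2.0, 1.0, 24)
        assert np.mean(normalize_to_baseline(values)[BLOCK1]) == pytest.approx(1.0)


class TestExtract:
    def _stationary_rec(self, state="NREM", seed=0, dur=30.0):
        rec, _ = simulate_session(Hypnogram.from_bouts([(dur, state)]), rng=seed)
        return rec

    def test_band_follows_state(self):
        rec = self._stationary_rec()
        ep = extract_epoch_power(rec, 10.0, "NREM")
        assert ep.band == "delta"
        ep = extract_epoch_power(self._stationary_rec("REM"), 10.0, "REM")
        assert ep.band == "theta"

    def test_stationary_epoch_normalizes_near_unity(self):
        means = []
        for seed in range(8):
            ep = extract_epoch_power(self._stationary_rec(seed=seed), 10.0, "NREM")
            means.append(np.mean(ep.normalized[8:]))
        assert np.mean(means) == pytest.approx(1.0, abs=0.15)

    def test_suppressed_epoch_plateau_near_gain(self):
        plats = []
        for seed in range(10):
            rec = self._stationary_rec(seed=seed)
            sched = make_ramp_schedule().shifted(10.0)
            rec = apply_sound_response(
                rec, sched, SuppressionProfile(0.35, 0.4, 30.0), "NREM"
            )
            plats.append(extract_epoch_power(rec, 10.0, "NREM").plateau_mean())
        assert np.mean(plats) == pytest.approx(0.35, abs=0.05)

    def test_window_outside_recording_rejected(self):
        rec = self._stationary_rec(dur=20.0)
        with pytest.raises(ValueError):
            extract_epoch_power(rec, 10.0, "NREM")  # needs onset+16 <= 20

    def test_wake_state_rejected(self):
        with pytest.raises(ValueError):
            extract_epoch_power(self._stationary_rec(), 10.0, "WAKE")

    def test_zero_signal_epoch_flagged_excluded(self):
        rec = EEGRecording(
            channels={"eeg_parietal": np.zeros(30000), "emg": np.zeros(30000)},
            fs=1000.0,
        )
        with pytest.warns(UserWarning):
            ep = extract_epoch_power(rec, 10.0, "NREM")
        assert ep.excluded


def _epoch(animal, session, values, state="NREM", sound="conditioned", day=1):
    values = np.asarray(values, dtype=float)
    return EpochPower(
        values=values,
        normalized=values,
        band="delta",
        state=state,
        sound_type=sound,
        animal_id=animal,
        session_id=session,
        day=day,
    )


class TestAggregate:
    def test_animals_weighted_equally_despite_session_imbalance(self):
        # animal A: two sessions at 2.0; animal B: ten sessions at 1.0
        eps = [_epoch("A", f"a{i}", np.full(24, 2.0)) for i in range(2)]
        eps += [_epoch("B", f"b{i}", np.full(24, 1.0)) for i in range(10)]
        agg = aggregate(eps)
        tcols = [c for c in agg.columns if c.startswith("t")]
        assert np.allclose(agg[tcols].to_numpy(), 1.5)

    def test_single_epoch_grand_mean_is_that_epoch(self):
        values = np.arange(24, dtype=float)
        agg = aggregate([_epoch("A", "s1", values)])
        tcols = [c for c in agg.columns if c.startswith("t")]
        assert np.allclose(agg[tcols].to_numpy()[0], values)

    def test_session_order_invariance(self):
        rng = np.random.default_rng(3)
        eps = [
            _epoch("A", f"s{i}", rng.gamma(2, 1, 24)) for i in range(6)
        ] + [_epoch("B", f"r{i}", rng.gamma(2, 1, 24)) for i in range(3)]
        agg1 = aggregate(eps)
        agg2 = aggregate(eps[::-1])
        tcols = [c for c in agg1.columns if c.startswith("t")]
        assert np.allclose(agg1[tcols].to_numpy(), agg2[tcols].to_numpy())

    def test_duplicated_session_acts_only_through_animal_mean(self):
        base = [
            _epoch("A", "s1", np.full(24, 1.0)),
            _epoch("B", "s2", np.full(24, 2.0)),
        ]
        dup = base + [_epoch("B", "s3", np.full(24, 2.0))]
        tcols = [f"t{k:02d}" for k in range(1, 25)]
        assert np.allclose(
            aggregate(base)[tcols].to_numpy(), aggregate(dup)[tcols].to_numpy()
        )

    def test_empty_input_warns(self):
        with pytest.warns(UserWarning):
            agg = aggregate([])
        assert agg.empty


class TestLongTable:
    def test_structure_blocks_and_time(self):
        table = to_long_table([_epoch("A", "s1", np.arange(24.0))])
        assert len(table) == 24
        assert list(table["block"].unique()) == [1, 2, 3]
        assert set(table["time"]) == set(range(1, 9))
        assert np.allclose(
            table.sort_values(["block", "time"])["normalized_power"], np.arange(24.0)
        )


class TestDownsample:
    def _rec(self, freq, fs=30000.0, dur=4.0):
        t = np.arange(int(dur * fs)) / fs
        return EEGRecording(
            channels={"eeg_parietal": np.sin(2 * np.pi * freq * t)}, fs=fs
        )

    def test_length_ratio_is_decimation_factor(self):
        out = downsample(self._rec(10.0), 1000.0)
        assert out.n_samples * 30 == self._rec(10.0).n_samples
        assert out.fs == 1000.0

    def test_passband_sine_amplitude_preserved(self):
        out = downsample(self._rec(100.0), 1000.0)
        x = out.channels["eeg_parietal"][500:-500]
        assert np.sqrt(np.mean(x**2)) == pytest.approx(1 / np.sqrt(2), rel=0.01)

    def test_stopband_component_attenuated_40db(self):
        out = downsample(self._rec(600.0), 1000.0)
        x = out.channels["eeg_parietal"][500:-500]
        assert np.sqrt(np.mean(x**2)) < (1 / np.sqrt(2)) * 10 ** (-40 / 20)

    def test_upsampling_rejected(self):
        with pytest.raises(ValueError):
            downsample(self._rec(10.0), 60000.0)

    def test_bandpower_analysis_matches_after_decimation(self):
        rec, _ = simulate_session(Hypnogram.from_bouts([(30.0, "NREM")]), rng=1)
        hi = EEGRecording(
            channels={
                "eeg_parietal": np.repeat(rec.channels["eeg_parietal"], 2)
            },
            fs=2000.0,
        )
        lo = downsample(hi, 1000.0)
        ep_lo = extract_epoch_power(lo, 10.0, "NREM")
        ep_ref = extract_epoch_power(rec, 10.0, "NREM")
        assert np.allclose(ep_lo.normalized, ep_ref.normalized, atol=0.2)
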