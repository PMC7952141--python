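import math

import numpy as np
import pytest

from phonokit import F0UndetectableError, PhonationParameters, SignalRecording
from phonokit.signal_metrics import (
    analyze_signal,
    bandpass,
    cpp_db,
    detect_cycles,
    hnr_db,
    jitter_pct,
    nne_db,
    rb,
    shimmer_pct,
    spl_db,
)
from phonokit.simulate import draw_cycle_sequence, synth_acoustic

FS = 96000.0


def _tone(freq, fs=FS, dur=1.0, amp=1.0):
    t = np.arange(int(dur * fs)) / fs
    return SignalRecording(amp * np.sin(2 * np.pi * freq * t), fs_hz=fs)


@pytest.fixture(scope="module")
def noisy_periodic():
    """500-cycle synthetic signal with noise 20 dB below the harmonic part."""
    p = PhonationParameters(
        f0_hz=100.0, duration_s=5.0, video_duration_s=None,
        noise_db_audio=-20.0, noise_floor_audio_pa=0.0, seed=11,
    )
    rec = synth_acoustic(p)
    return rec, detect_cycles(rec)


class TestBandpass:
    def test_dc_rejected(self):
        rec = SignalRecording(np.full(9600, 3.0), fs_hz=FS)
        out = bandpass(rec)
        assert np.sqrt(np.mean(out.samples**2)) < 1e-6 * 3.0

    def test_passband_tone_preserved_within_0p1_db(self):
        out = bandpass(_tone(1000.0))
        gain_db = 20 * np.log10(np.std(out.samples[9600:-9600]) / np.std(_tone(1000.0).samples))
        assert abs(gain_db) < 0.1

    def test_subsonic_tone_attenuated(self):
        out = bandpass(_tone(5.0))
        gain_db = 20 * np.log10(np.std(out.samples) / np.std(_tone(5.0).samples))
        assert gain_db <= -20.0

    def test_edge_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass(_tone(100.0, fs=16000.0), hi_hz=9000.0)


class TestCycleDetection:
    def test_counts_and_f0_on_harmonic_signal(self):
        p = PhonationParameters(f0_hz=100.0, duration_s=2.0, video_duration_s=None,
                                noise_db_audio=-40.0, seed=1)
        periods = detect_cycles(bandpass(synth_acoustic(p)))
        assert periods.n_cycles >= 190          # ~200 cycles in 2 s
        assert periods.f0_hz == pytest.approx(100.0, abs=0.5)

    def test_white_noise_undetectable(self):
        rng = np.random.default_rng(2)
        rec = SignalRecording(rng.normal(0, 1, int(FS)), fs_hz=FS)
        with pytest.raises(F0UndetectableError):
            detect_cycles(rec)

    def test_low_f0_supported_via_band_config(self):
        p = PhonationParameters(f0_hz=50.0, duration_s=2.0, video_duration_s=None, seed=3)
        periods = detect_cycles(bandpass(synth_acoustic(p)), f0_band_hz=(40.0, 400.0))
        assert periods.f0_hz == pytest.approx(50.0, abs=0.5)

    def test_too_short_record_undetectable(self):
        with pytest.raises(F0UndetectableError):
            detect_cycles(_tone(100.0, dur=0.015))


class TestPerturbation:
    @pytest.mark.parametrize(
        "values, expected",
        [
            (np.full(20, 0.010), 0.0),
            (np.tile([0.010, 0.011], 10), 100.0 * 0.001 / 0.0105),
        ],
    )
    def test_jitter_formula(self, values, expected):
        assert jitter_pct(values) == pytest.approx(expected, abs=1e-9)

    def test_shimmer_formula(self):
        amps = np.tile([1.0, 1.1], 10)
        assert shimmer_pct(amps) == pytest.approx(100.0 * 0.1 / 1.05, abs=1e-9)

    @pytest.mark.parametrize("cv", [0.01, 0.02])
    def test_jitter_recovery_against_half_normal_closed_form(self, cv):
        # E|T_i - T_{i+1}| for iid N(0, cv) periods gives Jitt = 100*cv*2/sqrt(pi)
        p = PhonationParameters(
            f0_hz=100.0, duration_s=5.0, video_duration_s=None, jitter_cv=cv,
            noise_db_audio=float("-inf"), noise_floor_audio_pa=0.0, seed=7,
        )
        periods = detect_cycles(bandpass(synth_acoustic(p)))
        expected = 100.0 * cv * 2.0 / math.sqrt(math.pi)
        assert jitter_pct(periods.periods_s) == pytest.approx(expected, rel=0.15)

    def test_shimmer_recovery_from_generator(self):
        p = PhonationParameters(
            f0_hz=100.0, duration_s=5.0, video_duration_s=None, shimmer_cv=0.03,
            noise_db_audio=float("-inf"), noise_floor_audio_pa=0.0, seed=8,
        )
        periods = detect_cycles(bandpass(synth_acoustic(p)))
        truth = draw_cycle_sequence(p)
        amps = truth.amp_left_mm2 + truth.amp_right_mm2
        expected = 100.0 * np.mean(np.abs(np.diff(amps))) / np.mean(amps)
        assert shimmer_pct(periods.amplitudes) == pytest.approx(expected, rel=0.15)


class TestNoiseMeasures:
    def test_noiseless_signal_caps(self):
        p = PhonationParameters(f0_hz=100.0, duration_s=1.0, video_duration_s=None,
                                noise_db_audio=float("-inf"), noise_floor_audio_pa=0.0,
                                seed=4)
        rec = synth_acoustic(p)
        periods = detect_cycles(rec)
        assert hnr_db(rec, periods) == 60.0
        assert nne_db(rec, periods) <= -55.0

    def test_hnr_matches_injected_snr(self, noisy_periodic):
        rec, periods = noisy_periodic
        assert hnr_db(rec, periods) == pytest.approx(20.0, abs=1.0)

    def test_nne_matches_injected_snr(self, noisy_periodic):
        rec, periods = noisy_periodic
        assert nne_db(rec, periods) == pytest.approx(-20.0, abs=1.0)

    def test_hnr_nne_complementarity(self, noisy_periodic):
        # with H >> N, NNE ~ -HNR
        rec, periods = noisy_periodic
        assert abs(hnr_db(rec, periods) + nne_db(rec, periods)) <= 1.0

    def test_pure_noise_with_forced_marks_is_noise_dominated(self):
        rng = np.random.default_rng(5)
        rec = SignalRecording(rng.normal(0, 1, int(FS)), fs_hz=FS)
        from phonokit.signal_metrics import PeriodSequence

        marks = np.arange(0, int(FS), 960)
        periods = PeriodSequence(
            marks_s=marks / FS, marks_idx=marks, fs_hz=FS,
            periods_s=np.diff(marks) / FS, amplitudes=np.ones(marks.size - 1),
        )
        assert hnr_db(rec, periods) < 3.0
        assert nne_db(rec, periods) > -3.0


class TestCPP:
    def test_pulse_train_exceeds_noise_by_10_db(self):
        rng = np.random.default_rng(6)
        pulses = np.zeros(int(2 * FS))
        pulses[:: int(FS / 100)] = 1.0
        pulses_rec = SignalRecording(pulses / np.std(pulses), fs_hz=FS)
        noise_rec = SignalRecording(rng.normal(0, 1, pulses.size), fs_hz=FS)
        assert cpp_db(pulses_rec) - cpp_db(noise_rec) >= 10.0

    def test_monotone_decreasing_in_generator_noise(self):
        vals = []
        for nz in (-30.0, -20.0, -10.0, 0.0):
            p = PhonationParameters(f0_hz=100.0, duration_s=2.0, video_duration_s=None,
                                    noise_db_audio=nz, seed=4)
            vals.append(cpp_db(bandpass(synth_acoustic(p))))
        assert all(b < a for a, b in zip(vals, vals[1:]))

    def test_time_shift_invariance(self):
        p = PhonationParameters(f0_hz=100.0, duration_s=2.0, video_duration_s=None,
                                noise_db_audio=-25.0, seed=9)
        rec = synth_acoustic(p)
        shift = int(0.08192 * FS)  # whole frames: interior content identical
        shifted = SignalRecording(np.roll(rec.samples, shift), fs_hz=FS)
        assert cpp_db(shifted) == pytest.approx(cpp_db(rec), abs=0.1)


class TestLevelsAndAero:
    @pytest.mark.parametrize("rms, expected", [(2.0, 100.0), (0.02, 60.0)])
    def test_spl_closed_form(self, rms, expected):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1.0, 96000)
        x *= rms / np.sqrt(np.mean(x**2))
        assert spl_db(SignalRecording(x, fs_hz=FS)) == pytest.approx(expected, abs=1e-6)

    def test_rb_arithmetic_and_errors(self):
        assert rb(1000.0, 50.0) == pytest.approx(20.0)
        with pytest.raises(ValueError):
            rb(1000.0, 0.0)


class TestChannelSymmetryAndScaling:
    def test_identical_processing_for_both_channel_labels(self):
        p = PhonationParameters(f0_hz=100.0, duration_s=2.0, video_duration_s=None,
                                noise_db_audio=-25.0, seed=10)
        samples = synth_acoustic(p).samples
        a = analyze_signal(SignalRecording(samples, fs_hz=FS, channel="acoustic"))
        b = analyze_signal(SignalRecording(samples, fs_hz=FS, channel="subglottal"))
        for field in ("f0_hz", "jitt_pct", "shim_pct", "hnr_db", "nne_db", "cpp_db"):
            assert getattr(a, field) == getattr(b, field)

    def test_metrics_invariant_to_amplitude_scaling_except_levels(self):
        p = PhonationParameters(f0_hz=100.0, duration_s=2.0, video_duration_s=None,
                                noise_db_audio=-25.0, seed=12)
        rec = synth_acoustic(p)
        scaled = SignalRecording(10.0 * rec.samples, fs_hz=FS)
        a, b = analyze_signal(rec), analyze_signal(scaled)
        for field in ("f0_hz", "jitt_pct", "shim_pct", "hnr_db", "nne_db", "cpp_db"):
            assert getattr(a, field) == pytest.approx(getattr(b, field), abs=1e-6)
        assert b.spl_db == pytest.approx(a.spl_db + 20.0, abs=1e-6)

    def test_whole_record_analyzed(self):
        p = PhonationParameters(f0_hz=100.0, duration_s=2.0, video_duration_s=None,
                                noise_db_audio=-30.0, seed=13)
        m = analyze_signal(synth_acoustic(p))
        assert m.n_cycles >= 190  # all ~200 cycles of the 2 s record
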