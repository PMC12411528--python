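import numpy as np
import pytest

from eitqct.eit_signal import (EITFrameSequence, ImpedanceSeries, compute_spectrum,
                               extract_global_waveform, peak_respiratory_frequency,
                               select_stable_window, split_ventilation_perfusion)
from eitqct.synthetic_data import BreathWaveformSpec, generate_breath_waveform, \
    generate_frame_sequence


class TestExtractGlobalWaveform:
    def test_constant_frames_sum_mask_pixels(self):
        frames = np.ones((20, 8, 8))
        mask = np.zeros((8, 8), dtype=bool)
        mask.flat[:10] = True
        seq = EITFrameSequence(frames=frames, sample_rate_hz=10.0, roi_mask=mask)
        series = extract_global_waveform(seq)
        assert np.allclose(series.values, 10.0)
        assert series.sample_rate_hz == 10.0

    def test_recovers_generator_waveform(self, clean_spec):
        seq, wf = generate_frame_sequence(clean_spec, grid_side=16, mask_fraction=0.4)
        series = extract_global_waveform(seq)
        assert np.allclose(series.values, wf.series.values, atol=1e-9)

    def test_single_frame_sequence(self):
        seq = EITFrameSequence(frames=np.ones((1, 4, 4)), sample_rate_hz=10.0,
                               roi_mask=np.ones((4, 4), dtype=bool))
        assert extract_global_waveform(seq).n_samples == 1

    def test_empty_mask_rejected(self):
        seq = EITFrameSequence(frames=np.ones((5, 4, 4)), sample_rate_hz=10.0,
                               roi_mask=np.zeros((4, 4), dtype=bool))
        with pytest.raises(ValueError, match="mask"):
            extract_global_waveform(seq)


class TestSpectrum:
    def test_pure_low_band_tone(self, tone_factory):
        spec = compute_spectrum(tone_factory(15.0))
        assert spec.low_integral / spec.total_integral >= 0.99

    def test_pure_high_band_tone(self, tone_factory):
        spec = compute_spectrum(tone_factory(30.0))
        assert spec.high_integral > spec.low_integral
        assert spec.high_integral > spec.perfusion_integral
        assert spec.high_integral / spec.total_integral >= 0.99

    def test_constant_series_all_zero(self):
        spec = compute_spectrum(ImpedanceSeries(np.full(64, 3.0), 10.0))
        assert spec.low_integral == spec.high_integral == spec.perfusion_integral == 0.0

    def test_band_integrals_additive_over_partition(self, composite_spec):
        wf = generate_breath_waveform(composite_spec)
        spec = compute_spectrum(wf.series)
        # oracle: one trapezoid over the whole 2 cpm-Nyquist range
        from eitqct.eit_signal import _band_area
        total = _band_area(spec.freqs_cpm, spec.amplitude, 2.0, wf.series.nyquist_cpm)
        assert spec.total_integral == pytest.approx(total, rel=1e-12)

    def test_parseval_power_conservation(self, tone_factory):
        series = tone_factory(17.0, amplitude=2.5)
        spec = compute_spectrum(series)
        x = series.values - series.values.mean()
        power = float(np.mean(x ** 2))
        amp = spec.amplitude.copy()
        one_sided_power = 0.5 * np.sum(amp[1:-1] ** 2) + amp[0] ** 2 + amp[-1] ** 2
        assert one_sided_power == pytest.approx(power, rel=1e-9)

    def test_tone_moving_bands_conserves_total(self, tone_factory):
        a = compute_spectrum(tone_factory(20.0))
        b = compute_spectrum(tone_factory(30.0))
        assert a.low_integral > a.high_integral
        assert b.high_integral > b.low_integral
        total_a = a.low_integral + a.high_integral
        total_b = b.low_integral + b.high_integral
        assert total_a == pytest.approx(total_b, rel=0.02)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="16"):
            compute_spectrum(ImpedanceSeries(np.arange(8.0), 10.0))


class TestPeakRespiratoryFrequency:
    def test_single_tone(self, tone_factory):
        spec = compute_spectrum(tone_factory(15.0))
        bin_w = spec.freqs_cpm[1] - spec.freqs_cpm[0]
        assert abs(peak_respiratory_frequency(spec) - 15.0) <= bin_w

    def test_larger_amplitude_wins(self, tone_factory):
        t12 = tone_factory(12.0, amplitude=2.0)
        t18 = tone_factory(18.0, amplitude=1.0)
        series = ImpedanceSeries(t12.values + t18.values, 10.0)
        spec = compute_spectrum(series)
        assert peak_respiratory_frequency(spec) == pytest.approx(12.0, abs=1.0)

    def test_flat_spectrum_lowest_bin_tiebreak(self):
        rng = np.random.default_rng(0)
        spec = compute_spectrum(ImpedanceSeries(rng.normal(size=600), 10.0))
        flat = spec
        flat.amplitude[:] = 1.0
        in_band = (flat.freqs_cpm >= 2.0) & (flat.freqs_cpm <= 40.0)
        assert peak_respiratory_frequency(flat) == flat.freqs_cpm[in_band][0]


class TestSplitVentilationPerfusion:
    @pytest.mark.parametrize("mode", ["fixed_40cpm", "adaptive_2p5x"])
    def test_cardiac_amplitude_recovery(self, composite_spec, mode):
        wf = generate_breath_waveform(composite_spec)
        _, perf = split_ventilation_perfusion(wf.series, mode=mode)
        spec = compute_spectrum(perf)
        i70 = int(np.argmin(np.abs(spec.freqs_cpm - 70.0)))
        assert spec.amplitude[i70] == pytest.approx(wf.truth.cardiac_amplitude, rel=0.05)

    def test_zero_cardiac_gives_no_cardiac_band_content(self, clean_spec):
        # breath harmonics above 40 cpm legitimately enter the perfusion
        # channel; what must vanish is content at the (absent) cardiac rate
        wf = generate_breath_waveform(clean_spec)
        _, perf = split_ventilation_perfusion(wf.series)
        spec = compute_spectrum(perf)
        i70 = int(np.argmin(np.abs(spec.freqs_cpm - 70.0)))
        tidal_rms = float(np.std(wf.series.values))
        assert spec.amplitude[i70] <= 1e-12 * tidal_rms
        assert float(np.std(perf.values)) <= 0.1 * tidal_rms

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_reconstruction_identity(self, seed):
        spec = BreathWaveformSpec(noise_sd=0.05, baseline_drift_amplitude=0.1,
                                  cardiac_amplitude_fraction=0.1, seed=seed)
        wf = generate_breath_waveform(spec)
        vent, perf = split_ventilation_perfusion(wf.series)
        recon = vent.values + perf.values + wf.series.values.mean()
        err = np.max(np.abs(recon - wf.series.values)) / np.ptp(wf.series.values)
        assert err <= 1e-9

    def test_adaptive_cutoff_above_nyquist_rejected(self, tone_factory):
        # 30 cpm peak at a 2 Hz sampling rate: cutoff 75 cpm >= Nyquist 60 cpm
        series = tone_factory(30.0, duration_s=60.0, sample_rate_hz=2.0)
        with pytest.raises(ValueError, match="cutoff"):
            split_ventilation_perfusion(series, mode="adaptive_2p5x")


class TestSelectStableWindow:
    def test_exact_length_is_identity(self, tone_factory):
        series = tone_factory(12.0, duration_s=60.0)
        window = select_stable_window(series, window_s=60.0)
        assert np.array_equal(window.values, series.values)

    def test_noisy_second_half_avoided(self):
        spec = BreathWaveformSpec(duration_s=120.0, noise_sd=0.02, seed=5)
        wf = generate_breath_waveform(spec)
        v = wf.series.values.copy()
        rng = np.random.default_rng(9)
        v[600:] += rng.normal(0, 0.3, size=600)  # 5x noisier second half
        noisy = ImpedanceSeries(v, 10.0)
        window = select_stable_window(noisy, window_s=60.0)
        # located within the first (quiet) half
        starts = [i for i in range(601) if np.array_equal(v[i:i + 600], window.values)]
        assert starts and starts[0] < 600

    def test_stationary_series_earliest_window_and_determinism(self, tone_factory):
        # an exactly periodic tone ties every candidate window; the earliest
        # detected cycle start must win, deterministically
        series = tone_factory(12.0, duration_s=90.0)
        window = select_stable_window(series, window_s=60.0)
        again = select_stable_window(series, window_s=60.0)
        assert np.array_equal(window.values, again.values)
        # the earliest detected cycle-start window is chosen
        from eitqct.eit_signal import _trough_indices, split_ventilation_perfusion
        vent, _ = split_ventilation_perfusion(series)
        first = int(_trough_indices(vent.values, 0.2 * np.ptp(vent.values))[0])
        assert np.array_equal(window.values, series.values[first:first + 600])

    def test_too_short_series_rejected(self, tone_factory):
        series = tone_factory(12.0, duration_s=30.0)
        with pytest.raises(ValueError, match="60"):
            select_stable_window(series, window_s=60.0)
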