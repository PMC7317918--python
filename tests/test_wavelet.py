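"""Wavelet transform: preprocessing, single modes, power spectra, group means."""

import numpy as np
import pytest
from scipy.signal import periodogram

from cardiocoh import (
    UniformSignal,
    WaveletParams,
    cwt,
    group_mean_spectra,
    normalise_spectrum,
    preprocess,
    time_average_power,
)

from conftest import make_tone


class TestPreprocess:
    def test_ramp_removed(self):
        t = np.arange(2400) / 4.0
        sig = UniformSignal(0.5 * t + 3.0, fs=4.0)
        out = preprocess(sig, 0.02, 1.0)
        assert abs(out.samples.mean()) < 1e-8
        slope = np.polyfit(t, out.samples, 1)[0]
        assert abs(slope) < 1e-4

    def test_out_of_band_tone_attenuated(self):
        t = np.arange(600 * 4) / 4.0
        x = np.sin(2 * np.pi * 0.001 * t) + np.sin(2 * np.pi * 0.3 * t)
        sig = UniformSignal(x, fs=4.0)
        out = preprocess(sig, 0.005, 2.0)
        f, p_in = periodogram(x, fs=4.0)
        _, p_out = periodogram(out.samples, fs=4.0)
        lo = (f > 0) & (f < 0.003)
        # >40 dB attenuation of the 0.001 Hz line
        assert p_out[lo].sum() < 1e-4 * p_in[lo].sum()

    def test_in_band_amplitude_preserved(self):
        sig = make_tone(0.3, 4.0, 600.0)
        out = preprocess(sig, 0.005, 2.0)
        interior = slice(240, -240)
        ratio = np.std(out.samples[interior]) / np.std(sig.samples[interior])
        assert abs(ratio - 1.0) < 0.01

    def test_too_short_record_rejected(self):
        sig = make_tone(0.3, 4.0, 100.0)
        with pytest.raises(ValueError):
            preprocess(sig, 0.005, 2.0)  # needs >= 600 s at fmin = 0.005


class TestCwt:
    def test_single_mode_peaks_at_nearest_grid_freq(self):
        params = WaveletParams(fmin=0.02, fmax=1.0)
        tfr = cwt(make_tone(0.1, 4.0, 600.0), params)
        k_star = tfr.nearest_freq_index(0.1)
        amax = np.abs(tfr.coeffs).argmax(axis=0)
        valid_cols = tfr.valid_mask[k_star]
        assert np.all(np.abs(amax[valid_cols] - k_star) <= 1)

    def test_two_tones_give_two_separated_ridges(self):
        t = np.arange(600 * 4) / 4.0
        x = np.sin(2 * np.pi * 0.05 * t) + np.sin(2 * np.pi * 0.35 * t)
        params = WaveletParams(fmin=0.02, fmax=1.0)
        spec = time_average_power(cwt(UniformSignal(x, fs=4.0), params))
        k1, k2 = spec.freqs.searchsorted(0.05), spec.freqs.searchsorted(0.35)
        peak = spec.power[[k1, k2]].min()
        trough = spec.power[spec.freqs.searchsorted(0.13):spec.freqs.searchsorted(0.14)].max()
        assert trough < 0.1 * peak

    def test_zero_signal_zero_coeffs(self):
        params = WaveletParams(fmin=0.05, fmax=1.0, preprocess=False)
        tfr = cwt(UniformSignal(np.zeros(1024), fs=4.0), params)
        assert np.all(tfr.coeffs == 0)

    def test_linearity(self):
        params = WaveletParams(fmin=0.05, fmax=1.0, preprocess=False)
        sig = make_tone(0.2, 4.0, 300.0)
        tfr1 = cwt(sig, params)
        tfr3 = cwt(sig.with_samples(3.0 * sig.samples), params)
        np.testing.assert_allclose(tfr3.coeffs, 3.0 * tfr1.coeffs, atol=1e-12)

    def test_time_shift_covariance(self):
        params = WaveletParams(fmin=0.05, fmax=1.0, preprocess=False)
        rng = np.random.default_rng(5)
        x = rng.normal(size=2048)
        shift = 64
        tfr_a = cwt(UniformSignal(x, fs=4.0), params)
        tfr_b = cwt(UniformSignal(np.roll(x, shift), fs=4.0), params)
        # sample t of the original appears at t+shift in the rolled record.
        # At the COI boundary edge contamination is still ~1/e by definition,
        # so compare only at twice the COI distance from either edge.
        n = x.size
        strict = np.zeros_like(tfr_a.valid_mask)
        for k in range(tfr_a.freqs.size):
            w = int(np.argmax(tfr_a.valid_mask[k]))  # COI width in samples
            if tfr_a.valid_mask[k].any() and 2 * w < n - 2 * w:
                strict[k, 2 * w : n - 2 * w] = True
        sel = strict[:, : n - shift] & strict[:, shift:]
        a = tfr_a.coeffs[:, : n - shift][sel]
        b = tfr_b.coeffs[:, shift:][sel]
        err = np.abs(a - b).max() / np.abs(a).max()
        assert err < 0.05

    def test_amplitude_stable_on_ridge(self):
        params = WaveletParams(fmin=0.02, fmax=1.0)
        tfr = cwt(make_tone(0.1, 4.0, 1200.0), params)
        k_star = tfr.nearest_freq_index(0.1)
        a = np.abs(tfr.coeffs[k_star, tfr.valid_mask[k_star]])
        assert a.std() / a.mean() < 0.01

    def test_nyquist_violation_rejected(self):
        with pytest.raises(ValueError):
            cwt(make_tone(0.1, 2.0, 600.0), WaveletParams(fmin=0.02, fmax=2.0))


class TestPower:
    def test_homogeneity(self):
        params = WaveletParams(fmin=0.05, fmax=1.0)
        sig = make_tone(0.2, 4.0, 400.0)
        p1 = time_average_power(cwt(sig, params))
        p2 = time_average_power(cwt(sig.with_samples(2 * sig.samples), params))
        np.testing.assert_allclose(p2.power, 4.0 * p1.power, rtol=1e-9)

    def test_white_noise_power_tracks_filter_bandwidth(self):
        # Monte-Carlo oracle: with unit-gain constant-relative-bandwidth
        # filters, the expected band power of white noise is proportional to
        # the filter bandwidth, i.e. proportional to frequency (slope +1 in
        # log-log), not flat.
        params = WaveletParams(fmin=0.1, fmax=1.0, preprocess=False)
        acc = []
        for seed in range(60):
            x = np.random.default_rng(seed).normal(size=1024)
            acc.append(time_average_power(cwt(UniformSignal(x, fs=4.0), params)).power)
        mean_power = np.mean(acc, axis=0)
        sel = slice(8, -8)  # interior frequencies
        slope = np.polyfit(np.log(params.freqs[sel]), np.log(mean_power[sel]), 1)[0]
        assert 0.85 < slope < 1.15

    def test_normalisation_unit_integral_and_scale_invariance(self):
        params = WaveletParams(fmin=0.05, fmax=1.0)
        sig = make_tone(0.2, 4.0, 400.0)
        n1 = normalise_spectrum(time_average_power(cwt(sig, params)))
        dlnf = np.log(2) / params.voices_per_octave
        assert abs(np.nansum(n1.power) * dlnf - 1.0) < 1e-12
        n10 = normalise_spectrum(
            time_average_power(cwt(sig.with_samples(10 * sig.samples), params))
        )
        np.testing.assert_allclose(n10.power, n1.power, rtol=1e-9)

    def test_all_zero_spectrum_rejected(self):
        from cardiocoh.wavelet import PowerSpectrumTA

        spec = PowerSpectrumTA(freqs=np.array([0.1, 0.2]), power=np.zeros(2),
                               n_valid=np.array([5, 5]))
        with pytest.raises(ValueError):
            normalise_spectrum(spec)

    def test_group_mean(self):
        from cardiocoh.wavelet import PowerSpectrumTA

        f = np.array([0.1, 0.2, 0.4])
        a = PowerSpectrumTA(freqs=f, power=np.array([1.0, 2.0, 3.0]), n_valid=np.ones(3))
        b = PowerSpectrumTA(freqs=f, power=np.array([3.0, 2.0, 1.0]), n_valid=np.ones(3))
        np.testing.assert_allclose(group_mean_spectra([a]).power, a.power)
        np.testing.assert_allclose(group_mean_spectra([a, a]).power, a.power)
        np.testing.assert_allclose(group_mean_spectra([a, b]).power, [2.0, 2.0, 2.0])
        c = PowerSpectrumTA(freqs=f * 2, power=a.power, n_valid=np.ones(3))
        with pytest.raises(ValueError):
            group_mean_spectra([a, c])

    def test_hdf5_round_trip(self, tmp_path):
        params = WaveletParams(fmin=0.05, fmax=1.0)
        tfr = cwt(make_tone(0.2, 4.0, 300.0), params)
        tfr.to_hdf5(tmp_path / "tfr.h5")
        from cardiocoh import TimeFrequencyRepresentation

        back = TimeFrequencyRepresentation.from_hdf5(tmp_path / "tfr.h5")
        np.testing.assert_array_equal(back.coeffs, tfr.coeffs)
        np.testing.assert_array_equal(back.coi_mask, tfr.coi_mask)
        assert back.params == tfr.params
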