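import numpy as np
import pytest

from apneafusion import (
    CWTConfig,
    SPWVDConfig,
    STFTConfig,
    blackman_window,
    cwt_scalogram,
    render_image,
    spwvd,
    stft_spectrogram,
)
from apneafusion.tfr import TFRGrid, default_colormap, morse_wavelet_ft

FS = 100.0


class TestBlackmanWindow:
    def test_endpoint_is_zero(self):
        w = blackman_window(64)
        assert w[0] == pytest.approx(0.42 - 0.5 + 0.08, abs=1e-12)

    def test_midpoint_is_one(self):
        w = blackman_window(65)
        assert w[32] == pytest.approx(0.42 + 0.5 + 0.08, abs=1e-12)

    @pytest.mark.parametrize("length", [2, 5, 64, 65])
    def test_symmetric(self, length):
        w = blackman_window(length)
        assert np.allclose(w, w[::-1], atol=1e-12)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            blackman_window(1)


class TestSpectrogram:
    def test_default_grid_dimensions(self):
        g = stft_spectrogram(np.random.default_rng(0).normal(size=6000), FS)
        assert g.values.shape == (33, 1485)

    @pytest.mark.parametrize(
        "n, window, overlap",
        [(6000, 64, 60), (1000, 128, 64), (500, 50, 0), (512, 64, 63)],
    )
    def test_frame_count_closed_form(self, n, window, overlap):
        x = np.random.default_rng(1).normal(size=n)
        g = stft_spectrogram(x, FS, STFTConfig(window_length=window, overlap=overlap))
        hop = window - overlap
        assert g.values.shape == (window // 2 + 1, (n - window) // hop + 1)

    def test_tone_localizes_and_matches_dft_oracle(self):
        t = np.arange(6000) / FS
        x = np.sin(2 * np.pi * 10.0 * t)
        g = stft_spectrogram(x, FS)
        target_row = np.argmin(np.abs(g.freq_axis - 10.0))
        assert np.all(g.values.argmax(axis=0) == target_row)
        # oracle: brute-force DFT of one windowed frame
        frame = x[400 : 400 + 64] * blackman_window(64)
        k = np.arange(64)
        dft = np.array([np.sum(frame * np.exp(-2j * np.pi * f * k / 64)) for f in range(33)])
        col = 400 // 4  # frame starting at sample 400
        expected = 20 * np.log10(np.abs(dft) + 1e-12)
        assert np.allclose(g.values[::-1, col], expected, atol=1e-9)

    def test_zero_input_is_flat_floor(self):
        g = stft_spectrogram(np.zeros(1000), FS)
        assert np.ptp(g.values) == 0.0

    def test_hop_shift_moves_one_column(self):
        x = np.random.default_rng(3).normal(size=2000)
        g1 = stft_spectrogram(x, FS)
        g2 = stft_spectrogram(x[4:], FS)  # one hop later
        assert np.allclose(g2.values, g1.values[:, 1:], atol=1e-9)

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            stft_spectrogram(np.zeros(63), FS)


class TestScalogram:
    def test_constant_input_hits_floor(self):
        g = cwt_scalogram(np.ones(2000), FS)
        assert np.all(g.values < -100.0)  # dB floor: zero-mean wavelet kills constants

    def test_freq_axis_construction(self):
        cfg = CWTConfig()
        freqs = cfg.frequencies()
        n = int(round(cfg.voices_per_octave * np.log2(cfg.freq_max / cfg.freq_min))) + 1
        assert len(freqs) == n
        assert np.allclose(np.diff(np.log2(freqs)), np.diff(np.log2(freqs))[0])
        g = cwt_scalogram(np.zeros(100), FS)
        assert len(g.freq_axis) == n
        assert g.values.shape[1] == 100

    def test_tone_ridge_within_one_voice(self):
        t = np.arange(6000) / FS
        x = np.sin(2 * np.pi * 5.0 * t)
        g = cwt_scalogram(x, FS)
        interior = slice(500, 5500)
        ridge = g.freq_axis[g.values[:, interior].argmax(axis=0)]
        voice = 2 ** (1 / CWTConfig().voices_per_octave)
        assert np.all(ridge <= 5.0 * voice + 1e-9)
        assert np.all(ridge >= 5.0 / voice - 1e-9)

    def test_direct_convolution_oracle_at_probe_scales(self):
        """Coefficient magnitudes from an explicit circular convolution with
        the time-domain wavelet match the FFT implementation."""
        cfg = CWTConfig()
        t = np.arange(1024) / FS
        x = np.sin(2 * np.pi * 5.0 * t)
        g = cwt_scalogram(x, FS, cfg)
        nfft = int(2 ** np.ceil(np.log2(2 * len(x))))
        pad_left = (nfft - len(x)) // 2
        xpad = np.pad(x, (pad_left, nfft - len(x) - pad_left), mode="edge")
        omega = 2 * np.pi * np.fft.fftfreq(nfft)
        wp = (cfg.beta / cfg.gamma) ** (1 / cfg.gamma)
        col = 512
        for f_probe in (3.3, 5.0, 7.6):
            row = np.argmin(np.abs(g.freq_axis - f_probe))
            f_row = g.freq_axis[row]
            scale_ = wp / (2 * np.pi * f_row / FS)
            psi_t = np.fft.ifft(morse_wavelet_ft(scale_ * omega, cfg.gamma, cfg.beta))
            # circular correlation evaluated directly at one column
            idx = (np.arange(nfft) - (pad_left + col)) % nfft
            coeff = np.dot(xpad, psi_t[idx])
            power_db = 10 * np.log10(np.abs(coeff) ** 2 + 1e-12)
            assert power_db == pytest.approx(g.values[row, col], abs=1e-6)

    def test_amplitude_scaling_quadratic_in_power(self):
        t = np.arange(2000) / FS
        x = np.sin(2 * np.pi * 5.0 * t)
        g1 = cwt_scalogram(x, FS)
        g2 = cwt_scalogram(2 * x, FS)
        mask = g1.values > -60
        assert np.allclose(g2.values[mask] - g1.values[mask], 20 * np.log10(2), atol=1e-6)

    def test_freq_max_beyond_nyquist_rejected(self):
        with pytest.raises(ValueError):
            cwt_scalogram(np.zeros(100), FS, CWTConfig(freq_max=60.0))


class TestSPWVD:
    def test_tone_ridge(self):
        t = np.arange(3000) / FS
        x = np.sin(2 * np.pi * 8.0 * t)
        g = spwvd(x, FS)
        interior = g.values[:, 20:-20]
        ridge = g.freq_axis[interior.argmax(axis=0)]
        assert np.all(np.abs(ridge - 8.0) <= 0.5)

    def test_cross_term_suppression_vs_unsmoothed(self):
        t = np.arange(3000) / FS
        x = np.sin(2 * np.pi * 5.0 * t) + np.sin(2 * np.pi * 15.0 * t)
        smoothed = spwvd(x, FS)
        raw = spwvd(x, FS, SPWVDConfig(time_window_length=1, freq_window_length=1))
        for g in (smoothed, raw):
            assert np.isrealobj(g.values)

        def midband_energy(g):
            rows = (g.freq_axis > 9.0) & (g.freq_axis < 11.0)
            return np.abs(g.values[rows, 20:-20]).mean()

        def tone_energy(g):
            rows = (np.abs(g.freq_axis - 5.0) < 1.0) | (np.abs(g.freq_axis - 15.0) < 1.0)
            return np.abs(g.values[rows, 20:-20]).mean()

        # cross-terms live midway between the tones; smoothing must cut their
        # energy relative to the genuine tone ridges
        assert midband_energy(smoothed) / tone_energy(smoothed) < midband_energy(
            raw
        ) / tone_energy(raw)

    def test_output_real_and_finite(self):
        x = np.random.default_rng(5).normal(size=500)
        g = spwvd(x, FS)
        assert np.all(np.isfinite(g.values))

    def test_window_longer_than_signal_rejected(self):
        with pytest.raises(ValueError):
            spwvd(np.zeros(20), FS)


class TestRenderImage:
    def _grid(self, values):
        values = np.asarray(values, dtype=float)
        return TFRGrid(
            values=values,
            freq_axis=np.arange(values.shape[0])[::-1].astype(float),
            time_axis=np.arange(values.shape[1]).astype(float),
            kind="spectrogram",
        )

    def test_constant_grid_maps_to_entry_zero(self):
        cmap = default_colormap()
        img = render_image(self._grid(np.full((4, 6), 3.0)))
        assert np.allclose(img, cmap[0])

    def test_endpoint_mapping_without_resize(self):
        cmap = default_colormap()
        img = render_image(self._grid([[0.0, 80.0], [40.0, 80.0]]), size=None)
        assert np.allclose(img[0, 0], cmap[0])
        assert np.allclose(img[0, 1], cmap[255])

    def test_shape_and_range(self):
        g = self._grid(np.random.default_rng(0).normal(size=(40, 90)))
        img = render_image(g)
        assert img.shape == (128, 128, 3)
        assert img.min() >= 0.0 and img.max() <= 1.0

    def test_monotone_in_intensity(self):
        values = np.random.default_rng(1).uniform(-50, 0, size=(8, 8))
        g = self._grid(values)
        cmap = np.tile(np.linspace(0, 1, 256)[:, None], (1, 3))  # gray ramp
        img = render_image(g, colormap=cmap, size=None)
        idx = img[..., 0] * 255
        order = np.argsort(values.ravel())
        assert np.all(np.diff(idx.ravel()[order]) >= -1e-9)

    def test_bad_colormap_rejected(self):
        with pytest.raises(ValueError):
            render_image(self._grid(np.zeros((2, 2))), colormap=np.zeros((10, 3)))
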