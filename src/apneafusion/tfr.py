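"""Time-frequency representations of ECG segments and their rendering.

Three representations are produced: a Blackman-window STFT spectrogram
(log magnitude in dB), a Morse-wavelet CWT scalogram (squared modulus in
dB over log-spaced frequencies), and a smoothed pseudo Wigner-Ville
distribution. Each is held in a :class:`TFRGrid` with explicit axes and
rendered to a fixed-size RGB raster through a 256-entry colormap.

Grids use image orientation: row 0 is the highest frequency, time
increases left to right.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import hilbert
from scipy.signal.windows import hamming
from skimage.transform import resize

from ._colormap_data import COLORMAP_CSV

#: floor added before log compression
DB_EPS = 1e-12
#: default displayed dynamic range in dB
DEFAULT_DYNAMIC_RANGE = 80.0
#: raster size consumed by the classifier
IMAGE_SIZE = (128, 128)


def default_colormap() -> np.ndarray:
    """The package's fixed 256-entry perceptually ordered RGB table."""
    rows = [[float(v) for v in line.split(",")] for line in COLORMAP_CSV.strip().splitlines()]
    cmap = np.asarray(rows, dtype=np.float64)
    assert cmap.shape == (256, 3)
    return cmap


@dataclass
class STFTConfig:
    """Short-time Fourier transform parameters (Blackman window).

    Defaults follow the 100 Hz ECG setting: 64-sample (640 ms) window with a
    60-sample (600 ms) overlap, i.e. a 4-sample hop.
    """

    window_length: int = 64
    overlap: int = 60

    def __post_init__(self) -> None:
        if self.window_length < 2:
            raise ValueError("window_length must be >= 2")
        if not 0 <= self.overlap < self.window_length:
            raise ValueError("need 0 <= overlap < window_length")

    @property
    def hop(self) -> int:
        return self.window_length - self.overlap


@dataclass
class CWTConfig:
    """Analytic Morse wavelet CWT parameters.

    ``gamma`` is the symmetry parameter and ``time_bandwidth`` the
    time-bandwidth product P^2 = beta*gamma; the defaults (3, 60) give the
    symmetric, highly oscillatory member commonly used for physiological
    signals. Frequencies are log-spaced with ``voices_per_octave`` voices
    between ``freq_min`` and ``freq_max``.
    """

    gamma: float = 3.0
    time_bandwidth: float = 60.0
    voices_per_octave: int = 10
    freq_min: float = 0.1
    freq_max: float = 50.0

    def __post_init__(self) -> None:
        if self.freq_min <= 0 or self.freq_min >= self.freq_max:
            raise ValueError("need 0 < freq_min < freq_max")
        if self.time_bandwidth <= self.gamma:
            raise ValueError("time_bandwidth must exceed gamma")

    @property
    def beta(self) -> float:
        return self.time_bandwidth / self.gamma

    def frequencies(self) -> np.ndarray:
        """Descending log-spaced analysis frequencies (Hz)."""
        n = int(round(self.voices_per_octave * np.log2(self.freq_max / self.freq_min))) + 1
        return np.geomspace(self.freq_max, self.freq_min, n)


@dataclass
class SPWVDConfig:
    """Smoothed pseudo Wigner-Ville parameters.

    ``time_window_length`` smooths along time (suppresses oscillatory
    cross-terms), ``freq_window_length`` is the lag window (frequency
    smoothing); both odd. The surface is evaluated every
    ``time_decimation`` samples at ``fft_length/2 + 1`` one-sided
    frequencies.
    """

    time_window_length: int = 31
    freq_window_length: int = 63
    fft_length: int = 512
    time_decimation: int = 4

    def __post_init__(self) -> None:
        for name in ("time_window_length", "freq_window_length"):
            v = getattr(self, name)
            if v < 1 or v % 2 == 0:
                raise ValueError(f"{name} must be odd and >= 1")
        if self.time_decimation < 1:
            raise ValueError("time_decimation must be >= 1")
        if self.fft_length < 2 * self.freq_window_length:
            # lag window must fit inside the FFT without wrap-around
            raise ValueError("fft_length too short for freq_window_length")


@dataclass
class TFRGrid:
    """A time x frequency surface of nonnegative (or dB) intensities.

    ``values`` has shape (n_freq, n_time); ``freq_axis`` is strictly
    decreasing (image orientation, high frequency on top).
    """

    values: np.ndarray
    freq_axis: np.ndarray
    time_axis: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.freq_axis = np.asarray(self.freq_axis, dtype=np.float64)
        self.time_axis = np.asarray(self.time_axis, dtype=np.float64)
        if self.values.shape != (len(self.freq_axis), len(self.time_axis)):
            raise ValueError("values shape must be (n_freq, n_time)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("TFR values must be finite")
        if len(self.freq_axis) > 1 and not np.all(np.diff(self.freq_axis) < 0):
            raise ValueError("freq_axis must be strictly decreasing (high frequency at top)")


def blackman_window(length: int) -> np.ndarray:
    """Symmetric Blackman window w(n) = 0.42 - 0.5 cos(2 pi n/(L-1)) + 0.08 cos(4 pi n/(L-1))."""
    if length < 2:
        raise ValueError("window length must be >= 2")
    n = np.arange(length)
    return 0.42 - 0.5 * np.cos(2 * np.pi * n / (length - 1)) + 0.08 * np.cos(
        4 * np.pi * n / (length - 1)
    )


def stft_spectrogram(
    segment_samples: np.ndarray, fs: float, config: STFTConfig | None = None
) -> TFRGrid:
    """One-sided Blackman-window STFT magnitude, log-compressed to dB.

    Frames are fully contained in the signal (no padding):
    ``n_time = (N - L)//hop + 1`` and ``n_freq = L/2 + 1``.
    """
    config = config or STFTConfig()
    x = np.asarray(segment_samples, dtype=np.float64)
    L, hop = config.window_length, config.hop
    if len(x) < L:
        raise ValueError(f"input of length {len(x)} shorter than window ({L})")
    n_frames = (len(x) - L) // hop + 1
    idx = hop * np.arange(n_frames)[:, None] + np.arange(L)[None, :]
    frames = x[idx] * blackman_window(L)[None, :]
    mag = np.abs(np.fft.rfft(frames, axis=1))  # (n_frames, L//2+1)
    db = 20.0 * np.log10(mag + DB_EPS)
    freqs = np.fft.rfftfreq(L, d=1.0 / fs)
    times = (hop * np.arange(n_frames) + (L - 1) / 2.0) / fs
    return TFRGrid(values=db.T[::-1], freq_axis=freqs[::-1], time_axis=times, kind="spectrogram")


def morse_wavelet_ft(omega: np.ndarray, gamma: float, beta: float) -> np.ndarray:
    """Frequency-domain generalized Morse wavelet, peak-normalized to 1.

    Psi(w) = U(w) * (w/w_p)^beta * exp(beta/gamma * (1 - (w/w_p)^gamma)),
    with peak frequency w_p = (beta/gamma)^(1/gamma). The peak normalization
    gives an L1-type convention: a unit tone yields unit-magnitude
    coefficients at its frequency.
    """
    wp = (beta / gamma) ** (1.0 / gamma)
    w = np.maximum(omega, 0.0) / wp
    with np.errstate(divide="ignore"):
        logpsi = beta * np.log(np.where(w > 0, w, 1.0)) + (beta / gamma) * (1.0 - w**gamma)
    psi = np.where(omega > 0, np.exp(logpsi), 0.0)
    return psi


def cwt_scalogram(
    segment_samples: np.ndarray, fs: float, config: CWTConfig | None = None
) -> TFRGrid:
    """Analytic Morse CWT; intensity is the squared modulus in dB.

    Computed in the frequency domain: the signal spectrum is multiplied by
    the wavelet's (positive-frequency) transfer function scaled so its peak
    sits at each analysis frequency, then inverse-transformed. Output has
    one column per input sample.
    """
    config = config or CWTConfig()
    x = np.asarray(segment_samples, dtype=np.float64)
    if x.size == 0:
        raise ValueError("empty input")
    if config.freq_max > fs / 2:
        raise ValueError(f"freq_max {config.freq_max} exceeds Nyquist {fs / 2}")
    n = len(x)
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    # edge-replication padding softens circular boundary effects and keeps
    # constants constant (so the zero-mean wavelet annihilates them exactly)
    pad_left = (nfft - n) // 2
    xp = np.pad(x, (pad_left, nfft - n - pad_left), mode="edge")
    X = np.fft.fft(xp)
    omega = 2 * np.pi * np.fft.fftfreq(nfft)  # rad/sample
    freqs = config.frequencies()
    wp = (config.beta / config.gamma) ** (1.0 / config.gamma)
    power = np.empty((len(freqs), n))
    for i, f in enumerate(freqs):
        scale_ = wp / (2 * np.pi * f / fs)  # wavelet peak lands on f
        psi = morse_wavelet_ft(scale_ * omega, config.gamma, config.beta)
        w = np.fft.ifft(X * psi)[pad_left : pad_left + n]
        power[i] = np.abs(w) ** 2
    db = 10.0 * np.log10(power + DB_EPS)
    times = np.arange(n) / fs
    return TFRGrid(values=db, freq_axis=freqs, time_axis=times, kind="scalogram")


def spwvd(segment_samples: np.ndarray, fs: float, config: SPWVDConfig | None = None) -> TFRGrid:
    """Smoothed pseudo Wigner-Ville distribution of the analytic signal.

    W(t, f) = 2 sum_m h(m) [sum_u g(u) z(t+u+m) z*(t+u-m)] e^{-j 4 pi f m / fs}

    with Hamming smoothing windows g (time) and h (lag), both normalized.
    The real part is returned at one-sided frequencies ``k*fs/(2*Nfft)``.
    """
    config = config or SPWVDConfig()
    x = np.asarray(segment_samples, dtype=np.float64)
    if x.size == 0:
        raise ValueError("empty input")
    if len(x) < max(config.time_window_length, config.freq_window_length):
        raise ValueError("smoothing windows longer than the signal")
    z = hilbert(x)
    n = len(z)
    lh = config.freq_window_length // 2
    lg = config.time_window_length // 2
    h = hamming(config.freq_window_length) if config.freq_window_length > 1 else np.ones(1)
    g = hamming(config.time_window_length) if config.time_window_length > 1 else np.ones(1)
    g = g / g.sum()
    h = h / h[lh]

    t_idx = np.arange(0, n, config.time_decimation)
    nfft = config.fft_length
    kernel = np.zeros((len(t_idx), nfft), dtype=complex)
    zpad = np.concatenate([np.zeros(lh, complex), z, np.zeros(lh, complex)])
    # smoothed instantaneous autocorrelation: A(t, m) = sum_u g(u) z(t+u+m) z*(t+u-m)
    for mi, m in enumerate(range(-lh, lh + 1)):
        prod = zpad[lh + m : lh + m + n] * np.conj(zpad[lh - m : lh - m + n])
        smoothed = np.convolve(prod, g, mode="same") if lg > 0 else prod
        kernel[:, m % nfft] += h[mi] * smoothed[t_idx]
    surf = np.fft.fft(kernel, axis=1).real.T  # (nfft, n_times)
    k = nfft // 2 + 1
    freqs = np.arange(k) * fs / (2.0 * nfft)
    vals = surf[:k][::-1]
    times = t_idx / fs
    return TFRGrid(values=vals, freq_axis=freqs[::-1], time_axis=times, kind="spwvd")


def render_image(
    grid: TFRGrid,
    colormap: np.ndarray | None = None,
    dynamic_range: float = DEFAULT_DYNAMIC_RANGE,
    size: tuple[int, int] = IMAGE_SIZE,
) -> np.ndarray:
    """Render a TFR grid to an (H, W, 3) RGB array in [0, 1].

    Intensities are clipped to ``[max - dynamic_range, max]``, affinely
    mapped to colormap indices 0..255, looked up, then resized with
    antialiased bilinear interpolation. No axes or margins are rendered.
    A degenerate (constant) grid maps to colormap entry 0.
    """
    cmap = default_colormap() if colormap is None else np.asarray(colormap, dtype=np.float64)
    if cmap.shape != (256, 3) or cmap.min() < 0 or cmap.max() > 1:
        raise ValueError("colormap must be a (256, 3) table with entries in [0, 1]")
    v = grid.values
    hi = v.max()
    lo = hi - abs(dynamic_range)
    if hi == v.min() or hi == lo:
        idx = np.zeros(v.shape, dtype=np.intp)
    else:
        clipped = np.clip(v, lo, hi)
        idx = np.round((clipped - lo) / (hi - lo) * 255.0).astype(np.intp)
    rgb = cmap[idx]
    if size is not None and rgb.shape[:2] != tuple(size):
        rgb = resize(rgb, size, order=1, mode="reflect", anti_aliasing=True)
    return np.clip(rgb, 0.0, 1.0)


def validate_rgb(image: np.ndarray, size: tuple[int, int] = IMAGE_SIZE) -> np.ndarray:
    """Check an array is a valid (H, W, 3) image in [0, 1]; returns it."""
    image = np.asarray(image)
    if image.shape != (*size, 3):
        raise ValueError(f"expected shape {(*size, 3)}, got {image.shape}")
    if image.min() < 0 or image.max() > 1:
        raise ValueError("image values must lie in [0, 1]")
    return image
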