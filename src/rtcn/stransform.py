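"""Time–frequency imaging of heartbeats.

The primary transform is the discrete Stockwell (S-)transform

    S(tau, f) = int x(t) |f|/sqrt(2*pi) * exp(-(tau-t)^2 f^2 / 2)
                 * exp(-2*pi*i*f*t) dt,

computed through its frequency-domain form: for each analysis frequency f the
signal spectrum is shifted by f, multiplied by a Gaussian voice window
exp(-2 pi^2 nu^2 / f^2) and inverse-transformed.  The Gaussian's time-domain
standard deviation is 1/|f|, so windows narrow as frequency grows — good time
resolution at high frequency, good frequency resolution at low frequency,
and absolute phase is preserved in the complex intermediate.  The
zero-frequency row is the signal mean (the |f| prefactor vanishes at f = 0).

Rows are placed on an exact integer-Hz grid (1 Hz resolution by default) by
zero-padding the analysis FFT to a multiple of fs/df samples.  STFT and
Morlet-CWT images are provided as ablation alternatives in the same container,
and :func:`to_model_input` turns any image into the fixed 3 x side x side
tensor the classifier consumes.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy.signal import ShortTimeFFT, windows


@dataclass
class TimeFreqImage:
    """Magnitude matrix over (frequency x time) with axis vectors."""

    values: np.ndarray          # [n_freq, n_time], >= 0
    freq_axis_hz: np.ndarray
    time_axis_s: np.ndarray
    method: str                 # "stransform" | "stft" | "cwt"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.freq_axis_hz = np.asarray(self.freq_axis_hz, dtype=float)
        self.time_axis_s = np.asarray(self.time_axis_s, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (freq x time)")
        if self.values.shape != (self.freq_axis_hz.size, self.time_axis_s.size):
            raise ValueError("axis lengths do not match the value matrix")
        if np.any(self.values < 0):
            raise ValueError("magnitude image must be non-negative")
        if np.any(np.diff(self.freq_axis_hz) <= 0):
            raise ValueError("frequency axis must be strictly ascending")


def s_transform_complex(x: np.ndarray, sampling_rate_hz: float,
                        f_max_hz: float = 50.0, freq_step_hz: float = 1.0):
    """Complex discrete S-transform on an integer multiple of the df grid.

    Returns ``(S, freqs)`` where ``S`` is [n_freq, n_time] complex and rows sit
    at ``0, df, 2 df, ... <= f_max``.  Phase is retained here; the public
    :func:`s_transform` images the magnitude.
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 2:
        raise ValueError("need at least two samples")
    fs = float(sampling_rate_hz)
    nyq = fs / 2.0
    if not 0 < f_max_hz <= nyq:
        raise ValueError(f"f_max must lie in (0, Nyquist={nyq:g}] Hz")

    base = int(round(fs / freq_step_hz))
    n_fft = base * max(1, int(np.ceil(x.size / base)))
    X = np.fft.fft(x, n_fft)
    df = fs / n_fft
    freqs = np.arange(0.0, f_max_hz + 0.5 * freq_step_hz, freq_step_hz)
    nu = np.fft.fftfreq(n_fft, d=1.0 / fs)  # signed bin frequencies

    S = np.empty((freqs.size, x.size), dtype=complex)
    S[0] = np.mean(x)  # DC voice: the signal mean, constant in time
    for row, f in enumerate(freqs[1:], start=1):
        p = int(round(f / df))
        voice = np.exp(-2.0 * np.pi ** 2 * nu ** 2 / f ** 2)
        S[row] = np.fft.ifft(np.roll(X, -p) * voice)[: x.size]
    return S, freqs


def s_transform(x: np.ndarray, sampling_rate_hz: float, f_max_hz: float = 50.0,
                freq_step_hz: float = 1.0, log1p: bool = False) -> TimeFreqImage:
    """Magnitude S-transform image at 1 Hz (default) frequency resolution."""
    S, freqs = s_transform_complex(x, sampling_rate_hz, f_max_hz, freq_step_hz)
    mag = np.abs(S)
    if log1p:
        mag = np.log1p(mag)
    t = np.arange(S.shape[1]) / sampling_rate_hz
    return TimeFreqImage(mag, freqs, t, "stransform")


def stft_image(x: np.ndarray, sampling_rate_hz: float, window_s: float = 0.128,
               f_max_hz: float = 50.0) -> TimeFreqImage:
    """Fixed-window (Hann) magnitude spectrogram, rows trimmed to f <= f_max."""
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 2:
        raise ValueError("need at least two samples")
    fs = float(sampling_rate_hz)
    if not 0 < f_max_hz <= fs / 2:
        raise ValueError("f_max must lie in (0, Nyquist]")
    nperseg = min(x.size, max(8, int(round(window_s * fs))))
    hop = max(1, nperseg // 8)
    sft = ShortTimeFFT(windows.hann(nperseg, sym=False), hop=hop, fs=fs,
                       fft_mode="onesided")
    Z = sft.stft(x)
    freqs = sft.f
    keep = freqs <= f_max_hz + 1e-9
    times = sft.t(x.size)
    return TimeFreqImage(np.abs(Z[keep]), freqs[keep], times, "stft")


def cwt_image(x: np.ndarray, sampling_rate_hz: float, f_max_hz: float = 50.0,
              wavelet: str = "morl", freq_step_hz: float = 1.0) -> TimeFreqImage:
    """Morlet scalogram sampled at pseudo-frequencies df..f_max."""
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 2:
        raise ValueError("need at least two samples")
    fs = float(sampling_rate_hz)
    if not 0 < f_max_hz <= fs / 2:
        raise ValueError("f_max must lie in (0, Nyquist]")
    freqs = np.arange(freq_step_hz, f_max_hz + 0.5 * freq_step_hz, freq_step_hz)
    scales = pywt.frequency2scale(wavelet, freqs / fs)
    coeffs, _ = pywt.cwt(x, scales, wavelet)
    # row i of coeffs corresponds to scales[i], i.e. to freqs[i] (ascending)
    t = np.arange(x.size) / fs
    return TimeFreqImage(np.abs(coeffs), freqs, t, "cwt")


_METHODS = {"stransform": s_transform, "stft": stft_image, "cwt": cwt_image}


def transform_beat(samples: np.ndarray, sampling_rate_hz: float,
                   method: str = "stransform", **kwargs) -> TimeFreqImage:
    """Dispatch to one of the three time–frequency methods by name."""
    if method not in _METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {sorted(_METHODS)}")
    return _METHODS[method](samples, sampling_rate_hz, **kwargs)


def resize_bilinear(values: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    """Separable bilinear resize with corner-aligned sampling."""
    v = np.asarray(values, dtype=float)
    h, w = v.shape

    def axis_coords(n_in, n_out):
        if n_out == 1 or n_in == 1:
            return np.zeros(n_out), np.zeros(n_out, dtype=int), np.zeros(n_out, dtype=int)
        pos = np.arange(n_out) * (n_in - 1) / (n_out - 1)
        lo = np.floor(pos).astype(int)
        hi = np.minimum(lo + 1, n_in - 1)
        return pos - lo, lo, hi

    fr, rlo, rhi = axis_coords(h, out_h)
    fc, clo, chi = axis_coords(w, out_w)
    rows = v[rlo] * (1 - fr)[:, None] + v[rhi] * fr[:, None]
    return rows[:, clo] * (1 - fc)[None, :] + rows[:, chi] * fc[None, :]


def to_model_input(image: TimeFreqImage, side: int = 224) -> np.ndarray:
    """Resize to side x side, min–max normalize to [0, 1], replicate 3 channels.

    A constant-valued image (degenerate range) maps to all zeros.
    """
    if image.values.size == 0:
        raise ValueError("empty time-frequency image")
    resized = resize_bilinear(image.values, side, side)
    lo, hi = resized.min(), resized.max()
    norm = (resized - lo) / (hi - lo) if hi > lo else np.zeros_like(resized)
    return np.repeat(norm[None, :, :], 3, axis=0)
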