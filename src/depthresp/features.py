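"""Spectral analysis and per-window features of the breathing signal.

The classifier sees two features per sliding window: the dominant frequency
of the window's amplitude spectrum (the breathing rate, uninformative about
amplitude) and the window's sample standard deviation (which collapses when
breathing stops).  Windows slide at the 10 Hz label grid so each signal
sample receives the label of the window centred on it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.fft import next_fast_len, rfft, rfftfreq
from scipy.signal.windows import hann

from .extract import BreathingSignal

__all__ = [
    "Spectrum",
    "WindowSpec",
    "FeatureMatrix",
    "amplitude_spectrum",
    "dominant_frequency",
    "sliding_windows",
    "extract_features",
    "labels_to_grid",
]

#: Default search band for the dominant breathing frequency: above posture
#: drift, below the band-pass high cutoff.  Adult sleep breathing sits at
#: 0.2–0.33 Hz; the elderly range extends to 0.16–0.5 Hz.
DEFAULT_BAND = (0.05, 1.0)

_MIN_SPECTRUM_SAMPLES = 16


@dataclass
class Spectrum:
    """One-sided amplitude spectrum on an ascending 0..fs/2 frequency grid."""

    frequencies: np.ndarray
    magnitudes: np.ndarray

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.magnitudes = np.asarray(self.magnitudes, dtype=float)
        if self.frequencies.shape != self.magnitudes.shape:
            raise ValueError("frequencies and magnitudes must be aligned")

    @property
    def bin_width(self) -> float:
        return float(self.frequencies[1] - self.frequencies[0])


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry in seconds.

    Defaults (10 s length, 0.1 s step) put one window centre on every point
    of the 10 Hz classification grid while covering at least two breath
    cycles at the slowest adult rate.
    """

    length: float = 10.0
    step: float = 0.1

    def __post_init__(self) -> None:
        if self.length <= 0 or self.step <= 0:
            raise ValueError("window length and step must be positive")
        if self.step > self.length:
            raise ValueError("step must not exceed window length")


@dataclass
class FeatureMatrix:
    """Per-window feature rows (dominant frequency Hz, sample std).

    ``scaling`` holds the per-feature (mean, sd) pairs for z-scoring; they
    are stored alongside, never applied to ``values`` in place.
    """

    values: np.ndarray          # (n_windows, 2)
    center_times: np.ndarray    # (n_windows,)
    scaling: tuple[np.ndarray, np.ndarray]

    feature_names = ("dominant_frequency", "std")

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.center_times = np.asarray(self.center_times, dtype=float)
        if self.values.ndim != 2 or len(self.values) != len(self.center_times):
            raise ValueError("feature rows and center times must be aligned")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("features contain non-finite values")

    def __len__(self) -> int:
        return len(self.values)

    def zscored(self) -> np.ndarray:
        mean, sd = self.scaling
        safe_sd = np.where(sd > 0, sd, 1.0)
        return (self.values - mean) / safe_sd

    @classmethod
    def from_values(cls, values: np.ndarray, center_times: np.ndarray) -> "FeatureMatrix":
        values = np.asarray(values, dtype=float)
        # scaling accumulated in canonical row order so it is bit-identical
        # under any permutation of the input rows
        ordered = values[np.lexsort(values.T[::-1])]
        scaling = (ordered.mean(axis=0), ordered.std(axis=0))
        return cls(values=values, center_times=center_times, scaling=scaling)

    @classmethod
    def concatenate(cls, mats: list["FeatureMatrix"]) -> "FeatureMatrix":
        """Pool feature matrices; scaling is recomputed on the pooled rows."""
        values = np.vstack([m.values for m in mats])
        centers = np.concatenate([m.center_times for m in mats])
        return cls.from_values(values, centers)


def _windowed_fft_mags(rows: np.ndarray, fs: float, pad_factor: int = 8):
    """Hann-window, zero-pad and rfft a batch of signal rows; returns (freqs, mags)."""
    n = rows.shape[-1]
    taper = hann(n)
    centered = rows - rows.mean(axis=-1, keepdims=True)
    nfft = next_fast_len(pad_factor * n)
    if nfft % 2:
        nfft += 1  # even length so the grid ends exactly at fs/2
    mags = np.abs(rfft(centered * taper, n=nfft, axis=-1))
    return rfftfreq(nfft, 1.0 / fs), mags


def amplitude_spectrum(
    signal: BreathingSignal | np.ndarray,
    fs: float | None = None,
    pad_factor: int = 8,
    window: str = "hann",
) -> Spectrum:
    """One-sided amplitude spectrum of the mean-removed, tapered signal.

    The signal is zero-padded to at least ``pad_factor`` times its length so
    spectral peaks are finely interpolated.  ``window='boxcar'`` disables the
    Hann taper (raw periodogram).
    """
    if isinstance(signal, BreathingSignal):
        x, fs = signal.values, signal.fs
    else:
        x = np.asarray(signal, dtype=float)
        if fs is None:
            raise ValueError("fs is required when passing a bare array")
    if x.size < _MIN_SPECTRUM_SAMPLES:
        raise ValueError(
            f"signal too short for spectral analysis: {x.size} < {_MIN_SPECTRUM_SAMPLES}"
        )
    if window == "boxcar":
        taper = np.ones(x.size)
    elif window == "hann":
        taper = hann(x.size)
    else:
        raise ValueError(f"unknown window {window!r}")
    centered = x - x.mean()
    nfft = next_fast_len(pad_factor * x.size)
    if nfft % 2:
        nfft += 1
    mags = np.abs(rfft(centered * taper, n=nfft))
    return Spectrum(frequencies=rfftfreq(nfft, 1.0 / fs), magnitudes=mags)


def dominant_frequency(spectrum: Spectrum, band: tuple[float, float] = DEFAULT_BAND) -> float:
    """Frequency of the maximum magnitude within ``band``; ties break low."""
    f = spectrum.frequencies
    mask = (f >= band[0]) & (f <= band[1])
    if not np.any(mask):
        raise ValueError(f"band {band} contains no spectral bins")
    sub = spectrum.magnitudes[mask]
    return float(f[mask][int(np.argmax(sub))])


def sliding_windows(
    signal: BreathingSignal, spec: WindowSpec = WindowSpec()
) -> tuple[np.ndarray, np.ndarray]:
    """Overlapping windows over the signal.

    Returns ``(windows, center_times)`` where ``windows`` has shape
    ``(n_windows, window_samples)`` and each centre time is the midpoint of
    the window's time span (on the 10 Hz grid when step = 0.1 s).  The window
    count is ``floor((T − length)/step) + 1``.
    """
    x = signal.values
    wlen = int(round(spec.length * signal.fs))
    step = max(1, int(round(spec.step * signal.fs)))
    if wlen > x.size:
        raise ValueError(f"window of {wlen} samples longer than signal of {x.size}")
    views = sliding_window_view(x, wlen)[::step]
    starts = np.arange(views.shape[0]) * step
    centers = signal.t0 + starts / signal.fs + spec.length / 2.0
    return views, centers


def extract_features(
    windows: np.ndarray,
    center_times: np.ndarray,
    fs: float,
    band: tuple[float, float] = DEFAULT_BAND,
) -> FeatureMatrix:
    """Per-window (dominant frequency, sample standard deviation) pairs.

    The dominant frequency comes from each window's Hann-tapered, zero-padded
    amplitude spectrum restricted to ``band``; the standard deviation uses
    the n−1 (sample) normalisation.  Z-scoring parameters are computed over
    the produced rows and stored in the matrix, not applied.
    """
    rows = np.asarray(windows, dtype=float)
    if rows.ndim != 2:
        raise ValueError("windows must be a 2-D array")
    if rows.shape[1] < _MIN_SPECTRUM_SAMPLES:
        raise ValueError(
            f"windows of {rows.shape[1]} samples are too short for spectra"
        )
    freqs, mags = _windowed_fft_mags(rows, fs)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    if not np.any(mask):
        raise ValueError(f"band {band} contains no spectral bins")
    domfreq = freqs[mask][np.argmax(mags[:, mask], axis=1)]
    stds = rows.std(axis=1, ddof=1)
    values = np.column_stack([domfreq, stds])
    return FeatureMatrix.from_values(values, np.asarray(center_times, dtype=float))


def labels_to_grid(
    center_times: np.ndarray, window_labels: np.ndarray, grid_times: np.ndarray
) -> np.ndarray:
    """Assign each grid point the label of the nearest window centre.

    Grid points before the first / after the last centre inherit the nearest
    (edge) centre's label.
    """
    centers = np.asarray(center_times, dtype=float)
    labels = np.asarray(window_labels)
    grid = np.asarray(grid_times, dtype=float)
    if centers.size == 0:
        raise ValueError("no window centres to assign from")
    right = np.searchsorted(centers, grid)
    left = np.clip(right - 1, 0, centers.size - 1)
    right = np.clip(right, 0, centers.size - 1)
    use_right = np.abs(centers[right] - grid) < np.abs(grid - centers[left])
    idx = np.where(use_right, right, left)
    return labels[idx]
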