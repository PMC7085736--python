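"""Depth frames → uniformly sampled breathing signal.

The chain is: ROI frame differencing (the mean over the chest rectangle of
the difference of consecutive depth maps), FIR band-pass filtering
(0.01–1 Hz, covering the breathing band while rejecting the DC level and
high-frequency sensor noise), optional second-order Savitzky–Golay
smoothing, and cubic-spline resampling of the irregularly timestamped
series onto a uniform 10 Hz grid — the rate at which polysomnography
breathing channels are sampled, so depth-derived and PSG signals are
directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.interpolate import CubicSpline

from .io import DepthSequence

__all__ = [
    "RawMotionSignal",
    "FilterSpec",
    "BreathingSignal",
    "frame_difference_signal",
    "design_bandpass",
    "apply_fir",
    "savgol_smooth",
    "resample_uniform",
    "extract_from_motion",
    "extract_breathing_signal",
]


@dataclass
class RawMotionSignal:
    """Frame-difference series d(n), one sample per consecutive frame pair.

    ``d(n)`` is the ROI mean of ``D_{n+1} - D_n``; by convention each
    difference sample carries the timestamp of the *later* frame.
    """

    values: np.ndarray
    timestamps: np.ndarray
    n_frames: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if len(self.values) != self.n_frames - 1:
            raise ValueError(
                f"difference signal has {len(self.values)} samples for "
                f"{self.n_frames} frames; expected n_frames - 1"
            )
        if len(self.values) != len(self.timestamps):
            raise ValueError("values and timestamps must be aligned")

    @property
    def mean_fs(self) -> float:
        span = self.timestamps[-1] - self.timestamps[0]
        return (len(self.values) - 1) / span if span > 0 else float("nan")


@dataclass
class FilterSpec:
    """FIR band-pass coefficients b(k) with their design metadata."""

    coefficients: np.ndarray
    f1: float
    f2: float
    design_fs: float

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)

    @property
    def order(self) -> int:
        return len(self.coefficients)

    def response_at(self, freq_hz: float) -> float:
        """Magnitude response |H(f)| at a physical frequency in Hz."""
        _, h = sps.freqz(self.coefficients, worN=[2 * np.pi * freq_hz / self.design_fs])
        return float(np.abs(h[0]))


@dataclass
class BreathingSignal:
    """Uniformly sampled breathing signal (canonical rate 10 Hz)."""

    values: np.ndarray
    fs: float = 10.0
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("breathing signal must be finite")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.values)) / self.fs

    @property
    def duration(self) -> float:
        return (len(self.values) - 1) / self.fs


def frame_difference_signal(seq: DepthSequence) -> RawMotionSignal:
    """Mean ROI change between consecutive frames:
    ``d(n) = (1/(R·S)) · Σᵢⱼ (D_{n+1}(i,j) − D_n(i,j))`` for n = 0..N−2.
    """
    if seq.n_frames < 2:
        raise ValueError("need at least two frames to form a difference signal")
    means = seq.roi_view().astype(np.float64).mean(axis=(1, 2))
    return RawMotionSignal(
        values=np.diff(means), timestamps=seq.timestamps[1:], n_frames=seq.n_frames
    )


def design_bandpass(
    M: int = 1001, f1: float = 0.01, f2: float = 1.0, design_fs: float = 30.0
) -> FilterSpec:
    """Windowed-sinc band-pass with exact DC rejection.

    A Hamming-windowed FIR band-pass of odd length ``M`` is designed for
    cutoffs ``(f1, f2)`` at ``design_fs``, then the coefficients are shifted
    by their mean so Σb(k) = 0 exactly — the mean signal level is rejected
    regardless of filter length.  The low cutoff of 0.01 Hz needs a long
    filter (default M = 1001) for a usable transition band.
    """
    if M % 2 == 0:
        raise ValueError(f"filter length M={M} must be odd")
    if not 0 < f1 < f2 < design_fs / 2:
        raise ValueError(
            f"need 0 < f1 < f2 < fs/2; got f1={f1}, f2={f2}, fs={design_fs}"
        )
    b = sps.firwin(M, [f1, f2], pass_zero=False, fs=design_fs, window="hamming")
    b = b - b.mean()
    return FilterSpec(coefficients=b, f1=f1, f2=f2, design_fs=design_fs)


def apply_fir(
    values: np.ndarray, spec: FilterSpec | np.ndarray, center: bool = True
) -> np.ndarray:
    """Convolve with b(k): ``y(n) = Σ_k b(k) d(n−k)`` after reflective padding.

    With ``center=True`` (default) the signal is padded by (M−1)/2 samples on
    each side and the warm-up discarded, which cancels the (M−1)/2-sample
    group delay of the linear-phase kernel so output samples stay aligned
    with their timestamps.  ``center=False`` pads M−1 samples at the head
    only (strictly causal form).  Output length equals input length.
    """
    b = spec.coefficients if isinstance(spec, FilterSpec) else np.asarray(spec, float)
    x = np.asarray(values, dtype=float)
    if x.size < 1:
        raise ValueError("empty input signal")
    M = len(b)
    if M == 1:
        return x * b[0]
    if center:
        left = (M - 1) // 2
        pads = (left, M - 1 - left)
    else:
        pads = (M - 1, 0)
    if x.size >= 2:
        xp = np.pad(x, pads, mode="reflect")
    else:
        xp = np.pad(x, pads, mode="edge")
    return np.convolve(xp, b, mode="valid")


def savgol_smooth(values: np.ndarray, window: int = 11, polyorder: int = 2) -> np.ndarray:
    """Savitzky–Golay smoothing: local least-squares polynomial fit per window.

    Length-preserving; edges are handled by fitting the boundary polynomial
    to the first/last window, so exact polynomials up to ``polyorder`` are
    reproduced everywhere.
    """
    if window % 2 == 0:
        raise ValueError(f"window {window} must be odd")
    if window <= polyorder:
        raise ValueError(f"window {window} must exceed polyorder {polyorder}")
    return sps.savgol_filter(np.asarray(values, float), window, polyorder, mode="interp")


def resample_uniform(
    values: np.ndarray, timestamps: np.ndarray, fs: float = 10.0
) -> BreathingSignal:
    """Cubic-spline resampling onto the uniform grid t₀, t₀+1/fs, …, ≤ t_last.

    The spline interpolates the irregular samples exactly at their knots and
    is never extrapolated beyond the last timestamp.
    """
    x = np.asarray(values, dtype=float)
    t = np.asarray(timestamps, dtype=float)
    if x.size != t.size:
        raise ValueError("values and timestamps must be aligned")
    if x.size < 4:
        raise ValueError("cubic-spline resampling needs at least 4 samples")
    dt = np.diff(t)
    if np.any(dt == 0):
        raise ValueError("duplicate timestamps")
    if np.any(dt < 0):
        raise ValueError("timestamps must be strictly increasing")
    spline = CubicSpline(t, x)
    n_out = int(np.floor((t[-1] - t[0]) * fs + 1e-9)) + 1
    grid = t[0] + np.arange(n_out) / fs
    return BreathingSignal(values=spline(grid), fs=fs, t0=float(t[0]))


def extract_from_motion(
    values: np.ndarray,
    timestamps: np.ndarray,
    fs: float = 10.0,
    filter_len: int = 1001,
    f1: float = 0.01,
    f2: float = 1.0,
    smooth: bool = True,
    savgol_window: int = 11,
    filter_before_resample: bool = True,
) -> BreathingSignal:
    """Band-pass, smooth and resample a raw motion signal.

    With ``filter_before_resample=True`` (the default processing order) the
    FIR filter runs at the native frame rate, treating the jittered samples
    as uniform at the record's mean FPS — an approximation that is accurate
    for the mild jitter of these sensors; set the flag False to resample
    first and filter on the uniform 10 Hz grid instead.
    """
    x = np.asarray(values, dtype=float)
    t = np.asarray(timestamps, dtype=float)
    if filter_before_resample:
        span = t[-1] - t[0]
        native_fs = (len(x) - 1) / span if span > 0 else fs
        design_fs = max(native_fs, 2.5 * f2)
        spec = design_bandpass(filter_len, f1, f2, design_fs)
        y = apply_fir(x, spec)
        if smooth:
            y = savgol_smooth(y, savgol_window)
        return resample_uniform(y, t, fs)
    sig = resample_uniform(x, t, fs)
    spec = design_bandpass(filter_len, f1, f2, design_fs=fs)
    y = apply_fir(sig.values, spec)
    if smooth:
        y = savgol_smooth(y, savgol_window)
    return BreathingSignal(values=y, fs=fs, t0=sig.t0)


def extract_breathing_signal(seq: DepthSequence, **kwargs) -> BreathingSignal:
    """Full chain: frame differencing then :func:`extract_from_motion`."""
    raw = frame_difference_signal(seq)
    return extract_from_motion(raw.values, raw.timestamps, **kwargs)
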