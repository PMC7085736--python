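"""Synthetic depth recordings of a sleeping, breathing person.

The generator emulates what a depth camera aimed at a sleeper's chest sees:
a rectangular chest region whose distance to the sensor oscillates
sinusoidally at the breathing rate (adults breathe at 0.26–0.33 Hz during
sleep; the elderly span 0.16–0.5 Hz), with apnea events rendered as
amplitude collapses of the oscillation, additive per-pixel sensor noise,
optional slow posture drift, and frame timestamps whose spacing jitters the
way consumer depth sensors' do (3–45 FPS depending on device).

Every function is deterministic given its ``seed``; a dataset is always
emitted together with its event ground truth so downstream evaluation needs
no transformation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .io import (
    APNEA_TYPES,
    AnnotationTrack,
    ApneaAnnotation,
    DepthSequence,
    _validate_roi,
    write_annotations,
    write_depth_stack,
    write_signal_csv,
)

__all__ = [
    "BreathingProfile",
    "ApneaEventSpec",
    "SensorProfile",
    "SENSORS",
    "synthesize_waveform",
    "jitter_timestamps",
    "render_depth_sequence",
    "random_event_schedule",
    "generate_record",
    "write_record",
]

#: Default attenuation (fraction of breathing amplitude remaining during an
#: event) per apnea category: central apnea is near-total cessation of effort,
#: obstructive apnea is continued effort against a blocked airway.
_DEFAULT_ATTENUATION = {"central": 0.1, "obstructive": 0.4, "mixed": 0.25}

#: Frequency of the slow "effort" modulation superimposed during obstructive
#: episodes — deliberately below the band-pass low cutoff region so it does
#: not masquerade as breathing.
_EFFORT_MOD_HZ = 0.05


@dataclass(frozen=True)
class BreathingProfile:
    """Kinematics of the simulated chest surface.

    Parameters
    ----------
    rate
        Breathing frequency in Hz.  Default 0.28 Hz (≈17 breaths/min, the
        middle of the adult sleep band).
    amplitude
        Peak chest displacement in depth units (mm).  Depth sensors resolve
        millimetres (reported distance errors: 3 mm for RealSense R200, 6 mm
        for Kinect v2), so 4–10 mm of chest excursion is a realistic scale.
    baseline_depth
        Mean chest-to-sensor distance in mm.
    noise_sd
        Additive Gaussian sensor noise, per pixel, in mm.
    drift_sd
        Scale of a Gaussian random-walk posture drift, mm per √s.
    """

    rate: float = 0.28
    amplitude: float = 6.0
    baseline_depth: float = 1500.0
    noise_sd: float = 1.2
    drift_sd: float = 0.0

    def __post_init__(self) -> None:
        if not 0.05 <= self.rate <= 2.0:
            raise ValueError(f"breathing rate {self.rate} Hz outside [0.05, 2.0]")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")
        if self.noise_sd < 0 or self.drift_sd < 0:
            raise ValueError("noise_sd and drift_sd must be non-negative")


@dataclass(frozen=True)
class ApneaEventSpec:
    """One scheduled apnea event in a synthetic record.

    ``attenuation`` is the fraction of breathing amplitude remaining during
    the event (0 = total cessation).  Defaults per type follow the clinical
    picture: central < 0.3, obstructive < 0.6.  Durations should stay within
    the envelope observed in annotated clinical events (5–44.5 s) unless an
    override is intended.
    """

    type: str
    start: float
    duration: float
    attenuation: float | None = None

    def __post_init__(self) -> None:
        if self.type not in APNEA_TYPES:
            raise ValueError(
                f"unknown apnea type {self.type!r}; allowed: {', '.join(APNEA_TYPES)}"
            )
        if self.duration <= 0:
            raise ValueError("event duration must be positive")
        att = self.attenuation
        if att is None:
            object.__setattr__(self, "attenuation", _DEFAULT_ATTENUATION[self.type])
        elif not 0.0 <= att <= 1.0:
            raise ValueError(f"attenuation {att} outside [0, 1]")

    @property
    def end(self) -> float:
        return self.start + self.duration

    def to_annotation(self) -> ApneaAnnotation:
        return ApneaAnnotation(self.start, self.end, self.type)


@dataclass(frozen=True)
class SensorProfile:
    """Frame-rate and geometry model of one depth sensor.

    ``fps_min``/``fps_max`` bound the instantaneous frame rate; ``mean_fps``
    is the long-run average.  ``fps_jitter`` selects the timestamp model:
    ``none`` (uniform grid), ``uniform`` (bounded symmetric interval jitter)
    or ``heavy_tail`` (mostly fast frames with occasional long gaps, the
    behaviour of sensors that time-share depth output with other processing).
    """

    name: str
    mean_fps: float
    fps_min: float
    fps_max: float
    fps_jitter: str = "uniform"
    rows: int = 64
    cols: int = 64

    def __post_init__(self) -> None:
        if not 3.0 <= self.mean_fps <= 90.0:
            raise ValueError(f"mean_fps {self.mean_fps} outside [3, 90]")
        if not 0 < self.fps_min <= self.mean_fps <= self.fps_max:
            raise ValueError("need fps_min <= mean_fps <= fps_max")
        if self.fps_jitter not in ("none", "uniform", "heavy_tail"):
            raise ValueError(f"unknown jitter model {self.fps_jitter!r}")
        if self.rows < 1 or self.cols < 1:
            raise ValueError("frame must have at least one row and column")


#: Frame-rate profiles of the five depth sensors evaluated for sleep
#: monitoring (observed FPS range and mean per device).  Kinect v2 shares its
#: depth pipeline with skeletal tracking, hence the heavy-tailed frame gaps.
SENSORS: dict[str, SensorProfile] = {
    "kinect2": SensorProfile("kinect2", 20.0, 3.0, 29.0, "heavy_tail", 424, 512),
    "sr300": SensorProfile("sr300", 35.0, 25.0, 45.0, "uniform", 480, 640),
    "r200": SensorProfile("r200", 33.0, 25.0, 43.0, "uniform", 468, 628),
    "d415": SensorProfile("d415", 30.0, 27.0, 33.0, "uniform", 720, 1280),
    "d435": SensorProfile("d435", 30.0, 25.0, 37.0, "uniform", 480, 848),
}


def _check_events(events: Sequence[ApneaEventSpec], duration: float) -> list[ApneaEventSpec]:
    evs = sorted(events, key=lambda e: e.start)
    for e in evs:
        if e.start < 0 or e.end > duration:
            raise ValueError(f"event [{e.start}, {e.end}] outside record [0, {duration}]")
    for a, b in zip(evs, evs[1:]):
        if b.start < a.end:
            raise ValueError(
                f"overlapping events: [{a.start}, {a.end}] and [{b.start}, {b.end}]"
            )
    return evs


def synthesize_waveform(
    profile: BreathingProfile,
    events: Sequence[ApneaEventSpec],
    duration: float,
    timestamps: np.ndarray,
    seed: int = 0,
) -> np.ndarray:
    """Chest-displacement series (mm, positive toward the sensor) on ``timestamps``.

    Outside events the displacement is ``amplitude*sin(2π*rate*t)`` plus drift
    and noise; inside an event the sinusoidal term is scaled by the event's
    attenuation.  Obstructive episodes additionally carry a slow
    (0.05 Hz) modulation of the residual effort; a mixed event behaves like a
    central one in its first half and an obstructive one in its second.
    """
    t = np.asarray(timestamps, dtype=float)
    if t.size == 0:
        raise ValueError("timestamps must be non-empty")
    if t.size > 1 and not np.all(np.diff(t) > 0):
        raise ValueError("timestamps must be strictly increasing")
    evs = _check_events(events, duration)

    envelope = np.ones_like(t)
    for e in evs:
        inside = (t >= e.start) & (t < e.end)
        if not np.any(inside):
            continue
        scale = np.full(inside.sum(), e.attenuation)
        ti = t[inside]
        if e.type == "obstructive":
            scale = scale * (1.0 + 0.5 * np.sin(2 * np.pi * _EFFORT_MOD_HZ * (ti - e.start)))
        elif e.type == "mixed":
            second_half = ti >= e.start + e.duration / 2
            mod = 1.0 + 0.5 * np.sin(2 * np.pi * _EFFORT_MOD_HZ * (ti - e.start))
            scale = np.where(second_half, scale * mod, scale)
        envelope[inside] = scale

    rng = np.random.default_rng(seed)
    series = profile.amplitude * envelope * np.sin(2 * np.pi * profile.rate * t)
    if profile.drift_sd > 0 and t.size > 1:
        steps = rng.normal(0.0, profile.drift_sd, t.size - 1) * np.sqrt(np.diff(t))
        series[1:] += np.cumsum(steps)
    if profile.noise_sd > 0:
        series += rng.normal(0.0, profile.noise_sd, t.size)
    return series


def jitter_timestamps(sensor: SensorProfile, duration: float, seed: int = 0) -> np.ndarray:
    """Frame timestamps over ``[0, duration)`` under the sensor's jitter model.

    The empirical mean FPS stays within 10% of ``sensor.mean_fps``; for the
    ``uniform`` model every instantaneous FPS lies inside
    ``[fps_min, fps_max]``, while ``heavy_tail`` mixes near-maximal frame
    rates with occasional gap multipliers so the instantaneous rate straddles
    the declared range.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    mean_dt = 1.0 / sensor.mean_fps
    n_est = int(np.ceil(duration * sensor.mean_fps * 1.5)) + 16

    if sensor.fps_jitter == "none":
        return np.arange(0.0, duration - 1e-12, mean_dt)

    if sensor.fps_jitter == "uniform":
        # relative jitter bounded so 1/dt stays inside [fps_min, fps_max]
        j = min(1.0 - sensor.mean_fps / sensor.fps_max,
                sensor.mean_fps / sensor.fps_min - 1.0)
        j = max(j, 0.0)
        dts = mean_dt * (1.0 + rng.uniform(-j, j, n_est))
    else:  # heavy_tail
        base = (1.0 / sensor.fps_max) * rng.uniform(0.9, 1.1, n_est)
        multipliers = np.array([4.0, 6.0, 8.0, 10.0])
        # gap probability chosen so the expected interval matches mean_fps
        p = (sensor.fps_max / sensor.mean_fps - 1.0) / (multipliers.mean() - 1.0)
        p = float(np.clip(p, 0.0, 1.0))
        gaps = rng.random(n_est) < p
        mult = np.where(gaps, rng.choice(multipliers, n_est), 1.0)
        dts = base * mult

    t = np.concatenate([[0.0], np.cumsum(dts)])
    return t[t < duration]


def render_depth_sequence(
    waveform: np.ndarray,
    timestamps: np.ndarray,
    sensor: SensorProfile,
    roi: Sequence[int],
    baseline: float = 1500.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> DepthSequence:
    """Render a displacement series into a uint16 depth-frame stack.

    Inside the ROI every pixel reads ``baseline − displacement + noise``
    (the chest moves toward the sensor when it rises); outside the ROI the
    scene is static at ``baseline + noise``.  Values are clipped to the
    sensor's 16-bit range and quantized to whole millimetres.
    """
    w = np.asarray(waveform, dtype=float)
    t = np.asarray(timestamps, dtype=float)
    if w.shape != t.shape:
        raise ValueError("waveform and timestamps must be aligned")
    r0, r1, c0, c1 = _validate_roi(roi, sensor.rows, sensor.cols)
    rng = np.random.default_rng(seed)

    frames = np.full((w.size, sensor.rows, sensor.cols), float(baseline))
    frames[:, r0:r1, c0:c1] -= w[:, None, None]
    if noise_sd > 0:
        frames += rng.normal(0.0, noise_sd, frames.shape)
    frames = np.clip(np.rint(frames), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    return DepthSequence(frames=frames, timestamps=t, roi=(r0, r1, c0, c1))


def random_event_schedule(
    duration: float,
    n_events: int,
    rng: np.random.Generator,
    duration_range: tuple[float, float] = (12.0, 37.0),
    attenuation_range: tuple[float, float] = (0.02, 0.2),
    types: Sequence[str] = ("central", "obstructive"),
    margin: float = 30.0,
    min_gap: float = 60.0,
) -> list[ApneaEventSpec]:
    """Place ``n_events`` non-overlapping events with at least ``min_gap`` between them.

    Events are jittered within equal time slots so placement is random but the
    spacing guarantee is deterministic.  Default durations span the central /
    obstructive clinical range (12–37 s).
    """
    usable = duration - 2 * margin
    slot = usable / n_events
    if slot < duration_range[1] + min_gap:
        raise ValueError(
            f"cannot fit {n_events} events of up to {duration_range[1]} s with "
            f"{min_gap} s gaps into {duration} s"
        )
    events = []
    for i in range(n_events):
        dur = rng.uniform(*duration_range)
        att = rng.uniform(*attenuation_range)
        start = margin + i * slot + rng.uniform(0.0, slot - dur - min_gap)
        events.append(
            ApneaEventSpec(type=types[i % len(types)], start=float(start),
                           duration=float(dur), attenuation=float(att))
        )
    return events


def generate_record(
    profile: BreathingProfile,
    sensor: SensorProfile,
    duration: float,
    events: Sequence[ApneaEventSpec],
    seed: int = 0,
    frame_shape: tuple[int, int] | None = (24, 24),
    roi: Sequence[int] | None = (4, 20, 4, 20),
) -> tuple[DepthSequence, AnnotationTrack, np.ndarray, np.ndarray]:
    """Full synthetic recording: depth stack plus ground truth.

    ``profile.noise_sd`` is applied per pixel at render time (so the ROI mean
    enjoys the 1/√(R·S) averaging a real chest patch gets), not to the
    waveform.  ``frame_shape`` overrides the sensor's native resolution with
    a small frame for tractable simulation; pass ``None`` to render at native
    size.  Returns ``(sequence, annotations, timestamps, clean_waveform)``.
    """
    if frame_shape is not None:
        sensor = replace(sensor, rows=frame_shape[0], cols=frame_shape[1])
    if roi is None:
        roi = (0, sensor.rows, 0, sensor.cols)
    base = int(seed) % (2**31 - 8)
    t = jitter_timestamps(sensor, duration, seed=base + 1)
    clean = synthesize_waveform(
        replace(profile, noise_sd=0.0), events, duration, t, seed=base + 2
    )
    seq = render_depth_sequence(
        clean, t, sensor, roi,
        baseline=profile.baseline_depth, noise_sd=profile.noise_sd, seed=base + 3,
    )
    track = AnnotationTrack([e.to_annotation() for e in events])
    return seq, track, t, clean


def write_record(
    out_dir: str | Path,
    seq: DepthSequence,
    annotations: AnnotationTrack,
    waveform: np.ndarray | None = None,
    prefix: str = "record",
) -> dict[str, Path]:
    """Write a generated recording and its ground truth to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "stack": out / f"{prefix}.bin",
        "sidecar": out / f"{prefix}.json",
        "timestamps": out / f"{prefix}_timestamps.csv",
        "annotations": out / f"{prefix}_annotations.csv",
    }
    write_depth_stack(seq, paths["stack"], paths["sidecar"], paths["timestamps"])
    write_annotations(annotations, paths["annotations"])
    if waveform is not None:
        paths["waveform"] = out / f"{prefix}_waveform.csv"
        write_signal_csv(seq.timestamps, waveform, paths["waveform"])
    return paths
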