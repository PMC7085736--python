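"""End-to-end wiring: simulate → extract → features → train → classify → evaluate.

Two entry points live here.  :func:`run_record_pipeline` processes one depth
recording with known annotations all the way to per-sample metrics and
per-event detection (training the classifier on segments built from the
annotations, as a sleep lab would from specialist marks).
:func:`run_pipeline` is the config-file driven variant used by the ``run``
CLI subcommand, writing every intermediate artifact to a run directory.

:func:`run_benchmark` generates a cohort of synthetic records at the benchmark
conditions (0.25 Hz breathing, 4–5 apnea events of 12–37 s per record with
attenuation ≤ 0.2, per-pixel noise 0.2× the 6 mm chest amplitude, RealSense
R200 frame-rate profile) and aggregates detection and per-sample accuracy
over the cohort.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml

from .classify import (
    NORMAL,
    TrainConfig,
    classify_signal,
    map_clusters_to_classes,
    predict_cluster,
    train_competitive,
    train_kmeans,
)
from .evaluate import (
    ConfusionMatrix,
    EventDetectionReport,
    MetricsReport,
    _segment_features,
    build_training_segments,
    compute_metrics,
    confusion_matrix,
    detect_events,
)
from .extract import BreathingSignal, extract_breathing_signal
from .features import FeatureMatrix, WindowSpec, labels_to_grid
from .io import AnnotationTrack, DepthSequence, write_signal_csv
from .synth import (
    SENSORS,
    BreathingProfile,
    generate_record,
    random_event_schedule,
    write_record,
)

__all__ = [
    "RecordResult",
    "RunConfig",
    "run_record_pipeline",
    "generate_benchmark_record",
    "run_benchmark",
    "run_pipeline",
]

_SEED_MOD = 2**31 - 101  # keep derived seeds comfortably below 2**31


@dataclass
class RecordResult:
    """Everything the pipeline derives from one annotated recording."""

    signal: BreathingSignal
    labels: np.ndarray
    detection: EventDetectionReport
    segment_cm: ConfusionMatrix
    segment_metrics: MetricsReport
    kmeans_cm: ConfusionMatrix | None = None
    kmeans_metrics: MetricsReport | None = None
    n_segments: int = 0


def run_record_pipeline(
    seq: DepthSequence,
    annotations: AnnotationTrack,
    seed: int = 0,
    window: WindowSpec = WindowSpec(),
    epochs: int = 1000,
    with_kmeans_baseline: bool = False,
    **extract_kwargs,
) -> RecordResult:
    """Process one recording: extract signal, train on annotation segments,
    classify the whole record, and score both per-sample and per-event.

    The competitive net trains on the pooled features of the training
    segments (z-scored internally); the optional K-means baseline trains on
    the same rows in raw units.  Per-sample metrics are computed on the
    segments — the spans where specialist-style truth exists.
    """
    signal = extract_breathing_signal(seq, **extract_kwargs)
    segset = build_training_segments(signal, annotations)
    if not segset.segments:
        raise ValueError("no usable training segments (all events excluded)")
    seg_feats = [_segment_features(s, window) for s in segset]
    feats = FeatureMatrix.concatenate(seg_feats)

    net = train_competitive(feats, TrainConfig(epochs=epochs, seed=int(seed) % _SEED_MOD))
    net.class_of_cluster = map_clusters_to_classes(net.weights_original_units())

    labels = classify_signal(net, signal, window)
    detection = detect_events(labels, signal.times, annotations)

    cm = ConfusionMatrix(0, 0, 0, 0)
    for seg in segset:
        pred = classify_signal(net, seg.as_signal(), window)
        cm = cm + confusion_matrix(pred, seg.truth)

    kmeans_cm = kmeans_metrics = None
    if with_kmeans_baseline:
        km = train_kmeans(feats.values, k=2, seed=int(seed) % _SEED_MOD)
        km_map = map_clusters_to_classes(km.centroids)
        kmeans_cm = ConfusionMatrix(0, 0, 0, 0)
        for seg, sf in zip(segset, seg_feats):
            d2 = ((sf.values[:, None, :] - km.centroids[None, :, :]) ** 2).sum(axis=2)
            wl = np.array([km_map[c] for c in np.argmin(d2, axis=1)], dtype=object)
            pred = labels_to_grid(sf.center_times, wl, seg.times)
            kmeans_cm = kmeans_cm + confusion_matrix(pred, seg.truth)
        kmeans_metrics = compute_metrics(kmeans_cm)

    return RecordResult(
        signal=signal,
        labels=labels,
        detection=detection,
        segment_cm=cm,
        segment_metrics=compute_metrics(cm),
        kmeans_cm=kmeans_cm,
        kmeans_metrics=kmeans_metrics,
        n_segments=len(segset.segments),
    )


def generate_benchmark_record(
    seed: int,
    duration: float = 900.0,
    rate: float = 0.25,
    amplitude: float = 6.0,
    noise_frac: float = 0.2,
    sensor: str = "r200",
    attenuation_max: float = 0.2,
    event_duration_range: tuple[float, float] = (12.0, 37.0),
    n_events: int | None = None,
) -> tuple[DepthSequence, AnnotationTrack]:
    """One synthetic benchmark record at the benchmark conditions.

    15 minutes of 0.25 Hz breathing with 4–5 central/obstructive events of
    12–37 s, amplitude attenuation at most 0.2, rendered as 24×24 depth
    frames (16×16 chest ROI) with per-pixel noise ``noise_frac × amplitude``
    under the chosen sensor's frame-rate jitter.
    """
    base = int(seed) % _SEED_MOD
    rng = np.random.default_rng(base)
    if n_events is None:
        n_events = int(rng.integers(4, 6))
    events = random_event_schedule(
        duration, n_events, rng,
        duration_range=event_duration_range,
        attenuation_range=(0.02, attenuation_max),
    )
    profile = BreathingProfile(rate=rate, amplitude=amplitude,
                               noise_sd=noise_frac * amplitude)
    seq, track, _, _ = generate_record(
        profile, SENSORS[sensor], duration, events, seed=base + 10
    )
    return seq, track


def run_benchmark(
    n_records: int = 20,
    base_seed: int = 1,
    with_kmeans_baseline: bool = True,
    **record_kwargs,
) -> dict:
    """Detection rate and per-sample metrics over a cohort of synthetic records.

    Returns a dict with the pooled event-detection percentage, pooled
    competitive-net confusion/metrics, and (optionally) the pooled
    unscaled-feature K-means baseline metrics.
    """
    total_events = detected_events = 0
    cm_nn = ConfusionMatrix(0, 0, 0, 0)
    cm_km = ConfusionMatrix(0, 0, 0, 0)
    per_record = []
    for i in range(n_records):
        rec_seed = (int(base_seed) * 100003 + i * 9973) % _SEED_MOD
        seq, track = generate_benchmark_record(rec_seed, **record_kwargs)
        res = run_record_pipeline(
            seq, track, seed=rec_seed + 1, with_kmeans_baseline=with_kmeans_baseline
        )
        total_events += res.detection.total_count
        detected_events += res.detection.detected_count
        cm_nn = cm_nn + res.segment_cm
        if with_kmeans_baseline:
            cm_km = cm_km + res.kmeans_cm
        per_record.append(
            {
                "seed": rec_seed,
                "events": res.detection.total_count,
                "detected": res.detection.detected_count,
                "f1": res.segment_metrics.f1,
            }
        )
    out = {
        "n_records": n_records,
        "total_events": total_events,
        "detected_events": detected_events,
        "detected_percent": 100.0 * detected_events / total_events if total_events else None,
        "nn_confusion": cm_nn,
        "nn_metrics": compute_metrics(cm_nn),
        "per_record": per_record,
    }
    if with_kmeans_baseline:
        out["kmeans_confusion"] = cm_km
        out["kmeans_metrics"] = compute_metrics(cm_km)
    return out


# ---------------------------------------------------------------------------
# config-driven run


@dataclass
class RunConfig:
    """Flat configuration for a full simulated run; unknown keys are rejected."""

    seed: int = 1
    duration_s: float = 600.0
    rate_hz: float = 0.28
    amplitude_mm: float = 6.0
    noise_sd_mm: float = 1.2
    sensor: str = "r200"
    n_events: int = 3
    event_min_s: float = 12.0
    event_max_s: float = 37.0
    attenuation_max: float = 0.2
    fs_hz: float = 10.0
    window_s: float = 10.0
    step_s: float = 0.1
    epochs: int = 1000

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(
                f"unknown config keys: {sorted(unknown)}; known keys: {sorted(known)}"
            )
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute the whole chain per the config; write artifacts and a report.

    The run directory receives the rendered recording, ground truth, the
    extracted signal, per-sample labels, the effective config, and
    ``report.json`` with the confusion matrix, metrics (percent, one
    decimal) and the event-detection summary.  Reproducible bit-for-bit for
    a fixed config: all stage seeds derive from ``config.seed`` by fixed
    offsets.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")

    base = int(config.seed) % _SEED_MOD
    rng = np.random.default_rng(base)
    if config.n_events > 0:
        events = random_event_schedule(
            config.duration_s, config.n_events, rng,
            duration_range=(config.event_min_s, config.event_max_s),
            attenuation_range=(0.02, config.attenuation_max),
        )
    else:
        events = []
    profile = BreathingProfile(
        rate=config.rate_hz, amplitude=config.amplitude_mm, noise_sd=config.noise_sd_mm
    )
    seq, track, _, clean = generate_record(
        profile, SENSORS[config.sensor], config.duration_s, events, seed=base + 10
    )
    write_record(out, seq, track, waveform=clean)

    window = WindowSpec(length=config.window_s, step=config.step_s)
    signal = extract_breathing_signal(seq, fs=config.fs_hz)
    write_signal_csv(signal.times, signal.values, out / "signal.csv")

    if events:
        result = run_record_pipeline(
            seq, track, seed=base + 20, window=window, epochs=config.epochs
        )
        labels = result.labels
        report = {
            "confusion_matrix": asdict(result.segment_cm),
            "metrics_percent": result.segment_metrics.as_dict(),
            "events": {
                "total": result.detection.total_count,
                "detected": result.detection.detected_count,
                "events_per_hour": round(result.detection.events_per_hour, 3),
            },
            "n_segments": result.n_segments,
        }
    else:
        # no events to train on: classify against a net trained on a reference
        # simulated record, then report event counts only
        ref_seq, ref_track = generate_benchmark_record(base + 30, duration=600.0)
        net_signal = extract_breathing_signal(ref_seq)
        segset = build_training_segments(net_signal, ref_track)
        feats = FeatureMatrix.concatenate([_segment_features(s, window) for s in segset])
        net = train_competitive(feats, TrainConfig(epochs=config.epochs, seed=base + 32))
        net.class_of_cluster = map_clusters_to_classes(net.weights_original_units())
        labels = classify_signal(net, signal, window)
        detection = detect_events(labels, signal.times, track)
        report = {
            "confusion_matrix": None,
            "metrics_percent": None,
            "events": {
                "total": 0,
                "detected": 0,
                "events_per_hour": round(detection.events_per_hour, 3),
            },
            "n_segments": 0,
        }

    import pandas as pd

    pd.DataFrame({"t_s": signal.times, "label": labels}).to_csv(
        out / "labels.csv", index=False
    )
    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True) + "\n")
    return report
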