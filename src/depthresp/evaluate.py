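"""Evaluation: training segments, confusion-matrix metrics, event detection.

Two complementary views of classifier quality are computed.  Per-sample
metrics compare the 10 Hz label sequence against specialist-style
annotations sample by sample (sensitivity TPR = TP/(TP+FN), specificity
TNR = TN/(TN+FP), precision PPV = TP/(TP+FP), accuracy
ACC = (TP+TN)/(TP+TN+FP+FN), F1 = 2·PPV·TPR/(PPV+TPR) = 2TP/(2TP+FP+FN),
apnea being the positive class).  Per-event detection asks the clinically
coarser question — was each annotated event overlapped by any predicted
apnea run — which feeds the events-per-hour severity index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classify import APNEA, NORMAL, CompetitiveNet, TrainConfig, classify_signal, \
    map_clusters_to_classes, train_competitive
from .extract import BreathingSignal
from .features import FeatureMatrix, WindowSpec, extract_features, sliding_windows
from .io import AnnotationTrack, ApneaAnnotation

__all__ = [
    "Segment",
    "SegmentSet",
    "ConfusionMatrix",
    "MetricsReport",
    "EventDetectionReport",
    "labels_from_annotations",
    "build_training_segments",
    "confusion_matrix",
    "compute_metrics",
    "detect_events",
    "cross_validate",
]


@dataclass
class Segment:
    """One training segment: an annotated event with margins of normal breathing."""

    values: np.ndarray
    fs: float
    t0: float
    truth: np.ndarray          # per-sample 'apnea'/'normal'
    event: ApneaAnnotation

    def as_signal(self) -> BreathingSignal:
        return BreathingSignal(values=self.values, fs=self.fs, t0=self.t0)

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.values)) / self.fs


@dataclass
class SegmentSet:
    segments: list[Segment]
    excluded: list[tuple[ApneaAnnotation, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self):
        return iter(self.segments)


def labels_from_annotations(times: np.ndarray, annotations: AnnotationTrack) -> np.ndarray:
    """Per-sample truth labels: apnea inside any annotated [start, end) span."""
    t = np.asarray(times, dtype=float)
    apnea = np.zeros(t.shape, dtype=bool)
    for e in annotations:
        apnea |= (t >= e.start) & (t < e.end)
    return np.where(apnea, APNEA, NORMAL).astype(object)


def build_training_segments(
    signal: BreathingSignal,
    annotations: AnnotationTrack,
    margin: float = 25.0,
    min_gap: float = 25.0,
) -> SegmentSet:
    """Cut one segment per annotated event: the event plus ``margin`` seconds
    of surrounding signal on each side (clipped to the record).

    Events with a neighbour starting or ending within ``min_gap`` seconds of
    their span are excluded from training (their margins would not be clean
    normal breathing) and listed with the reason.  Truth labels mark the
    annotated span apnea and the margins normal.
    """
    t_start = signal.t0
    t_end = signal.t0 + (len(signal.values) - 1) / signal.fs
    events = list(annotations)
    for e in events:
        if e.start < t_start - 1e-9 or e.end > t_end + 1e-9:
            raise ValueError(
                f"event [{e.start}, {e.end}] outside signal span [{t_start:.2f}, {t_end:.2f}]"
            )

    segments: list[Segment] = []
    excluded: list[tuple[ApneaAnnotation, str]] = []
    for e in events:
        too_close = None
        for other in events:
            if other is e:
                continue
            gap = max(other.start - e.end, e.start - other.end)
            if gap < min_gap:
                too_close = other
                break
        if too_close is not None:
            excluded.append(
                (e, f"event at [{too_close.start:.1f}, {too_close.end:.1f}] within "
                    f"{min_gap} s")
            )
            continue
        seg_start = max(t_start, e.start - margin)
        seg_end = min(t_end, e.end + margin)
        i0 = int(np.ceil((seg_start - signal.t0) * signal.fs - 1e-9))
        i1 = int(np.floor((seg_end - signal.t0) * signal.fs + 1e-9)) + 1
        values = signal.values[i0:i1]
        t0 = signal.t0 + i0 / signal.fs
        times = t0 + np.arange(len(values)) / signal.fs
        truth = np.where(
            (times >= e.start) & (times < e.end), APNEA, NORMAL
        ).astype(object)
        segments.append(Segment(values=values, fs=signal.fs, t0=t0, truth=truth, event=e))
    return SegmentSet(segments=segments, excluded=excluded)


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts with apnea as the positive class."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.tp + other.tp, self.fp + other.fp, self.fn + other.fn, self.tn + other.tn
        )


def confusion_matrix(pred: np.ndarray, truth: np.ndarray) -> ConfusionMatrix:
    """Tally the four cells over aligned label sequences."""
    p = np.asarray(pred)
    t = np.asarray(truth)
    if p.shape != t.shape:
        raise ValueError(f"label length mismatch: {p.shape} vs {t.shape}")
    for arr, name in ((p, "predicted"), (t, "truth")):
        bad = set(np.unique(arr)) - {APNEA, NORMAL}
        if bad:
            raise ValueError(f"unknown {name} labels: {sorted(bad)}")
    pp = p == APNEA
    tt = t == APNEA
    return ConfusionMatrix(
        tp=int(np.sum(pp & tt)),
        fp=int(np.sum(pp & ~tt)),
        fn=int(np.sum(~pp & tt)),
        tn=int(np.sum(~pp & ~tt)),
    )


@dataclass(frozen=True)
class MetricsReport:
    """TPR/TNR/PPV/ACC/F1 in percent; a metric with a zero denominator is None."""

    tpr: float | None
    tnr: float | None
    ppv: float | None
    acc: float | None
    f1: float | None

    def as_dict(self, ndigits: int | None = 1) -> dict[str, float | None]:
        out = {}
        for name in ("tpr", "tnr", "ppv", "acc", "f1"):
            v = getattr(self, name)
            out[name] = None if v is None else (round(v, ndigits) if ndigits is not None else v)
        return out


def compute_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Sensitivity, specificity, precision, accuracy and F1 from the counts.

    Reported as percentages.  Denominator-zero metrics are reported as None
    (undefined) rather than coerced to 0; an all-zero matrix is an error.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")

    def ratio(num: int, den: int) -> float | None:
        return None if den == 0 else 100.0 * num / den

    tpr = ratio(cm.tp, cm.tp + cm.fn)
    tnr = ratio(cm.tn, cm.tn + cm.fp)
    ppv = ratio(cm.tp, cm.tp + cm.fp)
    acc = ratio(cm.tp + cm.tn, cm.total)
    f1 = ratio(2 * cm.tp, 2 * cm.tp + cm.fp + cm.fn)
    return MetricsReport(tpr=tpr, tnr=tnr, ppv=ppv, acc=acc, f1=f1)


@dataclass
class EventDetectionReport:
    detected: list[bool]
    total_count: int
    predicted_intervals: list[tuple[float, float]]
    events_per_hour: float

    @property
    def detected_count(self) -> int:
        return int(sum(self.detected))


def _label_runs_to_intervals(
    labels: np.ndarray, times: np.ndarray
) -> list[tuple[float, float]]:
    mask = np.asarray(labels) == APNEA
    if not mask.any():
        return []
    dt = float(np.median(np.diff(times))) if len(times) > 1 else 0.0
    edges = np.flatnonzero(np.diff(mask.astype(int)))
    starts = [0] if mask[0] else []
    starts += [int(i) + 1 for i in edges if not mask[i]]
    ends = [int(i) for i in edges if mask[i]]
    if mask[-1]:
        ends.append(len(mask) - 1)
    return [(float(times[i0]), float(times[i1]) + dt) for i0, i1 in zip(starts, ends)]


def detect_events(
    labels: np.ndarray,
    times: np.ndarray,
    annotations: AnnotationTrack,
    min_event_s: float = 5.0,
    merge_gap_s: float = 2.0,
) -> EventDetectionReport:
    """Per-event detection from the 10 Hz label sequence.

    Predicted events are maximal apnea-labelled runs, after merging runs
    separated by gaps of at most ``merge_gap_s`` and discarding runs shorter
    than ``min_event_s`` (5 s — the minimum length of real annotated
    events).  An annotated event counts as detected if any predicted event
    overlaps it.  ``events_per_hour`` is the predicted event count over the
    record duration.
    """
    times = np.asarray(times, dtype=float)
    raw = _label_runs_to_intervals(labels, times)

    merged: list[tuple[float, float]] = []
    for s, e in raw:
        if merged and s - merged[-1][1] <= merge_gap_s:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    predicted = [(s, e) for s, e in merged if e - s >= min_event_s]

    detected = [
        any(ps < ann.end and ann.start < pe for ps, pe in predicted)
        for ann in annotations
    ]
    hours = (times[-1] - times[0]) / 3600.0 if len(times) > 1 else 0.0
    eph = len(predicted) / hours if hours > 0 else 0.0
    return EventDetectionReport(
        detected=detected,
        total_count=len(annotations),
        predicted_intervals=predicted,
        events_per_hour=eph,
    )


def _segment_features(seg: Segment, window: WindowSpec) -> FeatureMatrix:
    wins, centers = sliding_windows(seg.as_signal(), window)
    return extract_features(wins, centers, seg.fs)


def _score_segments(
    net: CompetitiveNet, segments: list[Segment], window: WindowSpec
) -> ConfusionMatrix:
    cm = ConfusionMatrix(0, 0, 0, 0)
    for seg in segments:
        pred = classify_signal(net, seg.as_signal(), window)
        cm = cm + confusion_matrix(pred, seg.truth)
    return cm


def cross_validate(
    segments: SegmentSet | list[Segment],
    n_repeats: int = 5,
    train_fraction: float = 0.70,
    seed: int = 0,
    train_config: TrainConfig | None = None,
    window: WindowSpec = WindowSpec(),
) -> tuple[list[MetricsReport], dict[str, tuple[float, float]]]:
    """Repeated random-subsample validation at segment granularity.

    Each of ``n_repeats`` rounds draws a seeded random ``train_fraction``
    (default 70%) of segments, trains a competitive net on their pooled
    features (heuristic cluster naming), and scores per-sample labels on the
    held-out segments.  Returns the per-round reports and a
    ``metric → (mean, sd)`` summary in percent.
    """
    segs = list(segments)
    if len(segs) < 4:
        raise ValueError(f"cross-validation needs >= 4 segments, got {len(segs)}")
    feats = {i: _segment_features(s, window) for i, s in enumerate(segs)}
    reports: list[MetricsReport] = []
    for r in range(n_repeats):
        rng = np.random.default_rng([seed, r])
        order = rng.permutation(len(segs))
        n_train = max(1, min(len(segs) - 1, int(round(train_fraction * len(segs)))))
        train_idx, test_idx = order[:n_train], order[n_train:]

        train_feats = FeatureMatrix.concatenate([feats[i] for i in train_idx])
        cfg = train_config or TrainConfig(seed=seed)
        net = train_competitive(train_feats, cfg)
        net.class_of_cluster = map_clusters_to_classes(net.weights_original_units())
        cm = _score_segments(net, [segs[i] for i in test_idx], window)
        reports.append(compute_metrics(cm))

    summary: dict[str, tuple[float, float]] = {}
    for name in ("tpr", "tnr", "ppv", "acc", "f1"):
        vals = [getattr(rep, name) for rep in reports if getattr(rep, name) is not None]
        if vals:
            summary[name] = (float(np.mean(vals)), float(np.std(vals)))
    return reports, summary
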