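"""Unsupervised two-class labelling of breathing-signal features.

The primary model is a competitive (winner-take-all, Kohonen) layer of L=2
neurons: on each presented feature vector the neuron whose weight vector is
nearest in Euclidean distance wins and moves toward the input by a decaying
learning rate, so the weights converge to cluster centroids — learning
vector quantization without a teacher.  A hand-rolled Lloyd K-means serves
as the baseline for comparison.

Clusters are anonymous; :func:`map_clusters_to_classes` names them, by
default via the physiology of apnea (the cluster whose centroid has the
smaller signal-standard-deviation feature is the apnea cluster), optionally
by majority vote against provided labels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .extract import BreathingSignal
from .features import FeatureMatrix, WindowSpec, extract_features, labels_to_grid, sliding_windows

__all__ = [
    "APNEA",
    "NORMAL",
    "TrainConfig",
    "CompetitiveNet",
    "KMeansResult",
    "train_competitive",
    "predict_cluster",
    "train_kmeans",
    "map_clusters_to_classes",
    "classify_signal",
]

APNEA = "apnea"
NORMAL = "normal"

try:  # optional compiled inner loop; the pure-Python fallback is identical
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


@dataclass(frozen=True)
class TrainConfig:
    """Competitive-layer training schedule.

    1000 epochs is the canonical budget for this classifier; the learning
    rate decays linearly from ``lr_start`` to ``lr_end`` across epochs.  The
    default rate of 0.01 is the classical Kohonen-layer setting: large
    enough to converge within the epoch budget, small enough that a single
    far outlier cannot drag a prototype out of the data bulk (online
    winner-take-all updates are unstable under rates an order of magnitude
    larger when the feature distribution is heavy-tailed).
    ``init='sample'`` seeds the weights with distinct data points (avoids
    dead neurons); ``init='random'`` draws them from a standard normal.
    ``n_init`` independent seeded restarts are trained and the weights with
    the lowest mean quantization error kept — online winner-take-all
    learning, like Lloyd's algorithm, has poor local optima (a prototype can
    settle on a tight minority cluster), and restart selection is the
    standard remedy.
    """

    epochs: int = 1000
    lr_start: float = 0.01
    lr_end: float = 0.001
    seed: int = 0
    init: str = "sample"
    n_init: int = 4

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not 0 < self.lr_end <= self.lr_start < 1:
            raise ValueError("need 0 < lr_end <= lr_start < 1")
        if self.init not in ("sample", "random"):
            raise ValueError(f"unknown init {self.init!r}")
        if self.n_init < 1:
            raise ValueError("n_init must be >= 1")


def _competitive_updates_py(X, W, perms, etas):
    n_neurons, d = W.shape
    for e in range(perms.shape[0]):
        eta = etas[e]
        for k in range(perms.shape[1]):
            idx = perms[e, k]
            best = 0
            best_dist = np.inf
            for i in range(n_neurons):
                dist = 0.0
                for j in range(d):
                    diff = X[idx, j] - W[i, j]
                    dist += diff * diff
                if dist < best_dist:
                    best_dist = dist
                    best = i
            for j in range(d):
                W[best, j] += eta * (X[idx, j] - W[best, j])
    return W


if _HAVE_NUMBA:
    _competitive_updates = _njit(cache=True)(_competitive_updates_py)
else:  # pragma: no cover
    _competitive_updates = _competitive_updates_py


@dataclass
class CompetitiveNet:
    """Trained competitive layer: L weight vectors in z-scored feature space.

    ``feature_scaling`` carries the (mean, sd) pairs of the training set so
    new inputs are standardized identically; ``class_of_cluster`` maps each
    neuron index to 'apnea' or 'normal' once assigned.
    """

    weights: np.ndarray                       # (L, d)
    feature_scaling: tuple[np.ndarray, np.ndarray]
    class_of_cluster: dict[int, str] | None = None
    config: TrainConfig | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 2:
            raise ValueError("weights must be a (L, d) matrix")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")

    @property
    def n_neurons(self) -> int:
        return self.weights.shape[0]

    def zscore(self, values: np.ndarray) -> np.ndarray:
        mean, sd = self.feature_scaling
        safe = np.where(np.asarray(sd) > 0, sd, 1.0)
        return (np.asarray(values, float) - mean) / safe

    def weights_original_units(self) -> np.ndarray:
        mean, sd = self.feature_scaling
        safe = np.where(np.asarray(sd) > 0, sd, 1.0)
        return self.weights * safe + mean

    # -- persistence --------------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        mean, sd = self.feature_scaling
        blob = {
            "weights": self.weights.tolist(),
            "scaling": {"mean": np.asarray(mean).tolist(), "sd": np.asarray(sd).tolist()},
            "class_of_cluster": (
                {str(k): v for k, v in self.class_of_cluster.items()}
                if self.class_of_cluster
                else None
            ),
            "config": self.config.__dict__ if self.config else None,
        }
        Path(path).write_text(json.dumps(blob, indent=1) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "CompetitiveNet":
        blob = json.loads(Path(path).read_text())
        mapping = blob.get("class_of_cluster")
        return cls(
            weights=np.asarray(blob["weights"], float),
            feature_scaling=(
                np.asarray(blob["scaling"]["mean"], float),
                np.asarray(blob["scaling"]["sd"], float),
            ),
            class_of_cluster={int(k): v for k, v in mapping.items()} if mapping else None,
            config=TrainConfig(**blob["config"]) if blob.get("config") else None,
        )


def _canonical_order(X: np.ndarray) -> np.ndarray:
    """Lexicographic row order: presentation depends only on the multiset of rows."""
    return np.lexsort(X.T[::-1])


def train_competitive(
    features: FeatureMatrix, config: TrainConfig = TrainConfig(), n_neurons: int = 2
) -> CompetitiveNet:
    """Kohonen competitive learning on the z-scored feature rows.

    Per presented vector the nearest neuron (Euclidean) wins and moves by
    ``η (x − w)``; η decays linearly ``lr_start → lr_end`` across epochs and
    presentation order is reshuffled every epoch from ``config.seed``.  Rows
    are canonicalized (sorted) before shuffling, so training is invariant to
    the input row order and bit-reproducible given the seed.
    """
    X = features.zscored()
    if len(X) < 1:
        raise ValueError("no feature vectors to train on")
    distinct = np.unique(X, axis=0)
    if config.init == "sample" and len(distinct) < n_neurons:
        raise ValueError(
            f"{len(distinct)} distinct feature vectors for {n_neurons} neurons; "
            "use init='random' for degenerate data"
        )
    order = _canonical_order(X)
    Xs = np.ascontiguousarray(X[order])

    epochs = config.epochs
    if epochs > 1:
        etas = config.lr_start + (config.lr_end - config.lr_start) * (
            np.arange(epochs) / (epochs - 1)
        )
    else:
        etas = np.array([config.lr_start])

    best_W = None
    best_err = np.inf
    for restart in range(config.n_init):
        rng = np.random.default_rng([config.seed, restart])
        if config.init == "sample":
            # first n distinct rows in a seeded random scan; prototypes start
            # inside the data bulk (|z| <= 3 per feature) when possible — a
            # prototype seeded on a rare far outlier wins only outliers and
            # never learns the main structure
            in_bulk = np.all(np.abs(Xs) <= 3.0, axis=1)
            candidates = np.flatnonzero(in_bulk)
            if len(np.unique(Xs[candidates], axis=0)) < n_neurons:
                candidates = np.arange(len(Xs))
            W = []
            for idx in rng.permutation(candidates):
                if not any(np.array_equal(Xs[idx], w) for w in W):
                    W.append(Xs[idx].copy())
                if len(W) == n_neurons:
                    break
            W = np.array(W)
        else:
            W = rng.standard_normal((n_neurons, Xs.shape[1]))

        perms = np.empty((epochs, len(Xs)), dtype=np.int64)
        for e in range(epochs):
            perms[e] = rng.permutation(len(Xs))
        W = _competitive_updates(Xs, W, perms, etas)
        d2 = ((Xs[:, None, :] - W[None, :, :]) ** 2).sum(axis=2)
        err = float(d2.min(axis=1).mean())
        if err < best_err - 1e-12:
            best_err = err
            best_W = W
    return CompetitiveNet(
        weights=best_W,
        feature_scaling=features.scaling,
        config=config,
    )


def predict_cluster(net: CompetitiveNet, values: np.ndarray) -> np.ndarray:
    """Winning neuron index per feature row (ties go to the lower index)."""
    V = np.atleast_2d(np.asarray(values, dtype=float))
    if V.shape[1] != net.weights.shape[1]:
        raise ValueError(
            f"feature dimension {V.shape[1]} does not match net dimension "
            f"{net.weights.shape[1]}"
        )
    Z = net.zscore(V)
    d2 = ((Z[:, None, :] - net.weights[None, :, :]) ** 2).sum(axis=2)
    return np.argmin(d2, axis=1)


@dataclass
class KMeansResult:
    centroids: np.ndarray
    assignments: np.ndarray
    inertia_history: list[float] = field(default_factory=list)

    @property
    def inertia(self) -> float:
        return self.inertia_history[-1]


def train_kmeans(
    values: np.ndarray, k: int = 2, seed: int = 0, max_iter: int = 300
) -> KMeansResult:
    """Lloyd's algorithm from a seeded sample init, to assignment fixpoint.

    Operates on the rows as given — no scaling is applied, so features with
    larger numeric ranges dominate the Euclidean geometry.  The within-cluster
    sum of squares is recorded per iteration and is non-increasing.
    """
    X = np.asarray(values, dtype=float)
    if X.ndim != 2:
        raise ValueError("values must be a 2-D array of feature rows")
    distinct = np.unique(X, axis=0)
    if len(distinct) < k:
        raise ValueError(f"{len(distinct)} distinct points for k={k}")
    rng = np.random.default_rng(seed)
    C = []
    for idx in rng.permutation(len(X)):
        if not any(np.array_equal(X[idx], c) for c in C):
            C.append(X[idx].copy())
        if len(C) == k:
            break
    C = np.array(C)

    assign = np.full(len(X), -1)
    history: list[float] = []
    for _ in range(max_iter):
        d2 = ((X[:, None, :] - C[None, :, :]) ** 2).sum(axis=2)
        new_assign = np.argmin(d2, axis=1)
        history.append(float(d2[np.arange(len(X)), new_assign].sum()))
        if np.array_equal(new_assign, assign):
            break
        assign = new_assign
        for i in range(k):
            members = X[assign == i]
            if len(members):  # empty cluster keeps its previous centroid
                C[i] = members.mean(axis=0)
    return KMeansResult(centroids=C, assignments=assign, inertia_history=history)


def map_clusters_to_classes(
    centroids_original_units: np.ndarray,
    assignments: np.ndarray | None = None,
    true_labels: np.ndarray | None = None,
    std_feature_index: int = 1,
) -> dict[int, str]:
    """Name the two clusters 'apnea' / 'normal'.

    Default heuristic: the centroid with the smaller standard-deviation
    feature (in original units) is the apnea cluster — breathing effort
    collapses during an event.  Supervised mode (``true_labels`` given,
    aligned with ``assignments``) assigns by apnea-fraction majority instead.
    """
    C = np.asarray(centroids_original_units, dtype=float)
    if C.shape[0] != 2:
        raise ValueError("cluster→class mapping is defined for exactly 2 clusters")

    if true_labels is not None:
        if assignments is None:
            raise ValueError("supervised mapping needs cluster assignments")
        labels = np.asarray(true_labels)
        fractions = []
        for i in range(2):
            members = labels[np.asarray(assignments) == i]
            fractions.append(np.mean(members == APNEA) if len(members) else 0.0)
        apnea_cluster = int(np.argmax(fractions))
        return {apnea_cluster: APNEA, 1 - apnea_cluster: NORMAL}

    stds = C[:, std_feature_index]
    if np.isclose(stds[0], stds[1]):
        raise ValueError(
            "cluster centroids have indistinguishable std features; "
            "use supervised mapping with reference labels"
        )
    apnea_cluster = int(np.argmin(stds))
    return {apnea_cluster: APNEA, 1 - apnea_cluster: NORMAL}


def classify_signal(
    net: CompetitiveNet,
    signal: BreathingSignal,
    window: WindowSpec = WindowSpec(),
) -> np.ndarray:
    """Per-sample apnea/normal labels on the signal's own 10 Hz grid.

    Features are extracted on sliding windows, each window is labelled by its
    winning neuron's class, and every signal sample inherits the label of the
    nearest window centre (so the label sequence has exactly one entry per
    signal sample).
    """
    if net.class_of_cluster is None:
        raise ValueError("net has no cluster→class mapping; map clusters first")
    windows, centers = sliding_windows(signal, window)
    feats = extract_features(windows, centers, signal.fs)
    clusters = predict_cluster(net, feats.values)
    class_names = np.array(
        [net.class_of_cluster[i] for i in range(net.n_neurons)], dtype=object
    )
    window_labels = class_names[clusters]
    return labels_to_grid(centers, window_labels, signal.times)
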