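"""Competitive-layer training, K-means baseline, cluster naming, labelling."""

import numpy as np
import pytest

from depthresp.classify import (
    APNEA,
    NORMAL,
    CompetitiveNet,
    TrainConfig,
    classify_signal,
    map_clusters_to_classes,
    predict_cluster,
    train_competitive,
    train_kmeans,
)
from depthresp.extract import BreathingSignal
from depthresp.features import FeatureMatrix, WindowSpec


def _matrix(values):
    values = np.asarray(values, float)
    return FeatureMatrix.from_values(values, np.arange(len(values), dtype=float))


def _blobs(n=200, seed=0, c0=(-2.0, -2.0), c1=(2.0, 2.0), sd=0.1):
    rng = np.random.default_rng(seed)
    a = rng.normal(c0, sd, (n // 2, 2))
    b = rng.normal(c1, sd, (n // 2, 2))
    return np.vstack([a, b]), a, b


class TestTrainCompetitive:
    def test_identical_inputs_fixed_point(self):
        # degenerate data: the single point is the fixed point of the update —
        # the winning prototype converges to it and every input maps there
        X = np.tile([1.5, -0.5], (50, 1))
        fm = FeatureMatrix(values=X, center_times=np.arange(50.0),
                           scaling=(np.zeros(2), np.ones(2)))
        net = train_competitive(fm, TrainConfig(seed=0, init="random", epochs=1000))
        clusters = predict_cluster(net, X)
        assert len(set(clusters)) == 1
        winner = clusters[0]
        np.testing.assert_allclose(net.weights[winner], [1.5, -0.5], atol=1e-6)

    def test_sample_init_requires_distinct_points(self):
        X = np.tile([1.0, 1.0], (10, 1))
        fm = FeatureMatrix(values=X, center_times=np.arange(10.0),
                           scaling=(np.zeros(2), np.ones(2)))
        with pytest.raises(ValueError, match="distinct"):
            train_competitive(fm, TrainConfig(seed=0, init="sample"))

    def test_two_blobs_recover_both_means(self):
        X, a, b = _blobs(seed=1)
        fm = _matrix(X)
        net = train_competitive(fm, TrainConfig(seed=2))
        W = net.weights_original_units()
        d = np.array([[np.linalg.norm(w - m.mean(axis=0)) for m in (a, b)] for w in W])
        # each weight near a distinct blob mean
        assert d[0].min() < 0.2 and d[1].min() < 0.2
        assert np.argmin(d[0]) != np.argmin(d[1])

    def test_same_seed_bit_identical(self):
        X, *_ = _blobs(seed=3)
        fm = _matrix(X)
        w1 = train_competitive(fm, TrainConfig(seed=5)).weights
        w2 = train_competitive(fm, TrainConfig(seed=5)).weights
        np.testing.assert_array_equal(w1, w2)

    def test_row_permutation_invariance(self):
        X, *_ = _blobs(seed=4)
        rng = np.random.default_rng(0)
        fm1 = _matrix(X)
        fm2 = _matrix(X[rng.permutation(len(X))])
        w1 = train_competitive(fm1, TrainConfig(seed=6)).weights
        w2 = train_competitive(fm2, TrainConfig(seed=6)).weights
        np.testing.assert_array_equal(np.sort(w1, axis=0), np.sort(w2, axis=0))

    def test_single_neuron_estimates_data_mean(self):
        rng = np.random.default_rng(8)
        X = rng.normal(0.0, 1.0, (500, 2))
        fm = FeatureMatrix(values=X, center_times=np.arange(500.0),
                           scaling=(np.zeros(2), np.ones(2)))
        net = train_competitive(fm, TrainConfig(seed=9), n_neurons=1)
        assert np.linalg.norm(net.weights[0] - X.mean(axis=0)) < 0.05

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            TrainConfig(epochs=0)
        with pytest.raises(ValueError):
            TrainConfig(lr_start=0.001, lr_end=0.01)


class TestPredictCluster:
    net = CompetitiveNet(
        weights=np.array([[0.0, 0.0], [2.0, 0.0]]),
        feature_scaling=(np.zeros(2), np.ones(2)),
    )

    def test_point_on_weight_wins(self):
        assert predict_cluster(self.net, [[2.0, 0.0]])[0] == 1

    def test_equidistant_tie_goes_to_lower_index(self):
        assert predict_cluster(self.net, [[1.0, 0.0]])[0] == 0

    def test_matches_exhaustive_distance_comparison(self, rng):
        pts = rng.normal(0, 2, (1000, 2))
        got = predict_cluster(self.net, pts)
        for p, g in zip(pts, got):
            dists = [np.linalg.norm(p - w) for w in self.net.weights]
            assert g == int(np.argmin(dists))

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="dimension"):
            predict_cluster(self.net, [[1.0, 2.0, 3.0]])


class TestTrainKmeans:
    def test_blob_centroids_near_sample_means(self):
        X, a, b = _blobs(seed=10)
        res = train_kmeans(X, k=2, seed=1)
        d = np.array([[np.linalg.norm(c - m.mean(axis=0)) for m in (a, b)] for c in res.centroids])
        assert d[0].min() < 0.2 and d[1].min() < 0.2
        assert np.argmin(d[0]) != np.argmin(d[1])

    def test_k1_centroid_is_global_mean(self):
        X, *_ = _blobs(seed=11)
        res = train_kmeans(X, k=1, seed=0)
        np.testing.assert_allclose(res.centroids[0], X.mean(axis=0), atol=1e-12)

    def test_objective_monotone_non_increasing(self, rng):
        X = rng.normal(0, 1, (300, 2))
        res = train_kmeans(X, k=2, seed=2)
        h = res.inertia_history
        assert all(h[i + 1] <= h[i] + 1e-9 for i in range(len(h) - 1))

    def test_agrees_with_sklearn_on_separated_blobs(self):
        sklearn = pytest.importorskip("sklearn.cluster")
        X, *_ = _blobs(seed=12)
        res = train_kmeans(X, k=2, seed=3)
        ref = sklearn.KMeans(n_clusters=2, n_init=10, random_state=0).fit(X)
        ours = np.sort(res.centroids, axis=0)
        theirs = np.sort(ref.cluster_centers_, axis=0)
        np.testing.assert_allclose(ours, theirs, atol=0.05)

    def test_too_few_distinct_points(self):
        with pytest.raises(ValueError, match="distinct"):
            train_kmeans(np.ones((5, 2)), k=2, seed=0)


class TestClusterMapping:
    def test_heuristic_smaller_std_is_apnea(self):
        mapping = map_clusters_to_classes(np.array([[0.3, 0.1], [0.3, 2.0]]))
        assert mapping == {0: APNEA, 1: NORMAL}

    def test_supervised_mode_follows_labels(self):
        centroids = np.array([[0.3, 0.1], [0.3, 2.0]])
        assign = np.array([0, 0, 1, 1])
        labels = np.array([NORMAL, NORMAL, APNEA, APNEA], dtype=object)
        mapping = map_clusters_to_classes(centroids, assign, labels)
        assert mapping == {1: APNEA, 0: NORMAL}

    def test_degenerate_centroids_rejected(self):
        with pytest.raises(ValueError, match="supervised"):
            map_clusters_to_classes(np.array([[0.3, 1.0], [0.5, 1.0]]))

    def test_heuristic_agrees_with_supervised_on_synthetic(self):
        # at strong attenuation the physiology heuristic and a labelled
        # majority vote must name the same cluster apnea
        from depthresp.pipeline import generate_benchmark_record
        from depthresp.extract import extract_breathing_signal
        from depthresp.evaluate import build_training_segments, _segment_features
        from depthresp.features import labels_to_grid

        for seed in (21, 22, 23):
            seq, track = generate_benchmark_record(
                seed, duration=300.0, n_events=2, attenuation_max=0.2
            )
            sig = extract_breathing_signal(seq)
            segs = build_training_segments(sig, track)
            fms = [_segment_features(s, WindowSpec()) for s in segs]
            fm = FeatureMatrix.concatenate(fms)
            truth = np.concatenate(
                [labels_to_grid(s.times, s.truth, f.center_times) for s, f in zip(segs, fms)]
            )
            net = train_competitive(fm, TrainConfig(seed=seed))
            heuristic = map_clusters_to_classes(net.weights_original_units())
            clusters = predict_cluster(net, fm.values)
            supervised = map_clusters_to_classes(
                net.weights_original_units(), clusters, truth
            )
            assert heuristic == supervised


class TestClassifySignal:
    @staticmethod
    def _trained_net(seed=30):
        from depthresp.pipeline import generate_benchmark_record
        from depthresp.extract import extract_breathing_signal
        from depthresp.evaluate import build_training_segments, _segment_features

        seq, track = generate_benchmark_record(seed, duration=300.0, n_events=2)
        sig = extract_breathing_signal(seq)
        segs = build_training_segments(sig, track)
        fm = FeatureMatrix.concatenate([_segment_features(s, WindowSpec()) for s in segs])
        net = train_competitive(fm, TrainConfig(seed=seed))
        net.class_of_cluster = map_clusters_to_classes(net.weights_original_units())
        return net

    def test_label_sequence_length_matches_signal(self):
        net = self._trained_net()
        t = np.arange(0, 60, 0.1)
        sig = BreathingSignal(values=0.2 * np.sin(2 * np.pi * 0.25 * t), fs=10.0)
        labels = classify_signal(net, sig, WindowSpec())
        assert len(labels) == len(sig.values)

    def test_pure_breathing_labelled_normal(self):
        net = self._trained_net()
        t = np.arange(0, 120, 0.1)
        sig = BreathingSignal(values=0.2 * np.sin(2 * np.pi * 0.25 * t), fs=10.0)
        labels = classify_signal(net, sig, WindowSpec())
        assert np.mean(labels == NORMAL) >= 0.95

    @pytest.mark.parametrize("seed", [30, 31, 32])
    def test_silent_spans_labelled_apnea(self, seed):
        # silence as the pipeline produces it — deep-event interiors of the
        # record the net was trained on — must classify apnea
        from depthresp.pipeline import generate_benchmark_record, run_record_pipeline

        seq, track = generate_benchmark_record(seed, duration=600.0, n_events=3)
        res = run_record_pipeline(seq, track, seed=seed)
        t = res.signal.times
        interior = np.zeros(t.shape, bool)
        for e in track:
            interior |= (t >= e.start + 5) & (t <= e.end - 5)
        assert interior.sum() > 100
        assert np.mean(res.labels[interior] == APNEA) >= 0.95

    def test_unmapped_net_rejected(self):
        net = CompetitiveNet(weights=np.zeros((2, 2)),
                             feature_scaling=(np.zeros(2), np.ones(2)))
        sig = BreathingSignal(values=np.sin(np.arange(300) * 0.1), fs=10.0)
        with pytest.raises(ValueError, match="mapping"):
            classify_signal(net, sig)


class TestModelPersistence:
    def test_json_roundtrip(self, tmp_path):
        net = CompetitiveNet(
            weights=np.array([[0.1, -0.2], [1.0, 2.0]]),
            feature_scaling=(np.array([0.25, 0.15]), np.array([0.04, 0.07])),
            class_of_cluster={0: APNEA, 1: NORMAL},
            config=TrainConfig(seed=3),
        )
        path = tmp_path / "model.json"
        net.to_json(path)
        back = CompetitiveNet.from_json(path)
        np.testing.assert_array_equal(back.weights, net.weights)
        np.testing.assert_array_equal(back.feature_scaling[0], net.feature_scaling[0])
        assert back.class_of_cluster == net.class_of_cluster
        assert back.config == net.config
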