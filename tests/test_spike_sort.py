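import numpy as np
import pytest

from retisort.spike_detect import DetectionResult
from retisort.spike_sort import (
    SortingConfig,
    kmeans_fit,
    mean_silhouette,
    select_k,
    sort_channel,
    wpd_features,
)
from retisort.synth import biphasic_template, score_sorting


def silhouette_oracle(X, labels):
    """Pure-python O(n^2) silhouette: a(i), b(i), s(i) and the mean."""
    n = len(X)
    s = np.zeros(n)
    for i in range(n):
        same, others = [], {}
        for j in range(n):
            if j == i:
                continue
            d = float(np.sqrt(((X[i] - X[j]) ** 2).sum()))
            if labels[j] == labels[i]:
                same.append(d)
            else:
                others.setdefault(labels[j], []).append(d)
        a = sum(same) / len(same) if same else 0.0
        b = min(sum(v) / len(v) for v in others.values())
        if a == b:
            s[i] = 0.0
        else:
            s[i] = (b - a) / max(a, b)
    return s


def make_template_waveforms(rng, n_per=20, amps=(160.0, 80.0), noise_frac=0.05):
    wfs, labels = [], []
    for u, amp in enumerate(amps):
        tpl = biphasic_template(10_000.0, amp, 1.0 + 0.6 * u)
        peak = int(np.argmax(np.abs(tpl)))
        base = np.zeros(20)
        lo = 8 - peak
        seg = tpl[max(-lo, 0) : max(-lo, 0) + 20 - max(lo, 0)]
        base[max(lo, 0) : max(lo, 0) + len(seg)] = seg
        for _ in range(n_per):
            wfs.append(base + rng.normal(0, noise_frac * amp, size=20))
            labels.append(u)
    return np.asarray(wfs), np.asarray(labels)


class TestWpdFeatures:
    def test_identical_spikes_have_identical_rows(self, rng):
        w = rng.normal(size=20)
        feats = wpd_features(np.vstack([w, w, rng.normal(size=20)]))
        np.testing.assert_allclose(feats.X[0], feats.X[1], atol=1e-12)

    def test_zero_waveform_has_zero_raw_features(self):
        feats = wpd_features(np.vstack([np.zeros(20), np.ones(20)]))
        np.testing.assert_allclose(feats.raw[0], 0.0, atol=1e-12)

    def test_sixteen_raw_features_at_depth_three(self, rng):
        feats = wpd_features(rng.normal(size=(5, 20)), depth=3)
        assert feats.raw.shape == (5, 16)

    def test_columns_standardized(self, rng):
        feats = wpd_features(rng.normal(size=(50, 24)))
        np.testing.assert_allclose(feats.X.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(feats.X.std(axis=0), 1.0, atol=1e-10)

    def test_planted_templates_linearly_separable(self, rng):
        wfs, labels = make_template_waveforms(rng)
        feats = wpd_features(wfs)
        c0 = feats.X[labels == 0].mean(axis=0)
        c1 = feats.X[labels == 1].mean(axis=0)
        d0 = ((feats.X - c0) ** 2).sum(axis=1)
        d1 = ((feats.X - c1) ** 2).sum(axis=1)
        pred = (d1 < d0).astype(int)
        assert np.all(pred == labels)

    def test_too_short_waveforms_rejected(self, rng):
        with pytest.raises(ValueError):
            wpd_features(rng.normal(size=(5, 6)), depth=3)

    def test_raw_coefficient_features_option(self, rng):
        # 20-sample waveforms, depth 3, periodized: 8 nodes x 3 coefficients
        feats = wpd_features(rng.normal(size=(5, 20)), summaries=False)
        assert feats.raw.shape == (5, 24)
        assert feats.names[0].endswith("_c0")


class TestKmeans:
    def test_k1_centroid_is_column_mean(self, rng):
        X = rng.normal(size=(40, 3))
        model = kmeans_fit(X, 1, seed=0)
        np.testing.assert_allclose(model.centroids[0], X.mean(axis=0))
        np.testing.assert_allclose(
            model.inertia, ((X - X.mean(axis=0)) ** 2).sum()
        )

    def test_two_separated_1d_groups_split_perfectly(self):
        X = np.array([[0.0], [0.1], [-0.1], [10.0], [10.1], [9.9]])
        model = kmeans_fit(X, 2, seed=0)
        assert len(set(model.labels[:3])) == 1
        assert len(set(model.labels[3:])) == 1
        assert model.labels[0] != model.labels[3]
        got = sorted(float(c) for c in model.centroids[:, 0])
        np.testing.assert_allclose(got, [0.0, 10.0], atol=1e-9)

    def test_inertia_non_increasing_within_run(self, rng):
        X = rng.normal(size=(200, 5))
        model = kmeans_fit(X, 4, seed=1, restarts=3)
        h = model.inertia_history
        assert all(a >= b - 1e-9 for a, b in zip(h, h[1:]))

    def test_converged_partition_is_lloyd_fixed_point(self, rng):
        X = rng.normal(size=(100, 4))
        model = kmeans_fit(X, 3, seed=2)
        from scipy.spatial.distance import cdist

        d2 = cdist(X, model.centroids, metric="sqeuclidean")
        np.testing.assert_array_equal(d2.argmin(axis=1), model.labels)
        for j in range(3):
            np.testing.assert_allclose(
                model.centroids[j], X[model.labels == j].mean(axis=0), atol=1e-9
            )

    def test_no_empty_clusters(self, rng):
        X = np.vstack([np.zeros((30, 2)), np.ones((2, 2)) * 100])
        model = kmeans_fit(X, 3, seed=0)
        assert set(model.labels) == {0, 1, 2}

    def test_k_exceeding_n_rejected(self, rng):
        with pytest.raises(ValueError):
            kmeans_fit(rng.normal(size=(3, 2)), 4)


class TestMeanSilhouette:
    def test_matches_brute_force_oracle_on_random_instances(self, rng):
        for _ in range(50):
            n = int(rng.integers(10, 200))
            k = int(rng.integers(2, 6))
            X = rng.normal(size=(n, int(rng.integers(2, 6))))
            labels = rng.integers(0, k, size=n)
            if len(np.unique(labels)) < 2:
                continue
            rep = mean_silhouette(X, labels)
            oracle = silhouette_oracle(X, labels)
            assert np.max(np.abs(rep.s - oracle)) < 1e-12
            assert np.all(rep.s >= -1 - 1e-12) and np.all(rep.s <= 1 + 1e-12)

    def test_agrees_with_sklearn(self, rng):
        from sklearn.metrics import silhouette_samples

        X = rng.normal(size=(120, 4))
        labels = rng.integers(0, 3, size=120)
        rep = mean_silhouette(X, labels)
        np.testing.assert_allclose(rep.s, silhouette_samples(X, labels), atol=1e-10)

    def test_tight_far_clusters_score_high(self, rng):
        X = np.vstack(
            [rng.normal(0, 0.05, size=(40, 3)), rng.normal(5, 0.05, size=(40, 3))]
        )
        labels = np.repeat([0, 1], 40)
        assert mean_silhouette(X, labels).mean_sc > 0.95

    def test_identical_points_score_zero(self):
        X = np.zeros((10, 2))
        labels = np.array([0] * 5 + [1] * 5)
        rep = mean_silhouette(X, labels)
        np.testing.assert_array_equal(rep.s, 0.0)

    def test_single_cluster_rejected(self, rng):
        with pytest.raises(ValueError):
            mean_silhouette(rng.normal(size=(10, 2)), np.zeros(10, dtype=int))


class TestSelectK:
    def test_three_blobs_recovered(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            centers = np.array([[0, 0], [3, 0], [0, 3]], dtype=float)
            X = np.vstack(
                [rng.normal(c, 0.1, size=(100, 2)) for c in centers]
            )
            model, rep = select_k(X, k_max=5, seed=seed)
            hits += model.k == 3
        assert hits >= 9

    def test_few_spikes_forced_to_single_unit(self, rng):
        model, rep = select_k(rng.normal(size=(5, 3)), seed=0)
        assert model.k == 1
        assert rep.chosen_k == 1

    def test_single_blob_stays_one_unit(self, rng):
        # dimensionality comparable to the 16-D feature space: any split of
        # one isotropic blob then has a low mean silhouette
        X = rng.normal(size=(150, 12))
        model, rep = select_k(X, seed=0)
        assert model.k == 1
        assert max(rep.by_k.values()) < 0.20


class TestSortChannel:
    def _det(self, waveforms):
        n = len(waveforms)
        return DetectionResult(
            indices=np.arange(n, dtype=np.int64) * 100,
            waveforms=np.asarray(waveforms), snr=np.nan, threshold=1.0,
        )

    def test_single_template_yields_one_unit(self, rng):
        wfs, _ = make_template_waveforms(rng, n_per=40, amps=(120.0,))
        ul = sort_channel(self._det(wfs), SortingConfig(seed=0))
        assert ul.n_units == 1

    def test_two_templates_recovered_with_high_agreement(self, rng):
        wfs, labels = make_template_waveforms(rng, n_per=40, amps=(160.0, 80.0))
        order = rng.permutation(len(wfs))
        ul = sort_channel(self._det(wfs[order]), SortingConfig(seed=0))
        assert ul.n_units == 2
        assert score_sorting(labels[order], ul.labels) >= 0.95

    def test_empty_channel(self):
        ul = sort_channel(self._det(np.empty((0, 20))), SortingConfig())
        assert ul.n_units == 0
        assert ul.labels.size == 0
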