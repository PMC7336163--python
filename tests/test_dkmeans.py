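import numpy as np
import pytest

from ddfnc.consortium import build_consortium
from ddfnc.dkmeans import (
    correlation_distance,
    decentralized_silhouette,
    multishot_gradient,
    multishot_lloyd,
    pooled_lloyd,
    singleshot_merge,
    two_stage_clustering,
)


# ---------------------------------------------------------------- oracle ---
def naive_corr_lloyd(X, k, C_init, max_iter=300):
    """Independent pooled Lloyd's oracle: explicit loops, correlation
    distance via np.corrcoef, mean-then-standardize centroid update."""

    def std(v):
        v = v - v.mean()
        return v / np.linalg.norm(v)

    Xs = np.array([std(row) for row in X])
    C = np.array([std(row) for row in C_init])
    labels = None
    for _ in range(max_iter):
        new_labels = np.array(
            [np.argmin([1 - np.corrcoef(x, c)[0, 1] for c in C]) for x in Xs]
        )
        if labels is not None and np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for j in range(k):
            members = Xs[labels == j]
            if len(members):
                C[j] = std(members.mean(axis=0))
    return C, labels


def window_consortium(rng, n_sites=3, n_per_site=60, p=12, k=3, spread=0.15, seed=0):
    """Small synthetic 'windows' with planted correlation-pattern clusters."""
    centers = rng.standard_normal((k, p))
    site_X, all_labels = [], []
    for _ in range(n_sites):
        lab = rng.integers(k, size=n_per_site)
        X = centers[lab] + spread * rng.standard_normal((n_per_site, p))
        site_X.append(X)
        all_labels.append(lab)
    cons = build_consortium([1] * n_sites, seed=seed)
    for site, X in zip(cons.sites, site_X):
        site.store["windows"] = X
        site.subjects = []
    return cons, np.vstack(site_X), np.concatenate(all_labels), centers


class TestCorrelationDistance:
    def test_identical_vectors(self, rng):
        u = rng.standard_normal(10)
        assert correlation_distance(u, u) == pytest.approx(0.0, abs=1e-12)

    def test_negated_vector(self, rng):
        u = rng.standard_normal(10)
        assert correlation_distance(u, -u) == pytest.approx(2.0, abs=1e-12)

    def test_orthogonal_centered_vectors(self):
        u = np.array([1.0, -1.0, 1.0, -1.0])
        v = np.array([1.0, 1.0, -1.0, -1.0])
        assert correlation_distance(u, v) == pytest.approx(1.0, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            correlation_distance(np.ones(5), np.arange(5.0))

    def test_range(self, rng):
        for _ in range(20):
            d = correlation_distance(rng.standard_normal(8), rng.standard_normal(8))
            assert 0.0 <= d <= 2.0


class TestMultishotLloyd:
    def test_single_site_equals_pooled(self, rng):
        cons, X, _, centers = window_consortium(rng, n_sites=1)
        ref = pooled_lloyd(X, 3, centers)
        res = multishot_lloyd(cons, "windows", 3, centers)
        np.testing.assert_array_equal(res.labels, ref.labels)
        np.testing.assert_allclose(res.C, ref.C, atol=1e-12)
        np.testing.assert_allclose(res.inertia_trace, ref.inertia_trace, atol=1e-10)

    @pytest.mark.parametrize("seed", range(20))
    def test_label_identity_with_pooled_across_seeds(self, seed):
        # the central clustering claim made exact, vs an independent oracle
        rng = np.random.default_rng(seed)
        cons, X, _, centers = window_consortium(rng, seed=seed, spread=0.6)
        C_init = X[rng.choice(len(X), size=3, replace=False)]
        res = multishot_lloyd(cons, "windows", 3, C_init)
        ref = pooled_lloyd(X, 3, C_init)
        np.testing.assert_array_equal(res.labels, ref.labels)
        oracle_C, oracle_labels = naive_corr_lloyd(X, 3, C_init)
        np.testing.assert_array_equal(res.labels, oracle_labels)
        np.testing.assert_allclose(res.C, oracle_C, atol=1e-8)

    def test_weighted_average_invariant_holds(self, rng):
        cons, _, _, centers = window_consortium(rng)
        res = multishot_lloyd(cons, "windows", 3, centers)
        assert res.weighted_average_ok

    def test_monotone_inertia(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            cons, X, _, _ = window_consortium(r, spread=0.8, seed=seed)
            C_init = X[r.choice(len(X), size=3, replace=False)]
            res = multishot_lloyd(cons, "windows", 3, C_init)
            assert np.all(np.diff(res.inertia_trace) <= 1e-10)

    def test_all_windows_labeled_in_range(self, rng):
        cons, X, _, centers = window_consortium(rng)
        res = multishot_lloyd(cons, "windows", 3, centers)
        assert res.labels.size == len(X)
        assert res.labels.min() >= 0 and res.labels.max() < 3

    def test_empty_cluster_reseeded(self, rng):
        cons, X, _, _ = window_consortium(rng, n_sites=2, n_per_site=20)
        # an initial centroid far outside the data hull -> empty cluster
        C_init = np.vstack([X[:2], 1e6 * np.arange(X.shape[1], dtype=float)])
        res = multishot_lloyd(cons, "windows", 3, C_init)
        assert np.isfinite(res.C).all()
        assert set(np.unique(res.labels)) <= {0, 1, 2}

    def test_planted_centroid_recovery(self, rng):
        from ddfnc.evaluation import hungarian_match

        cons, X, truth_labels, centers = window_consortium(rng, spread=0.05)
        res = multishot_lloyd(cons, "windows", 3, centers)
        match = hungarian_match(res.C.T, np.array([c - c.mean() for c in centers]).T)
        assert match.min_correlation > 0.98


class TestMultishotGradient:
    def test_k_points_exact_convergence(self):
        X = np.array([[1.0, 0.0, -1.0, 0.5], [0.0, 2.0, -2.0, 0.0], [3.0, -1.0, 0.0, -2.0]])
        cons = build_consortium([1], seed=0)
        cons.sites[0].store["windows"] = X
        cons.sites[0].subjects = []
        res = multishot_gradient(cons, "windows", 3, X.copy(), lr=1.0)
        from ddfnc.dkmeans import _standardize_rows

        np.testing.assert_allclose(res.C, _standardize_rows(X), atol=1e-8)

    def test_single_site_gradient_matches_analytic(self, rng):
        # one iteration with lr=1 from C0 reproduces the pooled Lloyd mean,
        # i.e. the aggregated gradient equals the analytic pooled gradient
        from ddfnc.dkmeans import _assign, _standardize_rows

        cons, X, _, centers = window_consortium(rng, n_sites=1)
        Xs = _standardize_rows(X)
        Cs = _standardize_rows(centers)
        labels, _ = _assign(Xs, Cs)
        res = multishot_gradient(cons, "windows", 3, centers, lr=1.0, max_iter=1)
        for j in range(3):
            expected = Cs[j] - (Cs[j] - Xs[labels == j].mean(axis=0))
            expected = (expected - expected.mean())
            expected /= np.linalg.norm(expected)
            np.testing.assert_allclose(res.C[j], expected, atol=1e-10)

    def test_matches_pooled_centroids(self, rng):
        from ddfnc.evaluation import hungarian_match

        cons, X, _, centers = window_consortium(rng, n_sites=2, spread=0.4)
        C_init = X[rng.choice(len(X), size=3, replace=False)]
        ref = pooled_lloyd(X, 3, C_init)
        res = multishot_gradient(cons, "windows", 3, C_init, lr=0.5)
        match = hungarian_match(res.C.T, ref.C.T)
        assert match.min_correlation > 0.85

    def test_invalid_lr(self, rng):
        cons, _, _, centers = window_consortium(rng)
        with pytest.raises(ValueError):
            multishot_gradient(cons, "windows", 3, centers, lr=0.0)


class TestSingleshotMerge:
    def test_replicated_sites_keep_local_centroids(self, rng):
        X = window_consortium(rng, n_sites=1, spread=0.05)[1]
        cons = build_consortium([1, 1], seed=0)
        for site in cons.sites:
            site.store["windows"] = X.copy()
            site.subjects = []
        res = singleshot_merge(cons, "windows", 3, seed=0)
        local = pooled_lloyd(X, 3, res.C)  # refitting moves nothing
        np.testing.assert_allclose(np.sort(res.C, axis=0), np.sort(local.C, axis=0), atol=1e-6)

    def test_single_site_equals_local_kmeans(self, rng):
        cons, X, _, _ = window_consortium(rng, n_sites=1)
        res = singleshot_merge(cons, "windows", 3, seed=5)
        rng2 = np.random.default_rng([5, 0])
        from ddfnc.dkmeans import _standardize_rows

        init = _standardize_rows(X)[rng2.choice(len(X), size=3, replace=False)]
        ref = pooled_lloyd(X, 3, init)
        # the merge stage may relabel clusters; partitions must coincide
        from itertools import permutations

        best = max(
            np.mean(np.array([p[l] for l in ref.labels]) == res.labels)
            for p in permutations(range(3))
        )
        assert best == 1.0

    def test_well_separated_clusters_exactly_recovered(self, rng):
        # between/within distance ratio >= 10: planted partition recovered
        cons, X, truth_labels, _ = window_consortium(
            rng, n_sites=3, n_per_site=40, spread=0.02
        )
        res = singleshot_merge(cons, "windows", 3, seed=1)
        # brute-force check: same partition up to cluster relabeling
        from itertools import permutations

        best = max(
            np.mean(np.array([p[l] for l in truth_labels]) == res.labels)
            for p in permutations(range(3))
        )
        assert best == 1.0

    def test_small_site_warns_but_contributes(self, rng):
        cons = build_consortium([1, 1], seed=0)
        big = window_consortium(rng, n_sites=1, n_per_site=50)[1]
        cons.sites[0].store["windows"] = big
        cons.sites[1].store["windows"] = big[:2]
        for site in cons.sites:
            site.subjects = []
        with pytest.warns(RuntimeWarning, match="windows"):
            res = singleshot_merge(cons, "windows", 3, seed=0)
        assert res.labels.size == 52


class TestTwoStage:
    def test_deterministic_under_fixed_seed(self, planted_dataset):
        from ddfnc.consortium import build_consortium
        from tests.conftest import attach_timecourse_windows

        subjects, truth = planted_dataset
        results = []
        for _ in range(2):
            cons = build_consortium([20, 20], seed=2, subjects=subjects)
            attach_timecourse_windows(cons, truth)
            results.append(two_stage_clustering(cons, k=5, n_init=1, seed=9))
        np.testing.assert_array_equal(results[0].C, results[1].C)
        np.testing.assert_array_equal(results[0].labels, results[1].labels)

    def test_planted_state_recovery(self, planted_consortium):
        from sklearn.metrics import adjusted_rand_score

        cons, truth = planted_consortium
        res = two_stage_clustering(cons, k=5, n_init=10, seed=2)
        planted = np.concatenate(truth.window_labels(22))
        assert adjusted_rand_score(planted, res.labels) > 0.9
        assert res.C0 is not None and res.C0.shape == res.C.shape

    def test_singleshot_variant_dispatch(self, planted_consortium):
        cons, _ = planted_consortium
        res = two_stage_clustering(cons, k=5, n_init=1, seed=0, variant="singleshot")
        assert res.variant == "singleshot"

    def test_unknown_variant(self, planted_consortium):
        cons, _ = planted_consortium
        with pytest.raises(KeyError):
            two_stage_clustering(cons, k=5, variant="merging_error")

    def test_silhouette_recorded(self, planted_consortium):
        cons, _ = planted_consortium
        res = two_stage_clustering(cons, k=5, n_init=2, seed=1)
        assert res.silhouette is not None and -1 <= res.silhouette <= 1


class TestDecentralizedSilhouette:
    def test_matches_sklearn_when_single_site(self, rng):
        from sklearn.metrics import silhouette_score

        from ddfnc.dkmeans import _standardize_rows

        X = _standardize_rows(rng.standard_normal((40, 8)))
        labels = rng.integers(2, size=40)
        ours = decentralized_silhouette([X], [labels])
        assert ours == pytest.approx(silhouette_score(X, labels, metric="correlation"))

    def test_none_when_undefined(self, rng):
        X = rng.standard_normal((10, 5))
        assert decentralized_silhouette([X], [np.zeros(10, dtype=int)]) is None
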