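import numpy as np
import pytest

from waveclust import (
    affinity_propagation,
    bregman_kmeans,
    kmeanspp_init,
    nnmf_cluster,
    selection_curve,
)


def blobs(rng, centers, n_per, sd):
    X = np.vstack([rng.normal(c, sd, size=(n_per, len(c))) for c in centers])
    truth = np.repeat(np.arange(len(centers)), n_per)
    return X, truth


def ari(a, b):
    from sklearn.metrics import adjusted_rand_score

    return adjusted_rand_score(a, b)


class TestKmeansPP:
    def test_k1_returns_one_point(self, rng):
        X = rng.normal(size=(10, 2))
        c = kmeanspp_init(X, 1, rng)
        assert c.shape == (1, 2)
        assert any(np.allclose(c[0], x) for x in X)

    def test_k_equals_distinct_points_selects_all(self, rng):
        X = np.repeat(np.arange(4.0)[:, None], 3, axis=0)  # 4 distinct points x3 copies
        c = kmeanspp_init(X, 4, rng)
        assert sorted(c.ravel().tolist()) == [0, 1, 2, 3]

    def test_k_above_distinct_points_errors(self, rng):
        X = np.zeros((5, 2))
        with pytest.raises(ValueError):
            kmeanspp_init(X, 2, rng)

    def test_separated_blobs_both_seeded(self):
        # two blobs 100x their radius apart: ++ seeding should hit both almost always
        hits = 0
        for seed in range(200):
            rng = np.random.default_rng(seed)
            X, _ = blobs(rng, [(0, 0), (100, 0)], 20, 0.5)
            c = kmeanspp_init(X, 2, rng)
            if {int(x > 50) for x in c[:, 0]} == {0, 1}:
                hits += 1
        assert hits >= 190


class TestBregmanKmeans:
    def test_potential_zero_at_k_equals_distinct_points(self, rng):
        X = rng.normal(size=(6, 3))
        res = bregman_kmeans(X, K=6, seed=0)
        assert res.potential == pytest.approx(0.0, abs=1e-12)

    def test_lloyd_potential_non_increasing(self, rng):
        X = rng.normal(size=(120, 4))
        for seed in range(50):
            res = bregman_kmeans(X, K=5, restarts=1, seed=seed)
            assert np.all(np.diff(res.history) <= 1e-9)

    def test_three_blobs_perfect_recovery(self, rng):
        X, truth = blobs(rng, [(0, 0), (10, 0), (0, 10)], 100, 1.0)
        res = bregman_kmeans(X, K=3, restarts=5, seed=0)
        assert ari(truth, res.labels) == 1.0

    def test_potential_matches_definition(self, rng):
        X = rng.normal(size=(40, 3))
        res = bregman_kmeans(X, K=4, restarts=2, seed=1)
        manual = sum(
            np.sum((X[i] - res.centers[res.labels[i]]) ** 2) for i in range(40)
        )
        assert res.potential == pytest.approx(manual, abs=1e-9)
        assert all(np.any(res.labels == k) for k in range(4))

    def test_best_of_restarts_not_worse_than_singles(self, rng):
        X = rng.normal(size=(80, 2))
        multi = bregman_kmeans(X, K=4, restarts=8, seed=7)
        singles = [bregman_kmeans(X, K=4, restarts=1, seed=s).potential for s in range(8)]
        assert multi.potential <= min(singles) + 1e-9

    def test_gene_order_permutation_invariance(self, rng):
        X, _ = blobs(rng, [(0, 0), (8, 8)], 30, 0.5)
        perm = rng.permutation(len(X))
        a = bregman_kmeans(X, K=2, restarts=5, seed=3).labels
        b = bregman_kmeans(X[perm], K=2, restarts=5, seed=3).labels
        assert ari(a[perm], b) == 1.0

    def test_kl_divergence_runs_on_shifted_coords(self, rng):
        X, truth = blobs(rng, [(1, 1), (10, 10)], 25, 0.3)
        res = bregman_kmeans(X, K=2, divergence="kl", restarts=3, seed=0)
        assert ari(truth, res.labels) == 1.0


class TestSelectionCurve:
    def test_elbow_on_four_planted_blobs(self, rng):
        X, _ = blobs(rng, [(0, 0), (10, 0), (0, 10), (10, 10)], 50, 0.5)
        curve = selection_curve(X, range(2, 9), restarts=5, seed=0)
        assert curve.best_k == 4

    def test_mean_potential_decreases_on_planted_data(self, rng):
        X, _ = blobs(rng, [(0, 0), (10, 0), (0, 10)], 60, 0.8)
        curve = selection_curve(X, range(2, 8), restarts=10, seed=0)
        assert np.all(np.diff(curve.mean_potential) <= 1e-6)

    def test_sd_zero_when_restarts_agree(self, rng):
        X, _ = blobs(rng, [(0, 0), (100, 0)], 20, 0.1)
        curve = selection_curve(X, [2], restarts=5, seed=0)
        assert curve.sd_potential[0] == pytest.approx(0.0, abs=1e-9)

    def test_out_of_range_k_errors(self, rng):
        with pytest.raises(ValueError):
            selection_curve(rng.normal(size=(10, 2)), [1, 2], seed=0)


class TestNNMF:
    def test_exact_low_rank_input_recovered(self, rng):
        F0 = np.zeros((30, 3))
        H0 = np.zeros((3, 21))
        for k in range(3):
            F0[10 * k : 10 * (k + 1), k] = rng.uniform(1, 2, 10)
            H0[k, 7 * k : 7 * (k + 1)] = rng.uniform(0.5, 1.5, 7)
        X = F0 @ H0
        res, F, H = nnmf_cluster(X, K=3, iters=3000, seed=0)
        assert np.linalg.norm(X - F @ H) ** 2 <= 1e-6
        # block structure recovered: each planted block is one pure cluster
        for k in range(3):
            assert len(set(res.labels[10 * k : 10 * (k + 1)])) == 1
        assert len(set(res.labels)) == 3

    def test_objective_monotone(self, rng):
        X = rng.uniform(size=(25, 18))
        res, _, _ = nnmf_cluster(X, K=4, iters=500, seed=1)
        assert np.all(np.diff(res.history) <= 1e-9 * max(res.history[0], 1.0))

    def test_k1_single_cluster(self, rng):
        res, _, _ = nnmf_cluster(rng.uniform(size=(12, 6)), K=1, seed=0)
        assert set(res.labels) == {0}

    def test_negative_input_errors(self):
        with pytest.raises(ValueError):
            nnmf_cluster(np.array([[1.0, -0.1], [0.2, 0.3]]), K=1)


class TestAffinityPropagation:
    @staticmethod
    def neg_sq_dist(X):
        return -((X[:, None, :] - X[None, :, :]) ** 2).sum(-1)

    def test_single_point_is_its_own_exemplar(self):
        res, ex = affinity_propagation(np.zeros((1, 1)))
        assert list(ex) == [0] and list(res.labels) == [0]

    def test_identical_points_merge_at_low_preference(self):
        S = np.zeros((2, 2))
        res, ex = affinity_propagation(S, preference=-10.0, damping=0.5)
        assert len(ex) == 1
        assert res.labels[0] == res.labels[1]

    def test_three_blobs_match_reference_implementation(self, rng):
        from sklearn.cluster import AffinityPropagation

        X, truth = blobs(rng, [(0, 0), (10, 0), (0, 10)], 20, 0.3)
        S = self.neg_sq_dist(X)
        res, ex = affinity_propagation(S, preference="median", damping=0.9)
        assert len(ex) == 3
        assert ari(truth, res.labels) == 1.0
        pref = float(np.median(S[~np.eye(60, dtype=bool)]))
        skl = AffinityPropagation(
            affinity="precomputed", preference=pref, damping=0.9, random_state=0
        ).fit(S)
        assert ari(res.labels, skl.labels_) == 1.0

    def test_invariant_to_constant_shift(self, rng):
        X, _ = blobs(rng, [(0, 0), (6, 6)], 15, 0.4)
        S = self.neg_sq_dist(X)
        a, _ = affinity_propagation(S, preference=-5.0, damping=0.7)
        b, _ = affinity_propagation(S + 3.0, preference=-2.0, damping=0.7)
        assert ari(a.labels, b.labels) == 1.0

    def test_bad_damping_errors(self):
        with pytest.raises(ValueError):
            affinity_propagation(np.zeros((3, 3)), damping=0.2)
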