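import numpy as np
import pytest
from scipy.stats import pearsonr

from waveclust import ExpressionDataset, delaunay_edges, filter_and_stats, score_edges


def brute_force_circumsphere_check(coords, simplices_edges=None):
    """Every Delaunay simplex must have an empty circumsphere (oracle)."""
    from scipy.spatial import Delaunay

    tri = Delaunay(coords)
    for simplex in tri.simplices:
        pts = coords[simplex]
        # circumcenter: solve 2 (p_i - p_0) . c = |p_i|^2 - |p_0|^2
        A = 2 * (pts[1:] - pts[0])
        b = np.sum(pts[1:] ** 2, axis=1) - np.sum(pts[0] ** 2)
        try:
            center = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            continue
        radius = np.linalg.norm(pts[0] - center)
        others = np.setdiff1d(np.arange(len(coords)), simplex)
        dists = np.linalg.norm(coords[others] - center, axis=1)
        assert np.all(dists >= radius * (1 - 1e-9)), "non-empty circumsphere"


def toy_dataset(values, times=None):
    values = np.asarray(values, dtype=float)
    return ExpressionDataset(
        gene_ids=[f"g{i}" for i in range(values.shape[0])],
        time_stamps=np.arange(values.shape[1], dtype=float) if times is None else times,
        values=values,
    )


class TestDelaunayEdges:
    def test_tetrahedron_complete_graph(self):
        coords = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)
        edges = delaunay_edges(coords)
        assert len(edges) == 6
        assert all(i < j for i, j in edges)

    def test_random_points_pass_circumsphere_oracle(self, rng):
        for _ in range(5):
            coords = rng.normal(size=(20, 3))
            delaunay_edges(coords)
            brute_force_circumsphere_check(coords)

    def test_coplanar_points_jittered(self, rng):
        coords = np.zeros((10, 3))
        coords[:, :2] = rng.normal(size=(10, 2))
        edges = delaunay_edges(coords, jitter=True, seed=0)
        assert len(edges) > 0

    def test_degenerate_without_jitter_errors(self, rng):
        coords = np.zeros((10, 3))
        coords[:, 0] = np.arange(10)  # collinear
        with pytest.raises(Exception):
            delaunay_edges(coords, jitter=False)

    def test_too_few_points_errors(self):
        with pytest.raises(ValueError):
            delaunay_edges(np.zeros((3, 3)))

    def test_edge_set_invariant_to_rigid_motion(self, rng):
        coords = rng.normal(size=(25, 3))
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        moved = coords @ q + np.array([5.0, -2.0, 1.0])
        a = {tuple(e) for e in delaunay_edges(coords)}
        b = {tuple(e) for e in delaunay_edges(moved)}
        assert a == b


class TestScoreEdges:
    def test_identical_and_opposed_profiles(self, rng):
        base = rng.normal(size=12)
        values = np.vstack([base, base, -base, rng.normal(size=12)])
        coords = rng.normal(size=(4, 3))
        edges = np.array([[0, 1], [0, 2]])
        res = score_edges(edges, toy_dataset(values), coords)
        row01 = res.edges.iloc[0]
        row02 = res.edges.iloc[1]
        assert row01["r"] == pytest.approx(1.0) and row01["sign"] == "positive"
        assert row02["r"] == pytest.approx(-1.0) and row02["sign"] == "negative"

    def test_p_matches_independent_t_cdf_oracle(self, rng):
        T = 36
        values = rng.normal(size=(6, T))
        coords = rng.normal(size=(6, 3))
        edges = np.array([[i, j] for i in range(6) for j in range(i + 1, 6)])
        res = score_edges(edges, toy_dataset(values), coords)
        for _, row in res.edges.iterrows():
            i = int(row["gene_i"][1:])
            j = int(row["gene_j"][1:])
            r_ref, p_ref = pearsonr(values[i], values[j])
            assert row["r"] == pytest.approx(r_ref, abs=1e-10)
            assert row["p"] == pytest.approx(p_ref, abs=1e-6)

    def test_permutation_p_close_to_ttest(self, rng):
        T = 30
        values = rng.normal(size=(4, T))
        coords = rng.normal(size=(4, 3))
        edges = np.array([[0, 1]])
        ds = toy_dataset(values)
        p_t = score_edges(edges, ds, coords, p_method="ttest").edges["p"][0]
        p_perm = score_edges(edges, ds, coords, p_method="permutation", n_perm=4000, seed=0).edges["p"][0]
        assert abs(p_t - p_perm) < 0.05

    def test_zero_variance_profile_dropped(self, rng):
        values = np.vstack([np.ones(10), rng.normal(size=10), rng.normal(size=10)])
        coords = rng.normal(size=(3, 3))
        edges = np.array([[0, 1], [1, 2]])
        res = score_edges(edges, toy_dataset(values), coords)
        assert len(res.edges) == 1

    def test_lengths_are_manifold_distances(self, rng):
        values = rng.normal(size=(4, 8))
        coords = rng.normal(size=(4, 3))
        edges = np.array([[1, 3]])
        res = score_edges(edges, toy_dataset(values), coords)
        assert res.edges["length"][0] == pytest.approx(np.linalg.norm(coords[1] - coords[3]))


class TestFilterAndStats:
    def _scored(self, rng, G=30, T=20):
        values = rng.normal(size=(G, T))
        coords = rng.normal(size=(G, 3))
        edges = delaunay_edges(coords)
        return score_edges(edges, toy_dataset(values), coords)

    def test_threshold_one_keeps_all(self, rng):
        res = filter_and_stats(self._scored(rng), p_threshold=1.0)
        assert res.stats["n_significant"] == res.stats["n_edges"]

    def test_threshold_zero_keeps_none(self, rng):
        res = filter_and_stats(self._scored(rng), p_threshold=0.0)
        assert res.stats["n_significant"] == 0

    def test_significant_set_monotone_in_threshold(self, rng):
        scored = self._scored(rng)
        prev = -1
        for p in (1e-4, 1e-3, 1e-2, 0.1, 1.0):
            n = filter_and_stats(scored, p_threshold=p).stats["n_significant"]
            assert n >= prev
            prev = n

    def test_tight_clusters_give_short_significant_edges(self, rng):
        # three tightly co-expressed groups: correlated neighbors sit close
        t = np.linspace(0, 4 * np.pi, 24)
        profiles, coords = [], []
        for g, (phase, center) in enumerate(
            [(0, (0, 0, 0)), (2 * np.pi / 3, (4, 0, 0)), (4 * np.pi / 3, (0, 4, 0))]
        ):
            for _ in range(12):
                profiles.append(np.sin(t + phase) + 0.05 * rng.normal(size=24))
                coords.append(np.asarray(center) + 0.3 * rng.normal(size=3))
        values = np.vstack(profiles)
        coords = np.vstack(coords)
        ds = toy_dataset(values, times=t)
        res = filter_and_stats(score_edges(delaunay_edges(coords), ds, coords), p_threshold=0.001)
        assert res.stats["mean_length_significant"] <= res.stats["mean_length_all"]
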