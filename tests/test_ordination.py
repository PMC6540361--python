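"""nMDS embedding, bin scores, K-means and cluster-count selection."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import IsotonicRegression
from sklearn.metrics import calinski_harabasz_score

from cytodiv import bin_scores, calinski_harabasz, choose_k, kmeans, nmds
from cytodiv.diversity import DistanceMatrix
from cytodiv.errors import ConfigError, NumericError
from cytodiv.ordination import ClusterModel, OrdinationResult


def _dist(X, labels=None):
    X = np.asarray(X, dtype=float)
    labels = labels or [f"s{i}" for i in range(len(X))]
    return DistanceMatrix(labels=labels, values=squareform(pdist(X)),
                          index_name="euclid")


def _stress1_oracle(D, X):
    """Kruskal stress-1 via an independent isotonic fit (sklearn PAVA)."""
    dvec = squareform(np.asarray(D), checks=False)
    d = pdist(X)
    order = np.argsort(dvec, kind="stable")
    dhat = np.empty_like(d)
    iso = IsotonicRegression()
    dhat[order] = iso.fit_transform(np.arange(len(d)), d[order])
    return float(np.sqrt(((d - dhat) ** 2).sum() / (d**2).sum()))


class TestNmds:
    def test_unit_square_embeds_exactly(self):
        D = _dist([[0, 0], [1, 0], [1, 1], [0, 1]])
        res = nmds(D, seed=1, restarts=5)
        assert res.stress < 1e-3
        assert np.allclose(res.sample_scores.mean(axis=0), 0, atol=1e-9)

    def test_three_points_always_embed(self):
        D = DistanceMatrix(labels=list("abc"),
                           values=np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0.0]]),
                           index_name="m")
        assert nmds(D, seed=2, restarts=5).stress < 1e-3

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(13)
        D = _dist(rng.normal(size=(6, 3)))
        a = nmds(D, seed=5, restarts=4)
        b = nmds(D, seed=5, restarts=4)
        assert (a.sample_scores == b.sample_scores).all()
        assert a.stress == b.stress

    def test_fewer_than_three_samples_rejected(self):
        D = DistanceMatrix(labels=["a", "b"], values=np.array([[0, 1], [1, 0.0]]),
                           index_name="m")
        with pytest.raises(ConfigError):
            nmds(D)

    def test_stress_invariant_under_rigid_motions(self):
        rng = np.random.default_rng(14)
        D = _dist(rng.normal(size=(7, 3)))
        res = nmds(D, seed=3, restarts=5)
        base = _stress1_oracle(D.values, res.sample_scores)
        assert base == pytest.approx(res.stress, abs=1e-8)
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        for X in (res.sample_scores @ R,                  # rotation
                  res.sample_scores * [-1, 1],            # reflection
                  res.sample_scores + [3.5, -2.0]):       # translation
            assert _stress1_oracle(D.values, X) == pytest.approx(base, abs=1e-9)


class TestBinScores:
    def _result(self, scores):
        return OrdinationResult(
            sample_labels=[f"s{i}" for i in range(len(scores))],
            sample_scores=np.asarray(scores, dtype=float),
            stress=0.0, seed=0, n_restarts=1, converged=True,
        )

    def test_single_sample_bin_takes_that_score(self):
        res = self._result([[1.0, 2.0], [-3.0, 4.0]])
        F = np.array([[0.0, 7.0]])
        np.testing.assert_allclose(bin_scores(res, F)[0], [-3.0, 4.0])

    def test_uniform_bin_is_centroid(self):
        res = self._result([[1.0, 0.0], [0.0, 1.0], [-1.0, -1.0]])
        F = np.array([[2.0, 2.0, 2.0]])
        np.testing.assert_allclose(bin_scores(res, F)[0],
                                   res.sample_scores.mean(axis=0))

    def test_matches_weighted_mean_oracle(self):
        rng = np.random.default_rng(15)
        res = self._result(rng.normal(size=(5, 2)))
        F = rng.integers(0, 10, (20, 5)).astype(float)
        got = bin_scores(res, F)
        for b in range(20):
            if F[b].sum() == 0:
                assert np.isnan(got[b]).all()
            else:
                want = (F[b] @ res.sample_scores) / F[b].sum()
                np.testing.assert_allclose(got[b], want)

    def test_zero_bin_gets_nan_and_warning(self):
        res = self._result([[1.0, 0.0], [0.0, 1.0]])
        F = np.array([[0.0, 0.0], [1.0, 1.0]])
        with pytest.warns(UserWarning, match="all-zero"):
            got = bin_scores(res, F)
        assert np.isnan(got[0]).all() and not np.isnan(got[1]).any()


class TestKmeans:
    def test_k_equals_n_zero_objective(self):
        pts = np.array([[0.0, 0], [5, 5], [10, 0]])
        m = kmeans(pts, K=3, seed=0)
        assert m.objective == pytest.approx(0.0, abs=1e-12)

    def test_duplicate_pairs_recovered(self):
        pts = np.array([[0.0, 0], [0, 0], [10, 10], [10, 10]])
        m = kmeans(pts, K=2, seed=0)
        assert m.objective == pytest.approx(0.0, abs=1e-12)
        assert {tuple(c) for c in m.centers} == {(0.0, 0.0), (10.0, 10.0)}

    def test_never_worse_than_random_assignments(self):
        rng = np.random.default_rng(16)
        pts = rng.normal(size=(50, 2))
        m = kmeans(pts, K=3, seed=1)
        for _ in range(100):
            labels = rng.integers(0, 3, 50)
            obj = sum(
                ((pts[labels == k] - pts[labels == k].mean(axis=0)) ** 2).sum()
                for k in range(3) if (labels == k).any()
            )
            assert m.objective <= obj + 1e-9

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ConfigError):
            kmeans(np.zeros((3, 2)), K=4)


class TestCalinskiHarabasz:
    def test_hand_example(self):
        pts = np.array([[0.0, 0], [0, 1], [10, 0], [10, 1]])
        m = ClusterModel(K=2, centers=np.array([[0, 0.5], [10, 0.5]]),
                         assignments=np.array([0, 0, 1, 1]), objective=1.0)
        assert calinski_harabasz(pts, m) == pytest.approx(200.0)

    def test_matches_sklearn(self):
        rng = np.random.default_rng(17)
        pts = rng.normal(size=(60, 2))
        m = kmeans(pts, K=4, seed=2)
        assert m.ch_score == pytest.approx(
            calinski_harabasz_score(pts, m.assignments)
        )

    def test_degenerate_zero_within_ss_is_infinite(self):
        pts = np.array([[0.0, 0], [0, 0], [5, 5], [5, 5]])
        m = ClusterModel(K=2, centers=np.array([[0, 0], [5, 5.0]]),
                         assignments=np.array([0, 0, 1, 1]), objective=0.0)
        with pytest.warns(UserWarning, match="infinite"):
            assert calinski_harabasz(pts, m) == np.inf

    def test_true_labels_beat_random_labels(self):
        rng = np.random.default_rng(18)
        pts = np.vstack([rng.normal(c, 0.3, (40, 2))
                         for c in ((0, 0), (8, 0), (0, 8))])
        true = np.repeat([0, 1, 2], 40)
        rand = rng.permutation(true)
        mt = ClusterModel(K=3, centers=np.zeros((3, 2)), assignments=true,
                          objective=0.0)
        mr = ClusterModel(K=3, centers=np.zeros((3, 2)), assignments=rand,
                          objective=0.0)
        assert calinski_harabasz(pts, mt) > calinski_harabasz(pts, mr)


class TestChooseK:
    def test_recovers_five_blobs(self, five_blob):
        pts, k_true = five_blob
        assert choose_k(pts, seed=0).K == k_true

    def test_recovers_two_blobs(self):
        rng = np.random.default_rng(19)
        pts = np.vstack([rng.normal(c, 0.1, (100, 2)) for c in ((0, 0), (7, 7))])
        assert choose_k(pts, seed=0).K == 2

    def test_identical_points_degenerate(self):
        with pytest.raises(NumericError):
            choose_k(np.ones((20, 2)), seed=0)

    def test_kmax_lowered_with_warning(self):
        rng = np.random.default_rng(20)
        pts = rng.normal(size=(8, 2))
        with pytest.warns(UserWarning, match="kmax"):
            sel = choose_k(pts, kmax=10, seed=0)
        assert sel.table["K"].max() == 7

    def test_table_covers_range_and_min_rule(self, five_blob):
        pts, _ = five_blob
        sel = choose_k(pts, kmin=2, kmax=6, seed=1)
        assert list(sel.table["K"]) == [2, 3, 4, 5, 6]
        sel_min = choose_k(pts, kmin=2, kmax=6, seed=1, rule="min")
        assert sel_min.K == sel.table.loc[sel.table["C"].idxmin(), "K"]
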