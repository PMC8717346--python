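import numpy as np
import pytest
from scipy.linalg import orthogonal_procrustes
from scipy.spatial.distance import pdist, squareform

from songspace.acoustic_space import (RFParams, classical_mds,
                                      fit_supervised_rf,
                                      fit_unsupervised_rf_proximity,
                                      kruskal_nmds, proximity_to_distance)


def procrustes_rms(A, B):
    A = A - A.mean(0)
    B = B - B.mean(0)
    R, _ = orthogonal_procrustes(A, B)
    return float(np.sqrt(((A @ R - B) ** 2).mean()))


class TestSupervisedRF:
    def test_separable_classes_near_zero_oob(self, rng):
        X = np.vstack([rng.normal(size=(60, 2)), rng.normal(size=(60, 2)) + 20])
        y = np.repeat(["f", "m"], 60)
        rep = fit_supervised_rf(X, y, RFParams(500, mtry=2, seed=1))
        assert rep.oob_total_error < 0.02
        assert rep.per_sex_correct["f"] > 0.95

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(20, 3))
        with pytest.raises(ValueError):
            fit_supervised_rf(X, np.repeat("m", 20), RFParams(50, seed=0))

    def test_oob_error_stable_across_seeds(self, rng):
        X = np.vstack([rng.normal(size=(50, 3)), rng.normal(size=(50, 3)) + 1.0])
        y = np.repeat(["f", "m"], 50)
        errs = [fit_supervised_rf(X, y, RFParams(2000, mtry=2, seed=s)
                                  ).oob_total_error for s in (1, 2)]
        assert abs(errs[0] - errs[1]) < 0.03

    def test_importances_present_for_all_features(self, rng):
        X = np.vstack([rng.normal(size=(30, 4)), rng.normal(size=(30, 4)) + 2])
        y = np.repeat(["f", "m"], 30)
        rep = fit_supervised_rf(X, y, RFParams(200, mtry=2, seed=0),
                                feature_names=list("abcd"))
        assert set(rep.importance) == set("abcd")
        assert sum(rep.importance.values()) == pytest.approx(1.0, abs=1e-6)


class TestUnsupervisedProximity:
    def test_duplicated_rows_have_high_proximity(self, rng):
        X = rng.normal(size=(40, 5))
        X = np.vstack([X, X[0]])
        P = fit_unsupervised_rf_proximity(X, RFParams(2000, mtry=3, seed=2))
        assert P.P[0, -1] > 0.95

    def test_symmetric_unit_diagonal(self, rng):
        X = rng.normal(size=(25, 4))
        P = fit_unsupervised_rf_proximity(X, RFParams(200, mtry=2, seed=0))
        assert np.allclose(P.P, P.P.T)
        assert np.allclose(np.diag(P.P), 1.0)
        assert P.P.min() >= 0 and P.P.max() <= 1

    def test_clusters_more_proximate_within(self, rng):
        X = np.vstack([rng.normal(size=(20, 3)), rng.normal(size=(20, 3)) + 8])
        P = fit_unsupervised_rf_proximity(X, RFParams(500, mtry=2, seed=3)).P
        within = (P[:20, :20].sum() - 20) / (20 * 19)
        between = P[:20, 20:].mean()
        assert within > between

    def test_isolated_point_low_row_mean(self, rng):
        X = rng.normal(size=(30, 3))
        X[0] += 50
        P = fit_unsupervised_rf_proximity(X, RFParams(500, mtry=2, seed=4)).P
        row_means = (P.sum(1) - 1) / (len(P) - 1)
        assert row_means[0] < np.median(row_means[1:])

    def test_single_feature_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_unsupervised_rf_proximity(rng.normal(size=(20, 1)),
                                          RFParams(50, seed=0))


class TestProximityToDistance:
    def test_identity_and_extremes(self):
        P = np.eye(4)
        D = proximity_to_distance(P)
        assert np.allclose(np.diag(D), 0)
        assert np.allclose(D[~np.eye(4, dtype=bool)], 1.0)
        assert np.allclose(proximity_to_distance(np.ones((3, 3))), 0.0)


class TestClassicalMDS:
    def test_recovers_planted_configuration(self, rng):
        X = rng.normal(size=(30, 2))
        D = squareform(pdist(X))
        emb = classical_mds(D, 2)
        assert procrustes_rms(emb.coords, X) < 1e-8

    def test_equilateral_triangle(self):
        D = np.ones((3, 3)) - np.eye(3)
        emb = classical_mds(D, 2)
        d = pdist(emb.coords)
        assert np.allclose(d, d[0])
        assert emb.eigenvalues[0] == pytest.approx(emb.eigenvalues[1])

    def test_zero_distances_give_zero_coords(self):
        emb = classical_mds(np.zeros((5, 5)), 2)
        assert np.allclose(emb.coords, 0)

    def test_euclidean_distances_reproduced(self, rng):
        X = rng.normal(size=(25, 3))
        D = squareform(pdist(X))
        emb = classical_mds(D, 3)
        D2 = squareform(pdist(emb.coords))
        assert np.abs(D - D2).max() < 1e-6

    def test_eigenvalues_descending(self, rng):
        D = squareform(pdist(rng.normal(size=(15, 4))))
        emb = classical_mds(D, 3)
        assert np.all(np.diff(emb.eigenvalues) <= 1e-9)


class TestKruskalNMDS:
    def test_exact_configuration_low_stress(self, rng):
        X = rng.normal(size=(25, 2))
        D = squareform(pdist(X))
        emb = kruskal_nmds(D, 2, seed=0)
        assert emb.stress < 0.01

    def test_stress_nested_in_dimension(self, rng):
        D = squareform(pdist(rng.normal(size=(20, 5))))
        s2 = kruskal_nmds(D, 2, seed=0).stress
        s3 = kruskal_nmds(D, 3, seed=0).stress
        assert s3 <= s2 + 1e-9

    def test_monotone_transform_invariance(self, rng):
        X = rng.normal(size=(22, 2))
        D = squareform(pdist(X))
        s1 = kruskal_nmds(D, 2, seed=1).stress
        s2 = kruskal_nmds(D ** 1.5, 2, seed=1).stress
        assert abs(s1 - s2) < 1e-3

    def test_deterministic_given_seed(self, rng):
        D = squareform(pdist(rng.normal(size=(18, 3))))
        a = kruskal_nmds(D, 2, seed=5)
        b = kruskal_nmds(D, 2, seed=5)
        assert np.array_equal(a.coords, b.coords)

    def test_all_identical_points_rejected(self):
        with pytest.raises(ValueError):
            kruskal_nmds(np.zeros((6, 6)), 2, seed=0)
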