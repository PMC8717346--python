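"""Random-forest acoustic spaces: supervised sex classification, unsupervised
proximity matrices, and their low-dimensional MDS / NMDS embeddings.

A *proximity* between two samples is the fraction of qualifying forest trees
in which they land in the same terminal node; with ``oob_only`` (the default)
a tree qualifies for a pair only when both samples are out-of-bag for it.
``1 - proximity`` is treated as a dissimilarity and embedded either by
classical (principal-coordinates) MDS or by Kruskal's non-metric MDS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestClassifier
from sklearn.isotonic import IsotonicRegression

__all__ = [
    "RFParams",
    "SexClassifier",
    "UnsupervisedForestProximity",
    "ClassicalMDS",
    "KruskalNMDS",
    "fit_supervised_rf",
    "fit_unsupervised_rf_proximity",
    "proximity_to_distance",
    "classical_mds",
    "kruskal_nmds",
]


@dataclass
class RFParams:
    """Forest hyper-parameters: number of trees, minimal node size, Gini
    splits, and the number of variables sampled at each split (mtry)."""

    n_trees: int = 2000
    min_node_size: int = 1
    mtry: int | None = 3
    seed: int = 0

    def __post_init__(self):
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


@dataclass
class SexClassificationReport:
    """Out-of-bag classification accuracy of songs to sex for one species."""

    species: str
    oob_total_error: float
    per_sex_correct: dict[str, float]
    importance: dict[str, float]
    n_per_sex: dict[str, int] = field(default_factory=dict)

    @property
    def oob_total_correct(self) -> float:
        return 1.0 - self.oob_total_error


def _make_forest(params: RFParams, n_features: int, seed_offset: int = 0
                 ) -> RandomForestClassifier:
    mtry = params.mtry if params.mtry is not None else max(1, int(np.sqrt(n_features)))
    mtry = min(mtry, n_features)
    return RandomForestClassifier(
        n_estimators=params.n_trees,
        min_samples_leaf=params.min_node_size,
        criterion="gini",
        max_features=mtry,
        oob_score=True,
        bootstrap=True,
        random_state=(params.seed + seed_offset) % (2**31 - 1),
        n_jobs=1,
    )


class SexClassifier(BaseEstimator):
    """Supervised random forest with out-of-bag accuracy bookkeeping.

    Parameters follow :class:`RFParams`. After :meth:`fit`:

    - ``oob_total_error_``: proportion of samples whose OOB-vote prediction
      disagrees with the label (each sample predicted only by trees whose
      bootstrap excluded it);
    - ``per_class_correct_``: OOB correct-classification proportion per class;
    - ``importances_``: mean-decrease-in-impurity variable importance.
    """

    def __init__(self, n_trees: int = 2000, min_node_size: int = 1,
                 mtry: int | None = 3, seed: int = 0):
        self.n_trees = n_trees
        self.min_node_size = min_node_size
        self.mtry = mtry
        self.seed = seed

    def fit(self, X, y, feature_names=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) < 2:
            raise ValueError("need both classes present")
        if counts.min() < 2:
            raise ValueError("each class needs >= 2 samples")
        params = RFParams(self.n_trees, self.min_node_size, self.mtry, self.seed)
        rf = _make_forest(params, X.shape[1])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # tiny classes can leave a few rows never OOB
            rf.fit(X, y)
        proba = rf.oob_decision_function_
        # rows never OOB (possible at very low tree counts) fall back to 0.5
        proba = np.where(np.isnan(proba), 1.0 / len(classes), proba)
        pred = rf.classes_[np.argmax(proba, axis=1)]
        correct = pred == y
        self.forest_ = rf
        self.classes_ = rf.classes_
        self.oob_total_error_ = float(1.0 - correct.mean())
        self.per_class_correct_ = {
            str(c): float(correct[y == c].mean()) for c in classes
        }
        self.n_per_class_ = {str(c): int(n) for c, n in zip(classes, counts)}
        names = (list(feature_names) if feature_names is not None
                 else [f"x{i}" for i in range(X.shape[1])])
        self.importances_ = dict(zip(names, rf.feature_importances_.astype(float)))
        return self

    def predict(self, X):
        return self.forest_.predict(np.asarray(X, dtype=float))


def fit_supervised_rf(X, y, params: RFParams, species: str = "",
                      feature_names=None) -> SexClassificationReport:
    """Functional wrapper over :class:`SexClassifier`."""
    clf = SexClassifier(params.n_trees, params.min_node_size, params.mtry,
                        params.seed).fit(X, y, feature_names=feature_names)
    return SexClassificationReport(
        species=species,
        oob_total_error=clf.oob_total_error_,
        per_sex_correct=clf.per_class_correct_,
        importance=clf.importances_,
        n_per_sex=clf.n_per_class_,
    )


@dataclass
class ProximityMatrix:
    """Symmetric matrix of pairwise terminal-node co-occupancy fractions."""

    labels: list
    P: np.ndarray
    oob_only: bool = True

    def to_distance(self) -> np.ndarray:
        return proximity_to_distance(self)


class UnsupervisedForestProximity(BaseEstimator):
    """Breiman-style unsupervised random forest proximity.

    A synthetic contrast class is built by sampling each feature independently
    from its empirical marginal (same n as the data); a two-class forest is
    fit to real-vs-synthetic; the proximity between two real samples is the
    fraction of qualifying trees in which they share a terminal node. With
    ``oob_only`` (default) a tree qualifies for a pair only when both samples
    are out-of-bag; pairs with no qualifying tree get proximity 0 with a
    warning. After :meth:`fit`, ``proximity_`` holds the
    :class:`ProximityMatrix` over the real samples only.
    """

    def __init__(self, n_trees: int = 2000, min_node_size: int = 1,
                 mtry: int | None = 3, oob_only: bool = True, seed: int = 0):
        self.n_trees = n_trees
        self.min_node_size = min_node_size
        self.mtry = mtry
        self.oob_only = oob_only
        self.seed = seed

    def fit(self, X, y=None, labels=None):
        X = np.asarray(X, dtype=float)
        n, p = X.shape
        if p < 2:
            raise ValueError("need >= 2 features (marginal scrambling degenerates)")
        if n < 10:
            raise ValueError("need >= 10 samples")
        rng = np.random.default_rng(self.seed)
        synth = np.column_stack([rng.choice(X[:, j], size=n) for j in range(p)])
        X_aug = np.vstack([X, synth])
        y_aug = np.repeat([0, 1], n)
        params = RFParams(self.n_trees, self.min_node_size, self.mtry, self.seed)
        rf = _make_forest(params, p)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rf.fit(X_aug, y_aug)

        counts = np.zeros((n, n))
        denom = np.zeros((n, n))
        n_aug = 2 * n
        for tree, sampled in zip(rf.estimators_, rf.estimators_samples_):
            inbag = np.zeros(n_aug, dtype=bool)
            inbag[sampled] = True
            if self.oob_only:
                idx = np.flatnonzero(~inbag[:n])
            else:
                idx = np.arange(n)
            if idx.size < 2:
                continue
            leaves = tree.apply(X[idx])
            same = leaves[:, None] == leaves[None, :]
            counts[np.ix_(idx, idx)] += same
            denom[np.ix_(idx, idx)] += 1.0

        no_tree = denom == 0
        if no_tree.any():
            warnings.warn(
                f"{int(no_tree.sum() - np.trace(no_tree))//2} sample pairs were "
                "never jointly out-of-bag; proximity set to 0"
            )
        P = np.divide(counts, denom, out=np.zeros_like(counts), where=~no_tree)
        np.fill_diagonal(P, 1.0)
        P = (P + P.T) / 2.0
        self.proximity_ = ProximityMatrix(
            labels=list(labels) if labels is not None else list(range(n)),
            P=P, oob_only=self.oob_only,
        )
        self.forest_ = rf
        return self

    def fit_transform(self, X, y=None, labels=None) -> np.ndarray:
        """Fit and return the dissimilarity matrix ``1 - P``."""
        return self.fit(X, labels=labels).proximity_.to_distance()


def fit_unsupervised_rf_proximity(X, params: RFParams, oob_only: bool = True,
                                  labels=None) -> ProximityMatrix:
    """Functional wrapper over :class:`UnsupervisedForestProximity`."""
    est = UnsupervisedForestProximity(params.n_trees, params.min_node_size,
                                      params.mtry, oob_only, params.seed)
    return est.fit(X, labels=labels).proximity_


def proximity_to_distance(P: ProximityMatrix | np.ndarray) -> np.ndarray:
    """D = 1 - P; symmetric with zero diagonal."""
    M = P.P if isinstance(P, ProximityMatrix) else np.asarray(P, dtype=float)
    D = 1.0 - M
    np.fill_diagonal(D, 0.0)
    return (D + D.T) / 2.0


@dataclass
class AcousticEmbedding:
    """Low-dimensional coordinates of samples in an acoustic space."""

    labels: list
    coords: np.ndarray
    method: str  # "classical_mds" | "kruskal_nmds"
    eigenvalues: np.ndarray | None = None
    stress: float | None = None
    k: int = 2


class ClassicalMDS(BaseEstimator):
    """Principal-coordinates analysis of a dissimilarity matrix.

    Double-centers ``-D**2 / 2``, eigendecomposes, and returns eigenvectors
    scaled by the square roots of the ``k`` largest positive eigenvalues
    (axes ordered by descending eigenvalue). Negative eigenvalues are kept in
    ``eigenvalues_`` for inspection but their axes are never returned; if
    fewer than ``k`` positive eigenvalues exist the available axes are
    returned with a warning.
    """

    def __init__(self, k: int = 2):
        self.k = k

    def fit_transform(self, D, labels=None) -> np.ndarray:
        D = np.asarray(D, dtype=float)
        n = D.shape[0]
        if D.shape != (n, n) or not np.allclose(D, D.T, atol=1e-10):
            raise ValueError("D must be a symmetric square matrix")
        if self.k >= n:
            raise ValueError("k must be < n")
        J = np.eye(n) - np.ones((n, n)) / n
        B = -0.5 * J @ (D ** 2) @ J
        if n > 600 and self.k < n // 4:
            # Lanczos for the leading eigenpairs; deterministic start vector
            from scipy.sparse.linalg import eigsh
            evals, evecs = eigsh(B, k=min(2 * self.k + 3, n - 1), which="LA",
                                 v0=np.full(n, 1.0 / np.sqrt(n)))
        else:
            evals, evecs = np.linalg.eigh(B)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        n_pos = int((evals > 1e-12 * max(abs(evals[0]), 1.0)).sum())
        k_eff = min(self.k, n_pos)
        if k_eff < self.k:
            warnings.warn(
                f"only {k_eff} positive eigenvalues; returning {k_eff} axes"
            )
        if k_eff == 0:
            coords = np.zeros((n, self.k))
            k_eff = self.k
        else:
            coords = evecs[:, :k_eff] * np.sqrt(evals[:k_eff])
        self.eigenvalues_ = evals
        self.embedding_ = AcousticEmbedding(
            labels=list(labels) if labels is not None else list(range(n)),
            coords=coords, method="classical_mds", eigenvalues=evals, k=k_eff,
        )
        return coords


def classical_mds(D, k: int, labels=None) -> AcousticEmbedding:
    est = ClassicalMDS(k)
    est.fit_transform(D, labels=labels)
    return est.embedding_


def _stress1(d: np.ndarray, dhat: np.ndarray) -> float:
    denom = float(np.sum(d ** 2))
    if denom == 0:
        return 0.0
    return float(np.sqrt(np.sum((d - dhat) ** 2) / denom))


class KruskalNMDS(BaseEstimator):
    """Kruskal's non-metric MDS by stress-1 majorization.

    Alternates isotonic (monotone) regression of configuration distances on
    the rank order of the input dissimilarities with a Guttman-transform
    configuration update, starting from the classical-MDS solution plus
    ``n_starts - 1`` jittered restarts. Ties in the dissimilarities are
    handled by the primary approach (tied dissimilarities impose no order
    constraint among themselves: they are sorted secondarily by the current
    configuration distances). Deterministic given ``seed``.
    """

    def __init__(self, k: int = 2, n_starts: int = 4, max_iter: int = 500,
                 tol: float = 1e-6, seed: int = 0):
        self.k = k
        self.n_starts = n_starts
        self.max_iter = max_iter
        self.tol = tol
        self.seed = seed

    def _run(self, D, X0):
        n = D.shape[0]
        iu = np.triu_indices(n, 1)
        delta = D[iu]
        X = X0.copy()
        iso = IsotonicRegression(increasing=True)
        stress_prev = np.inf
        stress = np.inf
        for _ in range(self.max_iter):
            d = pdist(X)
            # primary ties: stable sort by (delta, current d)
            order = np.lexsort((d, delta))
            dhat = np.empty_like(d)
            dhat[order] = iso.fit_transform(np.arange(len(d)), d[order])
            stress = _stress1(d, dhat)
            if abs(stress_prev - stress) < self.tol:
                break
            stress_prev = stress
            # Guttman transform toward the disparities
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(d > 0, dhat / d, 0.0)
            B = -squareform(ratio)
            np.fill_diagonal(B, -B.sum(axis=1))
            X = (B @ X) / n
        return X, stress

    def fit_transform(self, D, labels=None) -> np.ndarray:
        D = np.asarray(D, dtype=float)
        n = D.shape[0]
        if not np.any(D[np.triu_indices(n, 1)] > 0):
            raise ValueError("all dissimilarities zero; configuration undefined")
        X0 = ClassicalMDS(self.k).fit_transform(D)
        if X0.shape[1] < self.k:  # pad degenerate classical starts
            X0 = np.column_stack([X0, np.zeros((n, self.k - X0.shape[1]))])
        rng = np.random.default_rng(self.seed)
        scale = max(np.abs(X0).max(), 1e-6)
        best_X, best_stress = self._run(D, X0)
        for _ in range(max(0, self.n_starts - 1)):
            jitter = rng.normal(scale=0.1 * scale, size=X0.shape)
            X, s = self._run(D, X0 + jitter)
            if s < best_stress:
                best_X, best_stress = X, s
        self.stress_ = best_stress
        self.embedding_ = AcousticEmbedding(
            labels=list(labels) if labels is not None else list(range(n)),
            coords=best_X, method="kruskal_nmds", stress=best_stress, k=self.k,
        )
        return best_X


def kruskal_nmds(D, k: int = 2, n_starts: int = 4, seed: int = 0,
                 labels=None) -> AcousticEmbedding:
    est = KruskalNMDS(k=k, n_starts=n_starts, seed=seed)
    est.fit_transform(D, labels=labels)
    return est.embedding_
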