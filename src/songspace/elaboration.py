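"""Song-elaboration axes: PCA on the correlation matrix of the five
elaboration variables (song duration, element number, element rate,
frequency range, element diversity).

Frequency extremes are excluded: a higher or lower pitch is not by itself
more elaborate. The first three components are retained as elaboration
scores for downstream comparative models. The PCA is fitted on songs pooled
across species and sexes so male and female scores share one coordinate
system.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = ["ELABORATION_VARIABLES", "ElaborationPCA", "fit_pca", "pc_scores"]

ELABORATION_VARIABLES = (
    "song_duration",
    "element_number",
    "element_rate",
    "freq_range",
    "element_diversity",
)


class ElaborationPCA(BaseEstimator):
    """Correlation-matrix PCA of the five song-level elaboration variables.

    Variables are standardized (mean 0, SD 1 with the n-1 divisor) and the
    correlation matrix eigendecomposed; components are ordered by descending
    eigenvalue, and within each component the loading of largest absolute
    value is oriented positive (the eigenvector sign being arbitrary).
    Eigenvalues sum to the number of variables. Fitted attributes:
    ``loadings_`` (variables x components), ``eigenvalues_``, ``center_``,
    ``scale_``, ``variable_names_``.
    """

    def __init__(self, n_components_kept: int = 3,
                 variables: tuple[str, ...] = ELABORATION_VARIABLES):
        self.n_components_kept = n_components_kept
        self.variables = variables

    def fit(self, song_table: pd.DataFrame):
        X = song_table[list(self.variables)].to_numpy(dtype=float)
        if len(X) < 6:
            raise ValueError("need >= 6 songs to fit the PCA")
        if not np.isfinite(X).all():
            bad = [v for v, col in zip(self.variables, X.T)
                   if not np.isfinite(col).all()]
            raise ValueError(f"non-finite values in variables: {bad}")
        center = X.mean(axis=0)
        scale = X.std(axis=0, ddof=1)
        zero = [v for v, s in zip(self.variables, scale) if s == 0]
        if zero:
            raise ValueError(f"zero-variance variable(s): {zero}")
        Z = (X - center) / scale
        R = np.corrcoef(Z, rowvar=False)
        evals, evecs = np.linalg.eigh(R)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        # sign convention: dominant loading of each component positive
        for j in range(evecs.shape[1]):
            i = np.argmax(np.abs(evecs[:, j]))
            if evecs[i, j] < 0:
                evecs[:, j] = -evecs[:, j]
        self.variable_names_ = tuple(self.variables)
        self.loadings_ = evecs
        self.eigenvalues_ = evals
        self.center_ = center
        self.scale_ = scale
        return self

    def transform(self, song_table: pd.DataFrame, n_components: int | None = None
                  ) -> pd.DataFrame:
        """Per-song PC scores (first ``n_components_kept`` columns by default)."""
        k = n_components if n_components is not None else self.n_components_kept
        X = song_table[list(self.variable_names_)].to_numpy(dtype=float)
        if not np.isfinite(X).all():
            raise ValueError("songs with missing elaboration variables")
        Z = (X - self.center_) / self.scale_
        scores = Z @ self.loadings_[:, :k]
        return pd.DataFrame(scores, columns=[f"PC{i + 1}" for i in range(k)],
                            index=song_table.index)

    def fit_transform(self, song_table: pd.DataFrame) -> pd.DataFrame:
        return self.fit(song_table).transform(song_table)

    def loadings_table(self) -> pd.DataFrame:
        """Loadings and eigenvalues in a printable layout."""
        df = pd.DataFrame(self.loadings_, index=self.variable_names_,
                          columns=[f"PC{i + 1}" for i in range(len(self.eigenvalues_))])
        df.loc["eigenvalue"] = self.eigenvalues_
        df.loc["proportion_variance"] = self.eigenvalues_ / self.eigenvalues_.sum()
        return df


def fit_pca(song_table: pd.DataFrame, **kwargs) -> ElaborationPCA:
    return ElaborationPCA(**kwargs).fit(song_table)


def pc_scores(model: ElaborationPCA, song_table: pd.DataFrame) -> pd.DataFrame:
    return model.transform(song_table)
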