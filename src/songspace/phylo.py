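"""Phylogenetic covariance construction and Blomberg's K.

Under Brownian motion on a rooted tree, trait covariance between two tips is
proportional to the shared root-to-MRCA path length; the matrix of those
path lengths (the phylogenetic vcv) both drives the phylogenetic random
effect in the mixed models and underlies Blomberg's K, the ratio of observed
to Brownian-expected phylogenetic signal (K = 1 under Brownian motion).
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

from .io import tip_depths

__all__ = ["PhyloCovariance", "phylo_vcv", "blomberg_k"]


@dataclass
class PhyloCovariance:
    """Species-ordered matrix of shared root-to-MRCA path lengths."""

    species: list[str]
    C: np.ndarray

    def reorder(self, species: list[str]) -> "PhyloCovariance":
        idx = [self.species.index(s) for s in species]
        return PhyloCovariance(list(species), self.C[np.ix_(idx, idx)])


def phylo_vcv(tree: dendropy.Tree) -> PhyloCovariance:
    """Brownian-motion covariance matrix of a rooted tree with branch lengths.

    ``C[i, j]`` is the root-to-MRCA path length of tips i and j (equivalently
    ``(depth_i + depth_j - patristic_ij) / 2``); the diagonal holds tip depths.
    """
    if tree.seed_node is None:
        raise ValueError("tree must be rooted; root it first")
    depths = tip_depths(tree)
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    n = len(labels)
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    C = np.zeros((n, n))
    for i, a in enumerate(labels):
        C[i, i] = depths[a]
        for j in range(i + 1, n):
            b = labels[j]
            patristic = pdm.patristic_distance(taxa[a], taxa[b])
            C[i, j] = C[j, i] = 0.5 * (depths[a] + depths[b] - patristic)
    return PhyloCovariance(labels, C)


def blomberg_k(tree: dendropy.Tree, tip_values: dict[str, float],
               vcv: PhyloCovariance | None = None) -> float:
    """Blomberg's K for a continuous trait on a tree.

    With C the phylogenetic vcv, phylogenetic mean
    ``a = (1'C^-1 1)^-1 1'C^-1 y``, the statistic is the ratio of the
    observed mean squared error around ``a`` to the phylogenetically
    corrected one, scaled by its Brownian expectation
    ``(tr C - n / (1'C^-1 1)) / (n - 1)``. K = 1 on a star tree for any
    non-constant trait, and in expectation under Brownian motion on any tree.
    """
    if vcv is None:
        vcv = phylo_vcv(tree)
    n = len(vcv.species)
    if n < 4:
        raise ValueError("need >= 4 species")
    missing = [s for s in vcv.species if s not in tip_values]
    if missing:
        raise ValueError(f"tip values missing for species: {missing}")
    y = np.array([tip_values[s] for s in vcv.species], dtype=float)
    C = vcv.C
    try:
        Cinv = np.linalg.inv(C)
    except np.linalg.LinAlgError as err:
        raise ValueError(
            "singular phylogenetic covariance (duplicated zero-length tips?); "
            "consider jittering zero branches by ~1e-8"
        ) from err
    one = np.ones(n)
    denom_a = one @ Cinv @ one
    a_hat = (one @ Cinv @ y) / denom_a
    resid = y - a_hat
    mse0 = resid @ resid / (n - 1)
    mse = resid @ Cinv @ resid / (n - 1)
    expected = (np.trace(C) - n / denom_a) / (n - 1)
    return float((mse0 / mse) / expected)
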