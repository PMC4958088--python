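"""Genetic distances between cultivars, UPGMA dendrograms and cluster cuts.

Clonal cultivars are single multilocus genotypes, so population-level distance
formulas are applied to *individual allele profiles*: within one cultivar an
allele carries a share of 1/2 (diploid) or 1/3 (triploid) at its locus, 1.0
when homozygous.

Two metrics are offered.  The default, ``"nei"``, is Nei's standard genetic
distance with sums pooled across loci,

    D = -ln( J_xy / sqrt(J_xx * J_yy) ),   J_uv = sum_loci sum_a u_a v_a.

The alternative ``"share"`` is an allele-sharing distance: one minus the mean
over loci of the shared allele mass ``sum_a min(x_a, y_a)``.  Which variant a
given legacy analysis used is often unrecorded, hence both are provided.

Clustering is average-linkage (UPGMA) via :mod:`scipy.cluster.hierarchy`; the
result is ultrametric, and re-running on the same matrix is bit-for-bit
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .genotypes import GenotypeTable

__all__ = [
    "DistanceMatrix",
    "Dendrogram",
    "individual_allele_profile",
    "nei_distance_matrix",
    "upgma",
    "cut_tree",
    "write_newick",
]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distances with zero diagonal, labelled by cultivar code."""

    labels: tuple[int, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError(f"distance matrix shape {v.shape} does not match {n} labels")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        if (v < 0).any():
            raise ValueError("distances must be non-negative")
        object.__setattr__(self, "values", v)

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)


@dataclass(frozen=True)
class Dendrogram:
    """A rooted ultrametric tree: leaf labels plus a scipy linkage matrix."""

    labels: tuple[int, ...]
    linkage: np.ndarray

    @property
    def root_height(self) -> float:
        return float(self.linkage[-1, 2]) if len(self.linkage) else 0.0

    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2].copy()

    def is_ultrametric(self) -> bool:
        h = self.merge_heights()
        return bool(np.all(np.diff(h) >= -1e-9))


def individual_allele_profile(
    table: GenotypeTable, cultivar: int
) -> dict[str, dict[int, float]]:
    """Per-marker within-individual allele frequencies for one cultivar."""
    return {m: call.allele_shares() for m, call in table.profile(cultivar).items()}


def _profile_vectors(table: GenotypeTable) -> np.ndarray:
    """Stacked allele-share vectors over a common (marker, allele) axis."""
    axis: list[tuple[str, int]] = []
    for m in table.markers:
        alleles = sorted({a for call in table.marker_calls(m) for a in call.alleles})
        axis.extend((m, a) for a in alleles)
    index = {key: i for i, key in enumerate(axis)}
    x = np.zeros((table.n_cultivars, len(axis)))
    for row, code in enumerate(table.codes):
        for m, shares in individual_allele_profile(table, code).items():
            for a, s in shares.items():
                x[row, index[(m, a)]] = s
    return x


def nei_distance_matrix(table: GenotypeTable, metric: str = "nei") -> DistanceMatrix:
    """Pairwise distance matrix between all cultivars of ``table``.

    ``metric="nei"`` gives Nei's standard distance on individual allele
    profiles (0 for identical profiles); ``metric="share"`` gives the
    allele-sharing distance in [0, 1].
    """
    if table.n_cultivars < 2:
        raise ValueError("need at least two cultivars for a distance matrix")
    x = _profile_vectors(table)
    n = table.n_cultivars
    if metric == "nei":
        j = x @ x.T  # J_uv pooled across loci
        diag = np.sqrt(np.outer(np.diag(j), np.diag(j)))
        ratio = np.clip(j / diag, a_min=np.finfo(float).tiny, a_max=1.0)
        d = -np.log(ratio)
    elif metric == "share":
        d = np.zeros((n, n))
        n_loci = len(table.markers)
        for i in range(n):
            shared = np.minimum(x[i], x).sum(axis=1) / n_loci
            d[i] = 1.0 - shared
    else:
        raise ValueError(f"unknown metric {metric!r}; use 'nei' or 'share'")
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return DistanceMatrix(tuple(table.codes), d)


def upgma(matrix: DistanceMatrix) -> Dendrogram:
    """Average-linkage agglomerative clustering of a distance matrix."""
    if len(matrix.labels) < 2:
        raise ValueError("need at least two labels")
    z = hierarchy.linkage(matrix.condensed(), method="average")
    return Dendrogram(tuple(matrix.labels), z)


def cut_tree(tree: Dendrogram, height: float) -> list[list[int]]:
    """Clusters obtained by cutting the dendrogram at ``height``.

    Leaves whose cophenetic distance is <= ``height`` share a cluster.  The
    result is a partition of all leaf labels; clusters and their members are
    sorted by first appearance order of the labels.
    """
    if height < 0:
        raise ValueError("cut height must be non-negative")
    assignment = hierarchy.fcluster(tree.linkage, t=height, criterion="distance")
    clusters: dict[int, list[int]] = {}
    for label, cl in zip(tree.labels, assignment):
        clusters.setdefault(int(cl), []).append(label)
    return [clusters[k] for k in sorted(clusters, key=lambda k: tree.labels.index(clusters[k][0]))]


def write_newick(tree: Dendrogram) -> str:
    """Serialise the dendrogram as Newick with branch lengths.

    Heights are merge *distances*; each side of a merge receives half the
    height difference, so two taxa merging at height 2.0 render as
    ``(A:1.0,B:1.0);`` and leaf-to-root path lengths equal root_height / 2.
    """
    root = hierarchy.to_tree(tree.linkage)

    def render(node, parent_height: float) -> str:
        height = 0.0 if node.is_leaf() else float(node.dist)
        branch = (parent_height - height) / 2.0
        if node.is_leaf():
            return f"{tree.labels[node.id]}:{branch:.10g}"
        left = render(node.left, height)
        right = render(node.right, height)
        return f"({left},{right}):{branch:.10g}"

    body = render(root, float(root.dist))
    # the root itself carries no branch
    return body.rsplit(":", 1)[0] + ";"
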