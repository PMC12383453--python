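"""Multicollinearity reduction by correlation clustering.

Spearman correlations between features are converted to the distance
``1 - |r_s|``; agglomerative clustering with Ward's linkage is applied to
that distance matrix and the dendrogram is cut at a fixed height (default
0.1, which groups features with |r_s| of roughly 0.9 or more).  One
representative feature is retained per cluster.

Ward linkage on a precomputed non-Euclidean distance matrix is
mathematically unconventional (Ward assumes squared Euclidean geometry);
it is implemented as standard Ward-on-distances agglomeration to mirror
common practice, with this caveat documented here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr

__all__ = [
    "CorrelationMatrix", "FeatureClusters", "PUBLISHED_SELECTION_DROPPED",
    "spearman_matrix", "ward_clusters", "select_representatives",
]

#: Features dropped by the published selection (15 of 18 kept).
PUBLISHED_SELECTION_DROPPED = ("Q1 MLCGap", "SAS10", "MCS")


@dataclass
class CorrelationMatrix:
    """Symmetric Spearman correlation matrix with feature names."""

    values: np.ndarray
    features: list[str]

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.features), len(self.features)):
            raise ValueError("correlation matrix shape mismatch")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.features, columns=self.features)


@dataclass
class FeatureClusters:
    """A flat partition of features from hierarchical clustering."""

    clusters: list[list[str]]
    linkage_matrix: np.ndarray
    threshold: float

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)


def spearman_matrix(table: pd.DataFrame, features: list[str] | None = None
                    ) -> CorrelationMatrix:
    """Spearman rank correlation between feature columns.

    Ties receive average ranks.  Constant columns are rejected because
    their rank correlation is undefined.
    """
    if features is None:
        features = [c for c in table.columns
                    if pd.api.types.is_numeric_dtype(table[c])]
    if len(table) < 3:
        raise ValueError("need at least 3 rows for rank correlation")
    X = table[features].to_numpy(dtype=float)
    const = [f for f, s in zip(features, X.std(axis=0)) if s == 0]
    if const:
        raise ValueError(f"constant columns have undefined rank correlation: {const}")
    rho = spearmanr(X).statistic
    if np.isscalar(rho):  # two features
        rho = np.array([[1.0, rho], [rho, 1.0]])
    np.fill_diagonal(rho, 1.0)
    return CorrelationMatrix(values=rho, features=list(features))


def ward_clusters(corr: CorrelationMatrix, threshold: float = 0.1
                  ) -> FeatureClusters:
    """Cut the Ward dendrogram of the 1 - |r_s| distance matrix."""
    dist = 1.0 - np.abs(corr.values)
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0  # enforce exact symmetry
    Z = linkage(squareform(dist, checks=False), method="ward")
    labels = fcluster(Z, t=threshold, criterion="distance")
    clusters: dict[int, list[str]] = {}
    for name, lab in zip(corr.features, labels):
        clusters.setdefault(lab, []).append(name)
    ordered = sorted(clusters.values(), key=lambda c: corr.features.index(c[0]))
    return FeatureClusters(clusters=ordered, linkage_matrix=Z, threshold=threshold)


def select_representatives(clusters: FeatureClusters, corr: CorrelationMatrix,
                           rule: str = "medoid") -> list[str]:
    """Pick one representative feature per cluster.

    ``medoid``
        The member with the highest mean |r_s| to the other members, ties
        broken by feature order.
    ``published``
        Reproduce the published 15-feature selection (drops Q1 MLCGap,
        SAS10 and MCS); requires those columns to be present.
    """
    if rule == "published":
        missing = [f for f in PUBLISHED_SELECTION_DROPPED if f not in corr.features]
        if missing:
            raise ValueError(f"published preset requires columns {missing}")
        return [f for f in corr.features if f not in PUBLISHED_SELECTION_DROPPED]
    if rule != "medoid":
        raise ValueError(f"unknown representative rule {rule!r}")

    frame = corr.to_frame().abs()
    selected = []
    for members in clusters.clusters:
        if len(members) == 1:
            selected.append(members[0])
            continue
        sub = frame.loc[members, members].to_numpy()
        mean_r = (sub.sum(axis=0) - 1.0) / (len(members) - 1)
        selected.append(members[int(np.argmax(mean_r))])
    return [f for f in corr.features if f in set(selected)]


def selection_report(clusters: FeatureClusters, corr: CorrelationMatrix,
                     selected: list[str]) -> dict:
    """JSON-serializable summary of the clustering and the selection."""
    return {
        "threshold": clusters.threshold,
        "n_clusters": clusters.n_clusters,
        "clusters": clusters.clusters,
        "merge_heights": clusters.linkage_matrix[:, 2].tolist(),
        "selected": selected,
    }
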