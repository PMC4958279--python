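"""Exploratory multivariate analysis of the autoscaled feature table.

Hierarchical clustering (Ward on Euclidean distances), principal component
analysis, the ordered heatmap matrix for a feature subset, and a covariate
screen checking which sample covariates (genotype group, sex, litter, date
of birth) explain the dominant axis of variation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.decomposition import PCA

from .tables import FeatureTable, AUTOSCALED, check_metadata

__all__ = [
    "Dendrogram",
    "PcaResult",
    "hcluster",
    "pca",
    "heatmap_matrix",
    "covariate_screen",
]


@dataclass
class Dendrogram:
    """Agglomerative clustering of labelled observations.

    ``linkage`` is the (n−1)×4 scipy linkage matrix (merge heights
    nondecreasing under Ward); ``labels`` are the observation IDs in input
    order; ``leaf_order`` is the dendrogram's left-to-right leaf sequence.
    """

    linkage: np.ndarray
    labels: list[str]

    @property
    def leaf_order(self) -> list[str]:
        return [self.labels[i] for i in hierarchy.leaves_list(self.linkage)]

    def cut(self, n_clusters: int) -> pd.Series:
        """Cluster assignment (1..n_clusters) per label."""
        assign = hierarchy.fcluster(self.linkage, n_clusters, criterion="maxclust")
        return pd.Series(assign, index=self.labels, name="cluster")

    def to_newick(self) -> str:
        from skbio.tree import TreeNode

        tree = TreeNode.from_linkage_matrix(self.linkage, self.labels)
        return str(tree).strip()


@dataclass
class PcaResult:
    """Scores, loadings and explained-variance proportions."""

    scores: pd.DataFrame      # samples × components
    loadings: pd.DataFrame    # features × components
    variance_explained: np.ndarray


def hcluster(table: FeatureTable, axis: str = "samples") -> Dendrogram:
    """Ward/Euclidean agglomerative clustering of samples (or features).

    Deterministic for a given input order; equidistant merges are resolved
    by scipy's nearest-neighbor chain order (first-index preference).
    """
    table.require_complete(op="hcluster")
    if axis not in ("samples", "features"):
        raise ValueError("axis must be 'samples' or 'features'")
    x = table.data.to_numpy()
    labels = table.sample_ids
    if axis == "features":
        x = x.T
        labels = table.feature_ids
    if x.shape[0] < 2:
        raise ValueError("need at least 2 observations to cluster")
    z = hierarchy.linkage(x, method="ward", metric="euclidean")
    return Dendrogram(z, list(labels))


def pca(table: FeatureTable, n_components: int | None = None) -> PcaResult:
    """PCA of the autoscaled matrix (correlation-matrix PCA).

    Sign convention: each loading column is flipped so its largest-|entry|
    is positive.  ``n_components`` beyond the matrix rank is truncated with
    a warning.
    """
    table.require_scale(AUTOSCALED, op="pca")
    table.require_complete(op="pca")
    x = table.data.to_numpy()
    max_rank = min(x.shape[0] - 1, x.shape[1])
    if n_components is None:
        n_components = max_rank
    elif n_components > max_rank:
        warnings.warn(
            f"n_components={n_components} exceeds the matrix rank bound "
            f"{max_rank}; truncating", stacklevel=2,
        )
        n_components = max_rank
    model = PCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(x)
    loadings = model.components_.T  # features × components
    for c in range(loadings.shape[1]):
        if loadings[np.argmax(np.abs(loadings[:, c])), c] < 0:
            loadings[:, c] *= -1
            scores[:, c] *= -1
    comp_names = [f"PC{i + 1}" for i in range(n_components)]
    return PcaResult(
        scores=pd.DataFrame(scores, index=table.data.index, columns=comp_names),
        loadings=pd.DataFrame(loadings, index=table.data.columns, columns=comp_names),
        variance_explained=model.explained_variance_ratio_,
    )


def heatmap_matrix(
    table: FeatureTable, subset: list[str]
) -> tuple[pd.DataFrame, list[str], list[str]]:
    """Features × samples matrix ordered by the respective Ward dendrograms.

    Returns (ordered matrix, feature order, sample order); values are the
    autoscaled intensities, ready to draw as a clustered heatmap.
    """
    if len(subset) == 0:
        raise ValueError("subset must be nonempty")
    sub = FeatureTable(table.data.loc[:, list(subset)].copy(), table.scale)
    col_order = hcluster(sub, axis="samples").leaf_order
    if sub.n_features >= 2:
        row_order = hcluster(sub, axis="features").leaf_order
    else:
        row_order = list(subset)
    mat = sub.data.T.loc[row_order, col_order]
    return mat, row_order, col_order


def _r_squared(score: np.ndarray, covariate: pd.Series) -> tuple[float, bool]:
    """R² of the score regressed on a (one-hot coded) covariate."""
    codes, _ = pd.factorize(covariate)
    if len(np.unique(codes)) < 2:
        return 0.0, True  # constant covariate: degenerate
    design = pd.get_dummies(pd.Series(codes), drop_first=True).to_numpy(dtype=float)
    design = np.column_stack([np.ones(len(score)), design])
    beta, *_ = np.linalg.lstsq(design, score, rcond=None)
    resid = score - design @ beta
    ss_tot = np.sum((score - score.mean()) ** 2)
    if ss_tot == 0:
        return 0.0, True
    return float(1.0 - np.sum(resid**2) / ss_tot), False


def covariate_screen(
    table: FeatureTable,
    metadata: pd.DataFrame,
    covariates: tuple[str, ...] = ("group", "sex", "litter", "date_of_birth"),
    score: np.ndarray | None = None,
    r2_threshold: float = 0.5,
) -> pd.DataFrame:
    """R² between each covariate and the table's first principal component.

    The discriminant score defaults to PC1 of the autoscaled matrix; any
    precomputed per-sample score can be supplied instead.  Covariates with
    R² above ``r2_threshold`` are flagged.
    """
    meta = check_metadata(metadata, table.sample_ids)
    if score is None:
        score = pca(table, n_components=1).scores["PC1"].to_numpy()
    rows = []
    for cov in covariates:
        if cov not in meta.columns:
            raise ValueError(f"covariate {cov!r} not in metadata")
        r2, degenerate = _r_squared(np.asarray(score, dtype=float), meta[cov])
        rows.append(
            {
                "covariate": cov,
                "r_squared": r2,
                "flagged": bool(r2 > r2_threshold),
                "degenerate": degenerate,
            }
        )
    return pd.DataFrame(rows)
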