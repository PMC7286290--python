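"""Phenotype profiling: feature matrix scaling, rank clustering, enrichment.

Per-sample feature tables from all plates are combined into one matrix,
centered and scaled column-wise, optionally masked per plate (features
corrupted on one plate are excluded there), and clustered: each feature is
replaced by its ranks across samples, Euclidean distances between rank rows
are clustered agglomeratively (complete linkage) and the tree is cut at a
chosen number of phenotype groups.  Rank-based clustering makes the result
invariant to any strictly monotone distortion of the raw features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage, to_tree
from scipy.spatial.distance import pdist
from scipy.stats import rankdata


@dataclass
class PhenotypeMatrix:
    """Samples × features table after centering and scaling."""

    data: pd.DataFrame  # scaled values
    column_means: pd.Series
    column_sds: pd.Series
    excluded: dict = field(default_factory=dict)  # column -> reason

    @property
    def samples(self):
        return list(self.data.index)

    @property
    def features(self):
        return list(self.data.columns)


def assemble_and_scale(feature_tables, exclusions=None) -> PhenotypeMatrix:
    """Combine per-plate feature tables, center and scale columns.

    ``feature_tables`` is a DataFrame or a list of DataFrames (samples ×
    features, indexed by sample).  ``exclusions`` maps a plate's DataFrame
    position to a list of feature names to blank (set missing) for that
    plate.  Constant and all-missing columns are dropped with a warning.
    After scaling every retained column has mean 0 and sd 1.
    """
    if isinstance(feature_tables, pd.DataFrame):
        feature_tables = [feature_tables]
    tables = []
    for p, tab in enumerate(feature_tables):
        tab = tab.copy().astype(float)
        if exclusions and p in exclusions:
            for col in exclusions[p]:
                if col in tab.columns:
                    tab[col] = np.nan
        tables.append(tab)
    mat = pd.concat(tables, axis=0)
    if mat.shape[0] < 2 or mat.shape[1] < 1:
        raise ValueError("need at least 2 samples and 1 feature")

    excluded = {}
    for col in list(mat.columns):
        vals = mat[col].dropna()
        if len(vals) == 0:
            excluded[col] = "all values missing"
        elif vals.nunique() <= 1:
            excluded[col] = "constant across samples"
    if excluded:
        warnings.warn(f"dropping columns: {excluded}")
        mat = mat.drop(columns=list(excluded))

    means = mat.mean(axis=0)
    sds = mat.std(axis=0, ddof=1)
    scaled = (mat - means) / sds
    return PhenotypeMatrix(scaled, means, sds, excluded)


def rank_cluster(matrix: PhenotypeMatrix, n_clusters: int,
                 rank_mode: str = "per_column", linkage_method: str = "complete"):
    """Rank-based hierarchical clustering of samples.

    Each column is replaced by its ranks across samples (ties get average
    ranks; ``rank_mode="global"`` ranks the whole matrix at once instead),
    sample rows are compared by Euclidean distance and clustered with
    complete linkage; the tree is cut at ``n_clusters``.  Deterministic:
    there is no randomness in the linkage, and ties resolve by the fixed
    sample order.

    Returns ``(assignments Series, linkage matrix Z)``.
    """
    X = matrix.data.to_numpy(dtype=float)
    n = X.shape[0]
    if n_clusters > n:
        raise ValueError("more clusters requested than samples")
    if rank_mode == "per_column":
        R = np.column_stack([rankdata(X[:, j]) for j in range(X.shape[1])])
    elif rank_mode == "global":
        R = rankdata(X).reshape(X.shape)
    else:
        raise ValueError("rank_mode must be 'per_column' or 'global'")
    Z = linkage(pdist(R, metric="euclidean"), method=linkage_method)
    assign = fcluster(Z, t=n_clusters, criterion="maxclust")
    return pd.Series(assign, index=matrix.data.index, name="cluster"), Z


def dendrogram_newick(Z, labels) -> str:
    """Serialize a scipy linkage tree as Newick text."""
    tree = to_tree(Z)

    def walk(node, parent_dist):
        length = max(parent_dist - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        return f"({walk(node.left, node.dist)},{walk(node.right, node.dist)}):{length:.6g}"

    return f"({walk(tree.left, tree.dist)},{walk(tree.right, tree.dist)});"


def enrichment_flags(condition_fractions, control_fractions, fold_threshold: float = 1.5):
    """Flag classes over-represented versus control.

    ``condition_fractions`` is a mapping condition → {class: fraction};
    ``control_fractions`` maps class → fraction.  A class is flagged when
    condition fraction / control fraction exceeds ``fold_threshold``; a
    class absent from controls but present in the condition is flagged
    ``control-zero``.

    Returns a DataFrame with columns condition, class, fold, flag.
    """
    rows = []
    for cond, fracs in condition_fractions.items():
        for cls, f in fracs.items():
            ctrl = control_fractions.get(cls, 0.0)
            if ctrl > 0:
                fold = f / ctrl
                flag = "enriched" if fold > fold_threshold else ""
            else:
                fold = np.inf if f > 0 else np.nan
                flag = "control-zero" if f > 0 else ""
            rows.append(dict(condition=cond, **{"class": cls}, fold=fold, flag=flag))
    return pd.DataFrame(rows)
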