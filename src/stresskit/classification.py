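"""Tolerance classification: standardize -> PCA -> Ward -> labels -> profile.

The chain standardizes the nine index columns (so the PCA is the
correlation-matrix PCA and Ward distances are not dominated by the
g/plot-scaled yield columns), summarizes them by eigendecomposition of
the correlation matrix with per-variable contributions, clusters
genotypes by Ward's minimum-variance criterion cut at k groups, labels
the k = 4 groups on fixed cluster-mean rules, and profiles clusters by
trait means with Duncan letters.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as _dc_replace

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .data_model import (
    ClusterResult,
    IndexTable,
    PCAResult,
    TrialTable,
    ValidationError,
)
from .inference import mean_separation

#: The four tolerance classes, most to least tolerant.
TOLERANCE_LABELS: tuple[str, ...] = (
    "tolerant",
    "moderately_tolerant",
    "moderately_susceptible",
    "susceptible",
)


def standardize(index_table: IndexTable | pd.DataFrame) -> pd.DataFrame:
    """Column-wise z-scores (mean 0, SD 1 with the n−1 denominator).

    Raises :class:`ValidationError` naming the first zero-variance
    column, since a constant index cannot be standardized.
    """
    mat = index_table.matrix() if isinstance(index_table, IndexTable) else index_table
    mat = mat.astype(float)
    sd = mat.std(ddof=1)
    zero = sd.index[(sd == 0) | sd.isna()]
    if len(zero):
        raise ValidationError(f"zero-variance column(s): {', '.join(map(str, zero))}")
    return (mat - mat.mean()) / sd


def pca_indices(z: pd.DataFrame) -> PCAResult:
    """Correlation-matrix PCA of standardized index columns.

    Eigendecomposes the p x p correlation matrix; dimensions are ordered
    by descending eigenvalue, variance explained is 100·λ/p and the
    contribution of variable j to a dimension is 100 times its squared
    unit-eigenvector loading.  Eigenvector signs are fixed so the
    loading of the first column (Ys in an index table) is non-negative
    on every dimension, making biplots reproducible.
    """
    vals = z.to_numpy(float)
    if not np.all(np.isfinite(vals)):
        raise ValidationError("non-finite entries in standardized matrix")
    n, p = vals.shape
    if n < 3:
        raise ValidationError("need >= 3 observations for PCA")
    corr = vals.T @ vals / (n - 1)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    # sign convention: first variable's loading >= 0 per dimension
    for k in range(p):
        ref = eigvecs[0, k]
        if ref < 0 or (ref == 0 and eigvecs[:, k].sum() < 0):
            eigvecs[:, k] = -eigvecs[:, k]
    dims = [f"Dim.{k + 1}" for k in range(p)]
    variance = 100.0 * eigvals / p
    return PCAResult(
        eigenvalues=eigvals,
        variance_explained=variance,
        cumulative_variance=np.cumsum(variance),
        contributions=pd.DataFrame(100.0 * eigvecs**2, index=z.columns, columns=dims),
        loadings=pd.DataFrame(eigvecs, index=z.columns, columns=dims),
    )


def ward_cluster(z: pd.DataFrame, k: int = 4) -> ClusterResult:
    """Agglomerative Ward (minimum-variance) clustering cut at k groups.

    Operates on Euclidean distances between the standardized rows with
    the squared-Euclidean Ward objective (Ward.D2); merge heights are
    non-decreasing.  Cluster ids are 1..k in dendrogram leaf order.
    """
    n = len(z)
    if not 1 <= k < n:
        raise ValidationError(f"k must be in [1, {n - 1}], got {k}")
    linkage = hierarchy.linkage(z.to_numpy(float), method="ward")
    flat = hierarchy.fcluster(linkage, t=k, criterion="maxclust")
    assignment = pd.Series(flat, index=z.index, name="cluster")
    return ClusterResult(assignment=assignment, merge_history=linkage)


def dendrogram_newick(result: ClusterResult) -> str:
    """Nested-parenthesis (Newick) text of the merge history, with heights
    as branch lengths, for external plotting."""
    tree = hierarchy.to_tree(result.merge_history)
    leaves = list(result.assignment.index)

    def walk(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{leaves[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return f"({walk(tree.left, tree.dist)},{walk(tree.right, tree.dist)});"


def label_clusters(clusters: ClusterResult, index_table: IndexTable) -> ClusterResult:
    """Assign the four tolerance classes to k = 4 clusters.

    Fixed rule on cluster means of the index table:

    * tolerant — highest mean GMP (best joint productivity);
    * susceptible — of the rest, highest mean SSI;
    * moderately tolerant / moderately susceptible — of the remaining
      two, the one with the higher mean YSI is moderately tolerant.

    Exact ties in a ranking statistic raise an error demanding manual
    labels rather than breaking the tie silently.
    """
    if clusters.k != 4:
        raise ValidationError(f"labelling requires exactly 4 clusters, got {clusters.k}")
    mat = index_table.matrix()
    missing = set(clusters.assignment.index) - set(mat.index)
    if missing:
        raise ValidationError(f"genotypes missing from index table: {sorted(missing)[:5]}")
    means = mat.loc[clusters.assignment.index].groupby(clusters.assignment).mean()

    def argmax_unique(series: pd.Series, statistic: str) -> int:
        top = series.max()
        winners = series.index[series == top]
        if len(winners) > 1:
            raise ValidationError(
                f"tie in cluster mean {statistic} between clusters {list(winners)}; "
                "assign labels manually"
            )
        return int(winners[0])

    labels: dict[int, str] = {}
    tolerant = argmax_unique(means["GMP"], "GMP")
    labels[tolerant] = "tolerant"
    rest = means.drop(index=tolerant)
    susceptible = argmax_unique(rest["SSI"], "SSI")
    labels[susceptible] = "susceptible"
    last_two = rest.drop(index=susceptible)
    mod_tol = argmax_unique(last_two["YSI"], "YSI")
    labels[mod_tol] = "moderately_tolerant"
    (mod_sus,) = [c for c in last_two.index if c != mod_tol]
    labels[int(mod_sus)] = "moderately_susceptible"
    return _dc_replace(clusters, labels=labels)


@dataclass
class ClusterProfile:
    """Per-cluster trait means with Duncan letter groups (printed-table shape)."""

    means: pd.DataFrame  # cluster label x trait
    letters: pd.DataFrame  # same shape, compact letter display

    def formatted(self, digits: int = 2) -> pd.DataFrame:
        out = self.means.copy().astype(object)
        for i in out.index:
            for j in out.columns:
                out.loc[i, j] = f"{self.means.loc[i, j]:.{digits}f} {self.letters.loc[i, j]}"
        return out


def cluster_profile(
    labels: ClusterResult,
    trial: TrialTable,
    traits: list[str],
    environment: str,
    alpha: float = 0.05,
) -> ClusterProfile:
    """Cluster trait means under one environment, separated by Duncan's test.

    Genotype replicate means are computed first; cluster means average
    those.  Letters come from a one-way across-cluster ANOVA per trait
    (MS_error pooled within clusters over genotype means, harmonic mean
    cluster size as the effective replication).
    """
    if not labels.labels:
        raise ValidationError("clusters must be labelled before profiling")
    available = trial.traits
    bad = [t for t in traits if t not in available]
    if bad:
        raise ValidationError(
            f"trait(s) {bad} absent from trial; available: {', '.join(available)}"
        )
    order = [lbl for lbl in TOLERANCE_LABELS if lbl in labels.labels.values()]
    mean_rows: dict[str, pd.Series] = {}
    letter_rows: dict[str, pd.Series] = {}
    for trait in traits:
        geno_means = trial.genotype_means(environment, trait)
        missing = set(labels.assignment.index) - set(geno_means.index)
        if missing:
            raise ValidationError(
                f"genotype(s) {sorted(missing)[:5]} lack {trait!r} data in {environment!r}"
            )
        geno_means = geno_means.loc[labels.assignment.index]
        cluster_of = labels.assignment.map(labels.labels)
        grp = geno_means.groupby(cluster_of)
        cmeans = grp.mean().reindex(order)
        sizes = grp.size().reindex(order)
        n_total = int(sizes.sum())
        df_error = n_total - len(order)
        if df_error < 1:
            raise ValidationError("not enough genotypes for across-cluster separation")
        ss_within = float(((geno_means - cluster_of.map(grp.mean())) ** 2).sum())
        ms_error = ss_within / df_error
        r_harm = len(sizes) / float((1.0 / sizes).sum())
        mean_rows[trait] = cmeans
        letter_rows[trait] = mean_separation(
            cmeans, ms_error=ms_error, df_error=df_error, r=r_harm,
            method="Duncan", alpha=alpha,
        )
    return ClusterProfile(
        means=pd.DataFrame(mean_rows).loc[order],
        letters=pd.DataFrame(letter_rows).loc[order],
    )
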