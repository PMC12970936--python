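"""Subset-wise clustering and Mahalanobis group similarity with permutation nulls.

Group profiles are compared in multivariate space: for a chosen mediator
subset, the Mahalanobis distance between each pair of group mean vectors is
computed with the pooled within-group covariance,

    d(A, B) = sqrt((mu_A - mu_B)' Sigma^-1 (mu_A - mu_B)).

Distances are converted to relative similarity scores by inversion
(s = 1/d) and min-max scaling across all pairs within the subset, so the
most similar pair scores exactly 1 and the least similar exactly 0 --
distance magnitudes differ strongly between subsets of different size, and
the scaling makes scores comparable across subsets.

Significance: group labels are shuffled (preserving group sizes) and all
pairwise distances recomputed (default 10,000 permutations), pooling the
permuted distances into one null distribution per subset.  An observed
distance at or above the null's 95th percentile is flagged "far"; at or
below the 5th percentile, "close".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.linalg import solve_triangular
from scipy.spatial.distance import pdist

from sputumpanel.containers import MediatorMatrix
from sputumpanel.panel import CHEMOTACTIC, INFLAMMATORY, PANEL, PROTEASES_ENZYMES

_COND_LIMIT = 1e8
_RIDGE = 1e-6


@dataclass(frozen=True)
class MediatorSubset:
    """A named biological-function subset of the panel."""

    name: str
    members: tuple[str, ...]

    def restrict(self, available: list[str]) -> "MediatorSubset":
        missing = [m for m in self.members if m not in available]
        if missing:
            raise ValueError(f"subset {self.name!r}: mediators not measured: {missing}")
        return self


DEFAULT_SUBSETS: tuple[MediatorSubset, ...] = (
    MediatorSubset("all", tuple(PANEL)),
    MediatorSubset("inflammatory", tuple(INFLAMMATORY)),
    MediatorSubset("chemotactic", tuple(CHEMOTACTIC)),
    MediatorSubset("proteases_enzymes", tuple(PROTEASES_ENZYMES)),
)


# ------------------------------------------------------------------ #
# Group means, row scaling, clustering
# ------------------------------------------------------------------ #


def group_means(
    matrix: MediatorMatrix, participants: pd.DataFrame, subset: MediatorSubset | None = None
) -> pd.DataFrame:
    """Arithmetic group x mediator mean matrix for the chosen subset."""
    cols = list(subset.members) if subset is not None else matrix.mediators
    missing = [c for c in cols if c not in matrix.mediators]
    if missing:
        raise ValueError(f"subset mediators not in matrix: {missing}")
    groups = participants.loc[matrix.participants, "group"].astype(str)
    if groups.isna().any() or (groups.value_counts() < 1).any():
        raise ValueError("every group needs >= 1 participant")
    return matrix.values[cols].groupby(groups).mean().sort_index()


def scale_rows(means: pd.DataFrame) -> pd.DataFrame:
    """Scale each row to mean 0, sample SD 1 (the heatmap's row scaling)."""
    if means.shape[1] < 2:
        raise ValueError("row scaling needs >= 2 columns")
    sd = means.std(axis=1, ddof=1)
    if (sd == 0).any():
        raise ValueError(f"zero-SD row(s): {list(sd.index[sd == 0])}")
    return means.sub(means.mean(axis=1), axis=0).div(sd, axis=0)


@dataclass
class DendrogramResult:
    """Agglomerative clustering of rows and columns of a matrix."""

    row_linkage: np.ndarray
    col_linkage: np.ndarray
    row_order: list[str]
    col_order: list[str]
    distance: str
    linkage: str
    data: pd.DataFrame

    def row_newick(self) -> str:
        return _linkage_to_newick(self.row_linkage, list(self.data.index))

    def col_newick(self) -> str:
        return _linkage_to_newick(self.col_linkage, list(self.data.columns))


def _linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    tree = hierarchy.to_tree(Z)

    def render(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return render(tree, tree.dist) + ";"


def hierarchical_cluster(
    data: pd.DataFrame, distance: str = "euclidean", linkage: str = "complete"
) -> DendrogramResult:
    """Agglomerative clustering of both rows and columns.

    Deterministic given the input: scipy breaks merge-height ties by the
    lowest pair index.  Typically applied to the row-scaled group-mean
    matrix.
    """
    if data.shape[0] < 2 or data.shape[1] < 2:
        raise ValueError("need at least 2 rows and 2 columns to cluster")
    row_Z = hierarchy.linkage(pdist(data.to_numpy(), metric=distance), method=linkage)
    col_Z = hierarchy.linkage(pdist(data.to_numpy().T, metric=distance), method=linkage)
    row_order = [data.index[i] for i in hierarchy.leaves_list(row_Z)]
    col_order = [data.columns[i] for i in hierarchy.leaves_list(col_Z)]
    return DendrogramResult(row_Z, col_Z, row_order, col_order, distance, linkage, data.copy())


# ------------------------------------------------------------------ #
# Mahalanobis distance machinery
# ------------------------------------------------------------------ #


def _regularise(cov: np.ndarray) -> np.ndarray:
    """Ridge the covariance only when badly conditioned."""
    cond = np.linalg.cond(cov)
    if not np.isfinite(cond) or cond > _COND_LIMIT:
        cov = cov + _RIDGE * (np.trace(cov) / cov.shape[0]) * np.eye(cov.shape[0])
    return cov


def mahalanobis_distance(mean_a, mean_b, pooled_cov) -> float:
    """d = sqrt((mu_A - mu_B)' Sigma^-1 (mu_A - mu_B)); symmetric in A, B."""
    a = np.asarray(mean_a, dtype=float)
    b = np.asarray(mean_b, dtype=float)
    S = _regularise(np.asarray(pooled_cov, dtype=float))
    diff = a - b
    try:
        sol = np.linalg.solve(S, diff)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("singular pooled covariance after regularisation") from exc
    d2 = float(diff @ sol)
    return float(np.sqrt(max(d2, 0.0)))


def pooled_within_group_cov(X: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Pooled within-group sample covariance (group-wise centred residuals)."""
    groups, inverse = np.unique(labels, return_inverse=True)
    n, p = X.shape
    means = np.zeros((len(groups), p))
    for g in range(len(groups)):
        means[g] = X[inverse == g].mean(axis=0)
    resid = X - means[inverse]
    return resid.T @ resid / (n - len(groups))


@dataclass
class SimilarityReport:
    """Pairwise distances, scaled similarities, and permutation flags."""

    subset: str
    table: pd.DataFrame  # group_a, group_b, distance, similarity, scaled_similarity,
    #                       [percentile, far, close]
    n_permutations: int = 0
    seed: int | None = None
    null_distances: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def pair(self, a: str, b: str) -> pd.Series:
        t = self.table
        sel = ((t.group_a == a) & (t.group_b == b)) | ((t.group_a == b) & (t.group_b == a))
        return t[sel].iloc[0]


def _group_setup(matrix: MediatorMatrix, participants: pd.DataFrame, subset: MediatorSubset):
    cols = list(subset.members)
    missing = [c for c in cols if c not in matrix.mediators]
    if missing:
        raise ValueError(f"subset {subset.name!r}: mediators not in matrix: {missing}")
    X = matrix.values[cols].to_numpy(dtype=float)
    labels = participants.loc[matrix.participants, "group"].astype(str).to_numpy()
    groups, inverse = np.unique(labels, return_inverse=True)
    counts = np.bincount(inverse)
    if len(groups) < 3:
        raise ValueError("need >= 3 groups for pairwise similarity scaling")
    if (counts < 2).any():
        small = [g for g, c in zip(groups, counts) if c < 2]
        raise ValueError(f"group(s) with n < 2: {small}")
    return X, groups, inverse, counts


def _all_pair_distances(X: np.ndarray, inverse: np.ndarray, n_groups: int) -> np.ndarray:
    """Condensed vector of pairwise group Mahalanobis distances.

    Uses the pooled within-group covariance recomputed from the labels.
    """
    n, p = X.shape
    means = np.zeros((n_groups, p))
    for g in range(n_groups):
        means[g] = X[inverse == g].mean(axis=0)
    resid = X - means[inverse]
    S = _regularise(resid.T @ resid / (n - n_groups))
    L = np.linalg.cholesky(S)
    # Mahalanobis distance between means = Euclidean distance after whitening
    white = solve_triangular(L, means.T, lower=True).T
    return pdist(white, metric="euclidean")


def pairwise_similarity(
    matrix: MediatorMatrix, participants: pd.DataFrame, subset: MediatorSubset
) -> SimilarityReport:
    """All pairwise group distances and min-max scaled similarity scores.

    s = 1/d per pair; s' = (s - min s) / (max s - min s) within the subset,
    so the most similar pair scores 1 and the least similar 0.
    """
    X, groups, inverse, _ = _group_setup(matrix, participants, subset)
    d = _all_pair_distances(X, inverse, len(groups))
    if (d == 0).any():
        raise ZeroDivisionError("duplicate group means: zero Mahalanobis distance")
    s = 1.0 / d
    if np.isclose(s.max(), s.min()):
        raise ValueError("degenerate min-max scaling: all pairs equidistant")
    scaled = (s - s.min()) / (s.max() - s.min())
    rows = []
    k = 0
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            rows.append(
                {
                    "group_a": groups[i],
                    "group_b": groups[j],
                    "distance": d[k],
                    "similarity": s[k],
                    "scaled_similarity": scaled[k],
                }
            )
            k += 1
    return SimilarityReport(subset=subset.name, table=pd.DataFrame(rows))


def permutation_test(
    matrix: MediatorMatrix,
    participants: pd.DataFrame,
    subset: MediatorSubset,
    n_permutations: int = 10_000,
    seed: int = 0,
    far_percentile: float = 95.0,
    close_percentile: float = 5.0,
    pooled_null: bool = True,
) -> SimilarityReport:
    """Permutation-null significance for the pairwise distances.

    Group labels are shuffled across participants (group sizes preserved)
    and all pairwise Mahalanobis distances recomputed, re-pooling the
    covariance from the permuted labels.  By default the permuted distances
    of all pairs form one pooled null per subset; ``pooled_null=False``
    keeps a per-pair null instead.  Each observed distance receives its
    percentile in the null (fraction strictly below, ties counted half,
    x100); ``far`` flags percentile >= ``far_percentile``, ``close`` flags
    percentile <= ``close_percentile``.
    """
    if n_permutations < 1:
        raise ValueError(f"n_permutations must be >= 1, got {n_permutations}")
    report = pairwise_similarity(matrix, participants, subset)
    X, groups, inverse, _ = _group_setup(matrix, participants, subset)
    rng = np.random.default_rng(seed)
    n_pairs = len(report.table)
    null = np.empty((n_permutations, n_pairs))
    for it in range(n_permutations):
        perm = rng.permutation(inverse)
        null[it] = _all_pair_distances(X, perm, len(groups))

    obs = report.table["distance"].to_numpy()
    percentiles = np.empty(n_pairs)
    for k in range(n_pairs):
        ref = null.ravel() if pooled_null else null[:, k]
        below = (ref < obs[k]).mean()
        ties = (ref == obs[k]).mean()
        percentiles[k] = 100.0 * (below + 0.5 * ties)

    table = report.table.copy()
    table["percentile"] = percentiles
    table["far"] = percentiles >= far_percentile
    table["close"] = percentiles <= close_percentile
    return SimilarityReport(
        subset=subset.name,
        table=table,
        n_permutations=n_permutations,
        seed=seed,
        null_distances=null,
    )
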