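"""Clustering of chemicals on their pathway-enrichment profiles.

The ER matrix is reduced with PCA to the smallest dimensionality explaining
a target fraction of variance (default 95%), embedded with UMAP over a grid
of (n_neighbors, min_dist, seed), and partitioned with k-means over a range
of k and seeds.  Every candidate partition is scored with the silhouette
coefficient on the embedding where k-means ran; the grid keeps the
highest-silhouette solution and accepts it only if it clears a floor
(default 0.70) — otherwise the search reports failure, returning the
below-threshold best for inspection.

Default parameter ranges: n_neighbors 2..20, min_dist
{0.0, 0.1, 0.25, 0.5, 0.8, 0.99}, k 3..10, five seeds for both stochastic
stages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score as _sk_silhouette

__all__ = [
    "GridSpec",
    "ClusterSolution",
    "GridSearchResult",
    "reduce_pca",
    "embed",
    "silhouette_score",
    "grid_search_clustering",
    "subset_cancer_keywords",
    "cluster_er_matrix",
    "CANCER_KEYWORDS",
]

CANCER_KEYWORDS = ("cancer", "carcin", "metasta", "tumor")


@dataclass(frozen=True)
class GridSpec:
    """Search grid for the embedding + k-means stages."""

    n_neighbors: tuple[int, ...] = tuple(range(2, 21))
    min_dist: tuple[float, ...] = (0.0, 0.1, 0.25, 0.5, 0.8, 0.99)
    n_components: int = 2
    k_range: tuple[int, ...] = tuple(range(3, 11))
    seeds: tuple[int, ...] = (0, 1, 2, 3, 4)
    min_silhouette: float = 0.70

    def __post_init__(self) -> None:
        if not (self.n_neighbors and self.min_dist and self.k_range and self.seeds):
            raise ValueError("grid ranges must be nonempty")
        if not -1.0 < self.min_silhouette < 1.0:
            raise ValueError("min_silhouette must lie in (-1, 1)")


@dataclass
class ClusterSolution:
    """One accepted (or best-found) clustering of the ER matrix."""

    labels: pd.Series  # cluster id per chemical
    k: int
    silhouette: float
    params: dict = field(default_factory=dict)
    embedding: pd.DataFrame | None = None


@dataclass
class GridSearchResult:
    best: ClusterSolution | None
    accepted: bool
    min_silhouette: float
    n_evaluated: int

    def __bool__(self) -> bool:
        return self.accepted


def reduce_pca(matrix: pd.DataFrame, target_variance: float = 0.95) -> pd.DataFrame:
    """Project onto the fewest leading principal components reaching the
    cumulative explained-variance target."""
    X = np.asarray(matrix, dtype=float)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("PCA needs at least 2 rows and 2 columns")
    if np.allclose(X.var(axis=0), 0):
        raise ValueError("matrix has zero variance; nothing to reduce")
    pca = PCA(svd_solver="full", random_state=0)
    scores = pca.fit_transform(X)
    cum = np.cumsum(pca.explained_variance_ratio_)
    d = int(np.searchsorted(cum, target_variance - 1e-12) + 1)
    d = min(d, scores.shape[1])
    out = pd.DataFrame(
        scores[:, :d],
        index=matrix.index,
        columns=[f"PC{i+1}" for i in range(d)],
    )
    out.attrs["explained_variance_ratio"] = pca.explained_variance_ratio_[:d]
    return out


def embed(
    matrix: pd.DataFrame,
    n_neighbors: int,
    min_dist: float,
    n_components: int = 2,
    seed: int = 0,
) -> pd.DataFrame:
    """UMAP embedding of the (PCA-reduced) matrix; deterministic per seed.

    The embedding stage is a contract: any neighborhood-preserving nonlinear
    reduction with fixed-seed determinism can stand here; the default is the
    published UMAP procedure as implemented by umap-learn.
    """
    if matrix.shape[0] < n_neighbors + 1:
        raise ValueError(
            f"need at least n_neighbors+1={n_neighbors + 1} rows, got {matrix.shape[0]}"
        )
    import umap  # deferred: numba JIT import is slow

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reducer = umap.UMAP(
            n_neighbors=n_neighbors,
            min_dist=min_dist,
            n_components=n_components,
            random_state=seed,
            n_jobs=1,
        )
        coords = reducer.fit_transform(np.asarray(matrix, dtype=float))
    return pd.DataFrame(
        coords, index=matrix.index, columns=[f"UMAP{i+1}" for i in range(n_components)]
    )


def silhouette_score(points: np.ndarray | pd.DataFrame, labels: Sequence[int]) -> float:
    """Mean silhouette coefficient, Euclidean distance.

    For each point, a is its mean distance to its own cluster and b the
    smallest mean distance to another cluster; the coefficient is
    (b - a) / max(a, b).
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette needs at least 2 clusters")
    return float(_sk_silhouette(np.asarray(points, dtype=float), labels, metric="euclidean"))


def grid_search_clustering(matrix: pd.DataFrame, grid: GridSpec | None = None) -> GridSearchResult:
    """Exhaustive deterministic search over the embedding/k-means grid.

    Iterates n_neighbors ascending, min_dist ascending, seeds ascending and
    k ascending; the same seed value drives both the embedding and k-means
    at a grid point.  The highest-silhouette solution wins; exact ties go to
    the smaller k, then to the earlier grid position.  If the best falls
    below the silhouette floor the result is flagged as a failure report
    (``accepted=False``) but still carries the best-found solution.
    """
    if grid is None:
        grid = GridSpec()
    if matrix.shape[0] == 0 or matrix.shape[1] == 0:
        raise ValueError("empty matrix")
    best: ClusterSolution | None = None
    n_eval = 0
    for nn in sorted(grid.n_neighbors):
        if matrix.shape[0] < nn + 1:
            warnings.warn(f"skipping n_neighbors={nn}: only {matrix.shape[0]} rows")
            continue
        for md in sorted(grid.min_dist):
            for seed in sorted(grid.seeds):
                emb = embed(matrix, nn, md, grid.n_components, seed)
                for k in sorted(grid.k_range):
                    if k >= matrix.shape[0]:
                        continue
                    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
                    labels = km.fit_predict(np.asarray(emb))
                    if len(np.unique(labels)) < 2:
                        continue
                    sil = silhouette_score(emb, labels)
                    n_eval += 1
                    better = best is None or sil > best.silhouette or (
                        sil == best.silhouette and k < best.k
                    )
                    if better:
                        best = ClusterSolution(
                            labels=pd.Series(labels, index=matrix.index, name="cluster"),
                            k=int(len(np.unique(labels))),
                            silhouette=sil,
                            params={
                                "n_neighbors": nn,
                                "min_dist": md,
                                "n_components": grid.n_components,
                                "umap_seed": seed,
                                "kmeans_seed": seed,
                            },
                            embedding=emb,
                        )
    if best is None:
        raise ValueError("no feasible grid point (matrix too small for every n_neighbors)")
    return GridSearchResult(
        best=best,
        accepted=best.silhouette >= grid.min_silhouette,
        min_silhouette=grid.min_silhouette,
        n_evaluated=n_eval,
    )


def subset_cancer_keywords(
    matrix: pd.DataFrame,
    names: Mapping[str, str] | None = None,
    keywords: Iterable[str] = CANCER_KEYWORDS,
) -> tuple[pd.DataFrame, list[str]]:
    """Restrict the ER matrix to cancer-keyword pathways.

    Columns whose pathway name contains any keyword (case-insensitive
    substring) are kept; rows (chemicals) keeping at least one nonzero cell
    are retained.  ``names`` maps set_id -> display name; column labels are
    used directly when it is omitted.

    Returns ``(submatrix, retained chemicals)``.
    """
    kws = [k.lower() for k in keywords]
    cols = []
    for col in matrix.columns:
        name = names.get(col, "") if names is not None else str(col)
        if any(kw in str(name).lower() for kw in kws):
            cols.append(col)
    if not cols:
        warnings.warn("no pathway name matches a cancer keyword")
        return matrix.iloc[:0, :0], []
    sub = matrix[cols]
    keep = sub.index[(sub != 0).any(axis=1)]
    sub = sub.loc[keep]
    return sub, list(keep)


def cluster_er_matrix(
    er_matrix: pd.DataFrame,
    grid: GridSpec | None = None,
    target_variance: float = 0.95,
) -> GridSearchResult:
    """Convenience wrapper: PCA to the variance target, then the grid search."""
    reduced = reduce_pca(er_matrix, target_variance)
    return grid_search_clustering(reduced, grid)
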