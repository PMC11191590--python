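"""Per-cluster pathway profiles.

Within each chemical cluster, pathways from the cancer-focused collection
whose enrichment ratios vary strongly across the cluster's additives
(standard deviation above a per-cluster threshold) are selected; additives
enriching none of them are dropped.  The selected submatrix is
column-standardized and both axes are ordered by hierarchical clustering
for heatmap display.  Three headline lists summarize each cluster: the
*central* pathways (top 50 by number of enriching additives), the *uniquely
enriched* pathways (central here, central nowhere else), and the *highly
enriched* pathways (some additive reaches ER >= 100).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

__all__ = [
    "ClusterProfile",
    "select_differential_pathways",
    "scale_columns",
    "hierarchical_order",
    "central_pathways",
    "uniquely_enriched",
    "highly_enriched",
    "build_cluster_profile",
    "plot_profile_heatmap",
]

CANCER_CATEGORIES = (
    "cancer type",
    "cell cycle/proliferation",
    "cell death/survival",
    "DNA damage",
    "immune",
    "metabolism",
)


def select_differential_pathways(
    er_rows: pd.DataFrame,
    candidates: Sequence[str] | None = None,
    sd_threshold: float = 10.0,
) -> tuple[list[str], list[str]]:
    """Pathways with cross-additive ER standard deviation above the threshold.

    ``er_rows`` holds the cluster's additives (rows) × pathways (columns).
    SD uses the sample convention (n-1).  Additives enriching none of the
    selected pathways are dropped from the retained-additive list.

    Returns ``(selected set_ids, retained additives)``.
    """
    if er_rows.shape[0] == 0:
        raise ValueError("cluster has no additives")
    cols = er_rows.columns if candidates is None else [c for c in candidates if c in er_rows.columns]
    sub = er_rows[list(cols)]
    sd = sub.std(axis=0, ddof=1) if sub.shape[0] > 1 else pd.Series(0.0, index=sub.columns)
    selected = [c for c in sub.columns if sd[c] > sd_threshold]
    if not selected:
        warnings.warn(f"no pathway exceeds SD threshold {sd_threshold}")
        return [], []
    kept = sub[selected]
    retained = [cas for cas in kept.index if (kept.loc[cas] != 0).any()]
    return selected, retained


def scale_columns(matrix: pd.DataFrame) -> pd.DataFrame:
    """Center each column to mean 0 and divide by its sample SD (n-1).

    Constant columns become all-zero with a warning, matching the convention
    of R's ``scale()`` up to its NaN handling.
    """
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 rows to standardize")
    X = matrix.astype(float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    out = X - mu
    constant = sd == 0
    if constant.any():
        warnings.warn(f"{int(constant.sum())} constant column(s) set to zero")
    out.loc[:, ~constant] = out.loc[:, ~constant] / sd[~constant]
    out.loc[:, constant] = 0.0
    return out


def hierarchical_order(
    matrix: pd.DataFrame,
    axis: int = 0,
    metric: str = "euclidean",
    method: str = "complete",
) -> list:
    """Dendrogram leaf order from agglomerative clustering along one axis.

    axis=0 orders rows, axis=1 orders columns.  Scipy's deterministic
    tie-handling (input index order) makes the result reproducible.
    """
    X = matrix.T if axis == 1 else matrix
    labels = list(X.index)
    if len(labels) < 2:
        return labels
    Z = linkage(pdist(np.asarray(X, dtype=float), metric=metric), method=method)
    return [labels[i] for i in leaves_list(Z)]


def central_pathways(binary: pd.DataFrame, top_n: int = 50) -> list[str]:
    """Top pathways by number of enriching additives in the cluster.

    ``binary`` is an additives × pathways 0/1 (or truthy) matrix.  Ranking is
    by descending additive count with ties broken by set_id; at most
    ``top_n`` pathways are returned.
    """
    counts = (binary.astype(bool)).sum(axis=0)
    ranked = sorted(counts.index, key=lambda s: (-counts[s], str(s)))
    return [s for s in ranked if counts[s] > 0][:top_n]


def uniquely_enriched(central: Mapping[object, Sequence[str]]) -> dict[object, list[str]]:
    """Per cluster: its central pathways absent from every other cluster's list."""
    out = {}
    for cid, paths in central.items():
        others = set().union(*(set(p) for c, p in central.items() if c != cid)) if len(central) > 1 else set()
        out[cid] = [p for p in paths if p not in others]
    return out


def highly_enriched(er_rows: pd.DataFrame, er_floor: float = 100.0) -> list[str]:
    """Pathways whose maximum ER over the cluster's additives reaches the floor."""
    if er_rows.shape[0] == 0:
        return []
    mx = er_rows.max(axis=0)
    return sorted(c for c in er_rows.columns if mx[c] >= er_floor)


@dataclass
class ClusterProfile:
    """Heatmap-ready characterization of one chemical cluster."""

    cluster_id: object
    selected_pathways: list[str]
    retained_additives: list[str]
    scaled_matrix: pd.DataFrame
    additive_order: list[str]
    pathway_order: list[str]
    category_of: dict[str, str] = field(default_factory=dict)


def build_cluster_profile(
    cluster_id: object,
    er_rows: pd.DataFrame,
    candidates: Sequence[str] | None = None,
    sd_threshold: float = 10.0,
    categories: Mapping[str, str] | None = None,
) -> ClusterProfile:
    """Select differential pathways, standardize, and order both axes.

    ``categories`` is a user-supplied pathway -> cancer-relation category
    lookup; it is validated for coverage of the selected pathways and never
    invented.
    """
    selected, retained = select_differential_pathways(er_rows, candidates, sd_threshold)
    if not selected or len(retained) < 2:
        return ClusterProfile(cluster_id, selected, retained,
                              pd.DataFrame(), retained, selected)
    sub = er_rows.loc[retained, selected]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        scaled = scale_columns(sub)
    cat: dict[str, str] = {}
    if categories is not None:
        missing = [p for p in selected if p not in categories]
        if missing:
            raise KeyError(f"pathways without a category assignment: {missing}")
        bad = {p: categories[p] for p in selected if categories[p] not in CANCER_CATEGORIES}
        if bad:
            raise ValueError(f"unknown cancer-relation categories: {bad}")
        cat = {p: categories[p] for p in selected}
    return ClusterProfile(
        cluster_id=cluster_id,
        selected_pathways=selected,
        retained_additives=retained,
        scaled_matrix=scaled,
        additive_order=hierarchical_order(scaled, axis=0),
        pathway_order=hierarchical_order(scaled, axis=1),
        category_of=cat,
    )


def plot_profile_heatmap(profile: ClusterProfile, path: str | None = None):
    """Basic heatmap of a cluster profile with dendrogram leaf orders.

    Returns the matplotlib Figure; writes it to ``path`` when given.
    Rendering-quality heatmaps (annotations, category sidebars) are out of
    scope — this is a quick-look plot.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    m = profile.scaled_matrix.reindex(
        index=profile.additive_order, columns=profile.pathway_order
    )
    fig, ax = plt.subplots(
        figsize=(max(4, 0.3 * m.shape[1]), max(3, 0.15 * m.shape[0]))
    )
    im = ax.imshow(m.to_numpy(), aspect="auto", cmap="RdBu_r")
    ax.set_xticks(range(m.shape[1]), m.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(m.shape[0]), m.index, fontsize=5)
    ax.set_title(f"cluster {profile.cluster_id}: scaled ER")
    fig.colorbar(im, ax=ax, label="scaled ER")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
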