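"""Cross-group overlap of gene-expression impacts.

Chemicals of unknown carcinogenicity (IARC Group 3 or unclassified) are
compared against confirmed carcinogens (Group 1) through raw intersection
counts of their upregulated genes, downregulated genes, and significantly
enriched pathways; the queries with the largest aggregate overlap against
the reference group are ranked, and each query is profiled against the
union of pathways enriched by any reference chemical.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

__all__ = [
    "OverlapResult",
    "pairwise_overlap",
    "top_overlapping",
    "pathway_union_profile",
    "jaccard",
]


@dataclass(frozen=True)
class OverlapResult:
    cas_a: str
    cas_b: str
    shared_up: int
    shared_down: int
    shared_pathways: int


def _sets_for(cas: str, directions: Mapping[str, Mapping[str, set]], pathways: Mapping[str, set]):
    if cas not in directions and cas not in pathways:
        raise KeyError(f"unknown chemical: {cas}")
    d = directions.get(cas, {"up": set(), "down": set()})
    return d.get("up", set()), d.get("down", set()), pathways.get(cas, set())


def pairwise_overlap(
    cas_a: str,
    cas_b: str,
    directions: Mapping[str, Mapping[str, set]],
    pathways: Mapping[str, set],
) -> OverlapResult:
    """Intersection counts of up genes, down genes, and enriched pathways.

    ``directions`` is the per-chemical ``{"up": set, "down": set}`` map (see
    :func:`addscreen.gene_interactions.direction_sets`); ``pathways`` maps
    each chemical to its significant set_ids.
    """
    up_a, down_a, path_a = _sets_for(cas_a, directions, pathways)
    up_b, down_b, path_b = _sets_for(cas_b, directions, pathways)
    return OverlapResult(
        cas_a=cas_a,
        cas_b=cas_b,
        shared_up=len(up_a & up_b),
        shared_down=len(down_a & down_b),
        shared_pathways=len(path_a & path_b),
    )


_METRICS = {"up": "shared_up", "down": "shared_down", "pathways": "shared_pathways"}


def top_overlapping(
    query_group: Sequence[str],
    reference_group: Sequence[str],
    directions: Mapping[str, Mapping[str, set]],
    pathways: Mapping[str, set],
    metric: str = "up",
    k: int = 10,
    aggregate: str = "sum",
) -> pd.DataFrame:
    """Rank query chemicals by their overlap with the reference group.

    Each query's per-reference overlaps on the chosen metric are aggregated
    (sum by default, max optionally); queries are ranked descending with ties
    broken by CAS, and the top ``k`` are returned together with each query's
    best-matched reference chemical.
    """
    if metric not in _METRICS:
        raise ValueError(f"metric must be one of {sorted(_METRICS)}")
    if not query_group or not reference_group:
        raise ValueError("query and reference groups must be nonempty")
    attr = _METRICS[metric]
    rows = []
    for q in query_group:
        per_ref = {
            ref: getattr(pairwise_overlap(q, ref, directions, pathways), attr)
            for ref in reference_group
        }
        agg = sum(per_ref.values()) if aggregate == "sum" else max(per_ref.values())
        best_ref = min(per_ref, key=lambda r: (-per_ref[r], r))
        rows.append(
            {
                "cas": q,
                "aggregate_overlap": agg,
                "best_reference": best_ref,
                "best_reference_overlap": per_ref[best_ref],
            }
        )
    out = pd.DataFrame(rows).sort_values(
        ["aggregate_overlap", "cas"], ascending=[False, True], kind="mergesort"
    )
    return out.head(k).reset_index(drop=True)


def pathway_union_profile(
    reference_group: Sequence[str],
    query_group: Sequence[str],
    pathways: Mapping[str, set],
) -> pd.DataFrame:
    """Percent of the reference group's pathway union enriched by each query.

    U is the union of significant pathways over the reference group; each
    query scores 100 * |sig_q ∩ U| / |U|.  Queries at exactly zero are
    flagged (displays typically show the nonzero entries).
    """
    union: set = set()
    for ref in reference_group:
        union |= pathways.get(ref, set())
    if not union:
        raise ValueError("reference group has no enriched pathways")
    rows = []
    for q in query_group:
        shared = len(pathways.get(q, set()) & union)
        pct = 100.0 * shared / len(union)
        rows.append({"cas": q, "pct_of_reference_union": pct, "n_shared": shared,
                     "zero": shared == 0})
    return pd.DataFrame(rows)


def jaccard(a: set, b: set) -> float:
    """Optional similarity extra: |a ∩ b| / |a ∪ b| (0 for two empty sets)."""
    union = a | b
    return len(a & b) / len(union) if union else 0.0
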