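"""Chemical–gene interaction records and ortholog remapping.

Interaction tables follow the Comparative Toxicogenomics Database export
shape: one row per (chemical, gene, direction-of-regulation) report, with
the interacting organism recorded.  Records whose gene identifier is
nonhuman are remapped to human Entrez IDs through an ortholog table (as
curated by MGI / HCOP); a nonhuman gene with several human orthologs expands
into one record per ortholog, and genes with no ortholog are set aside.
The over-representation input for a chemical is the deduplicated union of
its up- and downregulated human genes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "InteractionRecord",
    "remap_orthologs",
    "build_ora_input",
    "direction_sets",
    "interaction_coverage",
    "ora_coverage",
    "load_interactions",
    "write_interactions",
    "load_ortholog_map",
    "InteractionCoverage",
    "OraCoverage",
]

HUMAN = "Homo sapiens"


@dataclass(frozen=True)
class InteractionRecord:
    """One chemical–gene regulation event."""

    cas: str
    gene_id: int
    gene_symbol: str = ""
    organism: str = HUMAN
    direction: str = "up"

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down"):
            raise ValueError(f"direction must be 'up' or 'down': {self.direction!r}")

    @property
    def is_human(self) -> bool:
        return self.organism == HUMAN


def remap_orthologs(
    records: Sequence[InteractionRecord],
    ortholog_map: Mapping[int, Sequence[int]],
) -> tuple[list[InteractionRecord], list[InteractionRecord]]:
    """Substitute human orthologs for nonhuman gene identifiers.

    Human records pass through unchanged.  A nonhuman record with k mapped
    human Entrez IDs becomes k human records with the same direction; a
    nonhuman record with no mapping goes to the unmapped bucket.  Expansion
    duplicates are collapsed on (cas, gene_id, direction).

    Returns ``(remapped, unmapped)``.
    """
    remapped: list[InteractionRecord] = []
    unmapped: list[InteractionRecord] = []
    seen: set[tuple[str, int, str]] = set()

    def _emit(rec: InteractionRecord) -> None:
        key = (rec.cas, rec.gene_id, rec.direction)
        if key not in seen:
            seen.add(key)
            remapped.append(rec)

    for rec in records:
        if rec.is_human:
            _emit(rec)
            continue
        targets = ortholog_map.get(rec.gene_id)
        if not targets:
            unmapped.append(rec)
            continue
        for human_id in targets:
            _emit(replace(rec, gene_id=int(human_id), organism=HUMAN))
    return remapped, unmapped


def build_ora_input(cas: str, records: Iterable[InteractionRecord]) -> set[int]:
    """Combined up+down human gene list for one chemical (deduplicated)."""
    genes = set()
    for rec in records:
        if rec.cas != cas:
            continue
        if not rec.is_human:
            raise ValueError(f"record for {cas} not remapped to human: {rec}")
        genes.add(rec.gene_id)
    return genes


def direction_sets(
    records: Iterable[InteractionRecord],
) -> dict[str, dict[str, set[int]]]:
    """Per-chemical up/down gene sets: ``{cas: {"up": set, "down": set}}``.

    A gene reported in both directions for one chemical appears in both sets.
    """
    out: dict[str, dict[str, set[int]]] = {}
    for rec in records:
        d = out.setdefault(rec.cas, {"up": set(), "down": set()})
        d[rec.direction].add(rec.gene_id)
    return out


@dataclass
class InteractionCoverage:
    n_registry: int
    n_with_interactions: int
    n_classified_with: int
    n_unclassified_with: int

    @property
    def pct_with_interactions(self) -> float:
        return 100.0 * self.n_with_interactions / self.n_registry


def interaction_coverage(
    is_classified: Mapping[str, bool],
    records: Iterable[InteractionRecord],
) -> InteractionCoverage:
    """Count registry chemicals with at least one gene interaction, split by
    the classified/unclassified partition."""
    with_data = {rec.cas for rec in records} & set(is_classified)
    n_classified = sum(1 for cas in with_data if is_classified[cas])
    return InteractionCoverage(
        n_registry=len(is_classified),
        n_with_interactions=len(with_data),
        n_classified_with=n_classified,
        n_unclassified_with=len(with_data) - n_classified,
    )


@dataclass
class OraCoverage:
    """How many interacting chemicals yielded over-representation results."""

    n_registry: int
    n_eligible: int
    n_classified_with_interactions: int
    n_classified_eligible: int
    n_unclassified_with_interactions: int
    n_unclassified_eligible: int

    @property
    def pct_eligible_of_registry(self) -> float:
        return 100.0 * self.n_eligible / self.n_registry

    @property
    def pct_classified_eligible(self) -> float:
        return 100.0 * self.n_classified_eligible / self.n_classified_with_interactions

    @property
    def pct_unclassified_eligible(self) -> float:
        return (
            100.0 * self.n_unclassified_eligible / self.n_unclassified_with_interactions
        )


def ora_coverage(
    is_classified: Mapping[str, bool],
    interacting: Iterable[str],
    eligible: Iterable[str],
) -> OraCoverage:
    """Tally ORA eligibility against the interacting subset, per class.

    ``interacting`` are chemicals with any gene interaction; ``eligible`` are
    the subset whose ORA produced results.
    """
    interacting = set(interacting) & set(is_classified)
    eligible = set(eligible) & interacting
    cls_int = {c for c in interacting if is_classified[c]}
    cls_eli = {c for c in eligible if is_classified[c]}
    return OraCoverage(
        n_registry=len(is_classified),
        n_eligible=len(eligible),
        n_classified_with_interactions=len(cls_int),
        n_classified_eligible=len(cls_eli),
        n_unclassified_with_interactions=len(interacting) - len(cls_int),
        n_unclassified_eligible=len(eligible) - len(cls_eli),
    )


# ---------------------------------------------------------------------------
# I/O

def load_interactions(path: str) -> list[InteractionRecord]:
    df = pd.read_csv(path, dtype={"cas": str, "gene_symbol": str, "organism": str, "direction": str})
    return [
        InteractionRecord(
            cas=row.cas,
            gene_id=int(row.gene_id),
            gene_symbol=row.gene_symbol if isinstance(row.gene_symbol, str) else "",
            organism=row.organism,
            direction=row.direction,
        )
        for row in df.itertuples()
    ]


def write_interactions(records: Iterable[InteractionRecord], path: str) -> None:
    pd.DataFrame(
        [
            {
                "cas": r.cas,
                "gene_id": r.gene_id,
                "gene_symbol": r.gene_symbol,
                "organism": r.organism,
                "direction": r.direction,
            }
            for r in records
        ],
        columns=["cas", "gene_id", "gene_symbol", "organism", "direction"],
    ).to_csv(path, index=False)


def load_ortholog_map(path: str) -> dict[int, list[int]]:
    """Read a source-gene → human-Entrez TSV (one pair per row)."""
    df = pd.read_csv(path, sep="\t")
    out: dict[int, list[int]] = {}
    for row in df.itertuples():
        out.setdefault(int(row.source_gene_id), []).append(int(row.human_entrez_id))
    return out
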