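"""Over-representation analysis (ORA) with enrichment ratios.

For each chemical, the submitted gene list (all up- and downregulated genes)
is tested against every pathway gene set with the upper-tail hypergeometric
test: drawing ``input_size`` genes from a background universe of
``background_size`` genes of which ``set_size`` belong to the pathway, the
p-value is P(overlap >= observed).  P-values are adjusted per chemical with
the Benjamini–Hochberg step-up procedure, and each tested pair carries an
enrichment ratio

    ER = overlap / expect,    expect = input_size * set_size / background_size

— the fold excess of observed overlap relative to random draws.  Chemicals
are finally assembled into a chemicals × pathways ER matrix, keeping ERs of
pairs that pass the FDR gate and zero elsewhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import IO, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

__all__ = [
    "GeneSet",
    "OraResult",
    "parse_gmt",
    "write_gmt",
    "filter_gene_sets",
    "ora_test",
    "adjust_fdr",
    "enrich_chemical",
    "enrich_all",
    "build_er_matrix",
    "significant_sets",
    "results_to_frame",
]

SOURCES = ("PANTHER", "Reactome", "KEGG", "Wikipathways", "WikipathwaysCancer", "other")


@dataclass(frozen=True)
class GeneSet:
    """One named pathway with its member genes."""

    set_id: str
    name: str
    genes: frozenset[int]
    source: str = "other"

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.set_id!r} has no members")


@dataclass(frozen=True)
class OraResult:
    """One chemical × pathway enrichment outcome."""

    cas: str
    set_id: str
    overlap: int
    input_size: int
    set_size: int
    background_size: int
    expect: float
    er: float
    p: float
    fdr: float = float("nan")


def parse_gmt(stream: IO[str] | str, source: str = "other") -> list[GeneSet]:
    """Parse a GMT stream: ``set_id <tab> description <tab> member...`` per line.

    Empty lines are skipped; duplicate members within a line are collapsed.
    Lines with fewer than three fields are malformed.
    """
    if isinstance(stream, str):
        with open(stream) as fh:
            return parse_gmt(fh, source=source)
    sets = []
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"GMT line {lineno}: expected >=3 tab-separated fields")
        set_id, name, *members = fields
        # Entrez IDs become ints; symbolic members are kept verbatim
        genes = frozenset(
            int(m) if m.strip().isdigit() else m.strip()
            for m in members
            if m.strip()
        )
        if not genes:
            raise ValueError(f"GMT line {lineno}: no members")
        sets.append(GeneSet(set_id=set_id, name=name, genes=genes, source=source))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            members = "\t".join(str(g) for g in sorted(gs.genes))
            fh.write(f"{gs.set_id}\t{gs.name}\t{members}\n")


def filter_gene_sets(
    sets: Iterable[GeneSet],
    background: frozenset[int] | set[int],
    min_size: int = 10,
    max_size: int = 2000,
) -> list[GeneSet]:
    """Intersect sets with the background and keep those with effective size
    in [min_size, max_size] (bounds inclusive)."""
    if not background:
        raise ValueError("background universe is empty")
    out = []
    for gs in sets:
        eff = gs.genes & frozenset(background)
        if min_size <= len(eff) <= max_size:
            out.append(GeneSet(gs.set_id, gs.name, frozenset(eff), gs.source))
    return out


def ora_test(
    input_genes: set[int] | frozenset[int],
    gene_set: GeneSet,
    background: set[int] | frozenset[int],
    cas: str = "",
) -> OraResult:
    """Upper-tail hypergeometric test of one gene list against one set.

    The set is assumed background-filtered; input genes outside the
    background are dropped here.
    """
    if not background:
        raise ValueError("background universe is empty")
    input_in_bg = set(input_genes) & set(background)
    if not input_in_bg:
        raise ValueError("no input genes in the background universe")
    M = len(background)
    n = len(gene_set.genes)  # successes in population
    N = len(input_in_bg)  # draws
    k = len(input_in_bg & gene_set.genes)
    expect = N * n / M
    er = k / expect if expect > 0 else 0.0
    # P(X >= k); sf(k-1) is the exact upper tail
    p = float(hypergeom.sf(k - 1, M, n, N)) if k > 0 else 1.0
    p = min(p, 1.0)
    return OraResult(
        cas=cas,
        set_id=gene_set.set_id,
        overlap=k,
        input_size=N,
        set_size=n,
        background_size=M,
        expect=expect,
        er=er,
        p=p,
    )


def adjust_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    q(i) = min_{j >= i} p(j) * m / j over the sorted p-values, capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def enrich_chemical(
    cas: str,
    input_genes: set[int] | frozenset[int],
    collection: Sequence[GeneSet],
    background: set[int] | frozenset[int],
    fdr_threshold: float = 0.25,
) -> list[OraResult]:
    """Test one chemical against a filtered collection and keep FDR-passing sets.

    The BH family is the whole collection submitted for this chemical (all
    source databases pooled into one adjustment).  Results are sorted by
    adjusted p, then ER descending, then set_id.
    """
    background = frozenset(background)
    input_in_bg = frozenset(input_genes) & background
    dropped = len(set(input_genes)) - len(input_in_bg)
    if dropped:
        warnings.warn(f"{cas}: {dropped} input gene(s) outside the background dropped")
    if not input_in_bg:
        raise ValueError(f"{cas}: no input genes in the background universe")
    collection = sorted(collection, key=lambda gs: gs.set_id)
    if not collection:
        warnings.warn(f"{cas}: no eligible gene sets to test")
        return []
    results = [ora_test(input_in_bg, gs, background, cas=cas) for gs in collection]
    qs = adjust_fdr([r.p for r in results])
    results = [
        OraResult(**{**r.__dict__, "fdr": float(q)}) for r, q in zip(results, qs)
    ]
    kept = [r for r in results if r.fdr <= fdr_threshold]
    kept.sort(key=lambda r: (r.fdr, -r.er, r.set_id))
    return kept


def enrich_all(
    inputs: Mapping[str, set[int]],
    collection: Sequence[GeneSet],
    background: set[int] | frozenset[int],
    fdr_threshold: float = 0.25,
    min_size: int = 10,
    max_size: int = 2000,
) -> dict[str, list[OraResult]]:
    """Batch ORA: filter the collection once, then test every chemical.

    Chemicals whose gene list is empty after background intersection are
    skipped (they are not ORA-eligible).
    """
    background = frozenset(background)
    filtered = filter_gene_sets(collection, background, min_size, max_size)
    out: dict[str, list[OraResult]] = {}
    for cas in sorted(inputs):
        genes = frozenset(inputs[cas]) & background
        if not genes:
            continue
        out[cas] = enrich_chemical(cas, genes, filtered, background, fdr_threshold)
    return out


def significant_sets(results: Mapping[str, Sequence[OraResult]]) -> dict[str, set[str]]:
    """Per-chemical set_ids that passed the FDR gate."""
    return {cas: {r.set_id for r in rs} for cas, rs in results.items()}


def build_er_matrix(
    results: Mapping[str, Sequence[OraResult]],
    chemicals: Iterable[str] | None = None,
    set_ids: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Chemicals × pathways matrix of enrichment ratios.

    Cells hold the ER of significant (FDR-passing) pairs and 0 elsewhere.
    Rows default to chemicals with at least one significant pathway — the
    chemicals for which the ORA produced results; columns default to every
    set_id appearing in any result.
    """
    if chemicals is None:
        chemicals = sorted(cas for cas, rs in results.items() if rs)
    else:
        chemicals = sorted(chemicals)
    if set_ids is None:
        set_ids = sorted({r.set_id for rs in results.values() for r in rs})
    else:
        set_ids = sorted(set_ids)
    mat = pd.DataFrame(0.0, index=pd.Index(chemicals, name="cas"),
                       columns=pd.Index(set_ids, name="set_id"))
    for cas in chemicals:
        for r in results.get(cas, ()):
            if r.set_id in mat.columns:
                mat.at[cas, r.set_id] = r.er
    return mat


def results_to_frame(results: Mapping[str, Sequence[OraResult]]) -> pd.DataFrame:
    rows = [
        {
            "cas": r.cas,
            "set_id": r.set_id,
            "overlap": r.overlap,
            "input_size": r.input_size,
            "set_size": r.set_size,
            "background_size": r.background_size,
            "expect": r.expect,
            "er": r.er,
            "p": r.p,
            "fdr": r.fdr,
        }
        for rs in results.values()
        for r in rs
    ]
    cols = ["cas", "set_id", "overlap", "input_size", "set_size",
            "background_size", "expect", "er", "p", "fdr"]
    return pd.DataFrame(rows, columns=cols)
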