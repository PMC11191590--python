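"""CAS-keyed registry of plastic additives.

A registry row describes one additive: its CAS registry number (the unique
key), a preferred name, a literature-derived confidence grade, and usage
annotations (functions such as "plasticizer", polymers such as "PVC", and
product strings such as "shower curtain").  Several source tables may
describe the same CAS; they are merged into one record per CAS.  Product
strings are grouped into coarse categories via positive/negative substring
rules (e.g. "cloth" matches clothing, but "tablecloth" is vetoed by a
negative string).
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "CasFormatError",
    "CasChecksumError",
    "ChemicalRecord",
    "CategoryRule",
    "normalize_cas",
    "cas_check_digit",
    "merge_source_records",
    "categorize_products",
    "summarize_usage",
    "load_registry",
    "write_registry",
    "load_category_rules",
    "UsageSummary",
]

_CAS_RE = re.compile(r"^(\d{2,7})-(\d{2})-(\d)$")

#: ordering of confidence grades, best first
CONFIDENCE_ORDER = ("high", "medium", "low", "unknown")


class CasFormatError(ValueError):
    """Raised when a string does not match the NNNNNNN-NN-N CAS pattern."""


class CasChecksumError(ValueError):
    """Raised when a CAS number fails its modulo-10 check digit."""


def cas_check_digit(digits: str) -> int:
    """Check digit for the CAS body ``digits`` (all digits except the last).

    Digits are weighted 1, 2, 3, ... from the right; the weighted sum modulo
    10 is the check digit.
    """
    total = sum(w * int(d) for w, d in enumerate(reversed(digits), start=1))
    return total % 10


def normalize_cas(raw: str) -> str:
    """Validate and canonicalize a CAS registry number.

    Returns the hyphenated form with leading zeros stripped from the first
    segment, so ``"050-00-0"`` and ``"50-00-0"`` compare equal as registry
    keys.

    Raises
    ------
    CasFormatError
        If ``raw`` does not look like ``NNNNNNN-NN-N`` (2-7 leading digits).
    CasChecksumError
        If the check digit is wrong.
    """
    if not isinstance(raw, str) or not raw.strip():
        raise CasFormatError(f"empty or non-string CAS: {raw!r}")
    s = raw.strip()
    m = _CAS_RE.match(s)
    if m is None:
        raise CasFormatError(f"malformed CAS number: {raw!r}")
    head, mid, check = m.groups()
    # leading zeros contribute nothing to the weighted sum, so stripping them
    # never changes the check digit; the first segment keeps >= 2 digits
    head_stripped = head.lstrip("0").rjust(2, "0")
    expected = cas_check_digit(head_stripped + mid)
    if expected != int(check):
        raise CasChecksumError(
            f"CAS {raw!r}: check digit {check} != expected {expected}"
        )
    return f"{head_stripped}-{mid}-{check}"


@dataclass(frozen=True)
class ChemicalRecord:
    """One additive, keyed by CAS."""

    cas: str
    name: str = ""
    aliases: tuple[str, ...] = ()
    confidence: str = "unknown"
    functions: frozenset[str] = frozenset()
    polymers: frozenset[str] = frozenset()
    products: frozenset[str] = frozenset()
    product_categories: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.confidence not in CONFIDENCE_ORDER:
            raise ValueError(f"unknown confidence grade: {self.confidence!r}")


@dataclass(frozen=True)
class CategoryRule:
    """Positive/negative substring rule mapping product strings to a category."""

    category: str
    positive: tuple[str, ...]
    negative: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.positive:
            raise ValueError(f"category {self.category!r}: positive strings required")


def _conf_rank(c: str) -> int:
    return CONFIDENCE_ORDER.index(c)


def merge_source_records(records: Sequence[ChemicalRecord]) -> ChemicalRecord:
    """Merge source records sharing one CAS into a single registry record.

    The merged confidence is the best of the individual grades ("the highest
    score wins").  Usage annotations are unioned.  The preferred name comes
    from the highest-confidence record, lexicographic ties going to the
    smaller name; all other names are kept as aliases.
    """
    if not records:
        raise ValueError("cannot merge an empty record list")
    cas_values = {r.cas for r in records}
    if len(cas_values) != 1:
        raise ValueError(f"records mix CAS numbers: {sorted(cas_values)}")
    best_conf = min(records, key=lambda r: _conf_rank(r.confidence)).confidence
    named = sorted(
        (r for r in records if r.name),
        key=lambda r: (_conf_rank(r.confidence), r.name),
    )
    name = named[0].name if named else ""
    aliases = set()
    for r in records:
        aliases.update(r.aliases)
        if r.name:
            aliases.add(r.name)
    aliases.discard(name)
    return ChemicalRecord(
        cas=records[0].cas,
        name=name,
        aliases=tuple(sorted(aliases)),
        confidence=best_conf,
        functions=frozenset().union(*(r.functions for r in records)),
        polymers=frozenset().union(*(r.polymers for r in records)),
        products=frozenset().union(*(r.products for r in records)),
        product_categories=frozenset().union(
            *(r.product_categories for r in records)
        ),
    )


def _norm_text(s: str) -> str:
    return " ".join(s.lower().split())


def categorize_products(
    products: Iterable[str], rules: Sequence[CategoryRule]
) -> set[str]:
    """Assign product strings to categories via substring rules.

    A product string matches a category iff it contains at least one of the
    category's positive substrings and none of its negative substrings
    (case-insensitive, whitespace-normalized).  The result is the union of
    matches over all product strings.
    """
    out: set[str] = set()
    for product in products:
        p = _norm_text(product)
        for rule in rules:
            if rule.category in out:
                continue
            if any(_norm_text(neg) in p for neg in rule.negative):
                continue
            if any(_norm_text(pos) in p for pos in rule.positive):
                out.add(rule.category)
    return out


@dataclass
class UsageSummary:
    """Usage annotation tallies over a registry."""

    per_additive: pd.DataFrame
    #: per-additive association-count distributions, zero-count additives excluded
    histograms: dict[str, pd.Series]
    #: additive counts per polymer / function / product category
    rankings: dict[str, pd.Series]
    means: dict[str, float] = field(default_factory=dict)


def summarize_usage(
    registry: Mapping[str, ChemicalRecord], top_n: int = 10
) -> UsageSummary:
    """Tally usage annotations: associations per additive and additives per
    polymer / function / product category.

    Additives with zero associations in a category are excluded from that
    category's per-additive distribution (but still appear in
    ``per_additive`` with a zero count).
    """
    axes = {
        "polymers": lambda r: r.polymers,
        "functions": lambda r: r.functions,
        "products": lambda r: r.products,
        "product_categories": lambda r: r.product_categories,
    }
    per = pd.DataFrame(
        {
            "cas": list(registry),
            **{
                f"n_{axis}": [len(get(r)) for r in registry.values()]
                for axis, get in axes.items()
            },
        }
    ).set_index("cas")
    histograms: dict[str, pd.Series] = {}
    means: dict[str, float] = {}
    rankings: dict[str, pd.Series] = {}
    for axis, get in axes.items():
        counts = per[f"n_{axis}"]
        nonzero = counts[counts > 0]
        histograms[axis] = nonzero.value_counts().sort_index()
        means[axis] = float(nonzero.mean()) if len(nonzero) else float("nan")
        tally: dict[str, int] = {}
        for r in registry.values():
            for item in get(r):
                tally[item] = tally.get(item, 0) + 1
        rankings[axis] = (
            pd.Series(tally, dtype="int64")
            .sort_values(ascending=False, kind="mergesort")
            .head(top_n)
        )
    return UsageSummary(per_additive=per, histograms=histograms, rankings=rankings, means=means)


# ---------------------------------------------------------------------------
# file I/O — registry CSV dialect with pipe-delimited multi-valued fields

_MULTI = ("aliases", "functions", "polymers", "products", "product_categories")


def _split_multi(v: object) -> frozenset[str]:
    if v is None or (isinstance(v, float) and pd.isna(v)) or v == "":
        return frozenset()
    return frozenset(s.strip() for s in str(v).split("|") if s.strip())


def load_registry(
    paths: str | Iterable[str],
    rules: Sequence[CategoryRule] | None = None,
    rejects: list[dict] | None = None,
) -> dict[str, ChemicalRecord]:
    """Load one or more registry CSVs, validate CAS keys, and merge per CAS.

    Rows whose CAS fails validation are quarantined into ``rejects`` (if a
    list is supplied) rather than silently dropped.  When ``rules`` is given,
    product categories are (re)derived from product strings.
    """
    if isinstance(paths, str):
        paths = [paths]
    by_cas: dict[str, list[ChemicalRecord]] = {}
    for path in paths:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        for row in df.to_dict("records"):
            try:
                cas = normalize_cas(row.get("cas", ""))
            except (CasFormatError, CasChecksumError) as exc:
                if rejects is not None:
                    rejects.append({**row, "reason": str(exc)})
                else:
                    warnings.warn(f"rejected registry row: {exc}")
                continue
            rec = ChemicalRecord(
                cas=cas,
                name=row.get("name", "") or "",
                aliases=tuple(sorted(_split_multi(row.get("aliases")))),
                confidence=(row.get("confidence") or "unknown").strip().lower()
                or "unknown",
                functions=_split_multi(row.get("functions")),
                polymers=_split_multi(row.get("polymers")),
                products=_split_multi(row.get("products")),
                product_categories=_split_multi(row.get("product_categories")),
            )
            by_cas.setdefault(cas, []).append(rec)
    registry = {cas: merge_source_records(recs) for cas, recs in sorted(by_cas.items())}
    if rules is not None:
        registry = {
            cas: replace(
                rec,
                product_categories=frozenset(categorize_products(rec.products, rules)),
            )
            for cas, rec in registry.items()
        }
    return registry


def write_registry(registry: Mapping[str, ChemicalRecord], path: str) -> None:
    rows = []
    for rec in registry.values():
        row = {"cas": rec.cas, "name": rec.name, "confidence": rec.confidence}
        for f in _MULTI:
            row[f] = "|".join(sorted(getattr(rec, f)))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def load_category_rules(path: str) -> list[CategoryRule]:
    """Read category rules from CSV (category,kind,string) or JSON.

    The JSON form is a list of ``{"category": ..., "positive": [...],
    "negative": [...]}`` objects.
    """
    if path.endswith(".json"):
        with open(path) as fh:
            data = json.load(fh)
        return [
            CategoryRule(
                category=d["category"],
                positive=tuple(d["positive"]),
                negative=tuple(d.get("negative", ())),
            )
            for d in data
        ]
    df = pd.read_csv(path, dtype=str)
    rules = []
    for cat, grp in df.groupby("category", sort=True):
        pos = tuple(grp.loc[grp["kind"] == "positive", "string"])
        neg = tuple(grp.loc[grp["kind"] == "negative", "string"])
        rules.append(CategoryRule(category=str(cat), positive=pos, negative=neg))
    return rules
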