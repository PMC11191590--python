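"""Harmonization of IARC and IRIS carcinogenicity classifications.

IARC assigns chemicals to monograph groups (1 carcinogenic, 2A probably,
2B possibly, 3 inadequate evidence); some chemicals are present in the
database without a group.  EPA IRIS assigns per-route descriptors that can
disagree between exposure routes; the most severe descriptor represents the
chemical.  The analysis partition is:

* carcinogen   — IARC Group 1, 2A or 2B
* classified   — carcinogens plus Group 3 (carcinogenic potential evaluated)
* unclassified — absent from IARC, or present without a group

Cross-database consistency compares the binary cancer verdicts of the two
databases under an explicit, overridable correspondence table.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ._util import round_half_up

__all__ = [
    "IarcGroup",
    "IrisStatus",
    "DerivedClass",
    "Verdict",
    "derive_class",
    "resolve_iris_multiroute",
    "consistency_check",
    "coverage_summary",
    "consistency_report",
    "DEFAULT_CORRESPONDENCE",
]


class IarcGroup(str, Enum):
    G1 = "G1"
    G2A = "G2A"
    G2B = "G2B"
    G3 = "G3"
    PRESENT_UNASSIGNED = "present_unassigned"
    ABSENT = "absent"


class IrisStatus(str, Enum):
    CARCINOGEN = "carcinogen"
    LIKELY_CARCINOGEN = "likely_carcinogen"
    PROBABLE_CARCINOGEN = "probable_carcinogen"
    POSSIBLE_CARCINOGEN = "possible_carcinogen"
    SUGGESTIVE = "suggestive"
    NONCANCER = "noncancer"
    ABSENT = "absent"


#: IRIS descriptors ordered most-carcinogenic first (absent excluded)
_IRIS_SEVERITY = (
    IrisStatus.CARCINOGEN,
    IrisStatus.LIKELY_CARCINOGEN,
    IrisStatus.PROBABLE_CARCINOGEN,
    IrisStatus.POSSIBLE_CARCINOGEN,
    IrisStatus.SUGGESTIVE,
    IrisStatus.NONCANCER,
)


@dataclass(frozen=True)
class DerivedClass:
    is_carcinogen: bool
    is_classified: bool

    def __post_init__(self) -> None:
        if self.is_carcinogen and not self.is_classified:
            raise ValueError("a carcinogen is by definition classified")

    @property
    def label(self) -> str:
        if self.is_carcinogen:
            return "carcinogen"
        return "classified_noncarcinogen" if self.is_classified else "unclassified"


def derive_class(iarc: IarcGroup) -> DerivedClass:
    """Map an IARC group to the carcinogen / classified / unclassified partition."""
    iarc = IarcGroup(iarc)
    if iarc in (IarcGroup.G1, IarcGroup.G2A, IarcGroup.G2B):
        return DerivedClass(is_carcinogen=True, is_classified=True)
    if iarc is IarcGroup.G3:
        return DerivedClass(is_carcinogen=False, is_classified=True)
    return DerivedClass(is_carcinogen=False, is_classified=False)


def resolve_iris_multiroute(entries: Sequence[IrisStatus | str]) -> IrisStatus:
    """Collapse per-exposure-route IRIS descriptors to one per chemical.

    A chemical listed as carcinogenic for any route counts as carcinogenic:
    the most severe descriptor present wins.
    """
    if not entries:
        raise ValueError("no IRIS entries to resolve")
    statuses = {IrisStatus(e) for e in entries}
    statuses.discard(IrisStatus.ABSENT)
    if not statuses:
        return IrisStatus.ABSENT
    return min(statuses, key=_IRIS_SEVERITY.index)


class Verdict(str, Enum):
    CONSISTENT = "consistent"
    INCONSISTENT = "inconsistent"
    NOT_COMPARABLE = "not_comparable"


def _default_correspondence() -> dict[tuple[IarcGroup, IrisStatus], Verdict]:
    """Binary cancer verdicts: IARC 1/2A/2B vs IRIS carcinogen..suggestive."""
    iarc_cancer = {IarcGroup.G1, IarcGroup.G2A, IarcGroup.G2B}
    iris_cancer = set(_IRIS_SEVERITY) - {IrisStatus.NONCANCER}
    table = {}
    for g in (IarcGroup.G1, IarcGroup.G2A, IarcGroup.G2B, IarcGroup.G3):
        for s in _IRIS_SEVERITY:
            agree = (g in iarc_cancer) == (s in iris_cancer)
            table[(g, s)] = Verdict.CONSISTENT if agree else Verdict.INCONSISTENT
    return table


DEFAULT_CORRESPONDENCE = _default_correspondence()


def consistency_check(
    iarc: IarcGroup | str,
    iris: IrisStatus | str,
    correspondence: Mapping[tuple[IarcGroup, IrisStatus], Verdict] | None = None,
) -> Verdict:
    """Compare the IARC and IRIS verdicts for one chemical.

    Chemicals absent from either database — or present in IARC without a
    group — are not comparable.
    """
    iarc, iris = IarcGroup(iarc), IrisStatus(iris)
    if iarc in (IarcGroup.ABSENT, IarcGroup.PRESENT_UNASSIGNED) or iris is IrisStatus.ABSENT:
        return Verdict.NOT_COMPARABLE
    table = DEFAULT_CORRESPONDENCE if correspondence is None else correspondence
    return table.get((iarc, iris), Verdict.NOT_COMPARABLE)


def consistency_report(
    iarc_labels: Mapping[str, IarcGroup],
    iris_labels: Mapping[str, IrisStatus],
    correspondence: Mapping[tuple[IarcGroup, IrisStatus], Verdict] | None = None,
) -> pd.DataFrame:
    """Per-chemical verdict table over the union of both label maps."""
    rows = []
    for cas in sorted(set(iarc_labels) | set(iris_labels)):
        g = IarcGroup(iarc_labels.get(cas, IarcGroup.ABSENT))
        s = IrisStatus(iris_labels.get(cas, IrisStatus.ABSENT))
        rows.append(
            {
                "cas": cas,
                "iarc_group": g.value,
                "iris_status": s.value,
                "verdict": consistency_check(g, s, correspondence).value,
            }
        )
    return pd.DataFrame(rows)


def coverage_summary(
    labels: Mapping[str, Enum] | pd.Series,
    absent_value: Enum,
    order: Iterable[Enum] | None = None,
    decimals: int = 2,
) -> pd.DataFrame:
    """Tabulate database coverage: counts and percentages per label.

    Percentages are reported over two explicit denominators: the whole
    registry (``pct_of_registry``) and the present-in-database subset
    (``pct_of_present``; blank for the absent row).  Raw unrounded values are
    kept alongside half-up-rounded ones so callers can choose the printed
    precision.
    """
    s = pd.Series(dict(labels)) if not isinstance(labels, pd.Series) else labels
    if s.empty:
        raise ValueError("empty registry")
    n_total = int(len(s))
    counts = s.value_counts()
    n_present = n_total - int(counts.get(absent_value, 0))
    values = list(order) if order is not None else sorted(counts.index, key=str)
    rows = []
    for v in values:
        c = int(counts.get(v, 0))
        pct_reg = 100.0 * c / n_total
        row = {
            "label": getattr(v, "value", v),
            "count": c,
            "pct_of_registry": pct_reg,
            "pct_of_registry_rounded": round_half_up(pct_reg, decimals),
        }
        if v != absent_value and n_present > 0:
            pct_present = 100.0 * c / n_present
            row["pct_of_present"] = pct_present
            row["pct_of_present_rounded"] = round_half_up(pct_present, decimals)
        rows.append(row)
    out = pd.DataFrame(rows).set_index("label")
    out.attrs["n_total"] = n_total
    out.attrs["n_present"] = n_present
    return out
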