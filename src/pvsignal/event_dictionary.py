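"""PT case definitions by substring matching over SMQ PT lists.

A case definition is a :class:`PtQuery`: a set of lowercase substrings
applied to the (narrow-scope) PT lists of one or more Standardized MedDRA
Queries. The composite gastrointestinal obstruction/perforation definition
uses nine substrings over SMQ 20000104 / 20000105 / 20000107; the
obstruction, perforation and ileus sub-definitions restrict the substring
list. MedDRA itself is licensed, so the SMQ→PT dictionary is always a
user-supplied file; tests ship a small synthetic stand-in.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
import yaml

from .srs_store import SrsDatabase

SOURCE_SMQS = ("20000104", "20000105", "20000107")

COMPOSITE_SUBSTRINGS = (
    "ileus",
    "stenosis",
    "obstruction",
    "obstructive",
    "impaction",
    "perforation",
    "perforated",
    "hypomotility",
    "intussusception",
)


@dataclass(frozen=True)
class SmqDefinition:
    smq_id: str
    name: str
    scope: str  # "narrow" or "broad"
    pts: tuple[str, ...]

    def __post_init__(self):
        if not self.pts:
            raise ValueError(f"SMQ {self.smq_id}: empty PT list")
        if self.scope not in ("narrow", "broad"):
            raise ValueError(f"SMQ {self.smq_id}: scope must be narrow|broad")


@dataclass(frozen=True)
class PtQuery:
    label: str
    substrings: tuple[str, ...]
    source_smqs: tuple[str, ...] = SOURCE_SMQS

    def __post_init__(self):
        if not self.substrings:
            raise ValueError("PtQuery needs at least one substring")
        object.__setattr__(self, "substrings", tuple(s.casefold() for s in self.substrings))


@dataclass(frozen=True)
class PtSet:
    """A deterministic, duplicate-free, sorted set of PT names."""

    label: str
    pts: tuple[str, ...] = field(default=())

    def __post_init__(self):
        object.__setattr__(self, "pts", tuple(sorted(set(self.pts))))

    def __len__(self) -> int:
        return len(self.pts)

    def __contains__(self, pt: str) -> bool:
        return pt in self.pts


def load_smq_dictionary(path) -> list[SmqDefinition]:
    """Read a CSV with columns smq_id, smq_name, scope, pt_name
    (one row per SMQ/scope/PT)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"smq_id", "smq_name", "scope", "pt_name"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: needs columns {sorted(required)}")
    out = []
    for (smq_id, name, scope), grp in df.groupby(["smq_id", "smq_name", "scope"], sort=True):
        out.append(SmqDefinition(smq_id=str(smq_id).strip(), name=name, scope=scope.strip().casefold(),
                                 pts=tuple(grp["pt_name"].str.strip())))
    return out


def load_queries(path) -> dict[str, PtQuery]:
    """Read case-definition queries from YAML: a list of
    {label, substrings, source_smqs}."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    queries = {}
    for item in raw["queries"]:
        q = PtQuery(
            label=item["label"],
            substrings=tuple(item["substrings"]),
            source_smqs=tuple(str(s) for s in item.get("source_smqs", SOURCE_SMQS)),
        )
        queries[q.label] = q
    return queries


def select_pts(smqs: list[SmqDefinition], query: PtQuery) -> PtSet:
    """Union, over the query's source SMQs, of PTs whose case-folded name
    contains at least one query substring. PTs shared between SMQs dedupe.
    Output is order-invariant to both SMQ list order and PT order."""
    by_id: dict[str, list[SmqDefinition]] = {}
    for s in smqs:
        by_id.setdefault(s.smq_id, []).append(s)
    unknown = [sid for sid in query.source_smqs if sid not in by_id]
    if unknown:
        raise KeyError(f"query '{query.label}': unknown SMQ id(s) {unknown}")
    hits: set[str] = set()
    for sid in query.source_smqs:
        for smq in by_id[sid]:
            for pt in smq.pts:
                folded = pt.casefold()
                if any(sub in folded for sub in query.substrings):
                    hits.add(pt)
    return PtSet(label=query.label, pts=tuple(hits))


def standard_queries() -> dict[str, PtQuery]:
    """The four case definitions: the nine-substring composite plus the
    obstruction / perforation / ileus restrictions, all sourced from
    SMQ 20000104, 20000105 and 20000107 (narrow scope)."""
    return {
        "composite": PtQuery("composite", COMPOSITE_SUBSTRINGS),
        "obstruction": PtQuery("obstruction", ("obstruction", "obstructive", "impaction")),
        "perforation": PtQuery("perforation", ("perforation", "perforated")),
        "ileus": PtQuery("ileus", ("ileus",)),
    }


def reports_with_events(db: SrsDatabase, pt_set: PtSet) -> set[str]:
    """Report_ids with at least one REAC row whose PT is in the set;
    a report with several matching PTs counts once."""
    if len(pt_set) == 0:
        raise ValueError("empty PT set")
    mask = db.reac["pt_name"].isin(pt_set.pts)
    return set(db.reac.loc[mask, "report_id"])
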