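"""Load, validate, link and filter the four-table SRS relational schema.

The data model mirrors JADER: DEMO (one row per report), DRUG (reported
drugs with an involvement code), HIST (primary illness), REAC (adverse
events coded as MedDRA PTs, with onset date and outcome). All tables link
on ``report_id``; referential integrity (every child row's report_id exists
in DEMO) is enforced at load and re-checked after every transformation.

Counting unit everywhere downstream is the *report*: a drug reported twice
in one report, or an event coded under two matching PTs, contributes one.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass, field, replace

import pandas as pd

from .dates import complete_dates, parse_partial_date

INVOLVEMENT_CODES = ("suspected", "concomitant", "interacting")
OUTCOME_CATEGORIES = (
    "death",
    "with_sequelae",
    "not_recovered",
    "convalescent",
    "recovery",
    "others",
)

DEMO_COLUMNS = {"report_id": "report_id", "sex": "sex", "age_band": "age_band", "reporting_year": "reporting_year"}
DRUG_COLUMNS = {
    "report_id": "report_id",
    "drug_name": "drug_name",
    "involvement": "involvement",
    "route": "route",
    "start_date": "start_date",
    "end_date": "end_date",
}
HIST_COLUMNS = {"report_id": "report_id", "illness": "illness"}
REAC_COLUMNS = {"report_id": "report_id", "pt_name": "pt_name", "onset_date": "onset_date", "outcome": "outcome"}


def normalize_name(name: object) -> str:
    """Normalize a free-text drug name: NFKC (full-width → half-width),
    trim, collapse internal whitespace, casefold."""
    if name is None or (isinstance(name, float) and pd.isna(name)):
        return ""
    s = unicodedata.normalize("NFKC", str(name))
    return " ".join(s.split()).casefold()


@dataclass
class LoadReport:
    """Row-level accounting of everything dropped or repaired at load."""

    n_reports: int = 0
    n_drug_rows: int = 0
    n_hist_rows: int = 0
    n_reac_rows: int = 0
    orphan_drug_rows: int = 0
    orphan_hist_rows: int = 0
    orphan_reac_rows: int = 0
    duplicate_demo_rows: int = 0
    invalid_involvement_rows: int = 0
    invalid_outcome_rows: int = 0
    duplicate_event_rows: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class SrsDatabase:
    """The four linked tables plus the load report.

    ``demo`` has unique report_ids; every report_id in ``drugs``/``hist``/
    ``reac`` exists in ``demo``. Drug names in ``drugs`` carry a
    ``drug_name_norm`` column used by all matching.
    """

    demo: pd.DataFrame
    drugs: pd.DataFrame
    hist: pd.DataFrame
    reac: pd.DataFrame
    load_report: LoadReport = field(default_factory=LoadReport)

    @property
    def n_reports(self) -> int:
        return len(self.demo)

    def report_ids(self) -> set[str]:
        return set(self.demo["report_id"])

    def validate(self) -> None:
        """Assert referential integrity; raises AssertionError on violation."""
        ids = self.report_ids()
        assert self.demo["report_id"].is_unique, "duplicate report_id in DEMO"
        for name, frame in (("DRUG", self.drugs), ("HIST", self.hist), ("REAC", self.reac)):
            if len(frame) and not frame["report_id"].isin(ids).all():
                raise AssertionError(f"orphan report_id in {name}")
        bad_inv = ~self.drugs["involvement"].isin(INVOLVEMENT_CODES)
        assert not bad_inv.any(), "invalid involvement code"


def _read_table(path, colmap: dict[str, str]) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[])
    df.columns = [c.strip() for c in df.columns]
    missing = [src for src in colmap.values() if src not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s) {missing}")
    out = pd.DataFrame({canon: df[src] for canon, src in colmap.items()})
    for c in out.columns:
        out[c] = out[c].astype(str).str.strip()
    return out


def load_database(
    demo_path,
    drug_path,
    hist_path,
    reac_path,
    column_maps: dict[str, dict[str, str]] | None = None,
) -> SrsDatabase:
    """Read the four CSVs, drop rows violating referential integrity
    (counted in the load report), normalize drug names, and dedupe
    duplicate (report, PT) event rows to the earliest complete onset date.

    ``column_maps`` optionally remaps {table: {canonical: source_column}}
    for files whose headers differ from the JADER English field names.
    """
    maps = {"demo": dict(DEMO_COLUMNS), "drug": dict(DRUG_COLUMNS), "hist": dict(HIST_COLUMNS), "reac": dict(REAC_COLUMNS)}
    if column_maps:
        for table, m in column_maps.items():
            maps[table].update(m)

    demo = _read_table(demo_path, maps["demo"])
    drugs = _read_table(drug_path, maps["drug"])
    hist = _read_table(hist_path, maps["hist"])
    reac = _read_table(reac_path, maps["reac"])
    report = LoadReport()

    dup = demo["report_id"].duplicated(keep="first")
    report.duplicate_demo_rows = int(dup.sum())
    demo = demo[~dup].reset_index(drop=True)
    ids = set(demo["report_id"])

    def _drop_orphans(frame: pd.DataFrame) -> tuple[pd.DataFrame, int]:
        ok = frame["report_id"].isin(ids)
        return frame[ok].reset_index(drop=True), int((~ok).sum())

    drugs, report.orphan_drug_rows = _drop_orphans(drugs)
    hist, report.orphan_hist_rows = _drop_orphans(hist)
    reac, report.orphan_reac_rows = _drop_orphans(reac)

    inv = drugs["involvement"].str.strip().str.casefold()
    bad = ~inv.isin(INVOLVEMENT_CODES)
    report.invalid_involvement_rows = int(bad.sum())
    drugs = drugs[~bad].reset_index(drop=True)
    drugs["involvement"] = inv[~bad.values].values
    drugs["drug_name_norm"] = drugs["drug_name"].map(normalize_name)

    out = reac["outcome"].str.strip().str.casefold()
    known = out.isin(OUTCOME_CATEGORIES) | (out == "")
    report.invalid_outcome_rows = int((~known).sum())
    reac = reac.copy()
    reac["outcome"] = out.where(known, "")

    # dedupe duplicate AE rows (same report, same PT): keep earliest complete
    # onset date; rows with no complete date sort last and survive only alone
    onset_ts = complete_dates(reac["onset_date"])
    order = onset_ts.fillna(pd.Timestamp.max)
    reac = reac.assign(_onset_ts=order).sort_values(
        ["report_id", "pt_name", "_onset_ts"], kind="stable"
    )
    dup_ev = reac.duplicated(subset=["report_id", "pt_name"], keep="first")
    report.duplicate_event_rows = int(dup_ev.sum())
    reac = reac[~dup_ev].drop(columns="_onset_ts").reset_index(drop=True)

    report.n_reports = len(demo)
    report.n_drug_rows = len(drugs)
    report.n_hist_rows = len(hist)
    report.n_reac_rows = len(reac)

    db = SrsDatabase(demo=demo, drugs=drugs, hist=hist, reac=reac, load_report=report)
    db.validate()
    return db


def filter_suspected(db: SrsDatabase) -> SrsDatabase:
    """Keep only DRUG rows with involvement 'suspected'; DEMO/HIST/REAC
    untouched. Idempotent."""
    drugs = db.drugs[db.drugs["involvement"] == "suspected"].reset_index(drop=True)
    out = replace(db, drugs=drugs)
    out.validate()
    return out


def match_drug_rows(db: SrsDatabase, patterns: list[str], contains: bool = False) -> pd.DataFrame:
    """DRUG rows whose normalized name matches any pattern.

    Default matching is exact on the normalized name; ``contains=True``
    switches to substring matching for brand/salt variants.
    """
    if not patterns:
        raise ValueError("empty drug pattern list")
    pats = [normalize_name(p) for p in patterns]
    names = db.drugs["drug_name_norm"]
    if contains:
        mask = pd.Series(False, index=names.index)
        for p in pats:
            mask |= names.str.contains(p, regex=False)
    else:
        mask = names.isin(pats)
    return db.drugs[mask]


def reports_exposed(db: SrsDatabase, drug_group: list[str], contains: bool = False) -> set[str]:
    """Report_ids with at least one *suspected* DRUG row matching the group.

    A report matching several drugs (or the same drug twice) counts once.
    """
    rows = match_drug_rows(db, drug_group, contains=contains)
    rows = rows[rows["involvement"] == "suspected"]
    return set(rows["report_id"])
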