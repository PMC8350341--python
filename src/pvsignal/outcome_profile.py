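"""Outcome tabulation per drug group or age band, mosaic-plot ready.

Each case report carries one of six outcome categories (death, with
sequelae, not recovered, convalescent, recovery, others). A report can
list several matching events with different outcomes; one outcome per
(report, stratum) is kept by a worst-severity rule. The module emits the
mosaic contingency structure — stratum widths proportional to totals,
rectangle heights proportional to outcome proportions — and a helper that
flags strata whose death share exceeds a threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

from .event_dictionary import PtSet
from .srs_store import OUTCOME_CATEGORIES, SrsDatabase, match_drug_rows

# worst first; missing outcomes pool into "others"
SEVERITY_ORDER = OUTCOME_CATEGORIES
_SEVERITY_RANK = {cat: i for i, cat in enumerate(SEVERITY_ORDER)}


@dataclass(frozen=True)
class OutcomeSummary:
    group_label: str
    counts: dict[str, int]
    total: int

    @property
    def proportions(self) -> dict[str, float]:
        if self.total == 0:
            return {}
        return {k: v / self.total for k, v in self.counts.items()}


def _worst_outcome(outcomes) -> str:
    cleaned = [o if o in _SEVERITY_RANK else "others" for o in outcomes]
    return min(cleaned, key=_SEVERITY_RANK.__getitem__)


def tabulate_outcomes(
    db: SrsDatabase,
    drug_groups: dict[str, list[str]],
    pt_set: PtSet,
    stratify_by: str = "drug_group",
    contains: bool = False,
) -> list[OutcomeSummary]:
    """One OutcomeSummary per stratum (drug group, or age band within the
    union of the groups). Case = report with ≥1 suspected drug in the
    group and ≥1 event in the PT set; one outcome per (report, stratum)
    by worst severity; missing outcomes count as "others". Strata with no
    cases are omitted.
    """
    if stratify_by not in ("drug_group", "age_band"):
        raise ValueError("stratify_by must be 'drug_group' or 'age_band'")

    events = db.reac[db.reac["pt_name"].isin(pt_set.pts)]

    def summarize(label: str, report_ids: set[str]) -> OutcomeSummary | None:
        sub = events[events["report_id"].isin(report_ids)]
        if len(sub) == 0:
            return None
        worst = sub.groupby("report_id", sort=True)["outcome"].agg(_worst_outcome)
        counts = {cat: 0 for cat in OUTCOME_CATEGORIES}
        for cat, n in worst.value_counts().items():
            counts[cat] += int(n)
        return OutcomeSummary(group_label=label, counts=counts, total=int(worst.size))

    out: list[OutcomeSummary] = []
    if stratify_by == "drug_group":
        for label, patterns in drug_groups.items():
            rows = match_drug_rows(db, patterns, contains=contains)
            ids = set(rows.loc[rows["involvement"] == "suspected", "report_id"])
            s = summarize(label, ids)
            if s is not None:
                out.append(s)
    else:
        all_patterns = [p for pats in drug_groups.values() for p in pats]
        rows = match_drug_rows(db, all_patterns, contains=contains)
        exposed = set(rows.loc[rows["involvement"] == "suspected", "report_id"])
        demo = db.demo[db.demo["report_id"].isin(exposed)]
        for band, grp in demo.groupby("age_band", sort=True):
            label = band if band else "unknown"
            s = summarize(label, set(grp["report_id"]))
            if s is not None:
                out.append(s)
    return out


def death_flags(summaries: list[OutcomeSummary], threshold: float = 0.10) -> list[str]:
    """Stratum labels whose death proportion strictly exceeds the
    threshold (default: more than 10% of cases)."""
    flagged = []
    for s in summaries:
        if s.total > 0 and s.counts.get("death", 0) / s.total > threshold:
            flagged.append(s.group_label)
    return flagged


def mosaic_table(summaries: list[OutcomeSummary]) -> dict:
    """Mosaic-plot-ready structure: stratum widths ∝ case totals, outcome
    heights ∝ within-stratum proportions."""
    grand = sum(s.total for s in summaries)
    return {
        "categories": list(OUTCOME_CATEGORIES),
        "strata": [
            {
                "label": s.group_label,
                "total": s.total,
                "width": (s.total / grand) if grand else 0.0,
                "heights": {c: s.proportions.get(c, 0.0) for c in OUTCOME_CATEGORIES},
            }
            for s in summaries
        ],
    }


def plot_mosaic(summaries: list[OutcomeSummary], ax=None, path=None):
    """Render the mosaic with matplotlib (optional dependency)."""
    import matplotlib

    if path is not None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    table = mosaic_table(summaries)
    if ax is None:
        _, ax = plt.subplots(figsize=(max(6, len(table["strata"])), 5))
    cmap = plt.get_cmap("RdYlGn")
    colors = {c: cmap(i / max(1, len(table["categories"]) - 1))
              for i, c in enumerate(table["categories"])}
    x = 0.0
    for stratum in table["strata"]:
        w = stratum["width"]
        y = 0.0
        for cat in table["categories"]:
            h = stratum["heights"][cat]
            if h > 0:
                ax.bar(x + w / 2, h, width=w * 0.97, bottom=y, color=colors[cat])
            y += h
        ax.text(x + w / 2, -0.03, stratum["label"], rotation=90, ha="center", va="top", fontsize=7)
        x += w
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.set_ylabel("outcome proportion")
    ax.set_xticks([])
    if path is not None:
        ax.figure.savefig(path, bbox_inches="tight", dpi=150)
        plt.close(ax.figure)
    return ax
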