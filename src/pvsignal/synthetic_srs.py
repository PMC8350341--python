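"""Synthetic JADER-schema databases with known ground truth.

The generator emits the four linked tables (DEMO/DRUG/HIST/REAC) together
with its own bookkeeping: the true report-level 2×2 table per drug, the
drawn onset latencies, and per-report assignments. Association strength is
parameterized on the odds scale — a report's odds of being a case are the
background odds multiplied by θ_d for every drug d it carries as a
*suspected* exposure — so the population reporting odds ratio for drug d
equals θ_d and the generator doubles as an estimator oracle.

Cases receive a gastrointestinal-obstruction PT and an onset latency drawn
from the Weibull law of one of their suspected drugs; non-cases receive an
unrelated PT. Dates degrade to year-month precision or go missing with a
configurable probability, emulating the partial dates of real SRS data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .disproportionality import ContingencyTable
from .srs_store import OUTCOME_CATEGORIES, LoadReport, SrsDatabase, normalize_name

AGE_BANDS = tuple(f"{10 * i}-{10 * i + 9}" for i in range(10))

DEFAULT_DIG_PTS = (
    "Ileus",
    "Ileus paralytic",
    "Intestinal obstruction",
    "Intestinal perforation",
    "Subileus",
    "Mechanical ileus",
    "Large intestinal obstruction",
    "Gastrointestinal perforation",
)
DEFAULT_NON_DIG_PTS = (
    "Nausea",
    "Rash",
    "Hepatic function abnormal",
    "Interstitial lung disease",
    "Thrombocytopenia",
    "Pyrexia",
    "Headache",
    "Vomiting",
    "Renal impairment",
    "Dizziness",
)

DEFAULT_OUTCOME_MIX = {
    "death": 0.08,
    "with_sequelae": 0.02,
    "not_recovered": 0.15,
    "convalescent": 0.15,
    "recovery": 0.45,
    "others": 0.15,
}


class OnsetSpec(BaseModel):
    weibull_alpha: float = Field(gt=0, default=20.0)  # scale, days
    weibull_beta: float = Field(gt=0, default=1.5)  # shape


class DrugSpec(BaseModel):
    name: str
    exposure_prob: float = Field(gt=0, lt=1)
    suspected_frac: float = Field(ge=0, le=1, default=0.6)
    odds_multiplier: float = Field(ge=0, default=1.0)  # true ROR θ
    onset: OnsetSpec = OnsetSpec()
    outcome_mix: dict[str, float] = Field(default_factory=lambda: dict(DEFAULT_OUTCOME_MIX))

    @model_validator(mode="after")
    def _check_mix(self):
        if set(self.outcome_mix) != set(OUTCOME_CATEGORIES):
            raise ValueError("outcome_mix must cover exactly the six outcome categories")
        total = sum(self.outcome_mix.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"outcome_mix sums to {total}, not 1")
        return self


class GeneratorConfig(BaseModel):
    n_reports: int = Field(gt=0, default=20_000)
    drugs: list[DrugSpec]
    background_event_prob: float = Field(gt=0, lt=1, default=0.017)
    dig_pts: tuple[str, ...] = DEFAULT_DIG_PTS
    non_dig_pts: tuple[str, ...] = DEFAULT_NON_DIG_PTS
    date_missing_prob: float = Field(ge=0, lt=1, default=0.08)
    multi_pt_prob: float = Field(ge=0, le=1, default=0.0)
    study_start: str = "2004-04-01"
    study_end: str = "2020-11-30"
    seed: int = 0

    @model_validator(mode="after")
    def _check(self):
        if set(self.dig_pts) & set(self.non_dig_pts):
            raise ValueError("dig_pts and non_dig_pts must be disjoint")
        names = [d.name for d in self.drugs]
        if len(set(names)) != len(names):
            raise ValueError("duplicate drug names")
        return self


def default_config(seed: int = 0, n_reports: int = 20_000) -> GeneratorConfig:
    """A small JADER-like world: background case probability matching the
    observed composite-case share, a strongly associated short-latency
    contrast agent, a moderately associated long-latency binder, and a
    null drug."""
    return GeneratorConfig(
        n_reports=n_reports,
        seed=seed,
        drugs=[
            DrugSpec(name="contrastium", exposure_prob=0.01, odds_multiplier=20.0,
                     onset=OnsetSpec(weibull_alpha=3.0, weibull_beta=1.7),
                     outcome_mix={**DEFAULT_OUTCOME_MIX, "death": 0.04, "recovery": 0.49}),
            DrugSpec(name="kalexate", exposure_prob=0.008, odds_multiplier=25.0,
                     onset=OnsetSpec(weibull_alpha=30.0, weibull_beta=1.0),
                     outcome_mix={**DEFAULT_OUTCOME_MIX, "death": 0.15, "recovery": 0.38}),
            DrugSpec(name="motilistat", exposure_prob=0.01, odds_multiplier=10.0,
                     onset=OnsetSpec(weibull_alpha=10.0, weibull_beta=1.6)),
            DrugSpec(name="placebrium", exposure_prob=0.02, odds_multiplier=1.0,
                     onset=OnsetSpec(weibull_alpha=20.0, weibull_beta=1.0)),
        ],
    )


@dataclass
class GroundTruth:
    """Generator bookkeeping, consistent row-for-row with the emitted db."""

    tables: dict[str, ContingencyTable]
    exposed_reports: dict[str, set[str]]
    suspected_reports: dict[str, set[str]]
    case_reports: set[str]
    latencies: dict[str, list[int]]  # drawn (rounded) latency per anchored case
    complete_in_window: dict[str, int]  # complete-date, 0..window pairings
    n_suspected_drug_rows: int
    n_drug_rows: int
    assignments: pd.DataFrame = field(repr=False, default=None)

    def as_dict(self) -> dict:
        return {
            "tables": {k: {"a": t.a, "b": t.b, "c": t.c, "d": t.d} for k, t in self.tables.items()},
            "n_cases": len(self.case_reports),
            "suspected_counts": {k: len(v) for k, v in self.suspected_reports.items()},
            "complete_in_window": dict(self.complete_in_window),
            "latency_counts": {k: len(v) for k, v in self.latencies.items()},
            "n_suspected_drug_rows": self.n_suspected_drug_rows,
            "n_drug_rows": self.n_drug_rows,
        }


def expected_ror(config: GeneratorConfig, drug_name: str) -> float:
    """The population reporting odds ratio for a drug: identically its
    odds multiplier θ under the generator's odds parameterization."""
    for d in config.drugs:
        if d.name == drug_name:
            return float(d.odds_multiplier)
    raise KeyError(f"unknown drug {drug_name!r}")


def _degrade_dates(raw_days: np.ndarray, missing: np.ndarray, partial: np.ndarray,
                   start_ts: pd.Timestamp) -> list[str]:
    """Render day offsets as YYYYMMDD strings, degrading flagged entries to
    missing ('') or year-month precision."""
    dates = start_ts + pd.to_timedelta(raw_days, unit="D")
    out = dates.strftime("%Y%m%d").to_numpy(dtype=object)
    out[missing & ~partial] = ""
    ym = dates.strftime("%Y%m").to_numpy(dtype=object)
    sel = missing & partial
    out[sel] = ym[sel]
    return list(out)


def generate(config: GeneratorConfig, window_days: int = 90) -> tuple[SrsDatabase, GroundTruth]:
    """Draw a database and its ground truth; fully reproducible from
    ``config.seed``.

    ``window_days`` only affects the ``complete_in_window`` bookkeeping,
    which mirrors what a time-to-onset extraction with that window should
    retain.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_reports
    start_ts = pd.Timestamp(config.study_start)
    end_ts = pd.Timestamp(config.study_end)
    span = (end_ts - start_ts).days
    report_ids = np.array([f"R{i:07d}" for i in range(n)], dtype=object)

    # --- exposures and involvement -------------------------------------
    n_drugs = len(config.drugs)
    exposed = np.zeros((n, n_drugs), dtype=bool)
    suspected = np.zeros((n, n_drugs), dtype=bool)
    for j, spec in enumerate(config.drugs):
        exposed[:, j] = rng.random(n) < spec.exposure_prob
        suspected[:, j] = exposed[:, j] & (rng.random(n) < spec.suspected_frac)

    # --- case status: odds multiply by θ_d per suspected exposure ------
    p0 = config.background_event_prob
    log_odds = np.full(n, np.log(p0 / (1 - p0)))
    for j, spec in enumerate(config.drugs):
        if spec.odds_multiplier <= 0:
            log_odds[suspected[:, j]] = -np.inf
        else:
            log_odds[suspected[:, j]] += np.log(spec.odds_multiplier)
    p_case = 1.0 / (1.0 + np.exp(-log_odds))
    case = rng.random(n) < p_case

    # anchor drug: uniform among the report's suspected drugs
    chosen = np.full(n, -1, dtype=int)
    any_susp = suspected.any(axis=1)
    for i in np.flatnonzero(case & any_susp):
        js = np.flatnonzero(suspected[i])
        chosen[i] = js[rng.integers(len(js))]

    # --- drug records ---------------------------------------------------
    # one row per (report, exposed drug); starts leave room for latencies
    rec_report, rec_drug = np.nonzero(exposed)
    m = rec_report.size
    start_days = rng.integers(0, max(1, span - 2 * window_days), size=m)
    durations = rng.integers(1, 61, size=m)
    start_missing = rng.random(m) < config.date_missing_prob
    start_partial = rng.random(m) < 0.5
    end_missing = rng.random(m) < config.date_missing_prob
    end_partial = rng.random(m) < 0.5
    involvement = np.where(
        suspected[rec_report, rec_drug],
        "suspected",
        np.where(rng.random(m) < 0.7, "concomitant", "interacting"),
    )
    drug_names = np.array([d.name for d in config.drugs], dtype=object)
    drug_df = pd.DataFrame(
        {
            "report_id": report_ids[rec_report],
            "drug_name": drug_names[rec_drug],
            "involvement": involvement,
            "route": rng.choice(["oral", "intravenous", ""], size=m, p=[0.7, 0.2, 0.1]),
            "start_date": _degrade_dates(start_days, start_missing, start_partial, start_ts),
            "end_date": _degrade_dates(start_days + durations, end_missing, end_partial, start_ts),
        }
    )
    drug_df["drug_name_norm"] = drug_df["drug_name"].map(normalize_name)

    # index of the (report, chosen drug) record for latency anchoring
    rec_index = {(int(r), int(d)): k for k, (r, d) in enumerate(zip(rec_report, rec_drug))}

    # --- events ---------------------------------------------------------
    alphas = np.array([d.onset.weibull_alpha for d in config.drugs])
    betas = np.array([d.onset.weibull_beta for d in config.drugs])
    onset_days = np.zeros(n, dtype=int)
    latency = np.full(n, -1, dtype=int)
    anchored = case & (chosen >= 0)
    for j in range(n_drugs):
        sel = np.flatnonzero(anchored & (chosen == j))
        if sel.size == 0:
            continue
        lat = alphas[j] * rng.weibull(betas[j], size=sel.size)
        lat = np.floor(lat + 0.5).astype(int)  # half-up to whole days
        starts = np.array([start_days[rec_index[(int(i), j)]] for i in sel])
        lat = np.minimum(lat, span - starts)  # truncate at study window
        onset_days[sel] = starts + lat
        latency[sel] = lat
    bg = np.flatnonzero(~anchored)
    onset_days[bg] = rng.integers(0, span + 1, size=bg.size)

    onset_missing = rng.random(n) < config.date_missing_prob
    onset_partial = rng.random(n) < 0.5

    pt = np.empty(n, dtype=object)
    ncase = int(case.sum())
    pt[case] = rng.choice(np.array(config.dig_pts, dtype=object), size=ncase)
    pt[~case] = rng.choice(np.array(config.non_dig_pts, dtype=object), size=n - ncase)

    # outcomes: anchored cases follow their drug's mix, the rest a common mix
    outcome = np.empty(n, dtype=object)
    cats = np.array(OUTCOME_CATEGORIES, dtype=object)
    bg_probs = np.array([DEFAULT_OUTCOME_MIX[c] for c in OUTCOME_CATEGORIES])
    outcome[:] = rng.choice(cats, size=n, p=bg_probs)
    for j, spec in enumerate(config.drugs):
        sel = np.flatnonzero(anchored & (chosen == j))
        if sel.size:
            probs = np.array([spec.outcome_mix[c] for c in OUTCOME_CATEGORIES])
            outcome[sel] = rng.choice(cats, size=sel.size, p=probs)

    reac_df = pd.DataFrame(
        {
            "report_id": report_ids,
            "pt_name": pt,
            "onset_date": _degrade_dates(onset_days, onset_missing, onset_partial, start_ts),
            "outcome": outcome,
        }
    )

    # optional second DIG PT on some cases (exercises report-level dedup)
    extra_sel = np.array([], dtype=int)
    if config.multi_pt_prob > 0:
        extra_sel = np.flatnonzero(case & (rng.random(n) < config.multi_pt_prob))
        if extra_sel.size:
            others = []
            for i in extra_sel:
                pool = [p for p in config.dig_pts if p != pt[i]]
                others.append(pool[rng.integers(len(pool))])
            extra = reac_df.iloc[extra_sel].copy()
            extra["pt_name"] = others
            reac_df = pd.concat([reac_df, extra], ignore_index=True)

    # --- demo and hist ---------------------------------------------------
    years = rng.integers(start_ts.year, end_ts.year + 1, size=n)
    demo_df = pd.DataFrame(
        {
            "report_id": report_ids,
            "sex": rng.choice(["male", "female", ""], size=n, p=[0.47, 0.47, 0.06]),
            "age_band": rng.choice(list(AGE_BANDS) + [""], size=n,
                                   p=[0.02, 0.02, 0.04, 0.06, 0.08, 0.12, 0.18, 0.22, 0.14, 0.06, 0.06]),
            "reporting_year": years.astype(str),
        }
    )
    hist_sel = rng.random(n) < 0.3
    hist_df = pd.DataFrame(
        {
            "report_id": report_ids[hist_sel],
            "illness": rng.choice(
                ["diabetes mellitus", "hypertension", "chronic kidney disease", "schizophrenia", "colon cancer"],
                size=int(hist_sel.sum()),
            ),
        }
    )

    db = SrsDatabase(demo=demo_df, drugs=drug_df, hist=hist_df, reac=reac_df,
                     load_report=LoadReport(n_reports=n, n_drug_rows=m,
                                            n_hist_rows=len(hist_df), n_reac_rows=len(reac_df)))
    db.validate()

    # --- ground truth -----------------------------------------------------
    tables: dict[str, ContingencyTable] = {}
    exposed_reports: dict[str, set[str]] = {}
    suspected_reports: dict[str, set[str]] = {}
    latencies: dict[str, list[int]] = {}
    complete_in_window: dict[str, int] = {}
    n_dig_events = np.zeros(n, dtype=int)
    n_dig_events[case] = 1
    n_dig_events[extra_sel] += 1

    for j, spec in enumerate(config.drugs):
        s = suspected[:, j]
        a = int((s & case).sum())
        b = int((s & ~case).sum())
        c = int((~s & case).sum())
        d = n - a - b - c
        tables[spec.name] = ContingencyTable(a=a, b=b, c=c, d=d)
        exposed_reports[spec.name] = set(report_ids[exposed[:, j]])
        suspected_reports[spec.name] = set(report_ids[s])
        latencies[spec.name] = [int(latency[i]) for i in np.flatnonzero(anchored & (chosen == j))]

        # complete, in-window pairings of (suspected drug row, DIG event)
        count = 0
        for i in np.flatnonzero(s & case):
            k = rec_index[(int(i), j)]
            if start_missing[k] or onset_missing[i]:
                continue
            delta = int(onset_days[i]) - int(start_days[k])
            if 0 <= delta <= window_days:
                count += int(n_dig_events[i])
        complete_in_window[spec.name] = count

    truth = GroundTruth(
        tables=tables,
        exposed_reports=exposed_reports,
        suspected_reports=suspected_reports,
        case_reports=set(report_ids[case]),
        latencies=latencies,
        complete_in_window=complete_in_window,
        n_suspected_drug_rows=int(suspected[rec_report, rec_drug].sum()),
        n_drug_rows=m,
        assignments=pd.DataFrame({
            "report_id": report_ids,
            "case": case,
            "anchor_drug": np.where(chosen >= 0, drug_names[np.clip(chosen, 0, None)], ""),
        }),
    )
    return db, truth


def write_csvs(db: SrsDatabase, truth: GroundTruth, outdir) -> dict[str, str]:
    """Emit the four tables in the loadable schema plus ground_truth.json."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, frame in (("demo", db.demo), ("drug", db.drugs.drop(columns="drug_name_norm")),
                        ("hist", db.hist), ("reac", db.reac)):
        p = outdir / f"{name}.csv"
        frame.to_csv(p, index=False)
        paths[name] = str(p)
    gt = outdir / "ground_truth.json"
    gt.write_text(json.dumps(truth.as_dict(), indent=1, sort_keys=True))
    paths["ground_truth"] = str(gt)
    return paths
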