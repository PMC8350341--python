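"""End-to-end orchestration: config in, Table-1/Table-2-shaped CSVs out.

The flow mirrors a standard SRS disproportionality study: load the four
tables → keep suspected drugs only → define cases from the PT dictionary →
per (drug group × case definition) compute the 2×2/ROR, the time-to-onset
summary and Weibull fit, and the outcome profile. Every filtering step is
counted in run_report.json so each exclusion is auditable.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import yaml
from pydantic import BaseModel, Field

from . import __version__
from .disproportionality import round_half_up, signal_table
from .event_dictionary import (
    load_queries,
    load_smq_dictionary,
    reports_with_events,
    select_pts,
    standard_queries,
)
from .outcome_profile import death_flags, mosaic_table, tabulate_outcomes
from .srs_store import filter_suspected, load_database
from .time_to_onset import classify_hazard, compute_durations, fit_weibull, summarize_times

log = logging.getLogger("pvsignal")


class PipelineError(RuntimeError):
    pass


class InputPaths(BaseModel):
    demo: str
    drug: str
    hist: str
    reac: str
    smq_dictionary: str
    drug_groups: str
    queries: str | None = None  # default: the four standard case definitions


class AnalysisOptions(BaseModel):
    window_days: int = Field(gt=0, default=90)
    quantile_method: str = "linear"
    weibull_ci: str = "wald"  # or "bootstrap"
    anchor: str = "start"  # or "end"
    match_contains: bool = False
    min_n_weibull: int = 3
    death_threshold: float = 0.10
    seed: int = 0


class PipelineConfig(BaseModel):
    inputs: InputPaths
    analysis: AnalysisOptions = AnalysisOptions()
    output_dir: str = "pvsignal_out"
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh))


def load_drug_groups(path) -> dict[str, dict]:
    """YAML: {groups: [{label, atc?, drugs: [name patterns]}]}; insertion
    order is output order."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    groups = {}
    for item in raw["groups"]:
        if not item.get("drugs"):
            raise PipelineError(f"drug group {item.get('label')!r} has no drug patterns")
        groups[item["label"]] = {"atc": item.get("atc", ""), "drugs": list(item["drugs"])}
    return groups


def _fmt(x: float | None, nd: int = 1) -> str:
    return "" if x is None else f"{round_half_up(x, nd):.{nd}f}"


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns the run report. Writes
    signal_table.csv/.json, time_to_onset.csv, outcomes.csv, mosaic.json
    and run_report.json into the output directory. Any fatal load error
    removes partial artifacts and raises PipelineError."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        return _run(config, out, written)
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise


def _run(config: PipelineConfig, out: Path, written: list[Path]) -> dict:
    ip, opts = config.inputs, config.analysis
    for label, p in (("demo", ip.demo), ("drug", ip.drug), ("hist", ip.hist), ("reac", ip.reac),
                     ("smq_dictionary", ip.smq_dictionary), ("drug_groups", ip.drug_groups)):
        if not Path(p).exists():
            raise PipelineError(f"input file for {label!r} not found: {p}")

    db = load_database(ip.demo, ip.drug, ip.hist, ip.reac)
    log.info("loaded %d reports (%d drug rows)", db.n_reports, len(db.drugs))
    suspected = filter_suspected(db)

    smqs = load_smq_dictionary(ip.smq_dictionary)
    queries = load_queries(ip.queries) if ip.queries else standard_queries()
    pt_sets = {label: select_pts(smqs, q) for label, q in queries.items()}
    groups_cfg = load_drug_groups(ip.drug_groups)
    groups = {label: g["drugs"] for label, g in groups_cfg.items()}

    composite_label = next(iter(pt_sets))
    case_ids = reports_with_events(suspected, pt_sets[composite_label])

    # --- Table 1 shape ---------------------------------------------------
    rows = signal_table(suspected, groups, pt_sets, contains=opts.match_contains)
    sig_csv = out / "signal_table.csv"
    with sig_csv.open("w") as fh:
        fh.write("group,query,total_n,case_n,ror,ci_low,ci_high,signal,estimable\n")
        for r in rows:
            fh.write(
                f"{r.group_label},{r.query_label},{r.table.n_exposed},{r.result.n_cases},"
                f"{_fmt(r.result.ror)},{_fmt(r.result.ci_low)},{_fmt(r.result.ci_high)},"
                f"{str(r.result.signal).lower()},{str(r.result.estimable).lower()}\n"
            )
    written.append(sig_csv)
    sig_json = out / "signal_table.json"
    sig_json.write_text(json.dumps(
        [
            {
                "group": r.group_label, "query": r.query_label,
                "table": {"a": r.table.a, "b": r.table.b, "c": r.table.c, "d": r.table.d},
                "ror": r.result.ror, "ci_low": r.result.ci_low, "ci_high": r.result.ci_high,
                "signal": r.result.signal, "estimable": r.result.estimable,
            }
            for r in rows
        ],
        indent=1,
    ))
    written.append(sig_json)

    # --- Table 2 shape ---------------------------------------------------
    tto_csv = out / "time_to_onset.csv"
    complete_pairs = 0
    exclusion_tally = {"incomplete_date": 0, "negative": 0, "beyond_window": 0}
    with tto_csv.open("w") as fh:
        fh.write("group,query,n,median,q1,q3,alpha,alpha_lo,alpha_hi,beta,beta_lo,beta_hi,hazard\n")
        for glabel, patterns in groups.items():
            for qlabel, pt_set in pt_sets.items():
                ds = compute_durations(suspected, patterns, pt_set,
                                       window_days=opts.window_days,
                                       contains=opts.match_contains, anchor=opts.anchor)
                if qlabel == composite_label:
                    complete_pairs += len(ds)
                    for k in exclusion_tally:
                        exclusion_tally[k] += ds.exclusions.get(k, 0)
                if len(ds) == 0:
                    fh.write(f"{glabel},{qlabel},0,,,,,,,,,,\n")
                    continue
                ts = summarize_times(ds, method=opts.quantile_method)
                fit = fit_weibull(ds, min_n=opts.min_n_weibull,
                                  ci_method=opts.weibull_ci, seed=opts.seed)
                if fit.converged and fit.beta_ci is not None:
                    hz = classify_hazard(fit).value
                    fh.write(
                        f"{glabel},{qlabel},{ts.n},{_fmt(ts.median)},{_fmt(ts.q1)},{_fmt(ts.q3)},"
                        f"{_fmt(fit.scale_alpha)},{_fmt(fit.alpha_ci[0])},{_fmt(fit.alpha_ci[1])},"
                        f"{_fmt(fit.shape_beta)},{_fmt(fit.beta_ci[0])},{_fmt(fit.beta_ci[1])},{hz}\n"
                    )
                else:
                    fh.write(f"{glabel},{qlabel},{ts.n},{_fmt(ts.median)},{_fmt(ts.q1)},{_fmt(ts.q3)},,,,,,,\n")
    written.append(tto_csv)

    # --- Fig. 3 shape ----------------------------------------------------
    summaries = tabulate_outcomes(suspected, groups, pt_sets[composite_label],
                                  stratify_by="drug_group", contains=opts.match_contains)
    outc_csv = out / "outcomes.csv"
    with outc_csv.open("w") as fh:
        fh.write("group,outcome,count,proportion\n")
        for s in summaries:
            for cat, cnt in s.counts.items():
                fh.write(f"{s.group_label},{cat},{cnt},{s.proportions[cat]:.6f}\n")
    written.append(outc_csv)
    mosaic = out / "mosaic.json"
    mosaic.write_text(json.dumps(mosaic_table(summaries), indent=1))
    written.append(mosaic)

    report = {
        "pvsignal_version": __version__,
        "load_report": db.load_report.as_dict(),
        "flow": {
            "reports_loaded": db.n_reports,
            "drug_rows_loaded": len(db.drugs),
            "drug_rows_suspected": len(suspected.drugs),
            "case_reports_composite": len(case_ids),
            "complete_date_pairs_composite": complete_pairs,
        },
        "time_to_onset_exclusions_composite": exclusion_tally,
        "pt_set_sizes": {label: len(ps) for label, ps in pt_sets.items()},
        "death_flagged_groups": death_flags(summaries, threshold=opts.death_threshold),
        "artifacts": [str(p) for p in written],
    }
    rr = out / "run_report.json"
    rr.write_text(json.dumps(report, indent=1, sort_keys=True))
    written.append(rr)
    log.info("wrote %d artifacts to %s", len(written), out)
    return report
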