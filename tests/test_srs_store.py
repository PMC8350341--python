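"""Loading, validation, linking and filtering of the four-table schema."""

import pandas as pd
import pytest

from pvsignal.dates import PartialDate, parse_partial_date
from pvsignal.srs_store import (
    filter_suspected,
    load_database,
    normalize_name,
    reports_exposed,
)
from pvsignal.synthetic_srs import default_config, generate, write_csvs

from conftest import make_db

HEADERS = {
    "demo": "report_id,sex,age_band,reporting_year\n",
    "drug": "report_id,drug_name,involvement,route,start_date,end_date\n",
    "hist": "report_id,illness\n",
    "reac": "report_id,pt_name,onset_date,outcome\n",
}


def _write_files(tmp_path, extra_rows=None):
    paths = {}
    for name, header in HEADERS.items():
        p = tmp_path / f"{name}.csv"
        body = "".join((extra_rows or {}).get(name, []))
        p.write_text(header + body)
        paths[name] = p
    return paths


class TestLoad:
    def test_empty_files_yield_empty_database(self, tmp_path):
        p = _write_files(tmp_path)
        db = load_database(p["demo"], p["drug"], p["hist"], p["reac"])
        assert db.n_reports == 0
        assert len(db.drugs) == len(db.hist) == len(db.reac) == 0

    def test_missing_mandatory_column_is_fatal(self, tmp_path):
        p = _write_files(tmp_path)
        (tmp_path / "demo.csv").write_text("report_id,sex\n")
        with pytest.raises(ValueError, match="missing mandatory column"):
            load_database(p["demo"], p["drug"], p["hist"], p["reac"])

    def test_orphan_child_rows_dropped_and_counted(self, tmp_path):
        p = _write_files(tmp_path, {
            "demo": ["R1,male,60-69,2020\n"],
            "drug": ["R1,loperamide,suspected,oral,20200101,\n",
                     "R9,loperamide,suspected,oral,20200101,\n"],
            "reac": ["R9,Ileus,20200103,recovery\n"],
        })
        db = load_database(p["demo"], p["drug"], p["hist"], p["reac"])
        assert db.load_report.orphan_drug_rows == 1
        assert db.load_report.orphan_reac_rows == 1
        assert len(db.drugs) == 1
        db.validate()

    def test_unparseable_date_keeps_row_with_missing_field(self, tmp_path):
        p = _write_files(tmp_path, {
            "demo": ["R1,male,60-69,2020\n"],
            "drug": ["R1,loperamide,suspected,oral,not-a-date,\n"],
        })
        db = load_database(p["demo"], p["drug"], p["hist"], p["reac"])
        assert len(db.drugs) == 1
        assert parse_partial_date(db.drugs.loc[0, "start_date"]) is None

    def test_duplicate_event_rows_dedupe_to_earliest_complete_onset(self, tmp_path):
        p = _write_files(tmp_path, {
            "demo": ["R1,male,60-69,2020\n"],
            "reac": ["R1,Ileus,20200310,recovery\n",
                     "R1,Ileus,20200301,recovery\n",
                     "R1,Ileus,202003,recovery\n"],
        })
        db = load_database(p["demo"], p["drug"], p["hist"], p["reac"])
        assert len(db.reac) == 1
        assert db.reac.loc[0, "onset_date"] == "20200301"
        assert db.load_report.duplicate_event_rows == 2

    def test_synthetic_roundtrip_preserves_counts_and_truth(self, tmp_path):
        cfg = default_config(seed=11, n_reports=100)
        db, truth = generate(cfg)
        paths = write_csvs(db, truth, tmp_path)
        loaded = load_database(paths["demo"], paths["drug"], paths["hist"], paths["reac"])
        assert loaded.n_reports == db.n_reports
        assert len(loaded.drugs) == len(db.drugs)
        assert len(loaded.reac) == len(db.reac)
        assert loaded.load_report.orphan_drug_rows == 0
        sus = filter_suspected(loaded)
        assert len(sus.drugs) == truth.n_suspected_drug_rows


class TestFilterSuspected:
    def test_keeps_only_suspected_rows(self):
        db = make_db(
            demo_rows=[{"report_id": "R1", "sex": "", "age_band": "", "reporting_year": ""}],
            drug_rows=[
                {"report_id": "R1", "drug_name": "a", "involvement": "suspected", "route": "", "start_date": "", "end_date": ""},
                {"report_id": "R1", "drug_name": "b", "involvement": "concomitant", "route": "", "start_date": "", "end_date": ""},
                {"report_id": "R1", "drug_name": "c", "involvement": "interacting", "route": "", "start_date": "", "end_date": ""},
            ],
        )
        out = filter_suspected(db)
        assert list(out.drugs["involvement"]) == ["suspected"]
        assert out.n_reports == 1  # demo untouched

    def test_idempotent_and_handles_no_suspected(self):
        db = make_db(
            demo_rows=[{"report_id": "R1", "sex": "", "age_band": "", "reporting_year": ""}],
            drug_rows=[{"report_id": "R1", "drug_name": "b", "involvement": "concomitant",
                        "route": "", "start_date": "", "end_date": ""}],
        )
        once = filter_suspected(db)
        twice = filter_suspected(once)
        assert len(once.drugs) == 0
        pd.testing.assert_frame_equal(once.drugs, twice.drugs)

    def test_retained_count_matches_generator_bookkeeping(self):
        db, truth = generate(default_config(seed=3, n_reports=10_000))
        assert len(filter_suspected(db).drugs) == truth.n_suspected_drug_rows


class TestReportsExposed:
    def test_report_with_duplicate_drug_rows_counts_once(self):
        rows = [
            {"report_id": "R1", "drug_name": "loperamide", "involvement": "suspected", "route": "", "start_date": "", "end_date": ""},
            {"report_id": "R1", "drug_name": "Loperamide ", "involvement": "suspected", "route": "", "start_date": "", "end_date": ""},
        ]
        db = make_db(demo_rows=[{"report_id": "R1", "sex": "", "age_band": "", "reporting_year": ""}], drug_rows=rows)
        assert reports_exposed(db, ["loperamide"]) == {"R1"}

    def test_multi_drug_match_counts_once(self):
        rows = [
            {"report_id": "R1", "drug_name": "acarbose", "involvement": "suspected", "route": "", "start_date": "", "end_date": ""},
            {"report_id": "R1", "drug_name": "miglitol", "involvement": "suspected", "route": "", "start_date": "", "end_date": ""},
        ]
        db = make_db(demo_rows=[{"report_id": "R1", "sex": "", "age_band": "", "reporting_year": ""}], drug_rows=rows)
        assert len(reports_exposed(db, ["acarbose", "miglitol", "voglibose"])) == 1

    def test_empty_pattern_list_rejected(self, tiny_db):
        with pytest.raises(ValueError):
            reports_exposed(tiny_db, [])

    def test_generator_assignment_counts_recovered(self):
        cfg = default_config(seed=5, n_reports=10_000)
        db, truth = generate(cfg)
        for spec in cfg.drugs:
            assert reports_exposed(db, [spec.name]) == truth.suspected_reports[spec.name]

    def test_union_over_disjoint_groups(self):
        db, _ = generate(default_config(seed=9, n_reports=5_000))
        a = reports_exposed(db, ["contrastium"])
        b = reports_exposed(db, ["kalexate"])
        assert reports_exposed(db, ["contrastium", "kalexate"]) == a | b


class TestPartialDates:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("20200229", PartialDate(2020, 2, 29)),
            ("202002", PartialDate(2020, 2)),
            ("2020", PartialDate(2020)),
            ("20190230", None),  # impossible calendar day
            ("2020-01-01", None),
            ("", None),
            ("99999999", None),
        ],
    )
    def test_parse(self, raw, expected):
        assert parse_partial_date(raw) == expected

    def test_string_roundtrip(self):
        for pd_ in (PartialDate(2015, 7, 31), PartialDate(2015, 7), PartialDate(2015)):
            assert parse_partial_date(str(pd_)) == pd_

    def test_day_without_month_rejected(self):
        with pytest.raises(ValueError):
            PartialDate(2020, None, 5)


def test_normalize_name_unifies_width_case_and_whitespace():
    assert normalize_name("Ｌｏｐｅｒａｍｉｄｅ") == "loperamide"
    assert normalize_name("  Barium   Sulfate ") == "barium sulfate"
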