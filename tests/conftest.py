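import importlib.resources

import pandas as pd
import pytest

from pvsignal.srs_store import LoadReport, SrsDatabase, normalize_name


def make_db(demo_rows, drug_rows=(), hist_rows=(), reac_rows=()):
    """Build an in-memory SrsDatabase from row dicts (tests only)."""
    demo = pd.DataFrame(list(demo_rows), columns=["report_id", "sex", "age_band", "reporting_year"])
    drugs = pd.DataFrame(list(drug_rows),
                         columns=["report_id", "drug_name", "involvement", "route", "start_date", "end_date"])
    hist = pd.DataFrame(list(hist_rows), columns=["report_id", "illness"])
    reac = pd.DataFrame(list(reac_rows), columns=["report_id", "pt_name", "onset_date", "outcome"])
    for frame in (demo, drugs, hist, reac):
        for c in frame.columns:
            frame[c] = frame[c].fillna("").astype(str)
    drugs["drug_name_norm"] = drugs["drug_name"].map(normalize_name)
    db = SrsDatabase(demo=demo, drugs=drugs, hist=hist, reac=reac, load_report=LoadReport())
    db.validate()
    return db


@pytest.fixture
def smq_fixture_path():
    """Synthetic stand-in dictionary shipped with the package (MedDRA
    itself is licensed and never bundled)."""
    return str(importlib.resources.files("pvsignal") / "data" / "synthetic_smq_fixture.csv")


@pytest.fixture
def tiny_db():
    """Four reports: drug+event, drug only, event only, neither."""
    return make_db(
        demo_rows=[
            {"report_id": "R1", "sex": "male", "age_band": "60-69", "reporting_year": "2019"},
            {"report_id": "R2", "sex": "female", "age_band": "70-79", "reporting_year": "2019"},
            {"report_id": "R3", "sex": "male", "age_band": "50-59", "reporting_year": "2020"},
            {"report_id": "R4", "sex": "female", "age_band": "40-49", "reporting_year": "2020"},
        ],
        drug_rows=[
            {"report_id": "R1", "drug_name": "loperamide", "involvement": "suspected",
             "route": "oral", "start_date": "20200101", "end_date": "20200110"},
            {"report_id": "R2", "drug_name": "loperamide", "involvement": "suspected",
             "route": "oral", "start_date": "20200201", "end_date": ""},
        ],
        reac_rows=[
            {"report_id": "R1", "pt_name": "Ileus", "onset_date": "20200103", "outcome": "recovery"},
            {"report_id": "R2", "pt_name": "Nausea", "onset_date": "20200202", "outcome": "recovery"},
            {"report_id": "R3", "pt_name": "Ileus", "onset_date": "20200301", "outcome": "death"},
            {"report_id": "R4", "pt_name": "Rash", "onset_date": "20200401", "outcome": "others"},
        ],
    )
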