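import sys
from datetime import date
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from icivig.faers_io import AEReport, Drug


def write_quarter(tmp_path, demo, drug, reac, outc=(), ther=(), indi=(),
                  deleted=(), delim="$"):
    """Write a tiny quarter fixture from header+row tuples."""
    tables = {
        "DEMO": (["primaryid", "caseid", "caseversion", "fda_dt", "age", "age_cod", "sex"], demo),
        "DRUG": (["primaryid", "caseid", "drug_seq", "role_cod", "drugname"], drug),
        "REAC": (["primaryid", "caseid", "pt"], reac),
        "OUTC": (["primaryid", "caseid", "outc_cod"], outc),
        "THER": (["primaryid", "caseid", "dsg_drug_seq", "start_dt"], ther),
        "INDI": (["primaryid", "caseid", "indi_drug_seq", "indi_pt"], indi),
    }
    for name, (header, rows) in tables.items():
        lines = [delim.join(header)] + [delim.join(str(v) for v in r) for r in rows]
        (tmp_path / f"{name}.txt").write_text("\n".join(lines) + "\n")
    if deleted:
        (tmp_path / "DELETED.txt").write_text("\n".join(deleted) + "\n")
    return tmp_path


def make_report(caseid="1001", age=60.0, sex="male", reactions=("Seizure",),
                drugs=None, outcomes=(), receipt=date(2020, 3, 1),
                receipt_imprecise=False):
    if drugs is None:
        drugs = [
            Drug("NIVOLUMAB", "nivolumab", "PS", ["Glioblastoma"],
                 [(date(2020, 1, 1), False)]),
            Drug("TEMODAR", "temozolomide", "PS", ["Glioblastoma"],
                 [(date(2020, 1, 1), False)]),
        ]
    return AEReport(
        caseid=caseid,
        primaryid=caseid + "1",
        caseversion=1,
        receipt_date=receipt,
        receipt_imprecise=receipt_imprecise,
        age=age,
        sex=sex,
        drugs=list(drugs),
        reactions=list(reactions),
        outcomes=list(outcomes),
    )


@pytest.fixture
def quarter_dir(tmp_path):
    """Three-case quarter: two ICI+chemo cases (one with Seizure), one chemo-only."""
    return write_quarter(
        tmp_path,
        demo=[
            ("10011", "1001", "1", "20200301", "60", "YR", "M"),
            ("10021", "1002", "1", "20200401", "50", "YR", "F"),
            ("10031", "1003", "1", "20200501", "70", "YR", "M"),
        ],
        drug=[
            ("10011", "1001", "1", "PS", "NIVOLUMAB"),
            ("10011", "1001", "2", "PS", "TEMODAR"),
            ("10021", "1002", "1", "PS", "OPDIVO"),
            ("10021", "1002", "2", "PS", "Temozolomide"),
            ("10031", "1003", "1", "PS", "TEMOZOLOMIDE"),
        ],
        reac=[
            ("10011", "1001", "Seizure"),
            ("10011", "1001", "Nausea"),
            ("10021", "1002", "Fatigue"),
            ("10031", "1003", "Nausea"),
        ],
        outc=[("10011", "1001", "DE")],
        ther=[
            ("10011", "1001", "1", "20200101"),
            ("10021", "1002", "1", "202002"),
            ("10031", "1003", "1", "20200301"),
        ],
        indi=[
            ("10011", "1001", "1", "Glioblastoma"),
            ("10021", "1002", "1", "Glioma"),
            ("10031", "1003", "1", "Astrocytoma"),
        ],
    )
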