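"""Reading, cleaning and deduplication of FAERS-style quarterly ASCII extracts.

The FDA distributes each FAERS quarter as six "$"-delimited tables linked by
``primaryid``/``caseid``: DEMO (demographics and administration), DRUG
(per-drug records with a role code), REAC (MedDRA preferred-term reactions),
OUTC (outcome codes, e.g. ``DE`` for death), THER (therapy start/stop dates)
and INDI (indications for use).  A quarterly "deleted cases" list names
reports the FDA has withdrawn.  This module parses those files into a
:class:`RawQuarter`, enforces referential integrity against DEMO, collapses
the multiple versions of a case into one :class:`AEReport` per ``caseid``,
and round-trips the normalized case store as JSON lines.
"""

from __future__ import annotations

import json
import logging
import re
from collections import Counter
from dataclasses import dataclass, field, asdict
from datetime import date
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

TABLE_NAMES = ("DEMO", "DRUG", "REAC", "OUTC", "THER", "INDI")

#: FAERS age-unit codes -> factor converting the stored value to years.
AGE_UNIT_TO_YEARS = {
    "YR": 1.0,
    "DEC": 10.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.1775,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / (365.25 * 24.0),
}

MAX_PLAUSIBLE_AGE = 120.0


class MissingTableError(FileNotFoundError):
    """A mandatory quarterly table is absent from the directory."""


@dataclass(frozen=True)
class Dialect:
    """File-format declaration for a quarterly extract.

    FAERS ships "$"-delimited text with one header line; fixtures may use
    other delimiters.
    """

    delimiter: str = "$"
    header: bool = True
    encoding: str = "latin-1"


@dataclass
class RawQuarter:
    """One quarter's six tables plus the deleted-case list.

    Tables are kept as string-typed DataFrames exactly as parsed; cleaning
    beyond referential integrity happens during :func:`deduplicate`.
    """

    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    outc: pd.DataFrame
    ther: pd.DataFrame
    indi: pd.DataFrame
    deleted_caseids: set[str] = field(default_factory=set)
    log: dict[str, int] = field(default_factory=dict)

    def table(self, name: str) -> pd.DataFrame:
        return getattr(self, name.lower())


@dataclass
class Drug:
    """One drug record on a report, with its linked therapy and indication rows."""

    verbatim_name: str
    standardized_name: str
    role: str  # PS, SS, C, I
    indications: list[str] = field(default_factory=list)
    therapy_starts: list[tuple[date, bool]] = field(default_factory=list)  # (date, imprecise)


@dataclass
class AEReport:
    """One deduplicated FAERS case."""

    caseid: str
    primaryid: str
    caseversion: int
    receipt_date: date | None
    receipt_imprecise: bool
    age: float | None
    sex: str  # "male" / "female" / "unknown"
    drugs: list[Drug]
    reactions: list[str]
    outcomes: list[str]

    @property
    def ps_drugs(self) -> list[Drug]:
        return [d for d in self.drugs if d.role == "PS"]

    @property
    def indications(self) -> list[str]:
        return [t for d in self.drugs for t in d.indications]

    @property
    def therapy_starts(self) -> list[tuple[date, bool]]:
        return [s for d in self.drugs for s in d.therapy_starts]

    def to_json(self) -> str:
        rec = asdict(self)
        rec["receipt_date"] = self.receipt_date.isoformat() if self.receipt_date else None
        for d in rec["drugs"]:
            d["therapy_starts"] = [[dt.isoformat(), imp] for dt, imp in d["therapy_starts"]]
        return json.dumps(rec, sort_keys=True)

    @classmethod
    def from_json(cls, line: str) -> "AEReport":
        rec = json.loads(line)
        rec["receipt_date"] = (
            date.fromisoformat(rec["receipt_date"]) if rec["receipt_date"] else None
        )
        drugs = []
        for d in rec.pop("drugs"):
            d["therapy_starts"] = [
                (date.fromisoformat(dt), bool(imp)) for dt, imp in d["therapy_starts"]
            ]
            drugs.append(Drug(**d))
        return cls(drugs=drugs, **rec)


def parse_faers_date(raw: object) -> tuple[date | None, bool]:
    """Parse a FAERS numeric date (YYYYMMDD, YYYYMM or YYYY).

    Partial dates are completed to the earliest consistent day (first of
    month / January 1) and flagged imprecise.  Returns ``(None, False)``
    for missing or unparseable values — the row is kept, the field dropped.
    """
    if raw is None or (isinstance(raw, float) and pd.isna(raw)):
        return None, False
    s = str(raw).strip()
    if s.endswith(".0"):
        s = s[:-2]
    if not s.isdigit():
        return None, False
    try:
        if len(s) == 8:
            return date(int(s[:4]), int(s[4:6]), int(s[6:8])), False
        if len(s) == 6:
            return date(int(s[:4]), int(s[4:6]), 1), True
        if len(s) == 4:
            return date(int(s), 1, 1), True
    except ValueError:
        return None, False
    return None, False


def normalize_age(value: object, unit: object) -> float | None:
    """Convert a FAERS age + age-unit pair to years; implausible ages -> missing."""
    if value is None or (isinstance(value, str) and not value.strip()) or pd.isna(value):
        return None
    try:
        v = float(value)
    except (TypeError, ValueError):
        return None
    code = str(unit).strip().upper() if unit is not None and not pd.isna(unit) else "YR"
    factor = AGE_UNIT_TO_YEARS.get(code)
    if factor is None:
        factor = 1.0  # unknown unit code: assume years
    years = v * factor
    if years < 0 or years > MAX_PLAUSIBLE_AGE:
        return None
    return years


def _find_table_file(dir_path: Path, name: str) -> Path | None:
    pattern = re.compile(rf"^{name}.*\.(txt|TXT)$", re.IGNORECASE)
    hits = sorted(p for p in dir_path.iterdir() if pattern.match(p.name))
    return hits[0] if hits else None


def read_quarter(dir_path: str | Path, dialect: Dialect = Dialect()) -> RawQuarter:
    """Read one quarterly directory into a :class:`RawQuarter`.

    All six tables are mandatory; a missing table raises
    :class:`MissingTableError` naming the file.  A ``DELETED*.txt`` file
    (one caseid per line) is optional.  Rows in non-DEMO tables whose
    ``primaryid`` never appears in DEMO are dropped and counted in
    ``RawQuarter.log`` — FAERS guarantees the linkage, fixtures may not.
    """
    dir_path = Path(dir_path)
    tables: dict[str, pd.DataFrame] = {}
    log: dict[str, int] = {}
    for name in TABLE_NAMES:
        path = _find_table_file(dir_path, name)
        if path is None:
            raise MissingTableError(f"mandatory FAERS table {name} not found in {dir_path}")
        df = pd.read_csv(
            path,
            sep=dialect.delimiter,
            dtype=str,
            header=0 if dialect.header else None,
            encoding=dialect.encoding,
            engine="python",
            on_bad_lines=lambda bad: log.__setitem__(  # noqa: PLW0108 — count, keep going
                f"malformed_{name}", log.get(f"malformed_{name}", 0) + 1
            ),
        )
        df.columns = [c.strip().lower() for c in df.columns]
        tables[name] = df

    demo_ids = set(tables["DEMO"]["primaryid"].astype(str))
    for name in TABLE_NAMES[1:]:
        df = tables[name]
        keep = df["primaryid"].astype(str).isin(demo_ids)
        n_dropped = int((~keep).sum())
        if n_dropped:
            logger.warning("%s: dropped %d rows with primaryid absent from DEMO", name, n_dropped)
            log[f"orphan_{name}"] = n_dropped
            tables[name] = df[keep].reset_index(drop=True)

    deleted: set[str] = set()
    del_pattern = re.compile(r"^DELETE.*\.(txt|TXT)$", re.IGNORECASE)
    for p in sorted(dir_path.iterdir()):
        if del_pattern.match(p.name):
            deleted |= {
                line.strip() for line in p.read_text(dialect.encoding).splitlines() if line.strip()
            }
    return RawQuarter(
        demo=tables["DEMO"],
        drug=tables["DRUG"],
        reac=tables["REAC"],
        outc=tables["OUTC"],
        ther=tables["THER"],
        indi=tables["INDI"],
        deleted_caseids=deleted,
        log=log,
    )


def _sex_label(raw: object) -> str:
    s = str(raw).strip().upper() if raw is not None and not pd.isna(raw) else ""
    return {"M": "male", "F": "female"}.get(s, "unknown")


def _is_missing(v: object) -> bool:
    return v is None or (isinstance(v, float) and v != v) or str(v).strip() == ""


def _assemble_report(
    demo_row: dict,
    drug_rows: list[tuple],   # (drug_seq, role_cod, drugname)
    reac_rows: list[tuple],   # (pt,)
    outc_rows: list[tuple],   # (outc_cod,)
    ther_rows: list[tuple],   # (dsg_drug_seq, start_dt)
    indi_rows: list[tuple],   # (indi_drug_seq, indi_pt)
) -> AEReport:
    receipt, receipt_imp = parse_faers_date(demo_row.get("fda_dt"))
    ther_by_seq: dict[str, list[tuple[date, bool]]] = {}
    for seq, start in ther_rows:
        dt, imp = parse_faers_date(start)
        if dt is not None:
            ther_by_seq.setdefault(str(seq), []).append((dt, imp))
    indi_by_seq: dict[str, list[str]] = {}
    for seq, term in indi_rows:
        if not _is_missing(term):
            indi_by_seq.setdefault(str(seq), []).append(str(term).strip())
    drugs = []
    for seq, role, name in drug_rows:
        seq = str(seq)
        name = "" if _is_missing(name) else str(name).strip()
        drugs.append(
            Drug(
                verbatim_name=name,
                standardized_name=name,
                role="" if _is_missing(role) else str(role).strip().upper(),
                indications=indi_by_seq.get(seq, []),
                therapy_starts=ther_by_seq.get(seq, []),
            )
        )
    reactions = sorted({str(t).strip() for (t,) in reac_rows if not _is_missing(t)})
    outcomes = sorted({str(t).strip().upper() for (t,) in outc_rows if not _is_missing(t)})
    ver = demo_row.get("caseversion")
    return AEReport(
        caseid=str(demo_row["caseid"]),
        primaryid=str(demo_row["primaryid"]),
        caseversion=1 if _is_missing(ver) else int(float(ver)),
        receipt_date=receipt,
        receipt_imprecise=receipt_imp,
        age=normalize_age(demo_row.get("age"), demo_row.get("age_cod")),
        sex=_sex_label(demo_row.get("sex")),
        drugs=drugs,
        reactions=reactions,
        outcomes=outcomes,
    )


def deduplicate(quarters: list[RawQuarter]) -> list[AEReport]:
    """Collapse all quarters to one :class:`AEReport` per ``caseid``.

    The retained record is the one with the highest ``caseversion``, ties
    broken by latest receipt date (``fda_dt``), then lexically largest
    ``primaryid`` — the conventional FAERS rule.  Caseids named in any
    quarter's deleted-case list are removed entirely.  The result is
    invariant to the ordering of ``quarters`` and idempotent.
    """
    if not quarters:
        return []
    demo = pd.concat([q.demo for q in quarters], ignore_index=True)
    deleted: set[str] = set().union(*(q.deleted_caseids for q in quarters))
    demo = demo[~demo["caseid"].astype(str).isin(deleted)].copy()
    if demo.empty:
        return []
    demo["caseid"] = demo["caseid"].astype(str)
    demo["primaryid"] = demo["primaryid"].astype(str)
    demo["_ver"] = pd.to_numeric(demo.get("caseversion", 1), errors="coerce").fillna(1)
    demo["_dt"] = demo.get("fda_dt", "").astype(str).str.ljust(8, "0")
    demo = demo.sort_values(["caseid", "_ver", "_dt", "primaryid"])
    winners = demo.drop_duplicates("caseid", keep="last")
    keep_pids = set(winners["primaryid"])

    def _sub(tbls: list[pd.DataFrame], cols: list[str]) -> dict[str, list[tuple]]:
        df = pd.concat(tbls, ignore_index=True)
        pids = df["primaryid"].astype(str)
        mask = pids.isin(keep_pids).to_numpy()
        out: dict[str, list[tuple]] = {}
        values = zip(pids.to_numpy()[mask],
                     *(df[c].to_numpy()[mask] for c in cols if c in df.columns))
        for pid, *rest in values:
            out.setdefault(pid, []).append(tuple(rest))
        return out

    drug_by = _sub([q.drug for q in quarters], ["drug_seq", "role_cod", "drugname"])
    reac_by = _sub([q.reac for q in quarters], ["pt"])
    outc_by = _sub([q.outc for q in quarters], ["outc_cod"])
    ther_by = _sub([q.ther for q in quarters], ["dsg_drug_seq", "start_dt"])
    indi_by = _sub([q.indi for q in quarters], ["indi_drug_seq", "indi_pt"])
    reports = []
    for row in winners.to_dict("records"):
        pid = row["primaryid"]
        rep = _assemble_report(
            row,
            drug_by.get(pid, []),
            reac_by.get(pid, []),
            outc_by.get(pid, []),
            ther_by.get(pid, []),
            indi_by.get(pid, []),
        )
        if not rep.reactions:
            logger.warning("case %s dropped: no reactions", rep.caseid)
            continue
        reports.append(rep)
    reports.sort(key=lambda r: r.caseid)
    return reports


_WS = re.compile(r"\s+")


def _fold(name: str) -> str:
    """Normalization used for drug-name lookup: trim, collapse whitespace,
    casefold, strip trailing periods."""
    return _WS.sub(" ", name.strip()).casefold().rstrip(".")


def standardize_drug_names(
    reports: list[AEReport], name_map: dict[str, str]
) -> tuple[list[AEReport], Counter]:
    """Map verbatim drug names to standard names (in place).

    Matching is case-insensitive after trimming and collapsing internal
    whitespace.  Unmatched names pass through verbatim and are tallied in
    the returned coverage counter.
    """
    if not name_map:
        logger.warning("empty drug name map: all names pass through verbatim")
    folded = {_fold(k): v for k, v in name_map.items()}
    unmatched: Counter = Counter()
    for rep in reports:
        for d in rep.drugs:
            std = folded.get(_fold(d.verbatim_name))
            if std is not None:
                d.standardized_name = std
            else:
                d.standardized_name = d.verbatim_name
                unmatched[d.verbatim_name] += 1
    return reports, unmatched


def write_case_store(reports: list[AEReport], path: str | Path) -> None:
    """Write the normalized case store as JSON lines, one report per line."""
    with open(path, "w") as fh:
        for rep in reports:
            fh.write(rep.to_json() + "\n")


def read_case_store(path: str | Path) -> list[AEReport]:
    with open(path) as fh:
        return [AEReport.from_json(line) for line in fh if line.strip()]


def read_name_map(path: str | Path) -> dict[str, str]:
    """Read a 2-column (verbatim,standard) CSV drug-name map."""
    df = pd.read_csv(path, dtype=str)
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
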