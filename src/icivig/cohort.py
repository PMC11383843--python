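"""Cohort construction: ICI drug classes, indication filtering, exposure arms.

The study design restricts to reports whose primary-suspect (PS) drugs were
given for malignant nervous-system neoplasms, then splits them into two
arms: checkpoint inhibitor plus chemotherapy (``ICI_Chemo``) versus
chemotherapy alone (``Only_Chemo``).  Within the exposed arm the regimen
records which ICI classes were combined (anti-PD-1, anti-PD-L1,
anti-CTLA-4, or combinations).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .faers_io import AEReport

logger = logging.getLogger(__name__)

ICI_CLASSES = frozenset({"PD1", "PDL1", "CTLA4"})
DRUG_CLASSES = frozenset({"PD1", "PDL1", "CTLA4", "CHEMO", "OTHER"})

#: Default MedDRA high-level group term targeted by the analysis.
NSC_HLGT = "Nervous system neoplasms malignant and unspecified NEC"

ARM_EXPOSED = "ICI_Chemo"
ARM_COMPARATOR = "Only_Chemo"

REGIMENS = (
    "PD1_Chemo",
    "PDL1_Chemo",
    "CTLA4_Chemo",
    "PD1_CTLA4_Chemo",
    "Combined-ICI_Chemo",
    "Only_Chemo",
)

AGE_GROUPS = ("<45", "45-64", ">64", "unknown")


@dataclass(frozen=True)
class CohortAssignment:
    caseid: str
    arm: str
    regimen: str
    age_group: str
    sex: str
    age: float | None


def load_default_class_map() -> dict[str, str]:
    """Packaged default mapping of standardized drug names to classes."""
    with resources.files("icivig.data").joinpath("drug_classes.csv").open() as fh:
        df = pd.read_csv(fh, dtype=str)
    return {k.casefold(): v for k, v in zip(df["standardized_name"], df["class"])}


def load_default_indication_lookup() -> dict[str, str]:
    """Packaged default indication-term -> HLGT lookup (stands in for MedDRA)."""
    with resources.files("icivig.data").joinpath("indication_hlgt.csv").open() as fh:
        df = pd.read_csv(fh, dtype=str)
    return {k.casefold(): v for k, v in zip(df["term"], df["hlgt"])}


def read_class_map(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, dtype=str)
    return {k.casefold(): v for k, v in zip(df.iloc[:, 0], df.iloc[:, 1])}


def read_indication_lookup(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, dtype=str)
    return {k.casefold(): v for k, v in zip(df.iloc[:, 0], df.iloc[:, 1])}


def drug_class(name: str, class_map: dict[str, str]) -> str:
    """Class of a standardized drug name; names off the map are OTHER."""
    return class_map.get(name.strip().casefold(), "OTHER")


def filter_indication(
    reports: list[AEReport],
    lookup: dict[str, str],
    target_terms: set[str] = frozenset({NSC_HLGT}),
) -> list[AEReport]:
    """Keep reports with at least one PS-drug indication in the target HLGTs.

    ``lookup`` maps indication terms (case-insensitively) to HLGTs; a term
    already equal to a target HLGT also matches.  The restriction to
    PS-drug indications mirrors the PS-drug exposure definition.
    """
    if not lookup:
        raise ValueError("indication->HLGT lookup is empty: cannot resolve HLGT membership")
    if not target_terms:
        raise ValueError("target_terms must be non-empty")
    targets = {t.casefold() for t in target_terms}
    kept = []
    for rep in reports:
        terms = [t for d in rep.ps_drugs for t in d.indications]
        for t in terms:
            hlgt = lookup.get(t.strip().casefold(), t.strip())
            if hlgt.casefold() in targets:
                kept.append(rep)
                break
    return kept


def assign_age_group(age: float | None) -> str:
    """Age bands <45 / [45, 64] / >64; missing -> unknown."""
    if age is None or pd.isna(age):
        return "unknown"
    if age < 45:
        return "<45"
    if age <= 64:
        return "45-64"
    return ">64"


def assign_arm(report: AEReport, class_map: dict[str, str]) -> CohortAssignment | None:
    """Assign exposure arm and regimen from the PS-drug class set.

    The regimen follows the set S of ICI classes among PS drugs:
    {PD1} -> PD1_Chemo, {PDL1} -> PDL1_Chemo, {CTLA4} -> CTLA4_Chemo,
    {PD1, CTLA4} -> PD1_CTLA4_Chemo, any other multi-class set ->
    Combined-ICI_Chemo; no ICI with >=1 chemotherapy PS drug -> Only_Chemo.
    Reports with neither an ICI nor a chemotherapy PS drug do not belong
    to either arm and are excluded (returns None, logged).
    """
    classes = {drug_class(d.standardized_name, class_map) for d in report.ps_drugs}
    ici = classes & ICI_CLASSES
    if ici:
        if ici == {"PD1"}:
            regimen = "PD1_Chemo"
        elif ici == {"PDL1"}:
            regimen = "PDL1_Chemo"
        elif ici == {"CTLA4"}:
            regimen = "CTLA4_Chemo"
        elif ici == {"PD1", "CTLA4"}:
            regimen = "PD1_CTLA4_Chemo"
        else:
            regimen = "Combined-ICI_Chemo"
        arm = ARM_EXPOSED
    elif "CHEMO" in classes:
        arm, regimen = ARM_COMPARATOR, "Only_Chemo"
    else:
        logger.info("case %s excluded: no ICI or chemotherapy PS drug", report.caseid)
        return None
    return CohortAssignment(
        caseid=report.caseid,
        arm=arm,
        regimen=regimen,
        age_group=assign_age_group(report.age),
        sex=report.sex,
        age=report.age,
    )


def build_cohort(reports: list[AEReport], class_map: dict[str, str]) -> pd.DataFrame:
    """Cohort table with one row per assignable case.

    Columns: caseid, arm, regimen, age_group, sex, age, death (DE outcome
    present).  Cases without an ICI or chemotherapy PS drug are dropped.
    """
    rows = []
    by_id = {}
    for rep in reports:
        asg = assign_arm(rep, class_map)
        if asg is None:
            continue
        by_id[rep.caseid] = rep
        rows.append(
            {
                "caseid": asg.caseid,
                "arm": asg.arm,
                "regimen": asg.regimen,
                "age_group": asg.age_group,
                "sex": asg.sex,
                "age": asg.age,
                "death": "DE" in rep.outcomes,
            }
        )
    return pd.DataFrame(
        rows, columns=["caseid", "arm", "regimen", "age_group", "sex", "age", "death"]
    )
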