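"""Generator of FAERS-like quarterly files with known ground truth.

The generator emulates the structure of the study's source data: a
two-arm nervous-system-cancer cohort (ICI plus chemotherapy vs
chemotherapy alone) reported through the six quarterly FAERS tables.
Every quantity the downstream pipeline estimates is planted explicitly
and recorded in a manifest:

* per-event reporting odds ratios — the comparator-arm event probability
  p0 and the true ROR fix the exposed-arm probability p1 through
  odds(p1) = ROR * odds(p0), so the expected 2x2 table reproduces the
  planted ROR;
* background events drawn identically in both arms (true ROR = 1) from a
  skewed preferred-term frequency table, with a Poisson number of extra
  terms per report so the b/d cells are realistically occupied;
* fatal outcomes from a logistic model with configurable odds ratios for
  older age and chemotherapy-only treatment;
* log-normal time-to-onset per age band, with the receipt date placed at
  therapy start plus the onset interval;
* duplicate case versions and officially-deleted cases at configurable
  rates, exercising the deduplication path.

Identical config + seed produces byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from ..faers_io import RawQuarter

# verbatim spellings per standardized drug name, exercising name cleanup
DRUG_VARIANTS: dict[str, list[str]] = {
    "nivolumab": ["NIVOLUMAB", "Nivolumab", "OPDIVO", "nivolumab."],
    "pembrolizumab": ["PEMBROLIZUMAB", "KEYTRUDA", "Pembrolizumab "],
    "atezolizumab": ["ATEZOLIZUMAB", "TECENTRIQ"],
    "durvalumab": ["DURVALUMAB", "IMFINZI"],
    "ipilimumab": ["IPILIMUMAB", "YERVOY", "Ipilimumab"],
    "tremelimumab": ["TREMELIMUMAB"],
    "temozolomide": ["TEMOZOLOMIDE", "TEMODAR", "Temozolomide"],
    "lomustine": ["LOMUSTINE", "CCNU"],
    "carboplatin": ["CARBOPLATIN"],
}

REGIMEN_DRUGS: dict[str, list[str]] = {
    "PD1_Chemo": ["nivolumab", "temozolomide"],
    "PDL1_Chemo": ["atezolizumab", "temozolomide"],
    "CTLA4_Chemo": ["ipilimumab", "lomustine"],
    "PD1_CTLA4_Chemo": ["nivolumab", "ipilimumab", "temozolomide"],
    "Combined-ICI_Chemo": ["durvalumab", "tremelimumab", "carboplatin"],
    "Only_Chemo": ["temozolomide"],
}

TARGET_INDICATIONS = ["Glioblastoma", "Glioma", "Astrocytoma", "Neuroblastoma",
                      "Malignant glioma"]
OFFTARGET_INDICATION = "Malignant melanoma"

BACKGROUND_PTS = [
    "Nausea", "Fatigue", "Headache", "Vomiting", "Pyrexia", "Diarrhoea",
    "Dizziness", "Rash", "Anaemia", "Thrombocytopenia", "Constipation",
    "Oedema peripheral", "Decreased appetite", "Insomnia", "Pruritus",
    "Dyspnoea", "Cough", "Arthralgia", "Myalgia", "Hypertension",
    "Alopecia", "Dysgeusia", "Neutropenia", "Dehydration", "Malaise",
]


def default_name_map() -> dict[str, str]:
    """Verbatim -> standardized map covering every generated spelling."""
    return {v: std for std, variants in DRUG_VARIANTS.items() for v in variants}


@dataclass
class ReportGeneratorConfig:
    """Ground-truth parameters of the synthetic report stream.

    ``planted_events`` maps a preferred term to (comparator probability
    p0, true ROR).  Defaults emulate the study conditions: a cohort of a
    few thousand nervous-system-cancer reports, a ~10% ICI_Chemo arm, a
    handful of planted immune-related events with elevated RORs, older
    age and chemotherapy-only treatment raising the odds of death.
    """

    n_cases: int = 5000
    ici_fraction: float = 0.10
    regimen_mix: dict[str, float] = field(
        default_factory=lambda: {
            "PD1_Chemo": 0.50,
            "PDL1_Chemo": 0.20,
            "CTLA4_Chemo": 0.10,
            "PD1_CTLA4_Chemo": 0.12,
            "Combined-ICI_Chemo": 0.08,
        }
    )
    planted_events: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "Seizure": (0.006, 10.0),
            "Confusional state": (0.006, 8.0),
            "Encephalopathy": (0.005, 6.0),
            "Muscular weakness": (0.005, 5.0),
        }
    )
    bg_lambda: float = 2.0  # Poisson mean of extra background PTs per report
    age_mean: float = 58.0
    age_sd: float = 15.0
    age_missing_rate: float = 0.08
    sex_probs: dict[str, float] = field(
        default_factory=lambda: {"M": 0.55, "F": 0.43, "UNK": 0.02}
    )
    death_base_logit: float = -2.2  # reference: age<45, ICI_Chemo
    death_or_age_mid: float = 1.0
    death_or_age_old: float = 2.5
    death_or_only_chemo: float = 1.8
    tto_lognormal: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "<45": (np.log(75.0), 0.7),
            "45-64": (np.log(120.0), 0.7),
            ">64": (np.log(45.0), 0.7),
            "unknown": (np.log(90.0), 0.7),
        }
    )
    partial_start_rate: float = 0.05  # therapy starts written as YYYYMM
    duplicate_rate: float = 0.05
    deleted_rate: float = 0.02
    offtarget_rate: float = 0.05
    seed: int | None = None

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for pt, (p0, ror) in self.planted_events.items():
            if not 0 < p0 < 1:
                raise ValueError(f"{pt}: baseline probability {p0} outside (0,1)")
            if ror <= 0:
                raise ValueError(f"{pt}: true ROR must be > 0")
            if exposed_probability(p0, ror) >= 1:
                raise ValueError(f"{pt}: infeasible odds (p1 >= 1)")
        for p in (self.ici_fraction, self.duplicate_rate, self.deleted_rate,
                  self.offtarget_rate, self.age_missing_rate):
            if not 0 <= p <= 1:
                raise ValueError("rates must lie in [0, 1]")
        if self.bg_lambda < 0:
            raise ValueError("bg_lambda must be nonnegative")


def exposed_probability(p0: float, true_ror: float) -> float:
    """p1 such that odds(p1)/odds(p0) equals the planted ROR."""
    odds = true_ror * p0 / (1.0 - p0)
    return odds / (1.0 + odds)


def _age_group(age: float | None) -> str:
    if age is None:
        return "unknown"
    if age < 45:
        return "<45"
    if age <= 64:
        return "45-64"
    return ">64"


def simulate_reports(config: ReportGeneratorConfig) -> tuple[RawQuarter, dict]:
    """Draw one quarter of reports in memory.

    Returns the quarter (same table layout :func:`icivig.faers_io.read_quarter`
    produces) and the ground-truth manifest.  The manifest's
    ``unique_caseids`` are the caseids expected to survive deduplication
    (deleted cases excluded); per-case truth (arm, regimen, events, death,
    age group) is under ``cases``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_cases
    caseids = [str(100000 + i) for i in range(n)]

    exposed = rng.random(n) < config.ici_fraction
    reg_names = list(config.regimen_mix)
    reg_probs = np.array([config.regimen_mix[r] for r in reg_names], dtype=float)
    reg_probs = reg_probs / reg_probs.sum()
    regimen = np.where(
        exposed, rng.choice(reg_names, size=n, p=reg_probs), "Only_Chemo"
    )

    age = rng.normal(config.age_mean, config.age_sd, size=n).clip(18, 95)
    age_missing = rng.random(n) < config.age_missing_rate
    sex_labels = list(config.sex_probs)
    sex_p = np.array([config.sex_probs[s] for s in sex_labels], dtype=float)
    sex = rng.choice(sex_labels, size=n, p=sex_p / sex_p.sum())

    # planted events: Bernoulli per arm-specific probability
    event_hits: dict[str, np.ndarray] = {}
    for pt, (p0, ror) in config.planted_events.items():
        p1 = exposed_probability(p0, ror)
        event_hits[pt] = rng.random(n) < np.where(exposed, p1, p0)

    # background events identical in both arms (true ROR = 1), Zipf-weighted
    bg_w = 1.0 / np.arange(1, len(BACKGROUND_PTS) + 1)
    bg_w /= bg_w.sum()
    n_bg = rng.poisson(config.bg_lambda, size=n)

    # death via logistic model on decoded age group and arm
    groups = np.array(
        [_age_group(None if m else a) for a, m in zip(age, age_missing)]
    )
    logit = np.full(n, config.death_base_logit)
    logit += np.log(config.death_or_age_mid) * (groups == "45-64")
    logit += np.log(config.death_or_age_old) * (groups == ">64")
    logit += np.log(config.death_or_only_chemo) * (~exposed)
    death = rng.random(n) < 1.0 / (1.0 + np.exp(-logit))

    # therapy start uniform over the study window; receipt = start + TTO
    window_start = date(2013, 1, 1)
    window_days = (date(2022, 6, 30) - window_start).days
    start_offsets = rng.integers(0, window_days, size=n)
    tto = np.empty(n)
    for g, (mu, sg) in config.tto_lognormal.items():
        mask = groups == g
        tto[mask] = rng.lognormal(mu, sg, size=int(mask.sum()))
    tto = np.maximum(np.round(tto), 0).astype(int)
    partial_start = rng.random(n) < config.partial_start_rate

    offtarget = rng.random(n) < config.offtarget_rate
    indication = np.where(
        offtarget,
        OFFTARGET_INDICATION,
        rng.choice(TARGET_INDICATIONS, size=n),
    )

    dup_idx = set(
        rng.choice(n, size=int(round(config.duplicate_rate * n)), replace=False).tolist()
    )
    non_dup = [i for i in range(n) if i not in dup_idx]
    del_pick = rng.choice(
        len(non_dup), size=int(round(config.deleted_rate * n)), replace=False
    )
    deleted_idx = {non_dup[i] for i in del_pick.tolist()}

    demo_rows, drug_rows, reac_rows, outc_rows, ther_rows, indi_rows = ([] for _ in range(6))
    cases_truth = {}
    for i in range(n):
        cid = caseids[i]
        start = window_start + timedelta(days=int(start_offsets[i]))
        receipt = start + timedelta(days=int(tto[i]))
        start_str = start.strftime("%Y%m") if partial_start[i] else start.strftime("%Y%m%d")
        pts = sorted(
            {pt for pt in config.planted_events if event_hits[pt][i]}
            | {BACKGROUND_PTS[j] for j in rng.choice(len(BACKGROUND_PTS), size=int(n_bg[i]), p=bg_w)}
        )
        if not pts:  # reactions must be non-empty
            pts = [BACKGROUND_PTS[int(rng.choice(len(BACKGROUND_PTS), p=bg_w))]]
        age_str = "" if age_missing[i] else f"{age[i]:.1f}"
        versions = [1, 2] if i in dup_idx else [1]
        for ver in versions:
            pid = f"{cid}{ver}"
            demo_rows.append((pid, cid, str(ver), receipt.strftime("%Y%m%d"),
                              age_str, "YR", sex[i]))
            for seq, std in enumerate(REGIMEN_DRUGS[str(regimen[i])], 1):
                variants = DRUG_VARIANTS[std]
                verbatim = variants[int(rng.integers(len(variants)))]
                drug_rows.append((pid, cid, str(seq), "PS", verbatim))
                ther_rows.append((pid, cid, str(seq), start_str))
                indi_rows.append((pid, cid, str(seq), indication[i]))
            for pt in pts:
                reac_rows.append((pid, cid, pt))
            if death[i]:
                outc_rows.append((pid, cid, "DE"))
        cases_truth[cid] = {
            "arm": "ICI_Chemo" if exposed[i] else "Only_Chemo",
            "regimen": str(regimen[i]),
            "age_group": str(groups[i]),
            "sex": {"M": "male", "F": "female"}.get(str(sex[i]), "unknown"),
            "events": [pt for pt in config.planted_events if event_hits[pt][i]],
            "all_pts": pts,
            "death": bool(death[i]),
            "tto_days": int(tto[i]),
            "indication": str(indication[i]),
            "deleted": i in deleted_idx,
        }

    quarter = RawQuarter(
        demo=pd.DataFrame(demo_rows, columns=["primaryid", "caseid", "caseversion",
                                              "fda_dt", "age", "age_cod", "sex"]),
        drug=pd.DataFrame(drug_rows, columns=["primaryid", "caseid", "drug_seq",
                                              "role_cod", "drugname"]),
        reac=pd.DataFrame(reac_rows, columns=["primaryid", "caseid", "pt"]),
        outc=pd.DataFrame(outc_rows, columns=["primaryid", "caseid", "outc_cod"]),
        ther=pd.DataFrame(ther_rows, columns=["primaryid", "caseid", "dsg_drug_seq",
                                              "start_dt"]),
        indi=pd.DataFrame(indi_rows, columns=["primaryid", "caseid", "indi_drug_seq",
                                              "indi_pt"]),
        deleted_caseids={caseids[i] for i in deleted_idx},
    )
    manifest = {
        "seed": config.seed,
        "n_cases": n,
        "planted_events": {
            pt: {"baseline_p": p0, "true_ror": ror,
                 "exposed_p": exposed_probability(p0, ror)}
            for pt, (p0, ror) in config.planted_events.items()
        },
        "death_model": {
            "base_logit": config.death_base_logit,
            "or_age_45_64": config.death_or_age_mid,
            "or_age_over_64": config.death_or_age_old,
            "or_only_chemo": config.death_or_only_chemo,
        },
        "tto_lognormal": {g: list(v) for g, v in config.tto_lognormal.items()},
        "deleted_caseids": sorted(quarter.deleted_caseids),
        "unique_caseids": sorted(set(caseids) - quarter.deleted_caseids),
        "duplicated_caseids": sorted(caseids[i] for i in dup_idx),
        "cases": cases_truth,
        "config": {k: v for k, v in asdict(config).items()
                   if not isinstance(v, dict)},
    }
    return quarter, manifest


def generate_faers(config: ReportGeneratorConfig, out_dir: str | Path) -> dict:
    """Write one quarter of "$"-delimited FAERS-style files plus the manifest.

    Produces ``DEMO.txt`` .. ``INDI.txt``, ``DELETED.txt`` (one caseid per
    line) and ``manifest.json`` under ``out_dir``.  Output is
    byte-identical for identical config + seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    quarter, manifest = simulate_reports(config)
    for name in ("demo", "drug", "reac", "outc", "ther", "indi"):
        df = getattr(quarter, name)
        df.to_csv(out_dir / f"{name.upper()}.txt", sep="$", index=False,
                  lineterminator="\n")
    (out_dir / "DELETED.txt").write_text(
        "".join(cid + "\n" for cid in sorted(quarter.deleted_caseids))
    )
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
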