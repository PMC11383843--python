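"""Configuration-driven orchestration of the full analysis.

Stages (each reads/writes only its declared files, so they can be run and
tested independently):

* ``simulate``  — write synthetic FAERS quarter(s) and expression bundle;
* ``ingest``    — parse quarters, deduplicate, standardize drug names,
  write the normalized case store (JSON lines) and name-coverage report;
* ``signals``   — indication filter, cohort assignment, disproportionality
  screen;
* ``clinical``  — time-to-onset tables/tests and logistic prognosis models;
* ``mechanism`` — ssGSEA medians, pathway/gene screening, bivariate model
  search, preranked GSEA;
* ``all``       — everything plus ``summary.json`` and a run log.

Every stage is a pure function of (inputs, config, seed); reruns with the
same config reproduce outputs byte-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import clinical_stats, cohort as cohort_mod, faers_io, mechanism
from .signal_detection import Thresholds, screen_events
from .synthetic_data import (
    ExpressionGeneratorConfig,
    ReportGeneratorConfig,
    default_name_map,
    generate_expression_bundle,
    generate_faers,
)

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid or inconsistent run configuration."""


@dataclasses.dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "icivig_run"
    faers_dir: str | None = None  # None -> use the synthetic quarter
    expression_dir: str | None = None
    gmt: str | None = None
    rors_csv: str | None = None  # cancer_type,observed_ror for user expression
    name_map: str | None = None
    class_map: str | None = None
    indication_lookup: str | None = None
    target_hlgts: list[str] = dataclasses.field(
        default_factory=lambda: [cohort_mod.NSC_HLGT]
    )
    thresholds: dict = dataclasses.field(default_factory=dict)
    ic_variant: str = "noren"
    screen_alpha: float = 0.05
    tto_start_rule: str = "earliest"
    include_imprecise_tto: bool = True
    response_scale: str = "ror"  # or "log_ror"
    n_perm: int = 1000
    synthetic_faers: dict = dataclasses.field(default_factory=dict)
    synthetic_expression: dict = dataclasses.field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        for key in ("faers_dir", "expression_dir", "gmt", "rors_csv",
                    "name_map", "class_map", "indication_lookup"):
            val = getattr(self, key)
            if val is not None and not Path(val).exists():
                raise ConfigError(f"{key} path does not exist: {val}")
        if self.ic_variant not in ("noren", "gamma"):
            raise ConfigError(f"unknown ic_variant {self.ic_variant!r}")
        if self.response_scale not in ("ror", "log_ror"):
            raise ConfigError(f"unknown response_scale {self.response_scale!r}")

    def thresholds_obj(self) -> Thresholds:
        return Thresholds(**self.thresholds)


def _out(config: RunConfig) -> Path:
    p = Path(config.out_dir)
    p.mkdir(parents=True, exist_ok=True)
    return p


def stage_simulate(config: RunConfig) -> dict:
    out = _out(config)
    fa_cfg = ReportGeneratorConfig(**{"seed": config.seed, **config.synthetic_faers})
    ex_cfg = ExpressionGeneratorConfig(
        **{"seed": config.seed + 1, **config.synthetic_expression}
    )
    fa_manifest = generate_faers(fa_cfg, out / "synthetic" / "faers" / "q1")
    ex_manifest = generate_expression_bundle(ex_cfg, out / "synthetic" / "expression")
    return {"faers_cases": fa_manifest["n_cases"],
            "expression_types": len(ex_manifest["planted_rors"])}


def stage_ingest(config: RunConfig) -> dict:
    out = _out(config)
    base = Path(config.faers_dir) if config.faers_dir else out / "synthetic" / "faers"
    quarter_dirs = sorted(
        d for d in base.iterdir() if d.is_dir()
    ) or [base]
    quarters = [faers_io.read_quarter(d) for d in quarter_dirs]
    reports = faers_io.deduplicate(quarters)
    name_map = (
        faers_io.read_name_map(config.name_map) if config.name_map else default_name_map()
    )
    reports, coverage = faers_io.standardize_drug_names(reports, name_map)
    faers_io.write_case_store(reports, out / "case_store.jsonl")
    pd.DataFrame(
        sorted(coverage.items()), columns=["verbatim_name", "n_unmatched"]
    ).to_csv(out / "name_coverage.csv", index=False)
    return {"n_quarters": len(quarters), "n_reports": len(reports),
            "n_unmatched_names": len(coverage)}


def _load_cohort_inputs(config: RunConfig):
    out = _out(config)
    reports = faers_io.read_case_store(out / "case_store.jsonl")
    class_map = (
        cohort_mod.read_class_map(config.class_map)
        if config.class_map
        else cohort_mod.load_default_class_map()
    )
    lookup = (
        cohort_mod.read_indication_lookup(config.indication_lookup)
        if config.indication_lookup
        else cohort_mod.load_default_indication_lookup()
    )
    reports = cohort_mod.filter_indication(reports, lookup, set(config.target_hlgts))
    return reports, class_map


def stage_signals(config: RunConfig) -> dict:
    out = _out(config)
    reports, class_map = _load_cohort_inputs(config)
    coh = cohort_mod.build_cohort(reports, class_map)
    coh.to_csv(out / "cohort.csv", index=False)
    reactions = {r.caseid: set(r.reactions) for r in reports}
    signals = screen_events(
        coh, reactions, thresholds=config.thresholds_obj(), ic_variant=config.ic_variant
    )
    signals.to_csv(out / "signals.csv", index=False)
    flagged = signals.loc[signals["is_signal"], "event_pt"].tolist()
    return {"n_cohort": len(coh), "n_events_tested": len(signals),
            "flagged_signals": flagged}


def stage_clinical(config: RunConfig) -> dict:
    out = _out(config)
    reports, class_map = _load_cohort_inputs(config)
    coh = cohort_mod.build_cohort(reports, class_map).set_index("caseid", drop=False)
    signals = pd.read_csv(out / "signals.csv")
    flagged = set(signals.loc[signals["is_signal"], "event_pt"])
    by_id = {r.caseid: r for r in reports}
    coh["irae"] = [
        bool(flagged & set(by_id[cid].reactions)) if cid in by_id else False
        for cid in coh.index
    ]

    # TTO over irAE cases
    recs = []
    for cid in coh.index[coh["irae"]]:
        rec = clinical_stats.compute_tto(
            by_id[cid],
            start_rule=config.tto_start_rule,
            include_imprecise=config.include_imprecise_tto,
        )
        if rec is not None:
            recs.append(rec)
    tto_df = pd.DataFrame([dataclasses.asdict(r) for r in recs])
    tto_df.to_csv(out / "tto.csv", index=False)
    results = {"n_tto_records": len(recs)}
    if recs:
        for split in ("age_group", "sex"):
            groups = {}
            for rec in recs:
                groups.setdefault(getattr(rec, split), []).append(rec.tto_days)
            tests = clinical_stats.compare_tto(groups)
            tests.insert(0, "split", split)
            mode = "a" if split == "sex" else "w"
            tests.to_csv(out / "tto_tests.csv", index=False, mode=mode,
                         header=(mode == "w"))
            ecdf = clinical_stats.tto_ecdf(groups)
            ecdf.insert(0, "split", split)
            ecdf.to_csv(out / "tto_cdf.csv", index=False, mode=mode,
                        header=(mode == "w"))

    # logistic models: prognosis (death) and irAE occurrence
    frames = []
    for outcome, covs in (
        ("death", ["irae", "age_group", "sex", "arm"]),
        ("irae", ["age_group", "sex", "arm"]),
    ):
        try:
            uni = clinical_stats.fit_logistic_univariable(coh, outcome, covs)
            multi = clinical_stats.fit_logistic(coh, outcome, covs)
        except ValueError as exc:
            logger.warning("logistic model for %s skipped: %s", outcome, exc)
            continue
        tab = clinical_stats.logistic_results_table(uni, multi)
        tab.insert(0, "outcome", outcome)
        frames.append(tab)
        results[f"logistic_{outcome}_converged"] = multi.converged
    if frames:
        pd.concat(frames, ignore_index=True).to_csv(out / "logistic.csv", index=False)
    return results


def _load_expression(config: RunConfig):
    out = _out(config)
    if config.expression_dir:
        exp_dir = Path(config.expression_dir)
        if not config.rors_csv:
            raise ConfigError("rors_csv required with a user expression_dir")
        rors = pd.read_csv(config.rors_csv, index_col=0).iloc[:, 0]
        cohorts = [
            mechanism.read_expression_tsv(p, p.stem, float(rors[p.stem]))
            for p in sorted(exp_dir.glob("*.tsv"))
        ]
        gmt_path = Path(config.gmt) if config.gmt else exp_dir / "gene_sets.gmt"
    else:
        exp_dir = out / "synthetic" / "expression"
        with open(exp_dir / "manifest.json") as fh:
            manifest = json.load(fh)
        cohorts = [
            mechanism.read_expression_tsv(
                exp_dir / f"{ct}.tsv", ct, float(r)
            )
            for ct, r in sorted(manifest["planted_rors"].items())
        ]
        gmt_path = exp_dir / "gene_sets.gmt"
    return cohorts, mechanism.read_gmt(gmt_path)


def stage_mechanism(config: RunConfig) -> dict:
    out = _out(config)
    cohorts, gene_sets = _load_expression(config)
    rors = mechanism.observed_rors(cohorts)
    if config.response_scale == "log_ror":
        rors = np.log(rors)
    scores = mechanism.median_pathway_scores(cohorts, gene_sets)
    screen = mechanism.screen_pathways(scores, rors, alpha=config.screen_alpha)
    screen.to_csv(out / "pathway_screen.csv", index=False)
    mechanism.lollipop_data(screen).to_csv(out / "lollipop.csv", index=False)
    result: dict = {"n_pathways_significant": int(screen["significant"].sum())}

    member_genes = sorted(set().union(*gene_sets.values()))
    gene_medians = mechanism.median_gene_expression(cohorts, member_genes)
    gene_screen, enrichment = mechanism.gene_screen_and_gsea(
        gene_medians,
        rors,
        gene_sets,
        alpha=config.screen_alpha,
        n_perm=config.n_perm,
        rng=np.random.default_rng(config.seed + 2),
    )
    gene_screen.to_csv(out / "gene_screen.csv", index=False)
    enrichment.to_csv(out / "enrichment.csv", index=False)
    result["n_genes_significant"] = int(gene_screen["significant"].sum())

    # candidate pool for the pairwise model search: every significantly
    # correlating variable, pathway scores and gene medians alike
    sig_paths = screen.loc[screen["significant"], "variable"].tolist()
    sig_genes = gene_screen.loc[gene_screen["significant"], "gene"].tolist()
    candidates = pd.concat([scores[sig_paths], gene_medians[sig_genes]], axis=1)
    result["n_candidates"] = candidates.shape[1]
    if candidates.shape[1] >= 2:
        fits = mechanism.bivariate_search(candidates, rors)
        mechanism.bivariate_results_table(fits).to_csv(
            out / "bivariate_fits.csv", index=False
        )
        best = fits[0]
        result["best_pair"] = list(best.predictors)
        result["best_pair_rs"] = best.rs_pred_obs
    else:
        logger.warning("fewer than 2 significant variables; bivariate search skipped")
    result["n_sets_enriched"] = int((enrichment["p_adj"] < 0.05).sum())
    return result


STAGES = {
    "simulate": stage_simulate,
    "ingest": stage_ingest,
    "signals": stage_signals,
    "clinical": stage_clinical,
    "mechanism": stage_mechanism,
}
STAGE_ORDER = ["simulate", "ingest", "signals", "clinical", "mechanism"]


def run(config: RunConfig, stages: list[str] | None = None) -> dict:
    """Run the requested stages (default: all) and write ``summary.json``.

    The summary carries per-stage counts, the flagged signal list and the
    best bivariate pair.  A stage failure aborts with the stage name and
    cause; outputs of completed stages are retained.
    """
    config.validate()
    out = _out(config)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path)
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    logging.getLogger("icivig").addHandler(handler)
    summary: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "stages": {},
    }
    try:
        for name in stages or STAGE_ORDER:
            if name == "simulate" and config.faers_dir and config.expression_dir:
                continue
            logger.info("stage %s starting", name)
            summary["stages"][name] = STAGES[name](config)
            logger.info("stage %s done", name)
    except Exception as exc:
        logger.error("stage failed: %s", exc)
        raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
    finally:
        logging.getLogger("icivig").removeHandler(handler)
        handler.close()
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True, default=str)
    return summary
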