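"""Time-to-onset analysis and logistic-regression prognosis models.

Spontaneous-report databases carry no follow-up time, so the two clinical
questions answerable here are (i) how long after therapy start the adverse
event surfaced (time to onset, TTO) and (ii) whether case covariates —
occurrence of an immune-related AE, age group, sex, regimen — shift the
odds of a fatal outcome.  TTO groups are compared with the two-sided
Mann-Whitney rank test; prognosis uses maximum-likelihood logistic
regression (IRLS, via statsmodels) with Wald intervals, in both
univariable (one covariate at a time) and multivariable form.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .faers_io import AEReport
from .cohort import assign_age_group

logger = logging.getLogger(__name__)

#: Reference level per categorical covariate (dropped indicator).
REFERENCE_LEVELS = {"age_group": "<45", "sex": "female", "arm": "ICI_Chemo",
                    "regimen": "PD1_Chemo"}


@dataclass(frozen=True)
class TTORecord:
    caseid: str
    tto_days: float
    age_group: str
    sex: str
    imprecise: bool


@dataclass
class LogisticFit:
    terms: list[tuple[str, float, float, float, float]]  # name, OR, lo, hi, p
    converged: bool
    n_used: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.terms, columns=["term", "odds_ratio", "ci_low", "ci_high", "p_value"]
        )


def compute_tto(
    report: AEReport,
    start_rule: str = "earliest",
    include_imprecise: bool = True,
) -> TTORecord | None:
    """Days from therapy start to the event for one report.

    The event date is the report's receipt date (reaction rows carry no
    onset date); the start is the earliest (default) or latest
    primary-suspect therapy start.  Returns None when either date is
    missing; negative intervals are excluded and logged.  Records built
    from partial dates are flagged imprecise and can be excluded via
    ``include_imprecise=False``.
    """
    starts = [s for d in report.ps_drugs for s in d.therapy_starts]
    if not starts or report.receipt_date is None:
        return None
    pick = min if start_rule == "earliest" else max
    start, start_imp = pick(starts, key=lambda s: s[0])
    imprecise = start_imp or report.receipt_imprecise
    if not include_imprecise and imprecise:
        return None
    tto = (report.receipt_date - start).days
    if tto < 0:
        logger.info("case %s excluded from TTO: event precedes therapy start", report.caseid)
        return None
    return TTORecord(
        caseid=report.caseid,
        tto_days=float(tto),
        age_group=assign_age_group(report.age),
        sex=report.sex,
        imprecise=imprecise,
    )


def compare_tto(groups: dict[str, np.ndarray | list[float]]) -> pd.DataFrame:
    """Pairwise two-sided Mann-Whitney tests between labelled TTO groups.

    Groups of size < 2 are skipped (logged).  Returns one row per pair:
    (group1, group2, n1, n2, statistic, p_value).
    """
    usable = {}
    for label, values in groups.items():
        arr = np.asarray(list(values), dtype=float)
        if arr.size < 2:
            logger.warning("TTO group %r skipped: fewer than 2 records", label)
            continue
        usable[label] = arr
    rows = []
    for g1, g2 in itertools.combinations(sorted(usable), 2):
        u, p = stats.mannwhitneyu(usable[g1], usable[g2], alternative="two-sided")
        rows.append({"group1": g1, "group2": g2, "n1": len(usable[g1]),
                     "n2": len(usable[g2]), "statistic": float(u), "p_value": float(p)})
    return pd.DataFrame(rows, columns=["group1", "group2", "n1", "n2", "statistic", "p_value"])


def tto_ecdf(groups: dict[str, np.ndarray | list[float]]) -> pd.DataFrame:
    """Empirical CDF points per group, for cumulative-onset plots."""
    rows = []
    for label in sorted(groups):
        arr = np.sort(np.asarray(list(groups[label]), dtype=float))
        n = arr.size
        for i, v in enumerate(arr, 1):
            rows.append({"group": label, "tto_days": v, "cum_fraction": i / n})
    return pd.DataFrame(rows, columns=["group", "tto_days", "cum_fraction"])


def _design_matrix(
    df: pd.DataFrame, covariates: list[str]
) -> tuple[pd.DataFrame, list[str]]:
    """Treatment-coded design with intercept; references per REFERENCE_LEVELS."""
    cols = {}
    for cov in covariates:
        s = df[cov]
        if s.dtype.kind in "bif":
            cols[cov] = s.astype(float)
            continue
        levels = [lv for lv in pd.unique(s.astype(str))]
        ref = REFERENCE_LEVELS.get(cov)
        if ref not in levels:
            ref = sorted(levels)[0]
        for lv in sorted(lv for lv in levels if lv != ref):
            cols[f"{cov}[{lv}]"] = (s.astype(str) == lv).astype(float)
    X = pd.DataFrame(cols, index=df.index)
    X.insert(0, "Intercept", 1.0)
    return X, list(X.columns[1:])


def fit_logistic(
    df: pd.DataFrame,
    outcome: str,
    covariates: list[str],
    max_iter: int = 100,
) -> LogisticFit:
    """Multivariable ML logistic fit of a binary outcome on the covariates.

    Categorical covariates are expanded to treatment-coded indicators
    (references: age <45, female sex, ICI_Chemo arm).  Wald 95% CIs and
    p-values per term.  Non-convergence or perfect separation yields
    ``converged=False`` with terms withheld.
    """
    data = df[[outcome, *covariates]].dropna()
    if len(data) < 10:
        raise ValueError(f"need >=10 complete cases, got {len(data)}")
    y = data[outcome].astype(float)
    if y.nunique() < 2:
        raise ValueError("degenerate outcome: only one class present")
    X, _ = _design_matrix(data, covariates)
    try:
        res = sm.Logit(y, X).fit(disp=0, maxiter=max_iter)
        converged = bool(res.mle_retvals.get("converged", False))
    except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError):
        return LogisticFit(terms=[], converged=False, n_used=len(data))
    if not converged or not np.all(np.isfinite(res.bse)):
        return LogisticFit(terms=[], converged=False, n_used=len(data))
    ci = res.conf_int(alpha=0.05)
    terms = [
        (
            name,
            float(np.exp(res.params[name])),
            float(np.exp(ci.loc[name, 0])),
            float(np.exp(ci.loc[name, 1])),
            float(res.pvalues[name]),
        )
        for name in X.columns
        if name != "Intercept"
    ]
    return LogisticFit(terms=terms, converged=True, n_used=len(data))


def fit_logistic_univariable(
    df: pd.DataFrame, outcome: str, covariates: list[str]
) -> dict[str, LogisticFit]:
    """One single-covariate logistic fit per covariate."""
    return {cov: fit_logistic(df, outcome, [cov]) for cov in covariates}


def logistic_results_table(
    uni: dict[str, LogisticFit], multi: LogisticFit
) -> pd.DataFrame:
    """Long results table with a ``model`` column in {uni, multi}."""
    frames = []
    for fit in uni.values():
        if fit.converged:
            f = fit.to_frame()
            f["model"] = "uni"
            frames.append(f)
    if multi.converged:
        f = multi.to_frame()
        f["model"] = "multi"
        frames.append(f)
    if not frames:
        return pd.DataFrame(
            columns=["term", "odds_ratio", "ci_low", "ci_high", "p_value", "model"]
        )
    return pd.concat(frames, ignore_index=True)
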