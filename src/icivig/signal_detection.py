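"""Disproportionality statistics on 2x2 report tables and the signal rule.

For each adverse-event preferred term (PT) the cohort is cross-tabulated at
the report level against the exposure split (ICI_Chemo vs Only_Chemo):

==========  ==================  =====================
            target PT present    target PT absent
==========  ==================  =====================
exposed              a                   b
comparator           c                   d
==========  ==================  =====================

Three classical signal statistics are computed:

* reporting odds ratio  ROR = (a·d)/(b·c) with a 95% Wald CI on the log
  scale, ``ROR025`` being the lower bound;
* proportional reporting ratio  PRR = [a/(a+b)] / [c/(c+d)] together with
  the Yates continuity-corrected chi-square of the table;
* information component  IC = log2[(a + 0.5)/(E + 0.5)] with
  E = (a+b)(a+c)/N, a shrinkage observed-to-expected measure whose lower
  2.5% credibility bound ``IC025`` uses either Norén's closed-form
  approximation (default) or the exact gamma-quantile form.

An event is declared a signal only when all five criteria hold:
a >= 3, ROR025 >= 1, IC025 > 1, PRR > 2 and chi2_yates >= 4.  A statistic
undefined because of a zero cell fails its criterion; no continuity
correction is applied to ROR/PRR.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import ARM_COMPARATOR, ARM_EXPOSED

Z95 = 1.96  # two-sided 95% normal quantile, fixed by convention


@dataclass(frozen=True)
class ContingencyTable:
    a: int  # target event, exposed
    b: int  # other events, exposed
    c: int  # target event, comparator
    d: int  # other events, comparator

    def __post_init__(self):
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or int(v) != v:
                raise ValueError("cells must be nonnegative integers")
        if self.N == 0:
            raise ValueError("empty table")

    @property
    def N(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class Thresholds:
    """The five-way conjunction defining a signal."""

    min_a: int = 3
    min_ror025: float = 1.0
    min_ic025: float = 1.0  # strict: ic025 > min_ic025
    min_prr: float = 2.0  # strict: prr > min_prr
    min_chi2: float = 4.0


@dataclass
class SignalResult:
    event_pt: str
    table: ContingencyTable
    ror: float
    ror025: float
    ror975: float
    prr: float
    chi2_yates: float
    ic: float
    ic025: float
    is_signal: bool
    criteria: dict[str, bool] = field(default_factory=dict)

    @property
    def failed_criteria(self) -> list[str]:
        return [k for k, v in self.criteria.items() if not v]


def ror_array(a, b, c, d) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised ROR and 95% Wald interval; NaN wherever a cell is zero."""
    a, b, c, d = (np.asarray(x, dtype=float) for x in (a, b, c, d))
    with np.errstate(divide="ignore", invalid="ignore"):
        ror = np.where(np.minimum(np.minimum(a, b), np.minimum(c, d)) > 0,
                       (a * d) / (b * c), np.nan)
        se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return ror, ror * np.exp(-Z95 * se), ror * np.exp(Z95 * se)


def prr_array(a, b, c, d) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised PRR and Yates chi-square; undefined parts NaN.

    The Yates term ``|ad - bc| - N/2`` floors at zero, so near-null tables
    give chi2 = 0 rather than a spurious positive value.
    """
    a, b, c, d = (np.asarray(x, dtype=float) for x in (a, b, c, d))
    N = a + b + c + d
    with np.errstate(divide="ignore", invalid="ignore"):
        prr = np.where((a + b > 0) & (c > 0),
                       (a / (a + b)) / (c / (c + d)), np.nan)
        den = (a + b) * (c + d) * (a + c) * (b + d)
        num = np.maximum(np.abs(a * d - b * c) - N / 2, 0.0) ** 2
        chi2 = np.where(den > 0, N * num / np.where(den > 0, den, 1.0), np.nan)
    return prr, chi2


def ic_array(a, b, c, d, variant: str = "noren") -> tuple[np.ndarray, np.ndarray]:
    """Vectorised information component and lower 2.5% credibility bound.

    ``variant="noren"`` uses the closed-form approximation
    ``IC025 = IC - 3.3(a+0.5)^(-1/2) - 2.4(a+0.5)^(-3/2)``;
    ``variant="gamma"`` takes the exact 2.5% quantile of the
    Gamma(a + 0.5, rate E + 0.5) posterior on the log2 scale.
    The +0.5 shrinkage makes both defined for any table with N > 0.
    """
    a, b, c, d = (np.asarray(x, dtype=float) for x in (a, b, c, d))
    N = a + b + c + d
    E = (a + b) * (a + c) / N
    ic = np.log2((a + 0.5) / (E + 0.5))
    if variant == "noren":
        ic025 = ic - 3.3 * (a + 0.5) ** -0.5 - 2.4 * (a + 0.5) ** -1.5
    elif variant == "gamma":
        q = stats.gamma.ppf(0.025, a + 0.5, scale=1.0 / (E + 0.5))
        ic025 = np.log2(q)
    else:
        raise ValueError(f"unknown IC variant {variant!r}")
    return ic, ic025


def ror_stats(t: ContingencyTable) -> tuple[float, float, float]:
    """ROR and its 95% Wald interval; NaN triple when any cell is zero."""
    ror, lo, hi = ror_array(t.a, t.b, t.c, t.d)
    return float(ror), float(lo), float(hi)


def prr_stats(t: ContingencyTable) -> tuple[float, float]:
    """PRR and Yates chi-square for one table; undefined parts are NaN."""
    prr, chi2 = prr_array(t.a, t.b, t.c, t.d)
    return float(prr), float(chi2)


def ic_stats(t: ContingencyTable, variant: str = "noren") -> tuple[float, float]:
    """Information component and IC025 for one table (see :func:`ic_array`)."""
    ic, ic025 = ic_array(t.a, t.b, t.c, t.d, variant=variant)
    return float(ic), float(ic025)


def judge_signal(
    t: ContingencyTable,
    event_pt: str = "",
    thresholds: Thresholds = Thresholds(),
    ic_variant: str = "noren",
) -> SignalResult:
    """Evaluate the five-way conjunction on one table.

    Any undefined (NaN) statistic fails its criterion — comparisons with
    NaN are explicitly forced false.
    """
    ror, ror025, ror975 = ror_stats(t)
    prr, chi2 = prr_stats(t)
    ic, ic025 = ic_stats(t, variant=ic_variant)
    th = thresholds
    crit = {
        "a": t.a >= th.min_a,
        "ror025": bool(ror025 >= th.min_ror025) if not np.isnan(ror025) else False,
        "ic025": bool(ic025 > th.min_ic025) if not np.isnan(ic025) else False,
        "prr": bool(prr > th.min_prr) if not np.isnan(prr) else False,
        "chi2_yates": bool(chi2 >= th.min_chi2) if not np.isnan(chi2) else False,
    }
    return SignalResult(
        event_pt=event_pt,
        table=t,
        ror=ror,
        ror025=ror025,
        ror975=ror975,
        prr=prr,
        chi2_yates=chi2,
        ic=ic,
        ic025=ic025,
        is_signal=all(crit.values()),
        criteria=crit,
    )


def build_table(
    cohort: pd.DataFrame, case_reactions: dict[str, set[str]], event_pt: str
) -> ContingencyTable:
    """Report-level 2x2 table for one PT.

    Each report counts once per cell regardless of how many times the PT
    appears on it.  ``case_reactions`` maps caseid to the set of PTs.
    """
    exposed = cohort["arm"] == ARM_EXPOSED
    has_pt = cohort["caseid"].map(lambda cid: event_pt in case_reactions.get(cid, ())).astype(bool)
    a = int((exposed & has_pt).sum())
    b = int((exposed & ~has_pt).sum())
    c = int((~exposed & has_pt).sum())
    d = int((~exposed & ~has_pt).sum())
    return ContingencyTable(a, b, c, d)


def screen_events(
    cohort: pd.DataFrame,
    case_reactions: dict[str, set[str]],
    thresholds: Thresholds = Thresholds(),
    ic_variant: str = "noren",
    events: list[str] | None = None,
) -> pd.DataFrame:
    """Judge every PT (or the given subset) against the conjunction rule.

    Returns the signal table with one row per event:
    (event_pt, a, b, c, d, ror, ror025, ror975, prr, chi2_yates, ic,
    ic025, is_signal, failed_criteria).  Counting is vectorised over a
    report x PT incidence matrix; semantics are identical to calling
    :func:`build_table` + :func:`judge_signal` per event.
    """
    cohort = cohort[cohort["caseid"].isin(case_reactions)]
    ids = cohort["caseid"].to_numpy()
    exposed = (cohort["arm"] == ARM_EXPOSED).to_numpy()
    n_exp = int(exposed.sum())
    n_cmp = int((~exposed).sum())
    if events is None:
        events = sorted({pt for cid in ids for pt in case_reactions[cid]})
    rows = []
    for pt in events:
        has = np.fromiter((pt in case_reactions[cid] for cid in ids), bool, len(ids))
        a = int((has & exposed).sum())
        c = int(has.sum()) - a
        t = ContingencyTable(a, n_exp - a, c, n_cmp - c)
        r = judge_signal(t, event_pt=pt, thresholds=thresholds, ic_variant=ic_variant)
        rows.append(
            {
                "event_pt": pt,
                "a": t.a, "b": t.b, "c": t.c, "d": t.d,
                "ror": r.ror, "ror025": r.ror025, "ror975": r.ror975,
                "prr": r.prr, "chi2_yates": r.chi2_yates,
                "ic": r.ic, "ic025": r.ic025,
                "is_signal": r.is_signal,
                "failed_criteria": ";".join(r.failed_criteria),
            }
        )
    return pd.DataFrame(rows)
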