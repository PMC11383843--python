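"""Independent brute-force reference implementations used as test oracles.

Everything here is written from the formula definitions with the standard
library / plain loops only, deliberately sharing no code with the package.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import optimize


def ror_oracle(a, b, c, d):
    if min(a, b, c, d) == 0:
        return math.nan, math.nan, math.nan
    ror = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return ror, ror * math.exp(-1.96 * se), ror * math.exp(1.96 * se)


def prr_oracle(a, b, c, d):
    if a + b == 0 or c == 0:
        return math.nan
    return (a / (a + b)) / (c / (c + d))


def chi2_yates_oracle(a, b, c, d):
    n = a + b + c + d
    den = (a + b) * (c + d) * (a + c) * (b + d)
    if den == 0:
        return math.nan
    term = abs(a * d - b * c) - n / 2
    if term < 0:
        term = 0.0
    return n * term * term / den


def ic_oracle(a, b, c, d):
    n = a + b + c + d
    e = (a + b) * (a + c) / n
    ic = math.log2((a + 0.5) / (e + 0.5))
    ic025 = ic - 3.3 * (a + 0.5) ** -0.5 - 2.4 * (a + 0.5) ** -1.5
    return ic, ic025


def ssgsea_oracle(values: dict[str, float], genes_in_set: set[str], tau: float) -> float:
    """Naive double-loop single-sample enrichment score for one sample.

    ``values`` maps gene -> expression.  Ranks are 1 = lowest expression,
    average on ties; the walk is in descending rank order with residual
    ties broken by the gene's position in the dict.
    """
    names = list(values)
    xs = [values[g] for g in names]
    ranks = []
    for x in xs:
        less = sum(1 for v in xs if v < x)
        eq = sum(1 for v in xs if v == x)
        ranks.append(less + (eq + 1) / 2.0)
    order = sorted(range(len(names)), key=lambda i: (-ranks[i], i))
    n = len(names)
    k = sum(1 for g in names if g in genes_in_set)
    denom_in = sum(abs(ranks[i]) ** tau for i in order if names[i] in genes_in_set)
    p_in = p_out = 0.0
    score = 0.0
    for i in order:
        if names[i] in genes_in_set:
            p_in += abs(ranks[i]) ** tau / denom_in
        else:
            p_out += 1.0 / (n - k)
        score += p_in - p_out
    return score


def enrichment_score_oracle(ranked_genes: list[str], stats_: list[float],
                            member: set[str]) -> float:
    """Step-by-step weight-1 running-sum ES on an already-ranked list."""
    denom = sum(abs(s) for g, s in zip(ranked_genes, stats_) if g in member)
    n_miss = sum(1 for g in ranked_genes if g not in member)
    run = 0.0
    best = 0.0
    for g, s in zip(ranked_genes, stats_):
        if g in member:
            run += abs(s) / denom
        else:
            run -= 1.0 / n_miss
        if abs(run) > abs(best):
            best = run
    return best


def spearman_oracle(x: list[float], y: list[float]) -> float:
    """Hand-rolled Spearman rho with average ranks on ties."""

    def ranks(v):
        out = []
        for a in v:
            less = sum(1 for b in v if b < a)
            eq = sum(1 for b in v if b == a)
            out.append(less + (eq + 1) / 2.0)
        return out

    rx, ry = ranks(x), ranks(y)
    mx, my = sum(rx) / len(rx), sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry))
    return num / den


def logistic_mle_oracle(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """ML logistic coefficients via a generic optimizer (BFGS on the NLL)."""

    def nll(beta):
        eta = X @ beta
        return float(np.sum(np.logaddexp(0.0, eta)) - y @ eta)

    def grad(beta):
        p = 1.0 / (1.0 + np.exp(-(X @ beta)))
        return X.T @ (p - y)

    res = optimize.minimize(nll, np.zeros(X.shape[1]), jac=grad, method="BFGS",
                            options={"gtol": 1e-10, "maxiter": 500})
    return res.x
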