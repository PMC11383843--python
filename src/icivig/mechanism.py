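"""Expression-based mechanism pipeline linking pathway activity to irAE RORs.

Each cancer-type cohort is a genes x samples expression matrix with an
observed irAE reporting odds ratio attached.  The pipeline:

1. scores every sample against immune gene sets with single-sample GSEA
   (rank-weighted ECDF difference, exponent tau = 0.25);
2. takes the median score (and median immune-gene expression) per cancer
   type;
3. screens pathways/genes by Spearman correlation of those medians against
   the observed RORs across cancer types;
4. exhaustively fits bivariate linear models ROR ~ b0 + b1*x1 + b2*x2 over
   all candidate pairs, judging each pair against its two nested
   univariate models with a 1-df likelihood-ratio test and ranking pairs
   by the Spearman correlation of fitted vs observed RORs;
5. runs preranked GSEA (weight-1 running sum, gene-label permutations,
   Benjamini-Hochberg across sets) on genes ranked by their ROR
   correlation.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

DEFAULT_TAU = 0.25
SCREEN_ALPHA = 0.05


@dataclass
class CohortExpression:
    """Genes x samples matrix for one cancer type plus its observed irAE ROR."""

    cancer_type: str
    matrix: pd.DataFrame  # index genes, columns samples
    observed_ror: float

    def __post_init__(self):
        if self.matrix.index.has_duplicates:
            raise ValueError(f"{self.cancer_type}: duplicate gene identifiers")
        if self.matrix.shape[1] < 10:
            logger.warning(
                "%s: only %d samples; median scores may be unstable",
                self.cancer_type, self.matrix.shape[1],
            )


@dataclass
class BivariateModelFit:
    predictors: tuple[str, str]
    beta0: float
    beta1: float
    beta2: float
    log_likelihood: float
    lrt_p_vs_x1: float  # full model vs model with x1 only
    lrt_p_vs_x2: float
    rs_pred_obs: float


# ---------------------------------------------------------------------------
# ssGSEA


def ssgsea_score(
    matrix: pd.DataFrame, genes: set[str], tau: float = DEFAULT_TAU
) -> pd.Series:
    """Single-sample GSEA score of one gene set for every sample.

    Per sample, genes are ranked by expression (descending; average ranks
    on ties, residual ties broken by gene label for determinism).  Walking
    down the ranked list, member genes advance a weighted in-set ECDF
    P_in (weight |rank|^tau) while non-members advance the uniform
    out-of-set ECDF P_out; the score is the sum of P_in - P_out over all
    positions.  The score depends on expression only through ranks, so it
    is invariant under strictly increasing transforms.
    """
    present = sorted(genes & set(matrix.index))
    n_genes = matrix.shape[0]
    if not present:
        raise ValueError("gene set has no overlap with the expression matrix")
    if len(present) == n_genes:
        raise ValueError("gene set covers every gene: out-of-set ECDF undefined")
    member = np.asarray(matrix.index.isin(present))
    scores = {}
    for sample in matrix.columns:
        x = matrix[sample].to_numpy(dtype=float)
        ranks = stats.rankdata(x, method="average")  # 1 = lowest expression
        # descending by rank; ties broken by position for determinism
        order = np.lexsort((np.arange(n_genes), -ranks))
        m = member[order]
        w = np.abs(ranks[order]) ** tau
        w[~m] = 0.0
        p_in = np.cumsum(w) / w.sum()
        p_out = np.cumsum(~m) / (n_genes - len(present))
        scores[sample] = float(np.sum(p_in - p_out))
    return pd.Series(scores, name="score")


def ssgsea_score_table(
    cohorts: list[CohortExpression],
    gene_sets: dict[str, set[str]],
    tau: float = DEFAULT_TAU,
    normalize: bool = False,
) -> dict[str, pd.DataFrame]:
    """Per-sample scores (sets x samples) for every cohort.

    With ``normalize=True`` scores are min-max rescaled across all samples
    of all cohorts, per set.  Sets without overlap are skipped with a log
    message.
    """
    tables = {}
    for co in cohorts:
        matrix = co.matrix
        n_genes = matrix.shape[0]
        # rank/sort once per sample, reuse across gene sets
        vals = matrix.to_numpy(dtype=float)
        ranks = np.apply_along_axis(stats.rankdata, 0, vals)
        orders = np.lexsort(
            (np.tile(np.arange(n_genes), (matrix.shape[1], 1)).T, -ranks), axis=0
        )
        rows = {}
        for name, genes in gene_sets.items():
            present = genes & set(matrix.index)
            if not present:
                logger.warning("%s / %s: no overlap with matrix", co.cancer_type, name)
                continue
            if len(present) == n_genes:
                logger.warning("%s / %s: set covers every gene", co.cancer_type, name)
                continue
            member = np.asarray(matrix.index.isin(sorted(present)))
            scores = np.empty(matrix.shape[1])
            for j in range(matrix.shape[1]):
                o = orders[:, j]
                m = member[o]
                w = np.abs(ranks[o, j]) ** tau
                w[~m] = 0.0
                p_in = np.cumsum(w) / w.sum()
                p_out = np.cumsum(~m) / (n_genes - len(present))
                scores[j] = np.sum(p_in - p_out)
            rows[name] = pd.Series(scores, index=matrix.columns)
        tables[co.cancer_type] = pd.DataFrame(rows).T
    if normalize:
        all_scores = pd.concat(tables.values(), axis=1)
        lo = all_scores.min(axis=1)
        span = all_scores.max(axis=1) - lo
        span[span == 0] = 1.0
        tables = {ct: df.sub(lo, axis=0).div(span, axis=0) for ct, df in tables.items()}
    return tables


def median_pathway_scores(
    cohorts: list[CohortExpression],
    gene_sets: dict[str, set[str]],
    tau: float = DEFAULT_TAU,
    normalize: bool = False,
) -> pd.DataFrame:
    """Median ssGSEA score per (cancer type, pathway): types x pathways."""
    tables = ssgsea_score_table(cohorts, gene_sets, tau=tau, normalize=normalize)
    return pd.DataFrame({ct: df.median(axis=1) for ct, df in tables.items()}).T


def median_gene_expression(
    cohorts: list[CohortExpression], genes: list[str] | None = None
) -> pd.DataFrame:
    """Median expression per (cancer type, gene): types x genes."""
    rows = {}
    for co in cohorts:
        m = co.matrix if genes is None else co.matrix.loc[co.matrix.index.isin(genes)]
        rows[co.cancer_type] = m.median(axis=1)
    return pd.DataFrame(rows).T


def observed_rors(cohorts: list[CohortExpression]) -> pd.Series:
    return pd.Series({co.cancer_type: co.observed_ror for co in cohorts})


# ---------------------------------------------------------------------------
# correlation screening


def screen_pathways(
    table: pd.DataFrame, rors: pd.Series, alpha: float = SCREEN_ALPHA,
    bh_adjust: bool = False,
) -> pd.DataFrame:
    """Spearman screen of per-type medians (types x variables) against RORs.

    Returns (variable, rs, p, sign, significant) sorted by p.  Variables
    constant across types have undefined rank correlation and are skipped
    with a log message.  Requires >=5 cancer types.  ``bh_adjust`` applies
    Benjamini-Hochberg before thresholding (off by default).
    """
    common = table.index.intersection(rors.index)
    if len(common) < 5:
        raise ValueError(f"need >=5 cancer types, got {len(common)}")
    y = rors.loc[common].to_numpy(dtype=float)
    rows = []
    for var in table.columns:
        x = table.loc[common, var].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            logger.warning("variable %r constant across types; skipped", var)
            continue
        rs, p = stats.spearmanr(x, y)
        rows.append({"variable": var, "rs": float(rs), "p": float(p),
                     "sign": "+" if rs >= 0 else "-"})
    df = pd.DataFrame(rows, columns=["variable", "rs", "p", "sign"])
    if df.empty:
        df["significant"] = pd.Series(dtype=bool)
        return df
    pvals = df["p"].to_numpy()
    if bh_adjust:
        pvals = multipletests(pvals, method="fdr_bh")[1]
        df["p_adj"] = pvals
    df["significant"] = pvals < alpha
    return df.sort_values("p", ignore_index=True)


# ---------------------------------------------------------------------------
# bivariate model search


def _gaussian_loglik(resid: np.ndarray) -> float:
    n = resid.size
    s2 = float(resid @ resid) / n  # MLE variance
    return -0.5 * n * (np.log(2 * np.pi * s2) + 1.0)


def _ols_loglik(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return beta, _gaussian_loglik(y - X @ beta)


def bivariate_search(
    candidates: pd.DataFrame, rors: pd.Series, collinear_r: float = 0.999
) -> list[BivariateModelFit]:
    """Fit every unordered pair of candidate variables against the RORs.

    ``candidates`` is types x variables (e.g. median pathway scores of the
    screening survivors).  Each pair is fit by least squares on the
    natural ROR scale; the pair's LRT p-values test the full model against
    each nested single-predictor model (chi2, 1 df).  Pairs are ranked by
    Spearman(fitted, observed), ties by the smaller of the two LRT
    p-values.  Nearly collinear pairs (|pearson r| > ``collinear_r``) are
    skipped.  Refuses n_types <= 3 (a two-slope model would be saturated).
    """
    common = candidates.index.intersection(rors.index)
    n = len(common)
    if n <= 3:
        raise ValueError(f"need more than 3 cancer types, got {n}")
    if candidates.shape[1] < 2:
        raise ValueError("need at least 2 candidate variables")
    y = rors.loc[common].to_numpy(dtype=float)
    X = candidates.loc[common]
    fits = []
    for x1, x2 in itertools.combinations(X.columns, 2):
        v1 = X[x1].to_numpy(dtype=float)
        v2 = X[x2].to_numpy(dtype=float)
        r = np.corrcoef(v1, v2)[0, 1]
        if abs(r) > collinear_r:
            logger.warning("pair (%s, %s) skipped: collinear (r=%.4f)", x1, x2, r)
            continue
        ones = np.ones(n)
        beta_full, ll_full = _ols_loglik(np.column_stack([ones, v1, v2]), y)
        _, ll_x1 = _ols_loglik(np.column_stack([ones, v1]), y)
        _, ll_x2 = _ols_loglik(np.column_stack([ones, v2]), y)
        lrt1 = max(2.0 * (ll_full - ll_x1), 0.0)
        lrt2 = max(2.0 * (ll_full - ll_x2), 0.0)
        fitted = np.column_stack([ones, v1, v2]) @ beta_full
        rs = stats.spearmanr(fitted, y)[0]
        fits.append(
            BivariateModelFit(
                predictors=(x1, x2),
                beta0=float(beta_full[0]),
                beta1=float(beta_full[1]),
                beta2=float(beta_full[2]),
                log_likelihood=float(ll_full),
                lrt_p_vs_x1=float(stats.chi2.sf(lrt1, df=1)),
                lrt_p_vs_x2=float(stats.chi2.sf(lrt2, df=1)),
                rs_pred_obs=float(rs),
            )
        )
    fits.sort(key=lambda f: (-f.rs_pred_obs, min(f.lrt_p_vs_x1, f.lrt_p_vs_x2)))
    return fits


def bivariate_results_table(fits: list[BivariateModelFit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "x1": f.predictors[0], "x2": f.predictors[1],
                "beta0": f.beta0, "beta1": f.beta1, "beta2": f.beta2,
                "log_likelihood": f.log_likelihood,
                "lrt_p_vs_x1": f.lrt_p_vs_x1, "lrt_p_vs_x2": f.lrt_p_vs_x2,
                "rs_pred_obs": f.rs_pred_obs,
            }
            for f in fits
        ]
    )


# ---------------------------------------------------------------------------
# preranked GSEA


def enrichment_score(ranked: pd.Series, genes: set[str]) -> float:
    """Weight-1 running-sum enrichment score on a ranked gene list.

    ``ranked`` maps gene -> ranking statistic, sorted descending.  Member
    hits advance the running sum by |statistic| (normalised); misses
    retreat it uniformly.  The ES is the extremum of the running sum
    (largest absolute deviation from zero, sign preserved).
    """
    member = np.asarray(ranked.index.isin(genes))
    if member.sum() == 0 or member.all():
        raise ValueError("gene set empty or exhaustive on the ranking")
    w = np.abs(ranked.to_numpy(dtype=float))
    w[~member] = 0.0
    if w.sum() == 0:  # all member stats zero: fall back to unweighted hits
        w[member] = 1.0
    p_hit = np.cumsum(w) / w.sum()
    p_miss = np.cumsum(~member) / (~member).sum()
    running = p_hit - p_miss
    return float(running[np.argmax(np.abs(running))])


def gene_screen_and_gsea(
    gene_medians: pd.DataFrame,
    rors: pd.Series,
    annotation_sets: dict[str, set[str]],
    alpha: float = SCREEN_ALPHA,
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Correlation-screen genes then run preranked GSEA on annotation sets.

    Genes are ranked by their Spearman correlation with the observed RORs
    (descending).  For each annotation set with >=3 ranked members the
    weight-1 enrichment score is computed; significance comes from
    ``n_perm`` gene-label permutations (two-sided on |ES|, add-one
    estimator) with Benjamini-Hochberg correction across sets.
    """
    if rng is None:
        rng = np.random.default_rng()
    gene_screen = screen_pathways(gene_medians, rors, alpha=alpha)
    gene_screen = gene_screen.rename(columns={"variable": "gene"})
    ranked = (
        gene_screen.set_index("gene")["rs"].sort_values(ascending=False, kind="stable")
    )
    rows = []
    for name, genes in annotation_sets.items():
        k = int(ranked.index.isin(genes).sum())
        if k < 3:
            logger.warning("annotation set %r skipped: %d ranked members", name, k)
            continue
        es = enrichment_score(ranked, genes)
        labels = ranked.index.to_numpy()
        count = 0
        for _ in range(n_perm):
            perm = set(rng.choice(labels, size=k, replace=False))
            if abs(enrichment_score(ranked, perm)) >= abs(es):
                count += 1
        p = (1 + count) / (n_perm + 1)
        rows.append({"set": name, "es": es, "n_members": k, "p": p})
    enr = pd.DataFrame(rows, columns=["set", "es", "n_members", "p"])
    if not enr.empty:
        enr["p_adj"] = multipletests(enr["p"].to_numpy(), method="fdr_bh")[1]
        enr = enr.sort_values("p", ignore_index=True)
    else:
        enr["p_adj"] = pd.Series(dtype=float)
    return gene_screen, enr


# ---------------------------------------------------------------------------
# file formats


def read_expression_tsv(path, cancer_type: str, observed_ror: float) -> CohortExpression:
    """Read a genes x samples TSV (first column gene identifiers)."""
    m = pd.read_csv(path, sep="\t", index_col=0)
    return CohortExpression(cancer_type=cancer_type, matrix=m, observed_ror=observed_ror)


def write_expression_tsv(cohort: CohortExpression, path) -> None:
    cohort.matrix.to_csv(path, sep="\t", index_label="gene")


def read_gmt(path) -> dict[str, set[str]]:
    """Read gene sets in GMT format (name, description, genes...)."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def write_gmt(gene_sets: dict[str, set[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name in sorted(gene_sets):
            genes = "\t".join(sorted(gene_sets[name]))
            fh.write(f"{name}\t{description}\t{genes}\n")


def lollipop_data(screen: pd.DataFrame) -> pd.DataFrame:
    """Plot-ready table for the pathway-correlation lollipop figure."""
    df = screen[screen["significant"]].copy()
    df["color"] = np.where(df["rs"] >= 0, "positive", "negative")
    return df.sort_values("rs", ignore_index=True)
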