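# Methods

This note documents the statistical models, the synthetic-data design, the
numerical choices and the known limitations of `icivig`. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Study design being implemented

The package implements a two-arm disproportionality design within a single
indication cohort: spontaneous adverse-event reports whose primary-suspect
(PS) drugs were given for malignant nervous-system neoplasms are split into
an exposed arm (immune checkpoint inhibitor plus chemotherapy, `ICI_Chemo`)
and a comparator arm (chemotherapy only, `Only_Chemo`). Restricting the
comparator to the same indication — rather than using the all-database
background — controls for indication-specific reporting patterns at the
cost of a smaller comparator. Downstream, per-cancer-type irAE reporting
odds ratios are related to immune pathway activity estimated from
expression cohorts.

## Ingestion and deduplication

Quarterly extracts arrive as six "$"-delimited tables (DEMO, DRUG, REAC,
OUTC, THER, INDI) linked by `primaryid`, plus a deleted-case list.
Spontaneous-report databases contain multiple versions of the same case;
the retained record per `caseid` is the one with the highest
`caseversion`, ties broken by latest receipt date, then lexically largest
`primaryid`. This is the conventional rule for FAERS-style data; it is
deterministic, idempotent and invariant to the ordering of quarters.
Cases named in any deleted-case list are removed entirely.

Partial dates (YYYY or YYYYMM) are completed to the earliest consistent
day and flagged imprecise; time-to-onset consumers can exclude flagged
records. Ages are normalized to years from the FAERS age/age-unit pair
(decade, month, week, day and hour codes are converted; unknown unit codes
are assumed to be years); values above 120 years are set missing. Drug
names are matched case-insensitively after trimming, collapsing internal
whitespace and stripping trailing periods; unmatched names pass through
verbatim and are tallied in a coverage report rather than dropped.

## Cohort and regimens

Arm assignment uses PS drugs only. The regimen follows the set S of ICI
classes among PS drugs: a single class maps to `PD1_Chemo`, `PDL1_Chemo`
or `CTLA4_Chemo`; S = {PD1, CTLA4} maps to `PD1_CTLA4_Chemo`; any other
multi-class combination maps to `Combined-ICI_Chemo` (kept distinct
because the PD-1 + CTLA-4 doublet is the clinically established
combination); no ICI with at least one chemotherapy PS drug maps to
`Only_Chemo`. Reports with neither an ICI nor a chemotherapy PS drug
belong to no arm and are excluded with a log entry — forcing them into
either arm would bias both.

Age bands are <45, 45–64 (closed interval) and >64, with missing ages in
their own `unknown` band so they stay in the logistic models without
imputation.

## Signal statistics

For each preferred term, counting is report-level: a report contributes
once per cell however often the term appears on it. The statistics are

- ROR = (a·d)/(b·c) with the Wald interval on the log scale (z = 1.96);
- PRR = [a/(a+b)]/[c/(c+d)] and the Yates χ², whose continuity term
  |ad − bc| − N/2 floors at zero so near-null tables score 0 rather than a
  spurious positive;
- IC = log₂[(a+0.5)/(E+0.5)] with E = (a+b)(a+c)/N. The default IC025 is
  the closed-form credibility-bound approximation
  IC − 3.3(a+0.5)^(−1/2) − 2.4(a+0.5)^(−3/2); a gamma-quantile variant
  (the exact 2.5% quantile of the Gamma(a+0.5, rate E+0.5) posterior on
  the log₂ scale) is available via `ic_variant: gamma`. The two agree
  closely for a ≳ 20.

Zero cells leave ROR/PRR undefined (no continuity correction is applied);
an undefined statistic simply fails its criterion. This is deliberate: the
conjunction already requires a ≥ 3, so patched estimates would only
manufacture borderline signals. The five thresholds (a ≥ 3, ROR025 ≥ 1,
IC025 > 1, PRR > 2, χ² ≥ 4) are overridable in the run configuration.

Two structural facts about the conjunction are worth knowing. First, the
shrinkage IC is not monotone in a at fixed b, c, d (the expected count E
grows with a too), so IC025 can fail on tables whose ROR passes
comfortably. Second, for tables with all cells ≤ 50, a-only, PRR-only and
χ²-only single-criterion failures cannot occur: a ≤ 2 or PRR ≤ 2 always
drags IC025 below 1 as well. The IC025 bound is therefore the binding
criterion for small counts.

## Time to onset and prognosis

FAERS-style reaction rows carry no onset date, so time to onset is defined
as receipt date minus the earliest PS-drug therapy start (configurable to
latest start); negative intervals are excluded as data errors. Group
comparisons use the two-sided Mann–Whitney rank test — the distributions
are right-skewed and the test is the standard distribution-free choice —
with empirical CDFs exported for plotting.

Prognosis is death, defined as outcome code `DE` present. Logistic models
(maximum likelihood via statsmodels' IRLS) are fitted univariably (one
covariate at a time) and multivariably; categorical covariates are
treatment-coded with references age <45, female sex and the `ICI_Chemo`
arm, so reported odds ratios read as risk relative to the youngest
ICI-treated female stratum. Wald 95% intervals and p-values are reported
per term; non-convergence or perfect separation yields a flagged,
term-free result instead of unstable estimates.

## Mechanism pipeline

**ssGSEA.** Per sample, genes are ranked by expression (average ranks on
ties; residual ties broken by gene position for determinism). Walking the
ranked list top-down, member genes advance a weighted in-set ECDF (weight
|rank|^τ, τ = 0.25) and non-members advance the uniform out-of-set ECDF;
the score is the sum of the ECDF differences over all positions, with no
further normalization (an optional min–max rescaling across samples is off
by default). Because the score depends on expression only through ranks,
it is invariant under strictly increasing transforms — the marginal
distribution of the generator is therefore immaterial. A set covering
every gene leaves the out-of-set ECDF undefined and is rejected; a set
with no overlap is skipped with a log entry.

**Screening.** Median score (and median immune-gene expression) per cancer
type is correlated with the observed RORs by Spearman's rank correlation,
two-sided, unadjusted, significance at p < 0.05 (Benjamini–Hochberg is
available but off by default, matching the screening convention of
reporting raw p-values at this stage). At least 5 cancer types are
required; constant variables are skipped.

**Bivariate model search.** Every unordered pair of screened variables is
fitted by least squares on the natural ROR scale (a log-ROR response is
available via `response_scale: log_ror`; the natural scale is the default
because the observed RORs are the quantity being predicted). The pair is
judged against each nested univariate model by a likelihood-ratio test
(Gaussian log-likelihood with the MLE variance, χ² with 1 df), and pairs
are ranked by the Spearman correlation of fitted vs observed RORs, ties by
the smaller LRT p-value. Designs with ≤ 3 types are refused (two slopes
would saturate), and nearly collinear pairs (|r| > 0.999) are skipped.
The candidate pool in the pipeline is all significantly correlating
variables — pathway scores and gene medians alike — so its size is
data-dependent, not fixed.

**Preranked GSEA.** Genes ranked by their ROR correlation are tested per
annotation set with the weight-1 running-sum enrichment score;
significance comes from gene-label permutations (add-one estimator,
two-sided on |ES|, 1,000 permutations by default) with Benjamini–Hochberg
across sets. Sets with fewer than 3 ranked members are skipped. A caveat
inherent to label permutation: genes that co-vary as a block (as the
generator's set members do by construction) cluster in the ranking
wherever the block lands, so sets of correlated genes reach small
permutation p-values more easily than independent-gene sets would.

## Synthetic-data generator

The generator is the package's specification of its study conditions, not
a tuning knob.

**Reports** (defaults: 5,000 cases, 10% ICI_Chemo arm with regimen mix
50/20/10/12/8% across PD1/PDL1/CTLA4/PD1+CTLA4/other combinations). Every
estimable quantity is planted and recorded in a JSON manifest:

- *Events.* Each planted event has a comparator-arm probability p0 and a
  true ROR; the exposed-arm probability follows odds(p1) = ROR·odds(p0),
  so the expected 2×2 table reproduces the planted ROR exactly. Defaults
  plant four events at RORs 10/8/6/5 on baselines of 0.5–0.6%. Background
  terms are drawn identically in both arms (true ROR 1) from a Zipf-skewed
  frequency table, a Poisson(λ = 2) count per report, so the b/d cells are
  realistically occupied; a report that draws nothing gets one background
  term (reactions are never empty). Note that odds(p1) < 1 for any finite
  ROR — the parameterization is always feasible; validation instead
  rejects p0 outside (0,1) and non-positive RORs.
- *Demographics.* Age ~ Normal(58, 15) clipped to [18, 95] with 8%
  missing; sex 55/43/2% male/female/unknown.
- *Outcome.* Death follows a logistic model with baseline logit −2.2
  (reference: age <45, ICI_Chemo) and odds ratios 2.5 for age >64 and 1.8
  for chemotherapy-only — the planted truth that the prognosis models
  estimate.
- *Onset.* Time to onset is log-normal per age band (medians 75/120/45
  days for <45 / 45–64 / >64, σ = 0.7 on the log scale), so the middle
  band genuinely differs from both others; the receipt date is therapy
  start (uniform over 2013–2022) plus the onset interval. 5% of therapy
  starts are written as partial YYYYMM dates to exercise the
  imprecise-date path.
- *Cleaning hazards.* 5% of cases receive a duplicate version-2 record
  and 2% are listed in the deleted file.

Identical config and seed produce byte-identical files.

**Expression** (defaults: 20 cancer types, 25 samples each, 400 genes,
gene sets of 30). Per planted set with target correlation ρ, a per-type
latent activity s_t = ρ·z_t + √(1−ρ²)·ε_t is drawn, with z_t the
standardized log of the type's planted ROR (defaults log-spaced over
0.8–25, the scale of per-cancer-type irAE RORs); member genes are shifted
by `effect`·s_t over Gaussian noise. Defaults plant one positive (ρ = 0.8)
and one negative (ρ = −0.6) pathway plus eight ρ = 0 decoys.

Two behaviours of this design matter for interpretation. Rank-based scores
*saturate*: if the planted shift dwarfs the within-type noise, all members
rank top, scores tie across strongly-shifted types, and rank correlations
cannot reach 1 — so an exact noiseless limit is demonstrated by driving
*sampling* noise down (many samples at effect ≈ σ, no competing sets), not
by σ → 0. And shifted sets *compete in the ranking*: a decoy set's own
latent displaces other sets' members, perturbing their scores. Both are
properties real expression data share.

**What the generator does not emulate:** reporting-volume seasonality,
real MedDRA hierarchies (a packaged lookup CSV stands in for the licensed
dictionary), microarray platform or batch effects, gene–gene correlation
beyond the block structure of the planted sets, and informative
missingness. Passing tests therefore demonstrate correctness of the
statistical machinery under a clean generative model, not robustness to
the full messiness of real spontaneous-report or expression data.

## Problem sizes and numerical choices

The statistic oracle check runs over every 2×2 table with cells in
[0, 50] (≈6.8 million tables, vectorised against a loop-based oracle at
1e-9 relative tolerance). Recovery checks use 100 seeds × 5,000 reports
(signals), 200 cohorts × 2,000 reports (logistic), and 100 seeds of the
20-type expression design (pathways); the acceptance script reports the
same quantities at 30–60 seeds to keep a full rerun near one minute.
Logistic fits cap at 100 IRLS iterations; the LRT statistic is floored at
0 against floating-point noise; Spearman p-values use scipy's
t-approximation, which is well calibrated at the 20-type design (verified
by the null-uniformity test). Seeds are mandatory everywhere randomness
exists; derived child seeds stay below 2³¹.

## Known limitations

- Disproportionality measures reporting associations, not incidence or
  causation; the package inherits every caveat of spontaneous-report data.
- The IC025 criterion binds hardest at small counts (see above), so the
  conjunction is conservative for rare events — by design, at the cost of
  sensitivity for true RORs below ~5 at the default cohort scale.
- Time to onset uses the receipt date as the event date; real onset dates,
  when present in a source, would be strictly better.
- Label-permutation GSEA overstates enrichment of internally correlated
  gene sets; sample-permutation GSEA would be preferable when per-sample
  data (not just medians) drive the ranking.
- The bivariate search is an exhaustive screen over pairs, not a model
  selection procedure with error control across the pair family.
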