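"""ssGSEA scoring, correlation screening, bivariate model search, GSEA."""

import numpy as np
import pandas as pd
import pytest

from icivig.mechanism import (
    CohortExpression,
    bivariate_search,
    enrichment_score,
    gene_screen_and_gsea,
    read_gmt,
    screen_pathways,
    ssgsea_score,
    write_gmt,
)

import oracles


def _matrix(rng, n_genes=20, n_samples=10):
    return pd.DataFrame(
        rng.standard_normal((n_genes, n_samples)),
        index=[f"G{i:02d}" for i in range(n_genes)],
        columns=[f"S{j}" for j in range(n_samples)],
    )


class TestSsgsea:
    def test_top_set_positive_bottom_set_negative(self):
        m = pd.DataFrame({"S1": np.arange(10, 0, -1.0)},
                         index=[f"G{i}" for i in range(10)])
        top = ssgsea_score(m, {"G0", "G1"})
        bottom = ssgsea_score(m, {"G8", "G9"})
        assert top["S1"] > 0 > bottom["S1"]

    def test_all_gene_set_rejected(self):
        m = _matrix(np.random.default_rng(0))
        with pytest.raises(ValueError, match="every gene"):
            ssgsea_score(m, set(m.index))

    def test_no_overlap_rejected(self):
        m = _matrix(np.random.default_rng(0))
        with pytest.raises(ValueError, match="no overlap"):
            ssgsea_score(m, {"ABSENT1", "ABSENT2"})

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(5):
            m = _matrix(rng)
            genes = set(rng.choice(m.index, size=3, replace=False))
            got = ssgsea_score(m, genes, tau=0.25)
            for s in m.columns:
                ref = oracles.ssgsea_oracle(dict(zip(m.index, m[s])), genes, 0.25)
                assert got[s] == pytest.approx(ref, rel=1e-9)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(4)
        m = _matrix(rng)
        genes = {"G01", "G05", "G17"}
        base = ssgsea_score(m, genes)
        for f in (np.exp, lambda x: x**3 + 2 * x, lambda x: 5 * x - 1):
            np.testing.assert_allclose(ssgsea_score(f(m), genes), base, atol=1e-12)

    def test_tied_expression_is_deterministic(self):
        m = pd.DataFrame({"S1": [1.0, 1.0, 1.0, 0.0, 2.0]},
                         index=list("ABCDE"))
        s1 = ssgsea_score(m, {"B"})
        s2 = ssgsea_score(m.copy(), {"B"})
        assert s1["S1"] == s2["S1"]


def _score_frame(rors, noise=None):
    idx = [f"CT{t}" for t in range(len(rors))]
    data = {"perfect": list(rors)}
    if noise is not None:
        data["noise"] = list(noise)
    return pd.DataFrame(data, index=idx), pd.Series(rors, index=idx)


class TestScreenPathways:
    def test_perfect_monotone(self):
        table, rors = _score_frame([1, 2, 3, 4, 5, 6, 7, 8])
        out = screen_pathways(table, rors).set_index("variable")
        assert out.loc["perfect", "rs"] == pytest.approx(1.0)
        assert out.loc["perfect", "sign"] == "+"

    def test_perfect_antitone(self):
        table, rors = _score_frame([1, 2, 3, 4, 5, 6, 7, 8])
        table["anti"] = -table["perfect"]
        out = screen_pathways(table, rors).set_index("variable")
        assert out.loc["anti", "rs"] == pytest.approx(-1.0)

    def test_tied_values_match_hand_ranking(self):
        scores = [3.0, 1.0, 4.0, 4.0, 2.0, 6.0, 5.0, 0.5]
        rors = [2.0, 1.0, 5.0, 4.0, 3.0, 9.0, 7.0, 0.8]
        table, r = _score_frame(rors)
        table["tied"] = scores
        out = screen_pathways(table, r).set_index("variable")
        assert out.loc["tied", "rs"] == pytest.approx(
            oracles.spearman_oracle(scores, rors), rel=1e-12
        )

    def test_constant_variable_skipped(self):
        table, rors = _score_frame([1, 2, 3, 4, 5, 6, 7, 8])
        table["flat"] = 1.0
        out = screen_pathways(table, rors)
        assert "flat" not in set(out["variable"])

    def test_too_few_types_rejected(self):
        table, rors = _score_frame([1, 2, 3, 4])
        with pytest.raises(ValueError, match=">=5"):
            screen_pathways(table, rors)


class TestBivariateSearch:
    def _planted(self, rng, n=20, sigma=0.1, extra=2):
        x1 = rng.standard_normal(n)
        x2 = rng.standard_normal(n)
        y = 1 + 2 * x1 - x2 + rng.normal(0, sigma, n)
        idx = [f"CT{t}" for t in range(n)]
        data = {"x1": x1, "x2": x2}
        for j in range(extra):
            data[f"z{j}"] = rng.standard_normal(n)
        return pd.DataFrame(data, index=idx), pd.Series(y, index=idx)

    def test_combinatorial_fit_count(self):
        cand, y = self._planted(np.random.default_rng(0), extra=3)
        k = cand.shape[1]
        assert len(bivariate_search(cand, y)) == k * (k - 1) // 2

    def test_parameter_recovery_and_ranking(self):
        cand, y = self._planted(np.random.default_rng(21))
        fits = bivariate_search(cand, y)
        best = fits[0]
        assert set(best.predictors) == {"x1", "x2"}
        assert 1.8 <= best.beta1 <= 2.2
        assert best.lrt_p_vs_x1 < 0.05 and best.lrt_p_vs_x2 < 0.05

    def test_best_pair_beats_univariate_spearman(self):
        from scipy.stats import spearmanr

        cand, y = self._planted(np.random.default_rng(22))
        best = bivariate_search(cand, y)[0]
        for v in best.predictors:
            rs_uni = abs(spearmanr(cand[v], y)[0])
            assert best.rs_pred_obs >= rs_uni - 1e-12

    def test_null_predictor_has_large_lrt_p(self):
        rng = np.random.default_rng(3)
        n = 20
        x1 = rng.standard_normal(n)
        y = 1 + 2 * x1 + rng.normal(0, 0.1, n)
        noise = rng.standard_normal(n)
        idx = [f"CT{t}" for t in range(n)]
        cand = pd.DataFrame({"x1": x1, "noise": noise}, index=idx)
        fit = bivariate_search(cand, pd.Series(y, index=idx))[0]
        # adding noise to x1 rarely helps: LRT vs the x1-only model is weak
        assert fit.lrt_p_vs_x1 > 0.05

    def test_lrt_statistic_nonnegative(self):
        cand, y = self._planted(np.random.default_rng(5), extra=3)
        for f in bivariate_search(cand, y):
            assert 0.0 <= f.lrt_p_vs_x1 <= 1.0 and 0.0 <= f.lrt_p_vs_x2 <= 1.0
            assert -1.0 <= f.rs_pred_obs <= 1.0

    def test_saturated_design_refused(self):
        idx = ["A", "B", "C"]
        cand = pd.DataFrame({"x1": [1, 2, 3], "x2": [2, 1, 3]}, index=idx)
        with pytest.raises(ValueError, match="more than 3"):
            bivariate_search(cand, pd.Series([1.0, 2.0, 3.0], index=idx))

    def test_collinear_pair_skipped(self):
        rng = np.random.default_rng(6)
        n = 10
        x = rng.standard_normal(n)
        idx = [f"CT{t}" for t in range(n)]
        cand = pd.DataFrame({"x1": x, "x2": 2 * x + 1e-9 * rng.standard_normal(n)},
                            index=idx)
        assert bivariate_search(cand, pd.Series(x, index=idx)) == []


class TestGsea:
    def test_es_matches_running_sum_oracle(self):
        rng = np.random.default_rng(8)
        stats_ = np.sort(rng.standard_normal(12))[::-1]
        genes = [f"G{i}" for i in range(12)]
        ranked = pd.Series(stats_, index=genes)
        member = {"G1", "G5", "G9"}
        assert enrichment_score(ranked, member) == pytest.approx(
            oracles.enrichment_score_oracle(genes, list(stats_), member), rel=1e-9
        )

    def test_constructed_top_set_enriched(self):
        rng = np.random.default_rng(15)
        types = [f"CT{t}" for t in range(12)]
        rors = pd.Series(np.linspace(1, 10, 12), index=types)
        genes = [f"G{i:02d}" for i in range(30)]
        # first five genes track the RORs, rest are noise
        data = {
            g: (rors.to_numpy() * 2 + rng.normal(0, 0.3, 12)
                if i < 5 else rng.standard_normal(12))
            for i, g in enumerate(genes)
        }
        medians = pd.DataFrame(data, index=types)
        sets = {"TRACKING": set(genes[:5]), "RANDOM": set(genes[20:28])}
        screen, enr = gene_screen_and_gsea(
            medians, rors, sets, n_perm=500, rng=np.random.default_rng(0)
        )
        enr = enr.set_index("set")
        assert enr.loc["TRACKING", "es"] > 0
        assert enr.loc["TRACKING", "p"] < 0.05
        assert enr.loc["RANDOM", "p"] > enr.loc["TRACKING", "p"]

    def test_small_annotation_set_skipped(self):
        rng = np.random.default_rng(2)
        types = [f"CT{t}" for t in range(10)]
        rors = pd.Series(rng.standard_normal(10), index=types)
        medians = pd.DataFrame(
            rng.standard_normal((10, 8)), index=types,
            columns=[f"G{i}" for i in range(8)],
        )
        _, enr = gene_screen_and_gsea(
            medians, rors, {"TINY": {"G0", "G1"}}, n_perm=50,
            rng=np.random.default_rng(0),
        )
        assert enr.empty

    def test_gmt_roundtrip(self, tmp_path):
        sets = {"A": {"G1", "G2"}, "B": {"G3", "G4", "G5"}}
        p = tmp_path / "sets.gmt"
        write_gmt(sets, p)
        assert read_gmt(p) == sets


def test_cohort_expression_rejects_duplicate_genes():
    m = pd.DataFrame(np.zeros((2, 12)), index=["G1", "G1"])
    with pytest.raises(ValueError, match="duplicate"):
        CohortExpression("CT", m, 1.0)
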