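"""Disproportionality statistics against brute-force oracles, plus the
five-way conjunction rule and its invariances."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")

from icivig.signal_detection import (
    ContingencyTable,
    Thresholds,
    build_table,
    ic_array,
    ic_stats,
    judge_signal,
    prr_array,
    prr_stats,
    ror_array,
    ror_stats,
    screen_events,
)

import oracles

T_REF = ContingencyTable(10, 90, 100, 9900)

cells = st.integers(min_value=0, max_value=50)
tables = st.tuples(cells, cells, cells, cells).filter(lambda t: sum(t) > 0)


class TestRor:
    def test_reference_values(self):
        ror, lo, hi = ror_stats(T_REF)
        assert ror == pytest.approx(11.0)
        assert lo == pytest.approx(5.559514928894626, rel=1e-12)

    def test_symmetric_table_is_null(self):
        assert ror_stats(ContingencyTable(5, 5, 5, 5))[0] == pytest.approx(1.0)

    def test_zero_cell_undefined(self):
        assert all(math.isnan(v) for v in ror_stats(ContingencyTable(0, 5, 5, 5)))

    @given(tables)
    @settings(max_examples=300)
    def test_matches_oracle(self, t):
        a, b, c, d = t
        got = ror_stats(ContingencyTable(a, b, c, d))
        exp = oracles.ror_oracle(a, b, c, d)
        for g, e in zip(got, exp):
            assert (math.isnan(g) and math.isnan(e)) or g == pytest.approx(e, rel=1e-9)


class TestPrrChi2:
    def test_reference_values(self):
        prr, chi2 = prr_stats(T_REF)
        assert prr == pytest.approx(10.0)
        assert chi2 == pytest.approx(66.32694080444081, rel=1e-12)

    def test_null_table(self):
        prr, chi2 = prr_stats(ContingencyTable(5, 5, 5, 5))
        assert prr == pytest.approx(1.0)
        assert chi2 == 0.0  # Yates term floors at zero

    def test_zero_margin_undefined(self):
        prr, _ = prr_stats(ContingencyTable(0, 0, 5, 5))
        assert math.isnan(prr)

    @given(tables)
    @settings(max_examples=300)
    def test_matches_oracle(self, t):
        a, b, c, d = t
        prr, chi2 = prr_stats(ContingencyTable(a, b, c, d))
        e_prr = oracles.prr_oracle(a, b, c, d)
        e_chi = oracles.chi2_yates_oracle(a, b, c, d)
        assert (math.isnan(prr) and math.isnan(e_prr)) or prr == pytest.approx(e_prr, rel=1e-9)
        assert (math.isnan(chi2) and math.isnan(e_chi)) or chi2 == pytest.approx(e_chi, rel=1e-9)

    def test_chi2_agrees_with_scipy_contingency(self):
        from scipy.stats import chi2_contingency

        for t in [(10, 90, 100, 9900), (12, 40, 7, 300), (30, 470, 27, 4470)]:
            a, b, c, d = t
            ref = chi2_contingency([[a, b], [c, d]], correction=True)[0]
            assert prr_stats(ContingencyTable(a, b, c, d))[1] == pytest.approx(ref, rel=1e-9)


class TestIC:
    def test_reference_values(self):
        ic, ic025 = ic_stats(T_REF)
        assert ic == pytest.approx(2.724099418408252, rel=1e-12)
        assert ic025 == pytest.approx(1.6351586343900604, rel=1e-12)

    def test_empty_event_column(self):
        ic, _ = ic_stats(ContingencyTable(0, 0, 0, 100))
        assert ic == 0.0  # log2(0.5/0.5): shrinkage handles the zero

    @given(tables)
    @settings(max_examples=300)
    def test_matches_oracle(self, t):
        a, b, c, d = t
        ic, ic025 = ic_stats(ContingencyTable(a, b, c, d))
        e_ic, e_ic025 = oracles.ic_oracle(a, b, c, d)
        assert ic == pytest.approx(e_ic, rel=1e-9)
        assert ic025 == pytest.approx(e_ic025, rel=1e-9)

    def test_gamma_variant_close_to_approximation_for_large_a(self):
        t = ContingencyTable(200, 1800, 150, 17850)
        _, approx = ic_stats(t, variant="noren")
        _, exact = ic_stats(t, variant="gamma")
        assert approx == pytest.approx(exact, abs=0.05)

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            ic_stats(T_REF, variant="bogus")


class TestInvariances:
    @given(st.tuples(st.integers(1, 50), st.integers(1, 50),
                     st.integers(1, 50), st.integers(1, 50)))
    @settings(max_examples=200)
    def test_transposition_symmetry(self, t):
        a, b, c, d = t
        ror1 = ror_stats(ContingencyTable(a, b, c, d))[0]
        ror2 = ror_stats(ContingencyTable(c, d, a, b))[0]
        assert ror1 == pytest.approx(1.0 / ror2, rel=1e-9)
        chi1 = prr_stats(ContingencyTable(a, b, c, d))[1]
        chi2_ = prr_stats(ContingencyTable(b, a, d, c))[1]
        assert chi1 == pytest.approx(chi2_, rel=1e-9)

    @given(st.tuples(st.integers(1, 30), st.integers(1, 30),
                     st.integers(1, 30), st.integers(1, 30)),
           st.integers(2, 6))
    @settings(max_examples=200)
    def test_scaling_fixes_ratios_grows_chi2(self, t, k):
        a, b, c, d = t
        base, scaled = ContingencyTable(a, b, c, d), ContingencyTable(k * a, k * b, k * c, k * d)
        assert ror_stats(scaled)[0] == pytest.approx(ror_stats(base)[0], rel=1e-9)
        assert prr_stats(scaled)[0] == pytest.approx(prr_stats(base)[0], rel=1e-9)
        assert prr_stats(scaled)[1] >= prr_stats(base)[1] - 1e-12

    @given(st.tuples(st.integers(1, 30), st.integers(1, 30),
                     st.integers(1, 30), st.integers(1, 30)))
    @settings(max_examples=200)
    def test_monotone_in_a(self, t):
        # strict monotonicity holds for the ratio statistics; the shrinkage
        # IC is exempt because its expected count E also grows with a
        a, b, c, d = t
        t0, t1 = ContingencyTable(a, b, c, d), ContingencyTable(a + 1, b, c, d)
        assert ror_stats(t1)[0] > ror_stats(t0)[0]
        assert prr_stats(t1)[0] > prr_stats(t0)[0]

    def test_ic_monotone_in_a_when_event_is_rare(self):
        # with the margins held near-constant (large d), more co-occurrence
        # raises the IC
        for a in range(1, 20):
            lo = ic_stats(ContingencyTable(a, 100, 100, 10000))[0]
            hi = ic_stats(ContingencyTable(a + 1, 100, 100, 10000))[0]
            assert hi > lo


class TestJudgeSignal:
    def test_small_a_fails_despite_huge_ror(self):
        r = judge_signal(ContingencyTable(2, 1, 1, 10000))
        assert not r.is_signal
        assert not r.criteria["a"]

    def test_reference_table_is_signal(self):
        r = judge_signal(T_REF)
        assert r.is_signal and all(r.criteria.values())

    def test_null_table_not_signal(self):
        assert not judge_signal(ContingencyTable(5, 5, 5, 5)).is_signal

    def test_undefined_stat_fails_its_criterion(self):
        r = judge_signal(ContingencyTable(5, 0, 0, 100))
        assert not r.criteria["ror025"] and not r.criteria["prr"]

    def test_custom_thresholds(self):
        r = judge_signal(T_REF, thresholds=Thresholds(min_a=11))
        assert not r.is_signal and r.failed_criteria == ["a"]


class TestBuildTable:
    COHORT_ROWS = [
        {"caseid": "1", "arm": "ICI_Chemo"},
        {"caseid": "2", "arm": "ICI_Chemo"},
        {"caseid": "3", "arm": "ICI_Chemo"},
        {"caseid": "4", "arm": "Only_Chemo"},
        {"caseid": "5", "arm": "Only_Chemo"},
    ]

    def _cohort(self):
        import pandas as pd

        return pd.DataFrame(self.COHORT_ROWS)

    def test_direct_counts(self):
        rx = {"1": {"Seizure"}, "2": {"Seizure"}, "3": {"Nausea"},
              "4": {"Seizure"}, "5": {"Nausea"}}
        t = build_table(self._cohort(), rx, "Seizure")
        assert (t.a, t.b, t.c, t.d) == (2, 1, 1, 1)

    def test_report_level_counting_ignores_multiplicity(self):
        # a PT listed twice on a report is a set member once
        rx = {"1": {"Seizure"}, "2": set(), "3": set(), "4": set(), "5": set()}
        t = build_table(self._cohort(), rx, "Seizure")
        assert t.a == 1

    def test_absent_event_gives_empty_target_cells(self):
        rx = {c["caseid"]: {"Nausea"} for c in self.COHORT_ROWS}
        t = build_table(self._cohort(), rx, "Seizure")
        assert t.a == 0 and t.c == 0

    def test_screen_matches_per_event_tables(self):
        import pandas as pd

        rx = {"1": {"Seizure", "Nausea"}, "2": {"Seizure"}, "3": {"Nausea"},
              "4": {"Fatigue"}, "5": {"Seizure"}}
        coh = pd.DataFrame(self.COHORT_ROWS)
        df = screen_events(coh, rx).set_index("event_pt")
        for pt in ["Seizure", "Nausea", "Fatigue"]:
            t = build_table(coh, rx, pt)
            row = df.loc[pt]
            assert (row.a, row.b, row.c, row.d) == (t.a, t.b, t.c, t.d)
            r = judge_signal(t, event_pt=pt)
            assert row.is_signal == r.is_signal


def test_array_forms_match_scalar_forms():
    rng = np.random.default_rng(0)
    cells4 = rng.integers(0, 50, size=(200, 4))
    cells4 = cells4[cells4.sum(axis=1) > 0]
    a, b, c, d = cells4.T
    ror, lo, hi = ror_array(a, b, c, d)
    prr, chi2 = prr_array(a, b, c, d)
    ic, ic025 = ic_array(a, b, c, d)
    for i, (ai, bi, ci, di) in enumerate(cells4):
        t = ContingencyTable(int(ai), int(bi), int(ci), int(di))
        np.testing.assert_allclose([ror[i], lo[i], hi[i]], ror_stats(t), rtol=1e-12)
        np.testing.assert_allclose([prr[i], chi2[i]], prr_stats(t), rtol=1e-12)
        np.testing.assert_allclose([ic[i], ic025[i]], ic_stats(t), rtol=1e-12)
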