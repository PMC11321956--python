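import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from faersig.signal_engine import (
    ContingencyTable,
    SignalConfig,
    SignalThresholds,
    bcpnn_ic,
    build_tables,
    chi_square,
    ebgm,
    evaluate_signals,
    mgps_ebgm,
    prr,
    ror,
)
from faersig import preprocess as pp
from faersig import synthetic as syn

from conftest import make_config

TABLE = ContingencyTable(a=10, b=90, c=100, d=9900)
INDEPENDENT = ContingencyTable(a=5, b=50, c=10, d=100)

cells = st.integers(1, 500)


def balanced_table(k, j, m, n):
    """Row-proportional table: a/(a+b) == c/(c+d) by construction."""
    return ContingencyTable(a=k * m, b=k * n, c=j * m, d=j * n)


class TestRor:
    def test_point_estimate(self):
        assert ror(TABLE)[0] == pytest.approx(11.0)

    def test_independence_is_one(self):
        assert ror(INDEPENDENT)[0] == pytest.approx(1.0)

    def test_woolf_interval_frozen(self):
        # exp(ln 11 +/- 1.96*sqrt(1/10+1/90+1/100+1/9900)), evaluated directly
        _, lo, hi = ror(TABLE)
        assert lo == pytest.approx(5.559514928894626, rel=1e-12)
        assert hi == pytest.approx(21.764488727446928, rel=1e-12)

    def test_zero_cell_degenerate(self):
        point, lo, hi = ror(ContingencyTable(a=0, b=5, c=5, d=5))
        assert math.isnan(point) and math.isnan(lo) and math.isnan(hi)

    def test_haldane_gives_finite_values(self):
        point, lo, hi = ror(ContingencyTable(a=0, b=5, c=5, d=5), zero_cell="haldane")
        assert point == pytest.approx((0.5 * 5.5) / (5.5 * 5.5))
        assert lo < point < hi

    @given(a=cells, b=cells, c=cells, d=cells)
    def test_row_swap_antisymmetry(self, a, b, c, d):
        forward = ror(ContingencyTable(a=a, b=b, c=c, d=d))[0]
        swapped = ror(ContingencyTable(a=c, b=d, c=a, d=b))[0]
        assert swapped == pytest.approx(1.0 / forward, rel=1e-12)

    @given(a=st.integers(1, 50), b=st.integers(51, 300), c=st.integers(51, 300),
           d=cells)
    def test_strictly_increasing_in_a(self, a, b, c, d):
        lower = ror(ContingencyTable(a=a, b=b, c=c, d=d))[0]
        upper = ror(ContingencyTable(a=a + 1, b=b, c=c, d=d))[0]
        assert upper > lower


class TestPrr:
    def test_point_estimate(self):
        assert prr(TABLE)[0] == pytest.approx(10.0)

    def test_independence_is_one(self):
        assert prr(INDEPENDENT)[0] == pytest.approx(1.0)

    def test_chi2_frozen(self):
        # scipy.stats.chi2_contingency(correction=False) on the same table
        assert prr(TABLE)[1] == pytest.approx(74.44717444717445, rel=1e-12)

    def test_chi2_zero_on_independence_margins(self):
        assert chi_square(balanced_table(2, 3, 5, 7)) == pytest.approx(0.0, abs=1e-12)

    def test_yates_reduces_chi2(self):
        assert chi_square(TABLE, yates=True) < chi_square(TABLE)

    def test_zero_c_degenerate(self):
        value, _ = prr(ContingencyTable(a=3, b=5, c=0, d=10))
        assert math.isnan(value)

    @settings(max_examples=100, deadline=None)
    @given(a=cells, b=cells, c=cells, d=cells)
    def test_chi2_matches_scipy(self, a, b, c, d):
        expected = stats.chi2_contingency([[a, b], [c, d]], correction=False)[0]
        assert chi_square(ContingencyTable(a=a, b=b, c=c, d=d)) == \
            pytest.approx(expected, rel=1e-10)

    @settings(max_examples=50, deadline=None)
    @given(a=cells, b=cells, c=cells, d=cells)
    def test_yates_matches_scipy(self, a, b, c, d):
        expected = stats.chi2_contingency([[a, b], [c, d]], correction=True)[0]
        assert chi_square(ContingencyTable(a=a, b=b, c=c, d=d), yates=True) == \
            pytest.approx(expected, rel=1e-10)

    @given(a=st.integers(1, 50), b=st.integers(51, 300), c=st.integers(51, 300),
           d=cells)
    def test_strictly_increasing_in_a(self, a, b, c, d):
        lower = prr(ContingencyTable(a=a, b=b, c=c, d=d))[0]
        upper = prr(ContingencyTable(a=a + 1, b=b, c=c, d=d))[0]
        assert upper > lower


class TestBcpnn:
    def test_ic_frozen(self):
        ic, ic025 = bcpnn_ic(TABLE)
        assert ic == pytest.approx(math.log2(9.181818181818182), rel=1e-12)
        assert ic025 == pytest.approx(1.4274187000059375, rel=1e-9)

    def test_independence_ic_zero(self):
        ic, _ = bcpnn_ic(ContingencyTable(a=100, b=900, c=900, d=8100))
        assert ic == pytest.approx(0.0, abs=1e-12)

    def test_all_mass_in_a(self):
        ic, _ = bcpnn_ic(ContingencyTable(a=50, b=0, c=0, d=0))
        assert ic == pytest.approx(0.0, abs=1e-12)

    def test_a_zero_has_finite_ic025(self):
        ic, ic025 = bcpnn_ic(ContingencyTable(a=0, b=10, c=10, d=100))
        assert ic == -math.inf
        assert math.isfinite(ic025)

    @given(a=cells, b=cells, c=cells, d=cells)
    def test_ic_equals_log2_ebgm(self, a, b, c, d):
        t = ContingencyTable(a=a, b=b, c=c, d=d)
        assert bcpnn_ic(t)[0] == pytest.approx(math.log2(ebgm(t)[0]), rel=1e-12)

    @given(a=cells, b=cells, c=cells, d=cells)
    def test_ic025_below_posterior_mean(self, a, b, c, d):
        ic, ic025 = bcpnn_ic(ContingencyTable(a=a, b=b, c=c, d=d))
        assert math.isfinite(ic025)


class TestEbgm:
    def test_point_frozen(self):
        value, eb05 = ebgm(TABLE)
        assert value == pytest.approx(9.181818181818182, rel=1e-12)
        assert eb05 == pytest.approx(5.187492981065049, rel=1e-12)

    def test_independence_is_one(self):
        assert ebgm(ContingencyTable(a=100, b=900, c=900, d=8100))[0] == \
            pytest.approx(1.0)

    @given(a=cells, b=cells, c=cells, d=cells)
    def test_eb05_below_ebgm(self, a, b, c, d):
        value, eb05 = ebgm(ContingencyTable(a=a, b=b, c=c, d=d))
        assert eb05 < value

    def test_zero_cell_keeps_point_drops_bound(self):
        value, eb05 = ebgm(ContingencyTable(a=3, b=0, c=5, d=10))
        assert math.isfinite(value)
        assert math.isnan(eb05)

    # IC/EBGM monotonicity in a holds when a stays below both off-diagonal
    # margins; as a dominates the margins, observed/expected must fall.
    @given(a=st.integers(1, 50), b=st.integers(52, 300), c=st.integers(52, 300),
           d=cells)
    def test_increasing_in_a_below_margins(self, a, b, c, d):
        lower = ebgm(ContingencyTable(a=a, b=b, c=c, d=d))[0]
        upper = ebgm(ContingencyTable(a=a + 1, b=b, c=c, d=d))[0]
        assert upper > lower


class TestIndependenceIdentity:
    @given(k=st.integers(1, 20), j=st.integers(1, 20), m=st.integers(1, 20),
           n=st.integers(1, 20))
    def test_all_statistics_at_null(self, k, j, m, n):
        t = balanced_table(k, j, m, n)
        assert ror(t)[0] == pytest.approx(1.0, rel=1e-12)
        assert prr(t)[0] == pytest.approx(1.0, rel=1e-12)
        assert chi_square(t) == pytest.approx(0.0, abs=1e-9)
        assert bcpnn_ic(t)[0] == pytest.approx(0.0, abs=1e-12)
        assert ebgm(t)[0] == pytest.approx(1.0, rel=1e-12)


class TestContingencyTableType:
    def test_n_is_cell_sum(self):
        assert TABLE.N == 10100

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(a=-1, b=1, c=1, d=1)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(a=0, b=0, c=0, d=0)

    def test_non_integer_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(a=1.5, b=1, c=1, d=1)


class TestBuildTables:
    def test_two_report_exhaustive_case(self, synonyms):
        reports = [pp.CaseReport(primaryid="1", caseid="1", fda_date="20200101"),
                   pp.CaseReport(primaryid="2", caseid="2", fda_date="20200101")]
        drugs = [pp.DrugMention("1", 1, "PS", "EMEND", "aprepitant"),
                 pp.DrugMention("2", 1, "PS", "OND", "ondansetron")]
        reacs = [pp.ReactionMention("1", "Event X"),
                 pp.ReactionMention("2", "Event Y")]
        tables = build_tables(reports, drugs, reacs, "aprepitant")
        assert tables["Event X"] == ContingencyTable(a=1, b=0, c=0, d=1)

    def test_absent_target_returns_empty(self, synonyms):
        reports = [pp.CaseReport(primaryid="1", caseid="1", fda_date="20200101")]
        reacs = [pp.ReactionMention("1", "Event X")]
        assert build_tables(reports, [], reacs, "aprepitant") == {}

    def test_non_ps_roles_do_not_attribute(self):
        reports = [pp.CaseReport(primaryid="1", caseid="1", fda_date="20200101")]
        drugs = [pp.DrugMention("1", 1, "C", "EMEND", "aprepitant")]
        reacs = [pp.ReactionMention("1", "Event X")]
        assert build_tables(reports, drugs, reacs, "aprepitant") == {}

    def test_pair_conservation_on_synthetic(self):
        cfg = make_config(seed=11, n_reports=1500, rho=5.0)
        _, gt = syn.generate(cfg)
        reports = [pp.CaseReport(primaryid=r.primaryid, caseid=r.caseid,
                                 fda_date="20200101") for r in gt.reports]
        drugs = [pp.DrugMention(r.primaryid, 1, "PS", r.drug, r.drug)
                 for r in gt.reports]
        reacs = [pp.ReactionMention(r.primaryid, pt)
                 for r in gt.reports for pt in r.pts]
        tables = build_tables(reports, drugs, reacs, "drugx")
        target_pairs = sum(len(r.pts) for r in gt.reports if r.drug == "drugx")
        total_pairs = sum(len(r.pts) for r in gt.reports)
        for t in tables.values():
            assert t.a + t.b == target_pairs
            assert t.N == total_pairs
        assert sum(t.a for t in tables.values()) == target_pairs

    def test_soc_level_counts_once_per_report(self, hierarchy):
        reports = [pp.CaseReport(primaryid="1", caseid="1", fda_date="20200101"),
                   pp.CaseReport(primaryid="2", caseid="2", fda_date="20200101")]
        drugs = [pp.DrugMention("1", 1, "PS", "EMEND", "aprepitant"),
                 pp.DrugMention("2", 1, "PS", "OND", "ondansetron")]
        # two GI PTs on report 1 must collapse to one SOC pair
        reacs = [pp.ReactionMention("1", "Nausea"),
                 pp.ReactionMention("1", "Vomiting"),
                 pp.ReactionMention("2", "Hiccups")]
        tables = build_tables(reports, drugs, reacs, "aprepitant",
                              level="SOC", hierarchy=hierarchy)
        assert tables["Gastrointestinal disorders"].a == 1


class TestEvaluateSignals:
    def test_low_count_terms_excluded(self):
        tables = {"rare": ContingencyTable(a=2, b=100, c=50, d=5000),
                  "common": ContingencyTable(a=30, b=72, c=50, d=5000)}
        results = evaluate_signals(tables)
        assert [r.term for r in results] == ["common"]

    def test_all_four_flags_positive(self):
        results = evaluate_signals({"hot": ContingencyTable(a=50, b=50, c=50, d=9850)})
        assert results[0].n_positive == 4
        assert results[0].flag_ror and results[0].flag_prr
        assert results[0].flag_bcpnn and results[0].flag_ebgm

    def test_null_table_no_flags(self):
        results = evaluate_signals({"null": ContingencyTable(a=50, b=450, c=500, d=4500)})
        assert results[0].n_positive == 0

    def test_sorted_by_descending_ror(self):
        tables = {
            "mid": ContingencyTable(a=20, b=100, c=100, d=5000),
            "top": ContingencyTable(a=50, b=50, c=50, d=5000),
            "low": ContingencyTable(a=5, b=500, c=500, d=5000),
        }
        results = evaluate_signals(tables)
        rors = [r.ror for r in results]
        assert rors == sorted(rors, reverse=True)
        assert results[0].term == "top"

    def test_degenerate_ror_sorts_last(self):
        tables = {
            "fine": ContingencyTable(a=5, b=50, c=10, d=100),
            "degenerate": ContingencyTable(a=5, b=0, c=10, d=100),
        }
        results = evaluate_signals(tables)
        assert results[-1].term == "degenerate"

    def test_min_a_threshold_validation(self):
        with pytest.raises(ValueError):
            SignalThresholds(min_a=0)

    def test_planted_signal_all_flags(self):
        cfg = make_config(seed=3, n_reports=8000, rho=10.0)
        _, gt = syn.generate(cfg)
        tables = {"Event 00": gt.truth_table("drugx", "Event 00")}
        result = evaluate_signals(tables)[0]
        assert result.n_positive == 4


class TestMgpsBackend:
    def test_shrinks_small_counts_toward_one(self):
        # mostly-null tables (expected count ~ observed) plus one outlier
        rng = np.random.default_rng(4)
        tables = []
        for _ in range(60):
            a = max(int(rng.poisson(5)), 1)
            tables.append(ContingencyTable(a=a, b=500, c=100, d=10000))
        outlier = ContingencyTable(a=40, b=500, c=100, d=10000)
        tables.append(outlier)
        pairs = mgps_ebgm(tables)
        raw = [t.a * t.N / ((t.a + t.b) * (t.a + t.c)) for t in tables]
        for (ebgm_val, eb05_val), raw_val in zip(pairs, raw):
            assert 0 < eb05_val < ebgm_val
        # empirical-Bayes estimate shrinks the outlier toward the bulk
        assert pairs[-1][0] < raw[-1]

    def test_backend_switch_in_evaluate(self):
        tables = {f"t{i}": ContingencyTable(a=5 + i, b=200, c=50, d=20000)
                  for i in range(10)}
        cfg = SignalConfig(ebgm_backend="mgps")
        results = evaluate_signals(tables, cfg)
        assert all(math.isfinite(r.eb05) for r in results)


@pytest.mark.parametrize("rho", [2.0, 5.0, 10.0])
def test_parameter_recovery(rho):
    """ROR point within +/-30% of planted rho, CI covering rho, in >=90% of 200 reps."""
    n_reps = 200
    within = cover = 0
    for rep in range(n_reps):
        cfg = make_config(
            seed=50_000 + rep, n_reports=9000, rho=rho, n_events=50,
            pts_per_report={1: 1.0}, missing_age=0.0, missing_sex=0.0)
        _, gt = syn.generate(cfg)
        t = gt.truth_table("drugx", "Event 00")
        assert t.a >= 30
        point, lo, hi = ror(t)
        within += abs(math.log(point / rho)) <= math.log(1.3)
        cover += lo <= rho <= hi
    assert within / n_reps >= 0.90
    assert cover / n_reps >= 0.90
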