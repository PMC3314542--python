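import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from birthlink.exceptions import UndefinedMetricError, ValidationError
from birthlink.report import (
    build_tables,
    chi_square_two_props,
    proportion_ci,
    run_pipeline,
    union_total,
)
from birthlink.stats import round_half_up
from birthlink.synthetic import SimConfig


class TestProportionCI:
    @pytest.mark.parametrize(
        "count,denom,expected",
        [
            (7_236, 397_968, (1.82, 1.78, 1.86)),
            (10_236, 398_196, (2.57, 2.52, 2.62)),
            (4_113, 36_236, (11.35, 11.02, 11.68)),
        ],
    )
    def test_reproduces_published_wald_intervals(self, count, denom, expected):
        assert proportion_ci(count, denom).rounded() == expected

    def test_zero_count_collapses_to_zero(self):
        est = proportion_ci(0, 50)
        assert est.rounded() == (0.0, 0.0, 0.0)

    def test_interval_clipped_to_unit_range(self):
        est = proportion_ci(1, 2)
        assert 0.0 <= est.ci_low <= est.ci_high <= 100.0
        near_one = proportion_ci(49, 50)
        assert near_one.ci_high <= 100.0

    def test_wilson_interval_is_narrower_near_boundary(self):
        wald = proportion_ci(1, 1000)
        wilson = proportion_ci(1, 1000, method="wilson")
        assert wilson.ci_low > 0.0 >= wald.ci_low

    def test_zero_denominator(self):
        with pytest.raises(UndefinedMetricError):
            proportion_ci(0, 0)


class TestChiSquare:
    def test_equal_proportions_give_zero_statistic(self):
        res = chi_square_two_props(10, 100, 10, 100)
        assert res.statistic == 0.0 and res.p_value == 1.0 and not res.significant

    def test_hand_evaluated_statistic(self):
        res = chi_square_two_props(10, 100, 20, 100)
        assert res.statistic == pytest.approx(3.9216, abs=5e-4)
        assert res.df == 1

    def test_boundary_table_is_maximal_for_its_margins(self):
        full = chi_square_two_props(30, 30, 0, 30)
        for a in range(31):
            res = chi_square_two_props(a, 30, 30 - a, 30)
            assert res.statistic <= full.statistic + 1e-9

    def test_empty_margin_is_undefined(self):
        with pytest.raises(UndefinedMetricError):
            chi_square_two_props(0, 10, 0, 10)

    @given(
        st.integers(0, 500), st.integers(1, 500),
        st.integers(0, 500), st.integers(1, 500),
    )
    def test_agrees_with_scipy_contingency(self, a, n_a, b, n_b):
        if a > n_a or b > n_b:
            return
        table = np.array([[a, n_a - a], [b, n_b - b]])
        if (table.sum(axis=0) == 0).any():
            return
        res = chi_square_two_props(a, n_a, b, n_b)
        ref = sps.chi2_contingency(table, correction=False)
        assert res.statistic == pytest.approx(ref.statistic, rel=1e-10, abs=1e-10)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9, abs=1e-12)

    @pytest.mark.parametrize(
        "a,n_a,b,n_b",
        [(10, 30, 20, 30), (15, 40, 22, 40), (20, 40, 28, 40),
         (18, 35, 10, 35), (12, 25, 6, 25)],
    )
    def test_asymptotic_p_close_to_exact_enumeration(self, a, n_a, b, n_b):
        """Small-margin sanity: the chi-square p-value is within 0.02 of the
        exact product-binomial enumeration at the pooled MLE, for tables
        whose expected cell counts are at least 5 (the approximation's usual
        validity condition)."""
        obs = chi_square_two_props(a, n_a, b, n_b)
        phat = (a + b) / (n_a + n_b)
        expected = min(phat, 1 - phat) * min(n_a, n_b)
        assert expected >= 5
        px = sps.binom.pmf(np.arange(n_a + 1), n_a, phat)
        py = sps.binom.pmf(np.arange(n_b + 1), n_b, phat)
        exact = 0.0
        for x in range(n_a + 1):
            for y in range(n_b + 1):
                if x + y in (0, n_a + n_b):
                    stat = 0.0
                else:
                    stat = chi_square_two_props(x, n_a, y, n_b).statistic
                if stat >= obs.statistic - 1e-12:
                    exact += px[x] * py[y]
        assert abs(obs.p_value - exact) < 0.02


class TestUnionTotal:
    def test_published_record_union(self):
        assert union_total(434_467, 404_734, 398_207) == 440_994

    @pytest.mark.parametrize("args,expected", [((7, 0, 0), 7), ((5, 5, 5), 5)])
    def test_boundaries(self, args, expected):
        assert union_total(*args) == expected

    def test_invalid_overlap(self):
        with pytest.raises(ValidationError):
            union_total(3, 4, 5)


class TestTables:
    def test_perfect_data_makes_all_sources_agree(self):
        cfg = SimConfig(
            years=(2001,), births_per_year=1200,
            sens_mdc=1.0, sens_rbdm=1.0, spec_mdc=1.0, spec_rbdm=1.0,
            miss_mdc=0.0, miss_rbdm=0.0,
            reg_prob_indig=1.0, reg_prob_nonindig=1.0,
            late_reg_extra_loss_final_year=0.0, rbdm_only_rate=0.0,
            dup_rate_linked=0.0, dup_rate_mdc=0.0, dup_rate_rbdm=0.0,
            id_corruption=0.0, seed=23,
        )
        result = run_pipeline(cfg, fp_rate=0.0, fn_rate=0.0)
        t3 = result.tables.table3
        totals = t3[t3["year"] == "total"].set_index("source")["indigenous"]
        assert totals["MDC"] == totals["RBDM"] == totals["ASV"] == totals["estimate"]
        t2 = result.tables.table2
        assert (t2["consistency"] == 100.0).all()

    def test_default_run_reproduces_qualitative_ordering(self):
        cfg = SimConfig(years=(2001, 2002, 2003), births_per_year=6000, seed=42)
        result = run_pipeline(cfg)
        t3 = result.tables.table3
        tot = t3[t3["year"] == "total"].set_index("source")["pct"]
        assert tot["MDC"] < tot["RBDM"] < tot["ASV"] <= tot["estimate"]

    def test_nonregistered_stratum_is_indigenous_enriched(self):
        cfg = SimConfig(years=(2001, 2002, 2003), births_per_year=6000, seed=42)
        result = run_pipeline(cfg)
        t5 = result.tables.table5
        tot = t5[t5["year"] == "total"].set_index("group")["pct"]
        assert tot["non_registered"] > tot["registered_linked"]

    def test_table_cells_recomputable_from_counts(self):
        cfg = SimConfig(years=(2001, 2002), births_per_year=2000, seed=7)
        result = run_pipeline(cfg)
        t3 = result.tables.table3
        sources = t3[t3["source"] != "estimate"]
        for _, row in sources.iterrows():
            if row["n_stated"] == 0:
                continue
            est = proportion_ci(row["indigenous"], row["n_stated"])
            assert round_half_up(est.pct) == row["pct"]
            assert round_half_up(est.ci_high) == row["ci_high"]

    def test_pipeline_is_deterministic(self, tmp_path):
        cfg = SimConfig(years=(2001,), births_per_year=1000, seed=5)
        run_pipeline(cfg, outdir=tmp_path / "a")
        run_pipeline(cfg, outdir=tmp_path / "b")
        for name in ("table2", "table3", "table4", "table5", "run_log.json"):
            fa = (tmp_path / "a" / f"{name}.csv") if "table" in name else tmp_path / "a" / name
            fb = (tmp_path / "b" / f"{name}.csv") if "table" in name else tmp_path / "b" / name
            assert fa.read_bytes() == fb.read_bytes()

    def test_exclusion_report_reconciles(self, linked_analysis):
        _, records, _, aset = linked_analysis
        report = aset.exclusion_report()
        retained = aset.n_entities  # entities, not records
        n_records = (
            len(aset.linked) * 2 + len(aset.both_missing) * 2
            + len(aset.mdc_only) + len(aset.rbdm_only)
        )
        assert n_records + report["duplicates_total"] == len(records)
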