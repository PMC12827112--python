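import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import faerskit as fk
from faerskit import faers_io, signals
from faerskit.signals import (
    ContingencyTable,
    SignalCriteria,
    build_contingency,
    evaluate_signal,
    onset_bins,
    percentage_block,
    prr_estimate,
    ror_estimate,
    run_disproportionality,
    summarize_demographics,
)
from conftest import make_dataset


class TestContingency:
    def test_toy_counts_by_hand(self, toy_dataset):
        t = build_contingency(toy_dataset, "X", level="PT")
        assert (t.a, t.b, t.c, t.d) == (2, 1, 1, 2)

    def test_absent_term_gives_empty_event_cells(self, toy_dataset):
        t = build_contingency(toy_dataset, "NOPE", level="PT")
        assert (t.a, t.c) == (0, 0) and (t.b, t.d) == (3, 3)

    def test_female_stratum_filters_cases(self, toy_dataset):
        t = build_contingency(toy_dataset, "X", level="PT", stratum="F")
        assert t.n == 2 and (t.a, t.b, t.c, t.d) == (1, 0, 1, 0)

    def test_soc_level_pools_terms(self, toy_dataset, toy_soc_map):
        t = build_contingency(toy_dataset, "SOC_1", level="SOC", soc_map=toy_soc_map)
        # X and Y both map to SOC_1; every case except U3 has one of them
        assert (t.a, t.b, t.c, t.d) == (3, 0, 2, 1)

    def test_case_counted_once_per_term(self):
        ds = make_dataset({"E1": (True, "F", {"X"}), "U1": (False, "F", set())})
        ds.reactions.loc[len(ds.reactions)] = {"caseid": "E1", "pt": "X"}
        t = build_contingency(ds, "X", level="PT")
        assert t.a == 1


class TestRatioEstimates:
    def test_ror_worked_example(self):
        est = ror_estimate(ContingencyTable(10, 90, 100, 9900))
        assert round(est.point, 2) == 11.00
        assert (round(est.ci_low, 2), round(est.ci_high, 2)) == (5.56, 21.76)

    def test_prr_worked_example(self):
        est = prr_estimate(ContingencyTable(10, 90, 100, 9900))
        assert round(est.point, 2) == 10.00
        assert (round(est.ci_low, 2), round(est.ci_high, 2)) == (5.38, 18.58)

    def test_symmetric_table_is_null(self):
        assert ror_estimate(ContingencyTable(5, 5, 5, 5)).point == pytest.approx(1.0)
        assert prr_estimate(ContingencyTable(5, 5, 5, 5)).point == pytest.approx(1.0)

    def test_equal_proportions_prr_is_one(self):
        assert prr_estimate(ContingencyTable(2, 8, 20, 80)).point == pytest.approx(1.0)

    def test_zero_cells_inestimable_without_correction(self):
        assert not ror_estimate(ContingencyTable(3, 0, 7, 100)).estimable
        assert not prr_estimate(ContingencyTable(3, 7, 0, 100)).estimable

    @given(
        a=st.integers(1, 30), b=st.integers(1, 30),
        c=st.integers(1, 30), d=st.integers(1, 30),
    )
    @settings(max_examples=60, deadline=None)
    def test_point_inside_ci(self, a, b, c, d):
        for est in (ror_estimate(ContingencyTable(a, b, c, d)),
                    prr_estimate(ContingencyTable(a, b, c, d))):
            assert est.ci_low <= est.point <= est.ci_high

    def test_increasing_a_strictly_increases_both(self):
        points = [
            (ror_estimate(ContingencyTable(a, 50, 20, 500)).point,
             prr_estimate(ContingencyTable(a, 50, 20, 500)).point)
            for a in range(1, 12)
        ]
        rors, prrs = zip(*points)
        assert all(x < y for x, y in zip(rors, rors[1:]))
        assert all(x < y for x, y in zip(prrs, prrs[1:]))


class TestSignalCriterion:
    def _flag(self, a, b=100, c=20, d=2000):
        t = ContingencyTable(a, b, c, d)
        return evaluate_signal(t, ror_estimate(t), prr_estimate(t))

    def test_count_gate_blocks_small_a(self):
        assert not self._flag(a=2, b=2, c=1, d=5000)  # huge ROR but a < 3

    def test_strong_association_flagged(self):
        assert self._flag(a=30)

    def test_ci_lower_limit_must_exceed_one(self):
        t = ContingencyTable(3, 100, 60, 2000)  # ROR ~ 1, CI spans 1
        assert not evaluate_signal(t, ror_estimate(t), prr_estimate(t))

    def test_inestimable_never_flagged(self):
        t = ContingencyTable(5, 0, 1, 100)
        assert not evaluate_signal(t, ror_estimate(t), prr_estimate(t))


class TestRunDisproportionality:
    def test_toy_term_ror(self, toy_dataset):
        rows = run_disproportionality(toy_dataset, level="PT")
        by_term = {r.term: r for r in rows}
        assert by_term["X"].ror.point == pytest.approx(4.0)  # (2*2)/(1*1)

    def test_only_terms_seen_in_exposed(self, toy_dataset):
        rows = run_disproportionality(toy_dataset, level="PT")
        assert {r.term for r in rows} == {"X", "Y"}  # Z has a=0

    def test_sorted_by_ror_descending_ties_by_term(self, toy_dataset):
        rows = run_disproportionality(toy_dataset, level="PT")
        pts = [r.ror.point if r.ror.estimable else -math.inf for r in rows]
        assert pts == sorted(pts, reverse=True)

    def test_gender_strata_partition_event_counts(self):
        tables, _ = fk.simulate_reports(fk.SimConfig(n_reports=5000, seed=21))
        ds = faers_io.assemble_dataset(
            tables.demo, tables.drug, tables.reac, tables.ther, tables.outc,
            {"baricitinib"},
        )
        a_all = {r.term: r.table.a for r in run_disproportionality(ds, "PT", "All")}
        a_f = {r.term: r.table.a for r in run_disproportionality(ds, "PT", "F")}
        a_m = {r.term: r.table.a for r in run_disproportionality(ds, "PT", "M")}
        unk_ids = set(ds.cases.loc[ds.cases["sex_norm"] == "Unknown", "caseid"])
        unk = ds.subset(ds.case_ids - unk_ids)  # F+M only
        a_fm = {r.term: r.table.a for r in run_disproportionality(unk, "PT", "All")}
        for term, a in a_all.items():
            assert a_f.get(term, 0) + a_m.get(term, 0) == a_fm.get(term, 0) <= a


class TestOnsetBins:
    def _ds(self, onsets):
        ds = make_dataset({f"C{i}": (False, "F", set()) for i in range(len(onsets))})
        ds.cases["onset_days"] = onsets
        return ds

    def test_left_closed_boundaries(self):
        ds = self._ds([6, 7, 27.9, 28, 59, 60, 400, np.nan])
        counts = onset_bins(ds)
        assert counts == {"<7": 1, "7-28": 2, "28-60": 2, ">=60": 2, "Unknown": 1}

    def test_counts_sum_to_case_count(self):
        ds = self._ds([1, np.nan, 90])
        assert sum(onset_bins(ds).values()) == ds.n_cases


class TestDemographicSummary:
    def test_percentage_arithmetic_two_decimals(self):
        rows = percentage_block({"A": 1, "B": 2}, denominator=3)
        assert rows == [("A", 1, 33.33), ("B", 2, 66.67)]

    def test_zero_count_reported_as_zero(self):
        rows = percentage_block({"A": 0, "B": 4})
        assert rows[0] == ("A", 0, 0.0)

    def test_weight_quartiles_linear_interpolation(self):
        ds = make_dataset({"C1": (False, "F", set()), "C2": (False, "F", set()),
                           "C3": (False, "F", set())})
        ds.cases["weight_kg"] = [64.70, 80.00, 97.52]
        s = summarize_demographics(ds)
        assert s.weight_median == pytest.approx(80.00)
        assert s.weight_q1 == pytest.approx(72.35)
        assert s.weight_q3 == pytest.approx(88.76)

    def test_block_counts_sum_to_denominator(self):
        tables, _ = fk.simulate_reports(fk.SimConfig(n_reports=2000, seed=2))
        ds = faers_io.assemble_dataset(
            tables.demo, tables.drug, tables.reac, tables.ther, tables.outc,
            {"baricitinib"},
        )
        s = summarize_demographics(ds)
        for block in ("gender", "age"):
            assert sum(c for _, c, _ in s.blocks[block]) == ds.n_cases
        assert sum(c for _, c, _ in s.blocks["onset"]) == ds.n_cases
        assert sum(c for _, c, _ in s.blocks["outcomes"]) == len(ds.outcomes)


class TestCriteriaConfig:
    def test_defaults_match_published_rule(self):
        crit = SignalCriteria()
        assert crit.min_a == 3
        assert crit.ror_ci_low_gt == 1.0 and crit.prr_ci_low_gt == 1.0
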