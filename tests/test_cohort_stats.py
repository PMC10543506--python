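"""Longitudinal change, cohort summaries, paired t-tests, eligibility."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from octfoci import (
    SlabCounts,
    change_per_eye,
    cohort_summary,
    eligibility_filter,
    paired_t_test,
    percent,
    round_half_up,
)


def t_p_quad_oracle(t: float, df: int) -> float:
    """Two-sided p by direct numerical integration of the t density."""
    c = math.gamma((df + 1) / 2) / (math.sqrt(df * math.pi) * math.gamma(df / 2))
    pdf = lambda x: c * (1 + x * x / df) ** (-(df + 1) / 2)
    tail, _ = integrate.quad(pdf, abs(t), np.inf)
    return 2 * tail


def eye(eye_id, visit, counts):
    return SlabCounts(eye_id=eye_id, visit=visit, counts=np.asarray(counts))


class TestRounding:
    def test_half_up_one_decimal(self):
        assert round_half_up(76.95) == 77.0
        assert round_half_up(15.384) == 15.4
        assert round_half_up(0.05) == 0.1  # half rounds up, not to even

    def test_worked_percentages(self):
        assert percent(52, 120) == 43.3
        assert percent(40, 52) == 76.9
        assert percent(8, 52) == 15.4
        assert percent(17, 52) == 32.7
        assert percent(4, 52) == 7.7


class TestChangePerEye:
    def test_no_change(self):
        rec = change_per_eye(eye("e1", "baseline", [1, 1, 1, 0, 0]),
                             eye("e1", "month24", [1, 1, 1, 0, 0]))
        assert rec.delta_total == 0 and rec.category_total == "no_change"

    def test_mixed_slab_changes_cancel(self):
        rec = change_per_eye(eye("e1", "baseline", [1, 2, 0, 0, 0]),
                             eye("e1", "month24", [2, 1, 0, 0, 0]))
        assert rec.delta_total == 0
        assert rec.category_total == "no_change"
        assert rec.category_per_slab[0] == "increase"
        assert rec.category_per_slab[1] == "decrease"
        assert rec.category_per_slab[2] == "no_change"

    def test_eye_and_visit_validation(self):
        with pytest.raises(ValueError, match="eye_id"):
            change_per_eye(eye("e1", "baseline", [0] * 5), eye("e2", "month24", [0] * 5))
        with pytest.raises(ValueError, match="visit"):
            change_per_eye(eye("e1", "month24", [0] * 5), eye("e1", "baseline", [0] * 5))

    def test_mean_delta_equals_difference_of_means(self):
        rng = np.random.default_rng(0)
        records = []
        for i in range(30):
            b = rng.integers(0, 10, 5)
            m = rng.integers(0, 10, 5)
            records.append(change_per_eye(eye(f"e{i}", "baseline", b),
                                          eye(f"e{i}", "month24", m)))
        mean_delta = np.mean([r.delta_total for r in records])
        diff = (np.mean([r.month24_total for r in records])
                - np.mean([r.baseline_total for r in records]))
        assert mean_delta == pytest.approx(diff, abs=1e-12)


class TestCohortSummary:
    def make_cohort(self, n_inc, n_dec, n_same):
        """Eyes with clearcut total increase / decrease / no change."""
        records = []
        i = 0
        for _ in range(n_inc):
            records.append(change_per_eye(eye(f"e{i}", "baseline", [1, 0, 0, 0, 0]),
                                          eye(f"e{i}", "month24", [2, 1, 0, 0, 0])))
            i += 1
        for _ in range(n_dec):
            records.append(change_per_eye(eye(f"e{i}", "baseline", [1, 2, 0, 0, 0]),
                                          eye(f"e{i}", "month24", [1, 1, 0, 0, 0])))
            i += 1
        for _ in range(n_same):
            records.append(change_per_eye(eye(f"e{i}", "baseline", [0, 1, 0, 0, 0]),
                                          eye(f"e{i}", "month24", [0, 1, 0, 0, 0])))
            i += 1
        return records

    def test_category_percentages_of_printed_cohort(self):
        """40 / 8 / 4 of 52 eyes -> 76.9% / 15.4% / 7.7%."""
        summary = cohort_summary(self.make_cohort(40, 8, 4))
        assert summary.n_eyes == 52
        assert summary.category_percent.loc["total", "increase"] == 76.9
        assert summary.category_percent.loc["total", "decrease"] == 15.4
        assert summary.category_percent.loc["total", "no_change"] == 7.7

    def test_category_counts_sum_to_n_in_every_stratum(self):
        summary = cohort_summary(self.make_cohort(11, 5, 3))
        sums = summary.category_counts.sum(axis=1)
        assert (sums == summary.n_eyes).all()

    def test_category_percentages_sum_to_100_within_rounding(self):
        summary = cohort_summary(self.make_cohort(40, 8, 4))
        for _, row in summary.category_percent.iterrows():
            assert row.sum() == pytest.approx(100.0, abs=0.3)

    def test_single_eye_distribution(self):
        records = [change_per_eye(eye("e", "baseline", [1, 0, 0, 0, 0]),
                                  eye("e", "month24", [1, 0, 0, 0, 0]))]
        summary = cohort_summary(records)
        assert summary.distribution_percent.loc["slab1", "baseline"] == 100.0

    def test_distribution_sums_to_100(self):
        summary = cohort_summary(self.make_cohort(10, 3, 2))
        for col in summary.distribution_percent:
            assert summary.distribution_percent[col].sum() == pytest.approx(100.0, abs=0.3)

    def test_sample_sd_uses_n_minus_1(self):
        records = self.make_cohort(2, 0, 0) + self.make_cohort(0, 0, 2)
        totals = [r.baseline_total for r in records]
        summary = cohort_summary(records)
        assert summary.visit_stats.loc["baseline", "sd"] == pytest.approx(
            np.std(totals, ddof=1))

    def test_empty_cohort_errors(self):
        with pytest.raises(ValueError):
            cohort_summary([])


class TestPairedTTest:
    def test_worked_example(self):
        res = paired_t_test([1, 2, 3, 4])
        assert res.t == pytest.approx(3.873, abs=5e-4)
        assert res.df == 3
        assert res.p == pytest.approx(t_p_quad_oracle(res.t, 3), abs=1e-10)

    def test_degenerate_all_zero(self):
        res = paired_t_test([0, 0, 0, 0])
        assert res.degenerate and res.p == 1.0

    def test_degenerate_constant_nonzero(self):
        res = paired_t_test([2, 2, 2])
        assert res.degenerate and res.p == 0.0 and math.isinf(res.t)

    def test_sign_symmetry(self):
        d = np.array([0.3, -1.2, 2.4, 0.7, 1.1])
        a, b = paired_t_test(d), paired_t_test(-d)
        assert a.t == pytest.approx(-b.t)
        assert a.p == pytest.approx(b.p)

    def test_needs_two_observations(self):
        with pytest.raises(ValueError):
            paired_t_test([1.0])

    def test_matches_scipy_and_quad_oracle(self):
        """t and p agree with scipy.stats.ttest_rel and with direct numerical
        integration of the t density to 1e-8."""
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = int(rng.integers(3, 51))
            d = rng.normal(rng.uniform(-1, 1), rng.uniform(0.5, 2), n)
            res = paired_t_test(d)
            t_sp, p_sp = stats.ttest_rel(d, np.zeros(n))
            assert res.t == pytest.approx(t_sp, abs=1e-10)
            assert res.p == pytest.approx(p_sp, abs=1e-10)
            assert res.p == pytest.approx(t_p_quad_oracle(res.t, res.df), abs=1e-8)

    def test_larger_t_smaller_p(self):
        ps = [paired_t_test([x, 2 * x, 3 * x, -x, x + 1]).p for x in (0.5, 1, 2, 4)]
        ts = [abs(paired_t_test([x, 2 * x, 3 * x, -x, x + 1]).t) for x in (0.5, 1, 2, 4)]
        order = np.argsort(ts)
        assert all(ps[order[i]] >= ps[order[i + 1]] for i in range(len(order) - 1))


class TestEligibility:
    def make_table(self, n_iamd=120, n_with_foci=52, n_extra=10):
        rows = []
        for i in range(n_iamd):
            rows.append({"eye_id": f"e{i}", "iamd": True,
                         "baseline_total": 3 if i < n_with_foci else 0,
                         "excluded": False})
        for i in range(n_extra):  # non-iAMD screened eyes
            rows.append({"eye_id": f"x{i}", "iamd": False,
                         "baseline_total": 2, "excluded": False})
        return pd.DataFrame(rows)

    def test_printed_cohort_proportion(self):
        """52 of 120 iAMD eyes with baseline foci -> 43.3% analysis cohort."""
        cohort, ledger = eligibility_filter(self.make_table())
        assert len(cohort) == 52
        assert ledger["iamd"] == 120
        assert ledger["pct_iamd_with_ihrf"] == 43.3

    def test_exclusion_flag_dominates(self):
        table = self.make_table(n_iamd=3, n_with_foci=3, n_extra=0)
        table.loc[0, "excluded"] = True
        cohort, _ = eligibility_filter(table)
        assert len(cohort) == 2

    def test_all_without_foci_empty_cohort(self):
        cohort, ledger = eligibility_filter(self.make_table(n_iamd=5, n_with_foci=0,
                                                            n_extra=0))
        assert len(cohort) == 0
        assert ledger["iamd_with_ihrf"] == 0
        with pytest.raises(ValueError):
            cohort_summary([])  # downstream summary errors cleanly
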