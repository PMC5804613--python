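"""Accuracy statistics: differences, PE/MDAPE, fixed bias, regression, power."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pkbias import (
    PairedSample,
    PowerSpec,
    build_stage_table,
    correlation_regression,
    difference,
    difference_vs_time_regression,
    exceedance,
    fixed_bias,
    mdape,
    performance_error,
    sample_size_for_correlation,
)
from pkbias.metrics import ci_from_moments
from conftest import exact_moment_sample


def make_pair(measured, predicted, elapsed=30.0, procedure="mastectomy", pid="p"):
    from pkbias.protocol import assign_stage

    return PairedSample(
        patient_id=pid,
        procedure=procedure,
        elapsed=elapsed,
        measured=measured,
        predicted=predicted,
        stage=assign_stage(elapsed),
    )


class TestDifferenceAndPE:
    def test_group_mean_identity(self):
        """Mean of differences equals difference of group means (2.08 vs
        1.81 -> 0.27), the identity the stage table relies on."""
        assert difference(make_pair(2.08, 1.81)) == pytest.approx(0.27)

    def test_zero_when_equal(self):
        assert difference(make_pair(1.5, 1.5)) == 0.0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        m=st.floats(min_value=0.01, max_value=10),
        p=st.floats(min_value=0.01, max_value=10),
    )
    def test_antisymmetry(self, m, p):
        assert difference(make_pair(m, p)) == -difference(make_pair(p, m))

    @pytest.mark.parametrize(
        "measured,predicted,pe",
        [(2.0, 1.6, 25.0), (1.5, 1.5, 0.0), (0.0, 1.0, -100.0)],
    )
    def test_performance_error(self, measured, predicted, pe):
        assert performance_error(make_pair(measured, predicted)) == pytest.approx(pe)


class TestMdape:
    def test_median_of_absolutes(self):
        # PEs of -10%, +20%, +30%
        pairs = [make_pair(0.9, 1.0), make_pair(1.2, 1.0), make_pair(1.3, 1.0)]
        assert mdape(pairs) == pytest.approx(20.0)

    def test_single_pair(self):
        assert mdape([make_pair(1.5, 1.0)]) == pytest.approx(50.0)

    def test_matches_sort_based_oracle(self):
        rng = np.random.default_rng(3)
        pairs = [
            make_pair(float(m), float(p))
            for m, p in zip(rng.uniform(0.5, 3, 25), rng.uniform(0.5, 3, 25))
        ]
        apes = sorted(abs((q.measured - q.predicted) / q.predicted * 100) for q in pairs)
        expected = apes[12]  # odd n: middle order statistic
        assert mdape(pairs) == pytest.approx(expected, rel=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mdape([])


class TestFixedBias:
    def test_constant_group_zero_width(self):
        summary = fixed_bias([0.3, 0.3, 0.3, 0.3])
        assert summary.mean_difference == pytest.approx(0.3)
        assert summary.ci_low == summary.ci_high == pytest.approx(0.3)
        assert summary.range_low == summary.range_high == pytest.approx(0.3)

    def test_needs_two_values(self):
        with pytest.raises(ValueError):
            fixed_bias([0.1])

    def test_ci_width_shrinks_as_sqrt_n(self):
        base = exact_moment_sample(0.2, 0.5, 40)
        w1 = np.diff(ci_from_moments(0.2, 0.5, 40))[0]
        w4 = np.diff(ci_from_moments(0.2, 0.5, 160))[0]
        # 1/sqrt(4) scaling up to the small drift of the t quantile with df
        assert w4 / w1 == pytest.approx(0.5, rel=0.05)
        assert w4 < w1
        summary = fixed_bias(list(base))
        assert summary.ci_high - summary.ci_low == pytest.approx(w1, rel=1e-12)

    def test_t_and_z_methods_close_at_large_n(self):
        lo_t, hi_t = ci_from_moments(0.27, 0.48, 83, method="t")
        lo_z, hi_z = ci_from_moments(0.27, 0.48, 83, method="z")
        assert hi_t - hi_z == pytest.approx(0.0, abs=0.005)
        assert hi_t > hi_z  # t is the (slightly) wider, stricter interval


class TestExceedance:
    def test_small_example(self):
        res = exceedance([0.6, -0.6, 0.0])
        assert (res.n_over_plus, res.n_under_minus) == (1, 1)
        assert res.fraction_abs == pytest.approx(2 / 3)

    def test_huge_threshold_counts_nothing(self):
        res = exceedance([0.6, -0.6, 0.0], threshold=1e9)
        assert res.n_over_plus == res.n_under_minus == 0

    def test_order_invariant(self):
        rng = np.random.default_rng(5)
        d = list(rng.normal(0, 1, 50))
        a = exceedance(d)
        b = exceedance(d[::-1])
        assert (a.n_over_plus, a.n_under_minus) == (b.n_over_plus, b.n_under_minus)

    def test_boundary_is_strict(self):
        res = exceedance([0.5, -0.5])
        assert res.n_over_plus == res.n_under_minus == 0


class TestCorrelationRegression:
    def test_identity_line(self):
        x = [1.0, 2.0, 3.0, 4.0]
        res = correlation_regression(x, x)
        assert res.r == pytest.approx(1.0)
        assert res.slope == pytest.approx(1.0)
        assert res.intercept == pytest.approx(0.0, abs=1e-14)

    def test_exact_negative_line(self):
        x = np.array([0.0, 1.0, 2.0, 5.0])
        res = correlation_regression(x, -2.0 * x + 5.0)
        assert res.r == pytest.approx(-1.0)
        assert res.slope == pytest.approx(-2.0)
        assert res.intercept == pytest.approx(5.0)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(9)
        x = rng.uniform(0, 4, 30)
        y = 0.9 * x + 0.3 + rng.normal(0, 0.5, 30)
        res = correlation_regression(x, y)
        X = np.c_[np.ones_like(x), x]
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert res.intercept == pytest.approx(beta[0], abs=1e-12)
        assert res.slope == pytest.approx(beta[1], abs=1e-12)
        r_direct = np.corrcoef(x, y)[0, 1]
        assert res.r == pytest.approx(r_direct, abs=1e-12)

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError):
            correlation_regression([1.0, 1.0, 1.0], [0.0, 1.0, 2.0])


class TestDifferenceVsTime:
    def test_constant_difference_degenerates_to_flat_line(self):
        pairs = [make_pair(1.3, 1.0, elapsed=e) for e in (10.0, 50.0, 200.0)]
        res = difference_vs_time_regression(pairs)
        assert res.slope == 0.0
        assert res.r == 0.0
        assert res.intercept == pytest.approx(0.3)

    def test_recovers_injected_linear_bias_exactly(self):
        a, c = 0.43, -0.0023
        pairs = [
            make_pair(1.0 + a + c * e, 1.0, elapsed=e)
            for e in (0.0, 30.0, 90.0, 150.0, 240.0, 330.0)
        ]
        res = difference_vs_time_regression(pairs)
        assert res.intercept == pytest.approx(a, abs=1e-12)
        assert res.slope == pytest.approx(c, abs=1e-14)
        assert res.r == pytest.approx(-1.0)

    def test_time_unit_rescales_slope(self):
        pairs = [
            make_pair(1.0 + 0.001 * e, 1.0, elapsed=e) for e in (0.0, 60.0, 120.0, 300.0)
        ]
        per_min = difference_vs_time_regression(pairs, time_unit=1.0)
        per_10min = difference_vs_time_regression(pairs, time_unit=10.0)
        assert per_10min.slope == pytest.approx(10.0 * per_min.slope, rel=1e-12)
        assert per_10min.r == pytest.approx(per_min.r, rel=1e-12)


class TestSampleSize:
    def test_fisher_z_formula(self):
        spec = PowerSpec(r_target=0.5, alpha=0.05, power=0.90)
        assert sample_size_for_correlation(spec) == 38

    def test_monotone_in_effect_size(self):
        sizes = [
            sample_size_for_correlation(PowerSpec(r_target=r)) for r in (0.3, 0.5, 0.7, 0.9)
        ]
        assert sizes == sorted(sizes, reverse=True)

    def test_monotone_in_power(self):
        lo = sample_size_for_correlation(PowerSpec(r_target=0.5, power=0.80))
        hi = sample_size_for_correlation(PowerSpec(r_target=0.5, power=0.95))
        assert lo <= hi

    def test_degenerate_effect_size_rejected(self):
        with pytest.raises(ValueError):
            PowerSpec(r_target=1.0)
        with pytest.raises(ValueError):
            PowerSpec(r_target=0.0)


class TestStageTable:
    def test_single_cell(self):
        pairs = [make_pair(2.0, 1.5, elapsed=e) for e in (10.0, 40.0, 80.0)]
        table = build_stage_table(pairs)
        assert len(table) == 1
        assert table[0].stage == 1
        assert table[0].n == 3

    def test_mastectomy_stage_profile(self):
        """Cell sizes (83, 74, 19, 0): empty stage-4 cell is omitted."""
        rng = np.random.default_rng(2)
        pairs = []
        for n, (lo, hi) in zip((83, 74, 19), ((0, 89), (90, 179), (180, 269))):
            for _ in range(n):
                e = float(rng.uniform(lo, hi))
                pairs.append(make_pair(float(rng.uniform(1, 3)), 1.5, elapsed=e))
        table = build_stage_table(pairs)
        assert [s.stage for s in table] == [1, 2, 3]
        assert [s.n for s in table] == [83, 74, 19]

    def test_cell_sizes_partition_pairs(self):
        rng = np.random.default_rng(8)
        pairs = [
            make_pair(
                float(rng.uniform(0.5, 3)),
                float(rng.uniform(0.5, 3)),
                elapsed=float(rng.uniform(0, 400)),
                procedure=rng.choice(["mastectomy", "prostatectomy"]),
            )
            for _ in range(200)
        ]
        table = build_stage_table(pairs)
        assert sum(s.n for s in table) == 200

    def test_mean_difference_identity(self):
        """Within a cell, mean difference == mean measured - mean predicted."""
        rng = np.random.default_rng(4)
        pairs = [
            make_pair(float(rng.uniform(1, 3)), float(rng.uniform(1, 3)), elapsed=20.0)
            for _ in range(30)
        ]
        (cell,) = build_stage_table(pairs)
        assert cell.bias.mean_difference == pytest.approx(
            cell.mean_measured - cell.mean_predicted, abs=1e-12
        )
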