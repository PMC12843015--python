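"""Closed-form RR/OR comparison: worked-example values, identities, and a
high-precision symbolic oracle."""

import math

import numpy as np
import pytest
import sympy as sp
from hypothesis import given, settings
from hypothesis import strategies as st

from corrisk import (
    DegenerateTableError,
    DegenerateVarianceError,
    compare_or,
    compare_rr,
    cov_log_rr,
    make_table,
    or_estimates,
    p_interaction,
    rr_estimates,
    var_log_rr,
    zeta_statistic,
)

from conftest import random_valid_tables


def precise_rr(counts):
    """Arbitrary-precision re-evaluation of the RR comparison from the raw
    formulas, via exact rationals and 40-digit symbolic logs."""
    a11, a12, a21, a22, a31, a32 = (sp.Integer(int(c)) for c in counts)
    r1, r2, r3 = a11 + a12, a21 + a22, a31 + a32
    one = sp.Integer(1)
    rr1 = (a11 / r1) / (a31 / r3)
    rr2 = (a11 / r1) / (a21 / r2)
    v1 = one / a11 - one / r1 + one / a31 - one / r3
    v2 = one / a11 - one / r1 + one / a21 - one / r2
    cov = one / a11 - one / r1
    log_diff = sp.log(rr1 / rr2)
    zeta = log_diff / sp.sqrt(v1 + v2 - 2 * cov)
    p = sp.erfc(sp.Abs(zeta) / sp.sqrt(2))
    fields = dict(
        rr1=rr1, rr2=rr2, log_diff=log_diff, var_log_rr1=v1, var_log_rr2=v2,
        cov_log=cov, zeta=zeta, p_interaction=p,
        rld_percent=(rr1 / rr2 - 1) * 100,
    )
    return {k: float(v.evalf(40)) for k, v in fields.items()}


def precise_or(counts):
    """Same oracle for the odds-ratio comparison."""
    a11, a12, a21, a22, a31, a32 = (sp.Integer(int(c)) for c in counts)
    one = sp.Integer(1)
    or1 = (a11 / a12) / (a31 / a32)
    or2 = (a11 / a12) / (a21 / a22)
    v1 = one / a11 + one / a12 + one / a31 + one / a32
    v2 = one / a11 + one / a12 + one / a21 + one / a22
    cov = one / a11 + one / a12
    log_diff = sp.log(or1 / or2)
    zeta = log_diff / sp.sqrt(v1 + v2 - 2 * cov)
    p = sp.erfc(sp.Abs(zeta) / sp.sqrt(2))
    fields = dict(
        or1=or1, or2=or2, log_diff=log_diff, var_log_or1=v1, var_log_or2=v2,
        cov_log=cov, zeta=zeta, p_interaction=p,
        ror_reduction_percent=(or1 / or2 - 1) * 100,
    )
    return {k: float(v.evalf(40)) for k, v in fields.items()}


class TestPointEstimates:
    def test_worked_example_rrs(self, trial_table):
        rr1, rr2 = rr_estimates(trial_table)
        assert rr1 == pytest.approx(1.5000, abs=1e-12)
        assert rr2 == pytest.approx(1.1250, abs=1e-12)

    def test_identical_rows_give_unit_ratios(self, null_table):
        assert rr_estimates(null_table) == (1.0, 1.0)
        assert or_estimates(null_table) == (1.0, 1.0)

    def test_zero_event_count_names_the_arm(self):
        with pytest.raises(DegenerateTableError, match="T2"):
            rr_estimates(make_table([54, 6, 48, 12, 0, 60]))

    def test_worked_example_ors(self, trial_table):
        or1, or2 = or_estimates(trial_table)
        assert or1 == pytest.approx(6.0000, abs=1e-12)
        assert or2 == pytest.approx(2.2500, abs=1e-12)

    def test_zero_cell_rejected_for_odds(self):
        with pytest.raises(DegenerateTableError):
            or_estimates(make_table([54, 0, 48, 12, 36, 24]))


class TestVarianceBuildingBlocks:
    def test_delta_method_variances_match_reference(self):
        assert var_log_rr(54, 60, 36, 60) == pytest.approx(0.012963, abs=5e-7)
        assert var_log_rr(54, 60, 48, 60) == pytest.approx(0.0060185, abs=5e-8)

    def test_all_events_has_zero_variance(self):
        assert var_log_rr(60, 60, 60, 60) == 0.0

    def test_covariance_matches_reference(self):
        assert cov_log_rr(54, 60) == pytest.approx(0.0018519, abs=5e-8)
        assert cov_log_rr(60, 60) == 0.0

    def test_covariance_is_shared_component_of_variance(self):
        # Cov equals the first two (referent) terms of Var(log RR)
        for a11, a1p, ak1, akp in [(54, 60, 36, 60), (3, 9, 2, 5), (1, 100, 50, 80)]:
            assert cov_log_rr(a11, a1p) == pytest.approx(
                var_log_rr(a11, a1p, ak1, akp) - (1 / ak1 - 1 / akp), abs=1e-15
            )

    def test_zero_event_count_rejected(self):
        with pytest.raises(DegenerateTableError):
            var_log_rr(0, 60, 36, 60)
        with pytest.raises(DegenerateTableError):
            cov_log_rr(0, 60)


class TestZetaAndP:
    def test_worked_example_zeta(self):
        zeta = zeta_statistic(0.28768, 0.012963, 0.0060185, 0.0018519)
        assert zeta == pytest.approx(2.3275, abs=2e-4)

    def test_zero_log_diff_gives_zero_zeta(self):
        assert zeta_statistic(0.0, 0.01, 0.02, 0.001) == 0.0

    def test_perfect_dependence_is_degenerate(self):
        with pytest.raises(DegenerateVarianceError):
            zeta_statistic(0.1, 0.01, 0.01, 0.01)

    def test_p_interaction_values(self):
        assert p_interaction(2.3275) == pytest.approx(0.01994, abs=2e-5)
        assert p_interaction(0.0) == 1.0
        # conventional two-sided 5% quantile of the standard normal
        assert p_interaction(1.959964) == pytest.approx(0.0500, abs=1e-6)
        # two-sidedness: sign of zeta is irrelevant
        assert p_interaction(-2.3275) == p_interaction(2.3275)

    def test_nonfinite_zeta_rejected(self):
        with pytest.raises(ValueError):
            p_interaction(float("nan"))


class TestCompareRR:
    def test_worked_example_full_result(self, trial_table):
        res = compare_rr(trial_table)
        assert res.log_diff == pytest.approx(0.28768, abs=5e-6)
        assert res.zeta == pytest.approx(2.3275, abs=5e-5)
        assert res.p_interaction == pytest.approx(0.01994, abs=1e-5)
        assert res.rld_percent == pytest.approx(33.333, abs=1e-3)
        assert res.se_log_diff == pytest.approx(math.sqrt(0.0129630 + 0.0060185 - 2 * 0.0018519), abs=1e-6)

    def test_swapping_treatment_arms_negates_the_statistic(self, trial_table):
        res = compare_rr(trial_table)
        swapped = compare_rr(make_table([54, 6, 36, 24, 48, 12]))
        assert swapped.log_diff == pytest.approx(-res.log_diff, abs=1e-14)
        assert swapped.zeta == pytest.approx(-res.zeta, abs=1e-12)
        assert swapped.p_interaction == pytest.approx(res.p_interaction, abs=1e-14)

    def test_null_table_is_exactly_null(self, null_table):
        res = compare_rr(null_table)
        assert res.log_diff == 0.0
        assert res.zeta == 0.0
        assert res.p_interaction == 1.0

    def test_scaling_counts_shrinks_se_but_not_correlation(self, trial_table):
        """As every count scales by m, the covariance-to-variance ratio is
        unchanged while the SE of the log-difference vanishes."""
        base = compare_rr(trial_table)
        prev_se = base.se_log_diff
        for m in (5, 25):
            scaled = compare_rr(make_table([c * m for c in (54, 6, 48, 12, 36, 24)]))
            assert scaled.cov_log / scaled.var_log_rr1 == pytest.approx(
                base.cov_log / base.var_log_rr1, rel=1e-12
            )
            assert scaled.se_log_diff < prev_se
            prev_se = scaled.se_log_diff

    def test_matches_high_precision_oracle(self):
        rng = np.random.default_rng(42)
        for table in random_valid_tables(rng, 60):
            got = compare_rr(table)
            expected = precise_rr(table.counts.ravel())
            for name, value in expected.items():
                assert getattr(got, name) == pytest.approx(value, rel=1e-12, abs=1e-13), name


class TestCompareOR:
    def test_worked_example_or_reduction(self, trial_table):
        res = compare_or(trial_table)
        assert round(res.ror_reduction_percent) == 167
        assert res.p_interaction == pytest.approx(0.01857, abs=1e-5)

    def test_column_swap_inverts_ors_but_keeps_significance(self, trial_table):
        res = compare_or(trial_table)
        flipped = compare_or(make_table([6, 54, 12, 48, 24, 36]))
        assert flipped.or1 == pytest.approx(1 / res.or1, rel=1e-12)
        assert flipped.or2 == pytest.approx(1 / res.or2, rel=1e-12)
        assert abs(flipped.zeta) == pytest.approx(abs(res.zeta), rel=1e-12)

    def test_rare_outcome_or_approximates_rr(self):
        """With event risks <= 1% and huge arms, log OR ~ log RR."""
        from corrisk import generate_table

        table = generate_table((100_000,) * 3, (0.010, 0.008, 0.005), seed=11)
        rr = compare_rr(table)
        odds = compare_or(table)
        assert abs(math.log(odds.or1) - math.log(rr.rr1)) < 0.02
        assert abs(math.log(odds.or2) - math.log(rr.rr2)) < 0.02

    def test_matches_high_precision_oracle(self):
        rng = np.random.default_rng(43)
        for table in random_valid_tables(rng, 60):
            got = compare_or(table)
            expected = precise_or(table.counts.ravel())
            for name, value in expected.items():
                assert getattr(got, name) == pytest.approx(value, rel=1e-12, abs=1e-13), name

    def test_serialization_round_trips(self, trial_table):
        import json

        payload = json.loads(compare_or(trial_table).to_json())
        assert payload["or1"] == 6.0
        assert payload["display"]["zeta"] == pytest.approx(2.354, abs=1e-3)


@given(
    a11=st.integers(1, 80), a12=st.integers(0, 80),
    a21=st.integers(1, 80), a22=st.integers(0, 80),
    a31=st.integers(1, 80), a32=st.integers(0, 80),
)
@settings(max_examples=200, deadline=None, derandomize=True)
def test_antisymmetry_and_shared_covariance(a11, a12, a21, a22, a31, a32):
    """For every valid table: Cov equals the referent component of each
    variance, and exchanging T1 with T2 negates log_diff and zeta while the
    p-value is invariant."""
    table = make_table([a11, a12, a21, a22, a31, a32])
    try:
        res = compare_rr(table)
    except DegenerateVarianceError:
        return  # both treatment arms fully unfavorable: no information
    ref_component = cov_log_rr(a11, a11 + a12)
    assert res.cov_log == ref_component
    assert res.var_log_rr1 >= res.cov_log >= 0
    assert res.var_log_rr2 >= res.cov_log
    assert 0 < res.p_interaction <= 1

    swapped = compare_rr(make_table([a11, a12, a31, a32, a21, a22]))
    assert swapped.log_diff == pytest.approx(-res.log_diff, abs=1e-12)
    assert swapped.zeta == pytest.approx(-res.zeta, rel=1e-9, abs=1e-12)
    assert swapped.p_interaction == pytest.approx(res.p_interaction, rel=1e-9)
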