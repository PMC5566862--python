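"""Power formulas: identities, monotonicity, and Monte-Carlo agreement."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from powermix import (
    expected_counts,
    power_binary,
    power_one_sample_t,
    power_relative_risk,
    power_two_sample_t,
    se_log_or,
    study_power,
    treated_rate,
)
from powermix.catalog import (
    EffectMeasure,
    MetaAnalysisRecord,
    StudyRecord,
    Subfield,
    load_builtin_catalogue,
)
from powermix.catalog import APOE_LABEL
from powermix.exceptions import ConfigurationError, DegenerateDesignError, DomainError


class TestTreatedRate:
    @pytest.mark.parametrize(
        "p0, orr, expected, tol",
        [
            (0.3, 1.0, 0.3, 1e-12),
            (0.5, 2.0, 2.0 / 3.0, 1e-12),
            (0.2, 3.0, 0.4286, 1e-4),
        ],
    )
    def test_known_values(self, p0, orr, expected, tol):
        assert treated_rate(p0, orr) == pytest.approx(expected, abs=tol)

    @given(
        p0=st.floats(0.01, 0.99),
        orr=st.floats(0.01, 100.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_produces_probability_with_exact_odds_ratio(self, p0, orr):
        p1 = treated_rate(p0, orr)
        assert 0.0 < p1 < 1.0
        implied = (p1 / (1 - p1)) / (p0 / (1 - p0))
        assert implied == pytest.approx(orr, rel=1e-9)

    def test_domain_error_outside_unit_interval(self):
        with pytest.raises(DomainError):
            treated_rate(0.0, 2.0)
        with pytest.raises(DomainError):
            treated_rate(1.0, 2.0)


class TestExpectedCounts:
    def test_symmetric_null_design(self):
        assert expected_counts(0.5, 1.0, 100, 100) == pytest.approx((50, 50, 50, 50))

    def test_simple_arithmetic(self):
        assert expected_counts(0.3, 1.0, 10, 20) == pytest.approx((3, 7, 6, 14))

    def test_treated_cell_follows_treated_rate(self):
        table = expected_counts(0.2, 3.0, 100, 100)
        assert table.e11 == pytest.approx(100 * treated_rate(0.2, 3.0), abs=1e-9)
        assert table.e11 == pytest.approx(42.857, abs=1e-2)

    def test_row_sums_equal_group_sizes(self):
        t = expected_counts(0.37, 1.7, 55, 83)
        assert t.e11 + t.e10 == pytest.approx(55)
        assert t.e01 + t.e00 == pytest.approx(83)

    def test_degenerate_design_raises(self):
        with pytest.raises(DegenerateDesignError):
            expected_counts(0.5, 1e-12, 10, 10)


class TestSeLogOr:
    @pytest.mark.parametrize(
        "table, expected, tol",
        [
            ((100, 100, 100, 100), 0.2, 1e-12),
            ((25, 25, 25, 25), 0.4, 1e-12),
            # direct formula evaluation: sqrt(1/3 + 1/7 + 1/6 + 1/14)
            ((3, 7, 6, 14), 0.8452, 1e-3),
        ],
    )
    def test_known_values(self, table, expected, tol):
        from powermix.power import ExpectedTable

        assert se_log_or(ExpectedTable(*table)) == pytest.approx(expected, abs=tol)

    def test_zero_cell_raises(self):
        from powermix.power import ExpectedTable

        with pytest.raises(DomainError):
            se_log_or(ExpectedTable(0, 7, 6, 14))


class TestPowerBinary:
    def test_null_odds_ratio_gives_alpha_at_any_n(self):
        for n in (150, 3000):
            assert power_binary(0.3, 1.00, n, n) == pytest.approx(0.05, abs=1e-12)
        # independent of the base rate too
        assert power_binary(0.07, 1.00, 150, 3000) == pytest.approx(0.05, abs=1e-12)

    def test_large_sample_large_effect_saturates(self):
        assert power_binary(0.3, 4.98, 5000, 5000) >= 0.999

    def test_log_symmetry_under_group_swap(self):
        # inverting the OR and swapping group roles (new base rate = old
        # treated rate) leaves the power unchanged
        for p0, orr, n1, n0 in [(0.3, 2.0, 80, 120), (0.15, 0.6, 200, 150)]:
            p1 = treated_rate(p0, orr)
            assert power_binary(p0, orr, n1, n0) == pytest.approx(
                power_binary(p1, 1.0 / orr, n0, n1), abs=1e-9
            )

    def test_monotone_in_n_for_fixed_effect(self):
        powers = [power_binary(0.3, 1.5, n, n) for n in (50, 100, 200, 400, 800)]
        assert all(b > a for a, b in zip(powers, powers[1:]))

    def test_first_order_error_against_exact_wald_enumeration(self):
        # the formula is a first-order approximation; against the exact
        # finite-sample Wald rejection rate (full 2x2 enumeration) its error
        # at n = 100 per group is below 0.01
        p0, orr, n = 0.3, 2.0, 100
        p1 = treated_rate(p0, orr)
        x = np.arange(n + 1)
        P1 = stats.binom.pmf(x, n, p1)
        P0 = stats.binom.pmf(x, n, p0)
        a = x[:, None].astype(float)
        b = n - a
        c = x[None, :].astype(float)
        d = n - c
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.abs(np.log(a * d / (b * c))) / np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        z = np.where(np.isfinite(z), z, 0.0)
        exact = float((P1[:, None] * P0[None, :] * (z > stats.norm.ppf(0.975))).sum())
        assert power_binary(p0, orr, n, n) == pytest.approx(exact, abs=0.01)


class TestPowerT:
    def test_null_effect_gives_alpha(self):
        assert power_two_sample_t(0.0, 30, 30) == pytest.approx(0.05, abs=1e-12)
        assert power_one_sample_t(0.0, 45) == pytest.approx(0.05, abs=1e-12)

    def test_one_sample_benchmarks_at_n_45(self):
        assert power_one_sample_t(0.3, 45) == pytest.approx(0.50, abs=0.02)
        assert power_one_sample_t(0.49, 45) == pytest.approx(0.90, abs=0.02)

    def test_strictly_increasing_in_effect_and_n(self):
        by_d = [power_two_sample_t(d, 40, 40) for d in (0.1, 0.3, 0.5, 0.8, 1.2)]
        assert all(b > a for a, b in zip(by_d, by_d[1:]))
        by_n = [power_two_sample_t(0.4, n, n) for n in (10, 20, 40, 80, 160)]
        assert all(b > a for a, b in zip(by_n, by_n[1:]))

    def test_vectorized_one_sample_matches_scalar(self):
        d = np.array([0.0, 0.2, 0.49])
        vec = power_one_sample_t(d, 45)
        assert vec == pytest.approx([power_one_sample_t(float(x), 45) for x in d])

    def test_sign_symmetry(self):
        assert power_two_sample_t(-0.5, 30, 40) == pytest.approx(
            power_two_sample_t(0.5, 30, 40), abs=1e-12
        )

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            power_two_sample_t(0.5, 1, 1)
        with pytest.raises(DomainError):
            power_one_sample_t(0.5, 1)


class TestPowerRelativeRisk:
    def test_null_ratio_gives_alpha(self):
        assert power_relative_risk(0.3, 1.0, 200, 200) == pytest.approx(0.05, abs=1e-12)

    def test_impossible_treated_rate_raises(self):
        with pytest.raises(DomainError):
            power_relative_risk(0.5, 2.1, 100, 100)

    def test_monotone_in_n(self):
        powers = [power_relative_risk(0.2, 1.4, n, n) for n in (100, 200, 400, 800)]
        assert all(b > a for a, b in zip(powers, powers[1:]))


class TestMonteCarloSpotChecks:
    """One seeded Monte-Carlo point per formula (full grids run in the
    acceptance suite); the formula must sit within 3 MC standard errors."""

    def test_binary_power_matches_wald_simulation(self):
        p0, orr, n = 0.2, 1.3, 600
        nsim = 100_000
        rng = np.random.default_rng(42)
        p1 = treated_rate(p0, orr)
        x1 = rng.binomial(n, p1, nsim).astype(float)
        x0 = rng.binomial(n, p0, nsim).astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.abs(np.log(x1 * (n - x0) / ((n - x1) * x0))) / np.sqrt(
                1 / x1 + 1 / (n - x1) + 1 / x0 + 1 / (n - x0)
            )
        rej = np.where(np.isfinite(z), z, 0.0) > stats.norm.ppf(0.975)
        mc = rej.mean()
        se = np.sqrt(mc * (1 - mc) / nsim)
        assert abs(power_binary(p0, orr, n, n) - mc) <= 3 * se

    def test_two_sample_t_power_matches_simulation(self):
        d, n1, n2 = 0.5, 64, 64
        nsim = 60_000
        rng = np.random.default_rng(7)
        g1 = rng.standard_normal((nsim, n1)) + d
        g2 = rng.standard_normal((nsim, n2))
        v1 = g1.var(axis=1, ddof=1)
        v2 = g2.var(axis=1, ddof=1)
        sp = np.sqrt(((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2))
        t = (g1.mean(axis=1) - g2.mean(axis=1)) / (sp * np.sqrt(1 / n1 + 1 / n2))
        rej = np.abs(t) > stats.t.ppf(0.975, n1 + n2 - 2)
        mc = rej.mean()
        se = np.sqrt(mc * (1 - mc) / nsim)
        assert abs(power_two_sample_t(d, n1, n2) - mc) <= 3 * se


class TestStudyPower:
    def test_apoe_studies_have_alpha_power_at_any_n(self):
        catalogue = load_builtin_catalogue()
        apoe = catalogue.record(APOE_LABEL)
        for n in (145, 3100):
            s = StudyRecord(meta_label=APOE_LABEL, n_group1=n, n_group2=n, base_rate=0.3)
            assert study_power(s, apoe) == pytest.approx(0.05, abs=1e-12)

    def test_null_d_record_gives_alpha(self):
        meta = MetaAnalysisRecord(
            label="m", n_studies=1, measure=EffectMeasure.COHENS_D,
            effect_size=0.0, ci_low=-0.2, ci_high=0.2, significant=False,
            subfield=Subfield.PSYCHOLOGY,
        )
        s = StudyRecord(meta_label="m", n_group1=20, n_group2=20)
        assert study_power(s, meta) == pytest.approx(0.05, abs=1e-12)

    def test_cohens_d_dispatch_equals_direct_call(self):
        meta = MetaAnalysisRecord(
            label="m", n_studies=1, measure=EffectMeasure.COHENS_D,
            effect_size=0.58, ci_low=0.51, ci_high=0.64, significant=True,
            subfield=Subfield.PSYCHOLOGY,
        )
        s = StudyRecord(meta_label="m", n_group1=33, n_group2=27)
        assert study_power(s, meta) == power_two_sample_t(0.58, 33, 27)

    def test_missing_base_rate_is_configuration_error(self):
        meta = MetaAnalysisRecord(
            label="m", n_studies=1, measure=EffectMeasure.ODDS_RATIO,
            effect_size=1.5, ci_low=1.2, ci_high=1.9, significant=True,
            subfield=Subfield.GENETIC,
        )
        s = StudyRecord(meta_label="m", n_group1=100, n_group2=100)
        with pytest.raises(ConfigurationError):
            study_power(s, meta)

    def test_mismatched_labels_rejected(self):
        meta = MetaAnalysisRecord(
            label="m", n_studies=1, measure=EffectMeasure.COHENS_D,
            effect_size=0.5, ci_low=0.2, ci_high=0.8, significant=True,
            subfield=Subfield.PSYCHOLOGY,
        )
        s = StudyRecord(meta_label="other", n_group1=10, n_group2=10)
        with pytest.raises(ConfigurationError):
            study_power(s, meta)
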