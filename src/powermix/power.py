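"""Statistical power of a single study under a meta-analytic effect size.

The population effect is assumed equal to the pooled (weighted mean)
effect from the corresponding meta-analysis — *not* the study's own
estimate, which distinguishes this quantity from post hoc power.

Binary outcomes
---------------
The test statistic is the log odds ratio divided by its standard error,
the latter obtained by the first-order (delta method) approximation
``sqrt(1/e11 + 1/e10 + 1/e01 + 1/e00)`` over the *expected* cell counts
of the 2x2 table, and referenced to the standard normal distribution.
With noncentrality ``mu = |ln OR| / SE`` the two-sided power is
``Phi(mu - z*) + Phi(-mu - z*)``; it equals alpha exactly when OR = 1,
for any sample size.  Relative risks are handled by the analogous
delta-method statistic on the log risk ratio with
``SE = sqrt((1-p1)/(n1 p1) + (1-p0)/(n0 p0))``; the RR recipe is a
first-order analogue chosen for symmetry with the OR treatment (the
original description details only the OR statistic).

Standardized mean differences
-----------------------------
Cohen's-d power uses the noncentral t distribution: for a two-sample
design ``lambda = d sqrt(n1 n2 / (n1 + n2))`` with ``df = n1 + n2 - 2``;
for a one-sample design ``lambda = d sqrt(n)`` with ``df = n - 1``.

All tests are two-sided at a configurable significance level
(default alpha = 0.05).  These formulas are first-order approximations
for the binary measures: their error relative to the exact finite-sample
rejection rate of the corresponding Wald test is O(1/n) (roughly 0.01 at
n = 100 per group, negligible by n ~ 400; see docs/methods.md).
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
from scipy import stats

from .catalog import EffectMeasure, MetaAnalysisRecord, StudyRecord
from .exceptions import ConfigurationError, DegenerateDesignError, DomainError

__all__ = [
    "ExpectedTable",
    "treated_rate",
    "expected_counts",
    "se_log_or",
    "power_binary",
    "power_two_sample_t",
    "power_one_sample_t",
    "power_relative_risk",
    "study_power",
]

DEFAULT_ALPHA = 0.05


class ExpectedTable(NamedTuple):
    """Expected 2x2 counts: group (1 = exposed/case) x outcome (1 = event)."""

    e11: float
    e10: float
    e01: float
    e00: float


def _check_alpha(alpha: float) -> None:
    if not (0.0 < alpha < 1.0):
        raise DomainError(f"alpha must lie in (0, 1), got {alpha}")


def treated_rate(base_rate: float, odds_ratio: float) -> float:
    """Event probability in the treated group implied by a base rate and OR.

    Solves ``p1/(1-p1) = OR * p0/(1-p0)``:
    ``p1 = OR p0 / (1 - p0 + OR p0)``.
    """
    if not (0.0 < base_rate < 1.0):
        raise DomainError(f"base_rate must lie in (0, 1), got {base_rate}")
    if odds_ratio <= 0:
        raise DomainError(f"odds_ratio must be > 0, got {odds_ratio}")
    return odds_ratio * base_rate / (1.0 - base_rate + odds_ratio * base_rate)


def expected_counts(
    base_rate: float,
    odds_ratio: float,
    n1: int,
    n0: int,
    floor: float = 1e-8,
) -> ExpectedTable:
    """Expected 2x2 cell counts for the given design.

    Row sums equal the group sizes by construction.  A cell below
    ``floor`` marks a degenerate design (the delta-method SE would be
    meaningless) and raises :class:`DegenerateDesignError`.
    """
    if n1 < 1 or n0 < 1:
        raise DomainError("group sizes must be >= 1")
    p1 = treated_rate(base_rate, odds_ratio)
    table = ExpectedTable(
        e11=n1 * p1,
        e10=n1 * (1.0 - p1),
        e01=n0 * base_rate,
        e00=n0 * (1.0 - base_rate),
    )
    if min(table) < floor:
        raise DegenerateDesignError(
            f"expected cell count below {floor}: {table}"
        )
    return table


def se_log_or(table: ExpectedTable) -> float:
    """First-order SE of the log odds ratio: sqrt of summed reciprocal counts."""
    if min(table) <= 0:
        raise DomainError("all expected cells must be > 0")
    return float(np.sqrt(sum(1.0 / c for c in table)))


def _normal_two_sided_power(mu: float, alpha: float) -> float:
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    return float(stats.norm.cdf(mu - z) + stats.norm.cdf(-mu - z))


def power_binary(
    base_rate: float,
    odds_ratio: float,
    n1: int,
    n0: int,
    alpha: float = DEFAULT_ALPHA,
) -> float:
    """Two-sided power of the expected-count Wald log-OR test.

    Equals ``alpha`` exactly when ``odds_ratio == 1`` — the power of a
    truly null effect is the type I error rate, independent of n.
    """
    _check_alpha(alpha)
    table = expected_counts(base_rate, odds_ratio, n1, n0)
    mu = abs(np.log(odds_ratio)) / se_log_or(table)
    return _normal_two_sided_power(mu, alpha)


def _t_two_sided_power(noncentrality, df: int, alpha: float):
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
    nc = np.asarray(noncentrality, dtype=float)
    power = stats.nct.sf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc)
    # exact central-t limit for null effects (nct at nc=0 is only approximate)
    power = np.where(nc == 0.0, alpha, power)
    if np.ndim(noncentrality) == 0:
        return float(power)
    return power


def power_two_sample_t(
    d: float, n1: int, n2: int, alpha: float = DEFAULT_ALPHA
) -> float:
    """Two-sided power of the two-sample t test for standardized difference d."""
    _check_alpha(alpha)
    if n1 < 1 or n2 < 1 or n1 + n2 < 3:
        raise DomainError("two-sample design needs n1 + n2 >= 3")
    df = n1 + n2 - 2
    lam = d * np.sqrt(n1 * n2 / (n1 + n2))
    return _t_two_sided_power(lam, df, alpha)


def power_one_sample_t(d, n: int, alpha: float = DEFAULT_ALPHA):
    """Two-sided power of the one-sample t test; ``d`` may be an array."""
    _check_alpha(alpha)
    if n < 2:
        raise DomainError("one-sample design needs n >= 2")
    lam = np.asarray(d, dtype=float) * np.sqrt(n)
    if np.ndim(d) == 0:
        return _t_two_sided_power(float(lam), n - 1, alpha)
    return _t_two_sided_power(lam, n - 1, alpha)


def power_relative_risk(
    base_rate: float,
    rr: float,
    n1: int,
    n0: int,
    alpha: float = DEFAULT_ALPHA,
) -> float:
    """Two-sided power of the delta-method Wald log-RR test."""
    _check_alpha(alpha)
    if not (0.0 < base_rate < 1.0):
        raise DomainError(f"base_rate must lie in (0, 1), got {base_rate}")
    if rr <= 0:
        raise DomainError(f"relative risk must be > 0, got {rr}")
    if n1 < 1 or n0 < 1:
        raise DomainError("group sizes must be >= 1")
    p1 = rr * base_rate
    if p1 >= 1.0:
        raise DomainError(
            f"rr * base_rate = {p1} >= 1: treated-group rate is not a probability"
        )
    se = np.sqrt((1.0 - p1) / (n1 * p1) + (1.0 - base_rate) / (n0 * base_rate))
    mu = abs(np.log(rr)) / se
    return _normal_two_sided_power(mu, alpha)


def study_power(
    study: StudyRecord,
    meta: MetaAnalysisRecord,
    alpha: float = DEFAULT_ALPHA,
) -> float:
    """Power of one study assuming its meta-analysis' pooled effect is real.

    Dispatches on the meta-analysis' effect measure.  Binary measures
    require the study's ``base_rate``; Cohen's d uses the two-sample
    noncentral-t design with the study's group sizes.
    """
    if study.meta_label != meta.label:
        raise ConfigurationError(
            f"study {study.meta_label!r} does not belong to meta-analysis {meta.label!r}"
        )
    if meta.measure is EffectMeasure.COHENS_D:
        return power_two_sample_t(
            meta.effect_size, study.n_group1, study.n_group2, alpha
        )
    if study.base_rate is None:
        raise ConfigurationError(
            f"{meta.label}: base_rate required for {meta.measure.value} measure"
        )
    if meta.measure is EffectMeasure.ODDS_RATIO:
        return power_binary(
            study.base_rate, meta.effect_size, study.n_group1, study.n_group2, alpha
        )
    return power_relative_risk(
        study.base_rate, meta.effect_size, study.n_group1, study.n_group2, alpha
    )
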