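"""Nonparametric comparison of power values across groups (subfields).

The K-group test of equivalence is a permutation test: the observed
Kruskal-Wallis rank statistic H is compared with its distribution under
random reassignment of group labels, which is exact under
exchangeability and makes no distributional assumption about the power
values (which are bounded, skewed and multimodal).  Pairwise follow-ups
use two-sided Mann-Whitney U tests with the tie-corrected normal
approximation; p-values are reported unadjusted by default, with an
optional Holm correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import stats

from .exceptions import DomainError

__all__ = [
    "GroupedPowers",
    "GroupTestResult",
    "group_medians",
    "kruskal_h",
    "permutation_equivalence_test",
    "pairwise_mannwhitney",
]


@dataclass(frozen=True)
class GroupedPowers:
    """Power values with one group label per value."""

    values: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float).ravel()
        labels = np.asarray(self.labels).ravel()
        if values.size != labels.size:
            raise DomainError("values and labels must have equal length")
        if values.size == 0:
            raise DomainError("grouped powers must be non-empty")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "labels", labels)

    @property
    def groups(self) -> tuple:
        return tuple(dict.fromkeys(self.labels.tolist()))

    def group_values(self, group) -> np.ndarray:
        return self.values[self.labels == group]


@dataclass(frozen=True)
class GroupTestResult:
    statistic: float
    p_value: float
    n_permutations: int
    per_group_medians: Mapping
    pairwise: Mapping | None = None
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "p_value": self.p_value,
            "n_permutations": self.n_permutations,
            "per_group_medians": {str(k): v for k, v in self.per_group_medians.items()},
            "pairwise": None
            if self.pairwise is None
            else {f"{a}|{b}": list(v) for (a, b), v in self.pairwise.items()},
            "seed": self.seed,
        }


def group_medians(grouped: GroupedPowers) -> dict:
    """Per-group empirical medians."""
    out = {}
    for g in grouped.groups:
        vals = grouped.group_values(g)
        if vals.size == 0:
            raise DomainError(f"group {g!r} is empty")
        out[g] = float(np.median(vals))
    return out


def _group_indicator(labels: np.ndarray, groups) -> np.ndarray:
    return np.stack([(labels == g).astype(float) for g in groups], axis=1)


def kruskal_h(values: np.ndarray, labels: np.ndarray) -> float:
    """Kruskal-Wallis H with tie correction (cross-checked against scipy)."""
    n = values.size
    ranks = stats.rankdata(values)
    groups = tuple(dict.fromkeys(labels.tolist()))
    h = 0.0
    for g in groups:
        r = ranks[labels == g]
        h += r.sum() ** 2 / r.size
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    _, counts = np.unique(values, return_counts=True)
    tie = 1.0 - (counts**3 - counts).sum() / (n**3 - n)
    if tie <= 0:
        raise DomainError("all values identical: rank test undefined")
    return float(h / tie)


def permutation_equivalence_test(
    grouped: GroupedPowers,
    n_perm: int = 9999,
    seed: int = 0,
) -> GroupTestResult:
    """Permutation test of group equivalence on the Kruskal-Wallis statistic.

    Labels are randomly permuted ``n_perm`` times; the p-value uses the
    add-one convention ``p = (1 + #{H_perm >= H_obs}) / (1 + n_perm)``,
    so p is never below ``1/(n_perm + 1)``.
    """
    if n_perm < 99:
        raise DomainError("n_perm must be >= 99")
    groups = grouped.groups
    if len(groups) < 2:
        raise DomainError("need at least two groups")
    values, labels = grouped.values, grouped.labels
    n = values.size
    h_obs = kruskal_h(values, labels)

    ranks = stats.rankdata(values)
    _, counts = np.unique(values, return_counts=True)
    tie = 1.0 - (counts**3 - counts).sum() / (n**3 - n)
    sizes = np.array([(labels == g).sum() for g in groups], dtype=float)

    rng = np.random.default_rng(seed)
    # permuting labels is equivalent to permuting the (fixed) rank vector
    perm_ranks = np.take_along_axis(
        np.broadcast_to(ranks, (n_perm, n)).copy(),
        rng.random((n_perm, n)).argsort(axis=1),
        axis=1,
    )
    indicator = _group_indicator(labels, groups)
    group_sums = perm_ranks @ indicator  # (n_perm, g)
    h_perm = 12.0 / (n * (n + 1)) * (group_sums**2 / sizes).sum(axis=1) - 3.0 * (n + 1)
    h_perm /= tie
    p = (1.0 + np.sum(h_perm >= h_obs - 1e-12)) / (1.0 + n_perm)
    return GroupTestResult(
        statistic=h_obs,
        p_value=float(p),
        n_permutations=n_perm,
        per_group_medians=group_medians(grouped),
        seed=seed,
    )


def _holm(pairs: list, pvals: list[float]) -> dict:
    order = np.argsort(pvals)
    m = len(pvals)
    adjusted = [0.0] * m
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvals[idx])
        adjusted[idx] = min(1.0, running)
    return dict(zip(pairs, adjusted))


def pairwise_mannwhitney(
    grouped: GroupedPowers,
    reference,
    adjust: str = "none",
) -> dict:
    """Two-sided Mann-Whitney U of a reference group against every other.

    Returns ``{(reference, other): (U, p)}`` where U counts pairs in
    which the reference value exceeds the other group's value (ties
    count one half).  Uses the tie-corrected normal approximation
    without continuity correction; ``adjust="holm"`` applies the Holm
    step-down correction to the p-values.
    """
    groups = grouped.groups
    if reference not in groups:
        raise DomainError(f"reference group {reference!r} not present")
    ref_vals = grouped.group_values(reference)
    pairs, stats_u, pvals = [], [], []
    for g in groups:
        if g == reference:
            continue
        other = grouped.group_values(g)
        if other.size < 1 or ref_vals.size < 1:
            raise DomainError("groups must be non-empty")
        res = stats.mannwhitneyu(
            ref_vals,
            other,
            alternative="two-sided",
            method="asymptotic",
            use_continuity=False,
        )
        pairs.append((reference, g))
        stats_u.append(float(res.statistic))
        pvals.append(float(res.pvalue))
    if adjust == "holm":
        adj = _holm(pairs, pvals)
        return {pair: (u, adj[pair]) for pair, u in zip(pairs, stats_u)}
    if adjust != "none":
        raise DomainError(f"unknown adjustment {adjust!r}")
    return {pair: (u, p) for pair, u, p in zip(pairs, stats_u, pvals)}
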