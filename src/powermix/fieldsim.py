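"""Simulated power distributions of hypothetical research fields.

A "field" is a population of one-sample t-test studies at a fixed sample
size whose effect sizes vary.  True effects are drawn from a Gaussian
truncated to positive values (mean 0.3 for a "low-power" field, about
50% typical power at n = 45; mean 0.49 for a "high-power" field, about
90%); null-like effects are drawn from a half-Gaussian centred at zero.
A field in which only a fraction of effects exist mixes the two, which
is what makes the resulting power histogram bimodal even when the
studies that chase real effects are well powered.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import DomainError
from .power import power_one_sample_t

__all__ = ["FieldConfig", "FieldSample", "sample_effect_sizes", "simulate_field", "summarize_field"]


@dataclass(frozen=True)
class FieldConfig:
    """Parameters of one simulated field.

    ``effect_mean``/``effect_sd`` parameterize the positive-truncated
    Gaussian of true effect sizes; ``prop_true`` is the fraction of
    studies whose effect exists (the remainder get half-Gaussian effects
    centred at zero).  In the alternative mode ``vary="n"``, the effect
    size is fixed at ``effect_mean`` and per-study sample sizes are
    drawn log-normally around ``n`` instead.
    """

    n_sim: int = 50_000
    n: int = 45
    effect_mean: float = 0.3
    effect_sd: float = 0.07
    prop_true: float = 1.0
    alpha: float = 0.05
    seed: int = 0
    vary: str = "effect"  # "effect" (default) or "n"
    n_sigma: float = 0.4  # log-normal spread of sample sizes in vary="n" mode

    def __post_init__(self) -> None:
        if self.effect_sd <= 0:
            raise DomainError("effect_sd must be > 0")
        if not (0.0 <= self.prop_true <= 1.0):
            raise DomainError("prop_true must lie in [0, 1]")
        if self.n < 2:
            raise DomainError("n must be >= 2")
        if self.vary not in ("effect", "n"):
            raise DomainError("vary must be 'effect' or 'n'")


@dataclass(frozen=True)
class FieldSample:
    effect_sizes: np.ndarray
    powers: np.ndarray
    is_true_effect: np.ndarray
    config: FieldConfig = field(repr=False)


def _truncated_normal_positive(mean, sd, size, rng) -> np.ndarray:
    """Exact rejection sampling of N(mean, sd^2) conditioned on > 0."""
    out = np.empty(size)
    pending = np.arange(size)
    while pending.size:
        draw = rng.normal(mean, sd, pending.size)
        ok = draw > 0
        out[pending[ok]] = draw[ok]
        pending = pending[~ok]
    return out


def sample_effect_sizes(config: FieldConfig, rng: np.random.Generator):
    """Draw effect sizes and their true-effect indicators.

    Returns ``(effect_sizes, is_true_effect)``; every effect is strictly
    positive.
    """
    is_true = rng.random(config.n_sim) < config.prop_true
    effects = np.abs(rng.normal(0.0, config.effect_sd, config.n_sim))
    n_true = int(is_true.sum())
    if n_true:
        effects[is_true] = _truncated_normal_positive(
            config.effect_mean, config.effect_sd, n_true, rng
        )
    return effects, is_true


def simulate_field(config: FieldConfig, rng: np.random.Generator | None = None) -> FieldSample:
    """Generate one field: per-study effects and their one-sample-t powers.

    Deterministic given ``config.seed`` (when no generator is passed).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    effects, is_true = sample_effect_sizes(config, rng)
    if config.vary == "effect":
        powers = power_one_sample_t(effects, config.n, config.alpha)
    else:
        sizes = np.maximum(
            2, np.round(rng.lognormal(np.log(config.n), config.n_sigma, config.n_sim))
        ).astype(int)
        powers = np.array(
            [
                power_one_sample_t(config.effect_mean, int(m), config.alpha)
                for m in sizes
            ]
        )
        effects = np.full(config.n_sim, config.effect_mean)
    return FieldSample(
        effect_sizes=effects, powers=np.asarray(powers), is_true_effect=is_true, config=config
    )


def summarize_field(sample: FieldSample, bins: int = 20) -> dict:
    """Histogram over [0, 1] plus median and mean power."""
    if sample.powers.size == 0:
        raise DomainError("field sample is empty")
    counts, edges = np.histogram(sample.powers, bins=bins, range=(0.0, 1.0))
    return {
        "bin_low": edges[:-1],
        "bin_high": edges[1:],
        "count": counts,
        "median_power": float(np.median(sample.powers)),
        "mean_power": float(np.mean(sample.powers)),
        "n_sim": int(sample.powers.size),
    }
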