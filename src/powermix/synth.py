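"""Synthetic catalogues with known ground truth.

Study-level designs (group sizes, base rates) behind published
meta-analysis tables are rarely printed, so analyses of per-study power
need an emulator with a known generative truth.  The generator mirrors
the structure of the built-in 49-meta-analysis catalogue: the same
subfield composition and per-meta-analysis study counts, per-subfield
effect-size laws, log-normal per-study group sizes, and a configurable
number of null meta-analyses per subfield whose pooled effect is exactly
the null value (OR = 1 or d = 0) — the mechanism that pins every such
study's power to the significance level regardless of sample size.

Default effect-size and sample-size laws were calibrated (analytically,
from the power formulas) so that median subfield powers reproduce the
qualitative ordering of the real catalogue — genetic studies lowest,
miscellaneous highest — and the overall power histogram is multimodal
with a low-power mode dominated by genetic and null studies.  This is a
calibration of the emulator, not a claim about ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .catalog import (
    Catalogue,
    EffectMeasure,
    MetaAnalysisRecord,
    StudyRecord,
    Subfield,
)
from .exceptions import ConfigurationError
from .power import se_log_or, expected_counts, study_power

__all__ = [
    "SubfieldSpec",
    "SynthConfig",
    "GroundTruth",
    "default_synth_config",
    "generate_catalogue",
    "generate_power_mixture",
]

# Per-meta-analysis study counts of the built-in catalogue, by subfield.
_TABLE_COUNTS = {
    Subfield.GENETIC: (18, 6, 4, 14, 27, 12, 6, 6, 36, 6, 53, 20, 14, 12),
    Subfield.PSYCHOLOGY: (13, 11, 56, 14, 57, 10, 11, 26),
    Subfield.TREATMENT: (6, 11, 14, 13, 8, 5, 7, 22, 2, 4, 8, 24, 10, 3, 8),
    Subfield.IMAGING: (14, 8, 11, 24, 8),
    Subfield.NEUROCHEMISTRY: (21, 17, 12),
    Subfield.MISCELLANEOUS: (12, 5, 14, 7),
}


@dataclass(frozen=True)
class SubfieldSpec:
    """Generative law of one subfield's meta-analyses.

    ``effect_location``/``effect_scale`` parameterize the effect law on
    the analysis scale: for Cohen's d, a positive-truncated
    N(location, scale^2); for ratio measures, log-normal
    (location/scale on the log-ratio scale).  ``n_median``/``n_sigma``
    give the log-normal law of per-group sample sizes; ``n_null``
    meta-analyses in the subfield get an exactly-null pooled effect.
    """

    subfield: Subfield
    studies_per_meta: tuple[int, ...]
    measure: EffectMeasure
    effect_location: float
    effect_scale: float
    n_median: float
    n_sigma: float
    n_null: int = 0
    base_rate_range: tuple[float, float] = (0.2, 0.4)

    def __post_init__(self) -> None:
        if self.n_null > len(self.studies_per_meta):
            raise ConfigurationError(
                f"{self.subfield.value}: n_null exceeds number of meta-analyses"
            )
        if self.effect_scale < 0 or self.n_sigma < 0:
            raise ConfigurationError("scales must be non-negative")
        lo, hi = self.base_rate_range
        if not (0.0 < lo <= hi < 1.0):
            raise ConfigurationError("base_rate_range must lie inside (0, 1)")

    @property
    def n_meta(self) -> int:
        return len(self.studies_per_meta)


@dataclass(frozen=True)
class SynthConfig:
    """Full generator configuration: one spec per subfield plus a seed."""

    specs: tuple[SubfieldSpec, ...]
    alpha: float = 0.05
    seed: int = 0
    # When set, a couple of printed-style inconsistencies are injected
    # (a flipped significance marker; a d-row carrying a ratio-scale CI)
    # to exercise catalogue validation.
    inject_inconsistencies: bool = False


@dataclass(frozen=True)
class GroundTruth:
    """Generative truth paired with a synthetic catalogue."""

    study_powers: np.ndarray  # aligned with catalogue.studies
    study_meta_labels: tuple[str, ...]
    true_effects: dict  # label -> effect on the printed scale
    null_labels: frozenset


def default_synth_config(seed: int = 0) -> SynthConfig:
    """Default configuration mirroring the built-in catalogue's structure.

    49 meta-analyses, 730 studies, subfield study totals
    234/198/145/65/50/38, and 7 null meta-analyses (3 genetic,
    4 treatment).
    """
    specs = (
        SubfieldSpec(
            subfield=Subfield.GENETIC,
            studies_per_meta=_TABLE_COUNTS[Subfield.GENETIC],
            measure=EffectMeasure.ODDS_RATIO,
            effect_location=np.log(1.25),
            effect_scale=0.12,
            n_median=150.0,
            n_sigma=0.5,
            n_null=3,
            base_rate_range=(0.2, 0.4),
        ),
        SubfieldSpec(
            subfield=Subfield.PSYCHOLOGY,
            studies_per_meta=_TABLE_COUNTS[Subfield.PSYCHOLOGY],
            measure=EffectMeasure.COHENS_D,
            effect_location=0.55,
            effect_scale=0.25,
            n_median=28.0,
            n_sigma=0.5,
        ),
        SubfieldSpec(
            subfield=Subfield.TREATMENT,
            studies_per_meta=_TABLE_COUNTS[Subfield.TREATMENT],
            measure=EffectMeasure.ODDS_RATIO,
            effect_location=np.log(0.6),
            effect_scale=0.12,
            n_median=70.0,
            n_sigma=0.5,
            n_null=4,
            base_rate_range=(0.25, 0.45),
        ),
        SubfieldSpec(
            subfield=Subfield.IMAGING,
            studies_per_meta=_TABLE_COUNTS[Subfield.IMAGING],
            measure=EffectMeasure.COHENS_D,
            effect_location=0.50,
            effect_scale=0.15,
            n_median=20.0,
            n_sigma=0.4,
        ),
        SubfieldSpec(
            subfield=Subfield.NEUROCHEMISTRY,
            studies_per_meta=_TABLE_COUNTS[Subfield.NEUROCHEMISTRY],
            measure=EffectMeasure.COHENS_D,
            effect_location=0.50,
            effect_scale=0.12,
            n_median=40.0,
            n_sigma=0.4,
        ),
        SubfieldSpec(
            subfield=Subfield.MISCELLANEOUS,
            studies_per_meta=_TABLE_COUNTS[Subfield.MISCELLANEOUS],
            measure=EffectMeasure.ODDS_RATIO,
            effect_location=np.log(2.5),
            effect_scale=0.20,
            n_median=80.0,
            n_sigma=0.5,
            base_rate_range=(0.25, 0.4),
        ),
    )
    return SynthConfig(specs=specs, seed=seed)


def _draw_effect(spec: SubfieldSpec, rng: np.random.Generator) -> float:
    """Meta-analytic effect on the printed scale (d, or ratio > 0)."""
    if spec.measure is EffectMeasure.COHENS_D:
        while True:
            d = rng.normal(spec.effect_location, spec.effect_scale)
            if d > 0:
                return float(d)
    return float(np.exp(rng.normal(spec.effect_location, spec.effect_scale)))


def _study_information(
    measure: EffectMeasure, effect: float, n1: int, n2: int, base_rate: float | None
) -> float:
    """Approximate Fisher information of one study about the pooled effect
    (inverse variance on the analysis scale)."""
    if measure is EffectMeasure.COHENS_D:
        return n1 * n2 / (n1 + n2)
    if measure is EffectMeasure.ODDS_RATIO:
        se = se_log_or(expected_counts(base_rate, effect, n1, n2))
        return 1.0 / se**2
    p1 = min(effect * base_rate, 0.99)
    var = (1.0 - p1) / (n1 * p1) + (1.0 - base_rate) / (n2 * base_rate)
    return 1.0 / var


def generate_catalogue(
    config: SynthConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[Catalogue, GroundTruth]:
    """Generate a synthetic catalogue with studies and its ground truth.

    Which meta-analyses are null is drawn at random within each subfield.
    CIs are synthesized from the pooled effect with a normal
    approximation on the analysis scale, using the summed per-study
    information; the significance marker is then set from whether the CI
    excludes the null, so markers and CIs are internally consistent
    unless ``inject_inconsistencies`` is on.  True per-study powers are
    computed through the same dispatch used by the analysis pipeline.
    """
    if config is None:
        config = default_synth_config()
    if rng is None:
        rng = np.random.default_rng(config.seed)

    records: list[MetaAnalysisRecord] = []
    studies: list[StudyRecord] = []
    powers: list[float] = []
    true_effects: dict = {}
    null_labels: set = set()

    for spec in config.specs:
        null_idx = set(
            rng.choice(spec.n_meta, size=spec.n_null, replace=False).tolist()
        )
        for i, n_studies in enumerate(spec.studies_per_meta):
            label = f"{spec.subfield.value}-{i + 1:02d}"
            is_null = i in null_idx
            if is_null:
                effect = spec.measure.null_value
                null_labels.add(label)
            else:
                effect = _draw_effect(spec, rng)
            true_effects[label] = effect

            base_rate = None
            if spec.measure.is_ratio:
                lo, hi = spec.base_rate_range
                base_rate = float(rng.uniform(lo, hi))

            meta_studies = []
            info = 0.0
            for _ in range(n_studies):
                n1 = int(max(2, round(rng.lognormal(np.log(spec.n_median), spec.n_sigma))))
                n2 = int(max(2, round(rng.lognormal(np.log(spec.n_median), spec.n_sigma))))
                meta_studies.append(
                    StudyRecord(
                        meta_label=label, n_group1=n1, n_group2=n2, base_rate=base_rate
                    )
                )
                info += _study_information(
                    spec.measure, max(effect, 1e-6) if spec.measure.is_ratio else effect,
                    n1, n2, base_rate,
                )

            se = 1.0 / np.sqrt(info)
            if spec.measure.is_ratio:
                center = np.log(effect) if effect > 0 else 0.0
                ci_low = float(np.exp(center - 1.96 * se))
                ci_high = float(np.exp(center + 1.96 * se))
                significant = ci_low > 1.0 or ci_high < 1.0
            else:
                ci_low = float(effect - 1.96 * se)
                ci_high = float(effect + 1.96 * se)
                significant = ci_low > 0.0 or ci_high < 0.0

            record = MetaAnalysisRecord(
                label=label,
                n_studies=n_studies,
                measure=spec.measure,
                effect_size=float(effect),
                ci_low=ci_low,
                ci_high=ci_high,
                significant=significant,
                subfield=spec.subfield,
            )
            records.append(record)
            for s in meta_studies:
                studies.append(s)
                powers.append(study_power(s, record, config.alpha))
            if not significant:
                null_labels.add(label)

    if config.inject_inconsistencies:
        records = _inject_inconsistencies(records)

    catalogue = Catalogue(records=tuple(records), studies=tuple(studies))
    truth = GroundTruth(
        study_powers=np.array(powers),
        study_meta_labels=tuple(s.meta_label for s in studies),
        true_effects=true_effects,
        null_labels=frozenset(null_labels),
    )
    return catalogue, truth


def _inject_inconsistencies(records: list[MetaAnalysisRecord]) -> list[MetaAnalysisRecord]:
    out = list(records)
    flipped = False
    ratio_ci = False
    for i, r in enumerate(out):
        if not flipped and r.significant:
            out[i] = replace(r, significant=False)
            flipped = True
        elif not ratio_ci and r.measure is EffectMeasure.COHENS_D and r.effect_size > 0:
            # a printed-style mishap: negative d carrying a ratio-scale CI
            out[i] = replace(r, effect_size=-r.effect_size, ci_low=0.83, ci_high=1.08)
            ratio_ci = True
        if flipped and ratio_ci:
            break
    return out


def generate_power_mixture(
    weights,
    means,
    sds,
    n: int,
    rng: np.random.Generator | None = None,
):
    """Labelled draws from a Gaussian mixture truncated to (0, 1].

    A fixture for mixture-recovery experiments: component labels are
    returned alongside the values, and draws falling outside (0, 1] are
    redrawn (exact truncation).
    """
    weights = np.asarray(weights, dtype=float)
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    if not (weights.size == means.size == sds.size):
        raise ConfigurationError("weights, means and sds must have equal length")
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ConfigurationError("weights must sum to 1")
    if np.any(sds <= 0):
        raise ConfigurationError("sds must be > 0")
    if rng is None:
        rng = np.random.default_rng(0)
    labels = rng.choice(weights.size, size=n, p=weights)
    values = rng.normal(means[labels], sds[labels])
    bad = np.flatnonzero((values <= 0.0) | (values > 1.0))
    while bad.size:
        values[bad] = rng.normal(means[labels[bad]], sds[labels[bad]])
        bad = bad[(values[bad] <= 0.0) | (values[bad] > 1.0)]
    return values, labels
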