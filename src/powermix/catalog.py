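"""Data model and tabular I/O for meta-analysis catalogues.

A *catalogue* is an ordered collection of meta-analysis records — one per
pooled effect estimate — optionally accompanied by study-level design
records (group sizes and, for binary outcomes, the control-group base
rate).  The built-in catalogue packages 49 neuroscience meta-analyses
covering 730 primary studies, classified into six methodological
subfields.

CSV schema (UTF-8, header row)
------------------------------
Catalogue file::

    label,n_studies,measure,effect,ci_low,ci_high,significant,subfield

with ``measure`` one of ``d|or|rr`` and ``significant`` ``0|1``.

Studies file::

    meta_label,n_group1,n_group2,base_rate

``base_rate`` is blank for Cohen's-d studies.
"""

from __future__ import annotations


from collections import Counter
from dataclasses import dataclass, replace
from enum import Enum
from typing import Iterable, Mapping, Sequence

import pandas as pd

from . import _table1
from .exceptions import DomainError, ParseError, SchemaError

__all__ = [
    "EffectMeasure",
    "Subfield",
    "MetaAnalysisRecord",
    "StudyRecord",
    "Catalogue",
    "ValidationIssue",
    "ValidationReport",
    "load_builtin_catalogue",
    "read_catalogue",
    "write_catalogue",
    "read_studies",
    "write_studies",
    "validate_catalogue",
    "null_meta_analyses",
    "subfield_totals",
    "APOE_LABEL",
    "QT_LABEL",
]

APOE_LABEL = _table1.APOE_LABEL
QT_LABEL = _table1.QT_LABEL


class EffectMeasure(str, Enum):
    """Effect-size measure of a meta-analysis."""

    COHENS_D = "d"
    ODDS_RATIO = "or"
    RELATIVE_RISK = "rr"

    @property
    def is_ratio(self) -> bool:
        """True for ratio-scale measures (odds ratio, relative risk)."""
        return self is not EffectMeasure.COHENS_D

    @property
    def null_value(self) -> float:
        """The no-effect value on the measure's scale (0 for d, 1 for ratios)."""
        return 1.0 if self.is_ratio else 0.0


class Subfield(str, Enum):
    """Methodological subfield of a meta-analysis."""

    GENETIC = "genetic"
    PSYCHOLOGY = "psychology"
    TREATMENT = "treatment"
    IMAGING = "imaging"
    NEUROCHEMISTRY = "neurochemistry"
    MISCELLANEOUS = "miscellaneous"


@dataclass(frozen=True)
class MetaAnalysisRecord:
    """One meta-analysis: pooled effect, CI, significance marker, subfield.

    The significance marker is taken from the source catalogue as printed
    and is never recomputed from the CI; see :func:`validate_catalogue`.
    """

    label: str
    n_studies: int
    measure: EffectMeasure
    effect_size: float
    ci_low: float
    ci_high: float
    significant: bool
    subfield: Subfield

    def __post_init__(self) -> None:
        if self.n_studies < 1:
            raise DomainError(f"{self.label}: n_studies must be >= 1")
        if self.ci_low > self.ci_high:
            raise DomainError(f"{self.label}: ci_low > ci_high")
        if self.measure.is_ratio and self.effect_size <= 0:
            raise DomainError(f"{self.label}: ratio effect must be > 0")

    @property
    def is_null(self) -> bool:
        """True when the pooled effect was not significant (null meta-analysis)."""
        return not self.significant


@dataclass(frozen=True)
class StudyRecord:
    """One primary study's design, linked to its meta-analysis by label."""

    meta_label: str
    n_group1: int
    n_group2: int
    base_rate: float | None = None

    def __post_init__(self) -> None:
        if self.n_group1 < 1 or self.n_group2 < 1:
            raise DomainError(f"{self.meta_label}: group sizes must be >= 1")
        if self.base_rate is not None and not (0.0 < self.base_rate < 1.0):
            raise DomainError(f"{self.meta_label}: base_rate must lie in (0, 1)")


@dataclass(frozen=True)
class Catalogue:
    """Ordered meta-analysis records with optional study-level records."""

    records: tuple[MetaAnalysisRecord, ...]
    studies: tuple[StudyRecord, ...] | None = None

    def __post_init__(self) -> None:
        labels = [r.label for r in self.records]
        dupes = [l for l, c in Counter(labels).items() if c > 1]
        if dupes:
            raise DomainError(f"duplicate labels in catalogue: {dupes}")
        if self.studies is not None:
            known = set(labels)
            for s in self.studies:
                if s.meta_label not in known:
                    raise DomainError(
                        f"study refers to unknown meta-analysis {s.meta_label!r}"
                    )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(r.label for r in self.records)

    def record(self, label: str) -> MetaAnalysisRecord:
        for r in self.records:
            if r.label == label:
                return r
        raise KeyError(label)

    @property
    def n_studies_total(self) -> int:
        """Sum of per-meta-analysis study counts."""
        return sum(r.n_studies for r in self.records)

    def studies_for(self, label: str) -> tuple[StudyRecord, ...]:
        if self.studies is None:
            return ()
        return tuple(s for s in self.studies if s.meta_label == label)

    def with_studies(self, studies: Iterable[StudyRecord]) -> "Catalogue":
        return replace(self, studies=tuple(studies))

    def to_frame(self) -> pd.DataFrame:
        """Catalogue records as a DataFrame in the documented CSV schema."""
        return pd.DataFrame(
            {
                "label": [r.label for r in self.records],
                "n_studies": [r.n_studies for r in self.records],
                "measure": [r.measure.value for r in self.records],
                "effect": [r.effect_size for r in self.records],
                "ci_low": [r.ci_low for r in self.records],
                "ci_high": [r.ci_high for r in self.records],
                "significant": [int(r.significant) for r in self.records],
                "subfield": [r.subfield.value for r in self.records],
            }
        )

    def studies_frame(self) -> pd.DataFrame:
        if self.studies is None:
            raise DomainError("catalogue has no study records")
        return pd.DataFrame(
            {
                "meta_label": [s.meta_label for s in self.studies],
                "n_group1": [s.n_group1 for s in self.studies],
                "n_group2": [s.n_group2 for s in self.studies],
                "base_rate": [s.base_rate for s in self.studies],
            }
        )


@dataclass(frozen=True)
class ValidationIssue:
    label: str
    kind: str
    message: str


@dataclass(frozen=True)
class ValidationReport:
    """Outcome of :func:`validate_catalogue`; empty issues means all checks pass."""

    issues: tuple[ValidationIssue, ...]

    @property
    def counts(self) -> Mapping[str, int]:
        return dict(Counter(i.kind for i in self.issues))

    @property
    def ok(self) -> bool:
        return not self.issues


def load_builtin_catalogue() -> Catalogue:
    """Return the packaged 49-row catalogue (no study records attached).

    The rows are preserved exactly as printed in the source table,
    including its internal inconsistencies; repeated calls return equal
    catalogues.
    """
    records = tuple(
        MetaAnalysisRecord(
            label=label,
            n_studies=n,
            measure=EffectMeasure(measure),
            effect_size=eff,
            ci_low=lo,
            ci_high=hi,
            significant=sig,
            subfield=Subfield(sub),
        )
        for (label, n, measure, eff, lo, hi, sig, sub) in _table1.ROWS
    )
    return Catalogue(records=records)


_CATALOGUE_COLUMNS = (
    "label",
    "n_studies",
    "measure",
    "effect",
    "ci_low",
    "ci_high",
    "significant",
    "subfield",
)
_STUDY_COLUMNS = ("meta_label", "n_group1", "n_group2", "base_rate")


def _float(raw: str, column: str, row: int) -> float:
    try:
        return float(raw)
    except (TypeError, ValueError):
        raise ParseError(f"row {row}: non-numeric {column} {raw!r}") from None


def _int(raw: str, column: str, row: int) -> int:
    try:
        return int(raw)
    except (TypeError, ValueError):
        raise ParseError(f"row {row}: non-integer {column} {raw!r}") from None


def read_catalogue(source) -> Catalogue:
    """Parse a catalogue CSV (path, or any pandas-readable buffer).

    Raises :class:`SchemaError` when a required column is missing and
    :class:`ParseError` (naming the row) when a cell cannot be parsed.
    """
    frame = pd.read_csv(source, dtype=str)
    missing = [c for c in _CATALOGUE_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"catalogue file missing column(s): {', '.join(missing)}")
    records = []
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        measure_raw = str(row.measure).strip().lower()
        try:
            measure = EffectMeasure(measure_raw)
        except ValueError:
            raise ParseError(f"row {i}: unknown effect measure {row.measure!r}") from None
        try:
            subfield = Subfield(str(row.subfield).strip().lower())
        except ValueError:
            raise ParseError(f"row {i}: unknown subfield {row.subfield!r}") from None
        lo = _float(row.ci_low, "ci_low", i)
        hi = _float(row.ci_high, "ci_high", i)
        # tolerate reversed printed ranges like "-0.97 to -1.25"
        lo, hi = min(lo, hi), max(lo, hi)
        records.append(
            MetaAnalysisRecord(
                label=str(row.label),
                n_studies=_int(row.n_studies, "n_studies", i),
                measure=measure,
                effect_size=_float(row.effect, "effect", i),
                ci_low=lo,
                ci_high=hi,
                significant=bool(_int(row.significant, "significant", i)),
                subfield=subfield,
            )
        )
    return Catalogue(records=tuple(records))


def write_catalogue(catalogue: Catalogue, target) -> None:
    """Write a catalogue to CSV in the same dialect ``read_catalogue`` accepts."""
    catalogue.to_frame().to_csv(target, index=False)


def read_studies(source, catalogue: Catalogue | None = None) -> tuple[StudyRecord, ...]:
    """Parse a studies CSV; when a catalogue is given, attach nothing — just
    check that every ``meta_label`` resolves."""
    frame = pd.read_csv(source, dtype=str)
    missing = [c for c in _STUDY_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"studies file missing column(s): {', '.join(missing)}")
    studies = []
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        base = row.base_rate
        base_rate = None if (base is None or str(base).strip() in ("", "nan")) else _float(base, "base_rate", i)
        studies.append(
            StudyRecord(
                meta_label=str(row.meta_label),
                n_group1=_int(row.n_group1, "n_group1", i),
                n_group2=_int(row.n_group2, "n_group2", i),
                base_rate=base_rate,
            )
        )
    if catalogue is not None:
        known = set(catalogue.labels)
        for s in studies:
            if s.meta_label not in known:
                raise SchemaError(f"study refers to unknown meta-analysis {s.meta_label!r}")
    return tuple(studies)


def write_studies(studies: Sequence[StudyRecord], target) -> None:
    frame = pd.DataFrame(
        {
            "meta_label": [s.meta_label for s in studies],
            "n_group1": [s.n_group1 for s in studies],
            "n_group2": [s.n_group2 for s in studies],
            "base_rate": [s.base_rate for s in studies],
        }
    )
    frame.to_csv(target, index=False)


def _ci_excludes_null(record: MetaAnalysisRecord) -> bool:
    null = record.measure.null_value
    return record.ci_low > null or record.ci_high < null


def validate_catalogue(catalogue: Catalogue) -> ValidationReport:
    """Report (without fixing) internal inconsistencies of a catalogue.

    Three kinds of issue are flagged:

    ``scale_mismatch``
        a Cohen's-d record whose CI appears to live on a ratio scale
        (entirely above 0.5 with sign opposite to the effect, or vice
        versa) — the CI cannot belong to the printed effect;
    ``significance_mismatch``
        the CI excludes the measure's null value while the record is
        marked non-significant, or spans the null while marked
        significant (scale-mismatched rows are skipped: their CI is not
        interpretable on the effect's scale);
    ``study_count_mismatch``
        attached study records do not sum to ``n_studies``.
    """
    issues: list[ValidationIssue] = []
    for r in catalogue.records:
        scale_mismatch = False
        if r.measure is EffectMeasure.COHENS_D:
            if (r.effect_size < 0 and r.ci_low > 0.5) or (
                r.effect_size > 0 and r.ci_high < -0.5
            ):
                scale_mismatch = True
                issues.append(
                    ValidationIssue(
                        r.label,
                        "scale_mismatch",
                        f"d = {r.effect_size} but CI {r.ci_low}-{r.ci_high} "
                        "appears to be on a ratio scale",
                    )
                )
        if not scale_mismatch:
            excludes = _ci_excludes_null(r)
            if excludes and not r.significant:
                issues.append(
                    ValidationIssue(
                        r.label,
                        "significance_mismatch",
                        "CI excludes the null but the record is marked non-significant",
                    )
                )
            elif not excludes and r.significant:
                issues.append(
                    ValidationIssue(
                        r.label,
                        "significance_mismatch",
                        "CI spans the null but the record is marked significant",
                    )
                )
    if catalogue.studies is not None:
        counts = Counter(s.meta_label for s in catalogue.studies)
        for r in catalogue.records:
            if counts.get(r.label, 0) != r.n_studies:
                issues.append(
                    ValidationIssue(
                        r.label,
                        "study_count_mismatch",
                        f"{counts.get(r.label, 0)} study records vs n_studies = {r.n_studies}",
                    )
                )
    return ValidationReport(issues=tuple(issues))


def null_meta_analyses(catalogue: Catalogue, complement: bool = False) -> Catalogue:
    """Subset of meta-analyses whose pooled effect was non-significant.

    With ``complement=True`` return the significant ("non-null") subset
    instead.  Attached study records follow their meta-analysis.
    """
    keep = [r for r in catalogue.records if r.is_null != complement]
    labels = {r.label for r in keep}
    studies = None
    if catalogue.studies is not None:
        studies = tuple(s for s in catalogue.studies if s.meta_label in labels)
    return Catalogue(records=tuple(keep), studies=studies)


def subfield_totals(catalogue: Catalogue) -> dict[Subfield, int]:
    """Per-subfield sums of study counts; values sum to the catalogue total."""
    totals: dict[Subfield, int] = {}
    for r in catalogue.records:
        totals[r.subfield] = totals.get(r.subfield, 0) + r.n_studies
    return totals
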