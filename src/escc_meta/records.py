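"""Study-level association records and their delimited-file plumbing.

The atom of every downstream computation is a per-study odds ratio with its
95% confidence interval, reported under either an additive genotype contrast
(minor-allele homozygotes vs. major-allele homozygotes) or an allelic
(per-allele) contrast.  Published ORs are converted to the log scale, with
the standard error recovered from the CI width, before any pooling.

The module also ships the curated study table of the ALDH2/ADH1B–ESCC
evidence base as a package fixture, together with the per-analysis study-set
membership needed to reproduce the published pooled estimates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Callable, Iterable, Sequence

import pandas as pd

__all__ = [
    "Z_95",
    "ValidationError",
    "SchemaError",
    "StudyRecord",
    "EffectEstimate",
    "AnalysisSet",
    "or_ci_to_effect",
    "effect_from_record",
    "load_studies",
    "write_studies",
    "table1_fixture",
]

#: Two-sided 95% normal quantile.  Kept at full precision rather than the
#: conventional 1.96 so that CI reconstruction round-trips exactly.
Z_95 = 1.959964

DESIGNS = frozenset({"population_case_control", "hospital_case_control", "gwas"})
ETHNICITIES = frozenset({"Asian", "African", "other"})
GENES = frozenset({"ALDH2", "ADH1B"})
MODELS = frozenset({"additive", "allelic"})

STUDY_FIELDS = [
    "study_id", "year", "design", "country", "ethnicity", "gene", "variant",
    "n_cases", "n_controls", "model", "or_point", "ci_low", "ci_high",
]


class ValidationError(ValueError):
    """A record or value violates a domain invariant."""


class SchemaError(ValueError):
    """An input table does not carry the expected columns."""


@dataclass(frozen=True)
class EffectEstimate:
    """A (log odds ratio, standard error) pair."""

    log_or: float
    se: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.log_or)):
            raise ValidationError(f"log_or must be finite, got {self.log_or}")
        if not (math.isfinite(self.se) and self.se > 0):
            raise ValidationError(f"se must be a positive finite real, got {self.se}")


@dataclass(frozen=True)
class StudyRecord:
    """One study-level association estimate (one row of the evidence table)."""

    study_id: str
    year: int
    design: str
    country: str
    ethnicity: str
    gene: str
    variant: str
    n_cases: int
    n_controls: int
    model: str
    or_point: float
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if self.design not in DESIGNS:
            raise ValidationError(f"design must be one of {sorted(DESIGNS)}, got {self.design!r}")
        if self.ethnicity not in ETHNICITIES:
            raise ValidationError(f"ethnicity must be one of {sorted(ETHNICITIES)}, got {self.ethnicity!r}")
        if self.gene not in GENES:
            raise ValidationError(f"gene must be one of {sorted(GENES)}, got {self.gene!r}")
        if self.model not in MODELS:
            raise ValidationError(f"model must be one of {sorted(MODELS)}, got {self.model!r}")
        if self.n_cases < 1:
            raise ValidationError(f"n_cases must be >= 1, got {self.n_cases}")
        if self.n_controls < 1:
            raise ValidationError(f"n_controls must be >= 1, got {self.n_controls}")
        for name in ("or_point", "ci_low", "ci_high"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValidationError(f"{name} must be strictly positive, got {v}")
        if not (self.ci_low <= self.or_point <= self.ci_high):
            raise ValidationError(
                f"or_point must lie inside its CI: ci_low={self.ci_low}, "
                f"or_point={self.or_point}, ci_high={self.ci_high}"
            )

    @property
    def key(self) -> tuple[str, str, str, str]:
        return (self.study_id, self.gene, self.variant, self.model)


@dataclass(frozen=True)
class AnalysisSet:
    """Membership of one pooled analysis: which studies contribute which effect.

    ``minor_major``, subject totals, and the amount-of-evidence letter are
    analysis-level metadata carried through to reporting; the published
    per-analysis minor-allele counts behind the amount letter are not
    recoverable from study-level ORs, so the letter is data, not inference.
    """

    gene: str
    variant: str
    model: str
    study_ids: tuple[str, ...]
    minor_major: str = ""
    n_cases: int | None = None
    n_controls: int | None = None
    amount_grade: str | None = None

    def __post_init__(self) -> None:
        if not self.study_ids:
            raise ValidationError("study_ids must be nonempty")
        if len(set(self.study_ids)) != len(self.study_ids):
            raise ValidationError("study_ids must be unique")
        if self.model not in MODELS:
            raise ValidationError(f"model must be one of {sorted(MODELS)}, got {self.model!r}")

    @property
    def label(self) -> str:
        return f"{self.gene} {self.variant} ({self.model})"

    def resolve(self, records: Sequence[StudyRecord]) -> list[StudyRecord]:
        """Return the member records, in membership order.

        Raises :class:`ValidationError` if any member study is missing from
        ``records`` for this (gene, variant, model).
        """
        index = {
            r.study_id: r
            for r in records
            if r.gene == self.gene and r.variant == self.variant and r.model == self.model
        }
        missing = [s for s in self.study_ids if s not in index]
        if missing:
            raise ValidationError(
                f"analysis set {self.label}: member studies not found: {missing}"
            )
        return [index[s] for s in self.study_ids]


def or_ci_to_effect(or_point: float, ci_low: float, ci_high: float) -> EffectEstimate:
    """Convert an odds ratio with 95% CI to a log-OR and standard error.

    ``se = (ln ci_high − ln ci_low) / (2 · 1.959964)``, i.e. the CI is assumed
    to be a symmetric-on-the-log-scale Wald interval.
    """
    for name, v in (("or_point", or_point), ("ci_low", ci_low), ("ci_high", ci_high)):
        if not (math.isfinite(v) and v > 0):
            raise ValidationError(f"{name} must be strictly positive, got {v}")
    if ci_low == ci_high:
        raise ValidationError(f"zero-width interval: ci_low == ci_high == {ci_low}")
    if not (ci_low <= or_point <= ci_high):
        raise ValidationError(
            f"or_point outside its CI: ci_low={ci_low}, or_point={or_point}, ci_high={ci_high}"
        )
    return EffectEstimate(
        log_or=math.log(or_point),
        se=(math.log(ci_high) - math.log(ci_low)) / (2.0 * Z_95),
    )


def effect_from_record(record: StudyRecord) -> EffectEstimate:
    return or_ci_to_effect(record.or_point, record.ci_low, record.ci_high)


def _records_from_frame(df: pd.DataFrame, source: str) -> list[StudyRecord]:
    missing = [c for c in STUDY_FIELDS if c not in df.columns]
    if missing:
        raise SchemaError(f"{source}: missing columns {missing}")
    records: list[StudyRecord] = []
    errors: list[str] = []
    seen: set[tuple[str, str, str, str]] = set()
    for pos, row in enumerate(df.itertuples(index=False), start=2):  # header is row 1
        try:
            rec = StudyRecord(
                study_id=str(row.study_id),
                year=int(row.year),
                design=str(row.design),
                country=str(row.country),
                ethnicity=str(row.ethnicity),
                gene=str(row.gene),
                variant=str(row.variant),
                n_cases=int(row.n_cases),
                n_controls=int(row.n_controls),
                model=str(row.model),
                or_point=float(row.or_point),
                ci_low=float(row.ci_low),
                ci_high=float(row.ci_high),
            )
            if rec.key in seen:
                raise ValidationError(f"duplicate (study_id, gene, variant, model) {rec.key}")
            seen.add(rec.key)
            records.append(rec)
        except (ValidationError, ValueError) as exc:
            sid = getattr(row, "study_id", "?")
            errors.append(f"row {pos} (study_id={sid}): {exc}")
    if errors:
        raise ValidationError(f"{source}: {len(errors)} invalid row(s):\n" + "\n".join(errors))
    return records


def load_studies(path: str | Path, delimiter: str = ",") -> list[StudyRecord]:
    """Load and validate study records from a delimited file.

    Every row is checked against the record invariants; offending rows are
    reported with their file row number and study_id.  Input order is
    preserved.
    """
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    return _records_from_frame(df, str(path))


def write_studies(records: Iterable[StudyRecord], path: str | Path, delimiter: str = ",") -> None:
    df = pd.DataFrame([{f: getattr(r, f) for f in STUDY_FIELDS} for r in records])
    df.to_csv(path, sep=delimiter, index=False)


def _fixture_text(name: str) -> str:
    return (resources.files("escc_meta") / "data" / name).read_text(encoding="utf-8")


def table1_fixture() -> tuple[list[StudyRecord], list[AnalysisSet]]:
    """The packaged ALDH2/ADH1B–ESCC evidence table and analysis memberships.

    Returns every study-level OR of the curated evidence base (one record per
    study × gene × variant × genetic model) plus the five reconstructible
    pooled-analysis memberships.  Membership was validated by checking that
    pooling each set reproduces the published pooled OR, CI, and I².
    """
    import io

    studies = _records_from_frame(
        pd.read_csv(io.StringIO(_fixture_text("included_studies.csv")), dtype=str,
                    keep_default_na=False),
        "included_studies.csv",
    )
    sets_df = pd.read_csv(io.StringIO(_fixture_text("analysis_sets.csv")), dtype=str,
                          keep_default_na=False)
    sets = [
        AnalysisSet(
            gene=row.gene,
            variant=row.variant,
            model=row.model,
            study_ids=tuple(row.study_ids.split(";")),
            minor_major=row.minor_major,
            n_cases=int(row.n_cases),
            n_controls=int(row.n_controls),
            amount_grade=row.amount_grade,
        )
        for row in sets_df.itertuples(index=False)
    ]
    for s in sets:
        s.resolve(studies)  # fail loudly if the fixture is inconsistent
    return studies, sets
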