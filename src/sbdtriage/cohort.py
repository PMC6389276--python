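"""Patient-record data model for a GP-referred colonoscopy cohort.

A referred patient carries demographics (age, sex, BMI), a small blood panel
(triglycerides, glucose, magnesium, creatinine, plus optional extra markers),
two stool tests (faecal haemoglobin / FIT, binarized at any detectable level,
and faecal calprotectin), the referral symptoms, the triage category assigned
by the consultant (1 most urgent .. 3 least urgent), and — once colonoscopy is
done — the histology findings.

Histology is collapsed to a single binary outcome, *significant bowel disease*
(SBD): colorectal cancer, a high-risk adenoma (>= 10 mm, >= 3 at procedure,
villous component or high-grade dysplasia), or IBD.  Everything else (small or
few adenomas, hyperplastic polyps, low-grade dysplasia only, a normal
colonoscopy) is non-SBD.

Continuous markers are reduced to ordinal categories (low / normal / high)
against per-marker reference ranges before any association testing.  Missing
values are carried as ``None`` and surfaced explicitly — never imputed.
"""

from __future__ import annotations

import csv
import enum
import math
import tomllib
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from .errors import CohortParseError, MissingDataError

__all__ = [
    "SYMPTOMS",
    "BLOOD_MARKERS",
    "AgeCategory",
    "BmiCategory",
    "OrdinalCategory",
    "ReferenceRange",
    "HistologyFindings",
    "PatientRecord",
    "classify_sbd",
    "categorize_value",
    "categorize_age",
    "categorize_bmi",
    "default_reference_ranges",
    "load_reference_ranges",
    "read_cohort",
    "write_cohort",
    "COHORT_COLUMNS",
]

#: Referral symptoms recorded on the GP letter, in CSV column order.
SYMPTOMS: tuple[str, ...] = (
    "altered_bowel_habit",
    "rectal_bleeding",
    "diarrhoea",
    "abdominal_pain",
    "iron_deficiency_anaemia",
)

#: The four blood markers scored by the Blood Risk Score, in panel order.
BLOOD_MARKERS: tuple[str, ...] = ("triglycerides", "glucose", "magnesium", "creatinine")

#: Age threshold (years) splitting the cohort into younger/older strata.
AGE_CUTOFF = 65

#: Study age eligibility window (inclusive).
AGE_MIN, AGE_MAX = 20, 85


class OrdinalCategory(enum.Enum):
    """Ordinal level of a continuous marker against its reference range."""

    LOW = "low"
    NORMAL = "normal"
    HIGH = "high"


class AgeCategory(enum.Enum):
    YOUNGER = "younger"
    OLDER = "older"


class BmiCategory(enum.Enum):
    UNDERWEIGHT = "underweight"
    NORMAL = "normal"
    OVERWEIGHT = "overweight"
    OBESE = "obese"
    MORBIDLY_OBESE = "morbidly_obese"


@dataclass(frozen=True)
class ReferenceRange:
    """A marker's normal interval and which departure counts as abnormal.

    ``low`` / ``high`` of ``None`` mean unbounded on that side.  The normal
    interval is closed: a value exactly on a bound is normal.
    ``abnormal_direction`` names the departure that is clinically scored for
    this marker ("high", "low", or "either").
    """

    marker_name: str
    low: float | None
    high: float | None
    abnormal_direction: str = "either"

    def __post_init__(self) -> None:
        if self.low is not None and self.high is not None and not self.low < self.high:
            raise ValueError(
                f"{self.marker_name}: reference range low ({self.low}) must be "
                f"strictly below high ({self.high})"
            )
        if self.abnormal_direction not in ("high", "low", "either"):
            raise ValueError(f"unknown abnormal_direction {self.abnormal_direction!r}")


@dataclass(frozen=True)
class HistologyFindings:
    """Colonoscopy/histology outcome flags for one patient.

    ``None`` marks a flag that was not reported; :func:`classify_sbd` refuses
    to classify findings whose missing flags could change the answer.
    ``hyperplastic_only`` is descriptive (hyperplastic polyps never qualify as
    SBD) and defaults to ``False``.
    """

    cancer: bool | None = None
    adenoma_count: int | None = None
    max_adenoma_size_mm: float | None = None
    villous_component: bool | None = None
    high_grade_dysplasia: bool | None = None
    ibd: bool | None = None
    hyperplastic_only: bool = False
    normal: bool = False

    def __post_init__(self) -> None:
        if self.adenoma_count is not None and self.adenoma_count < 0:
            raise ValueError("adenoma_count must be nonnegative")
        if self.max_adenoma_size_mm is not None and self.max_adenoma_size_mm < 0:
            raise ValueError("max_adenoma_size_mm must be nonnegative")
        if self.normal:
            flags = (
                self.cancer,
                self.villous_component,
                self.high_grade_dysplasia,
                self.ibd,
                self.hyperplastic_only,
            )
            if any(f for f in flags) or (self.adenoma_count or 0) != 0:
                raise ValueError("normal colonoscopy excludes every other finding")


@dataclass
class PatientRecord:
    """One referred patient; ``None`` marks a missing field."""

    patient_id: str
    age: int
    sex: str
    bmi: float | None = None
    triglycerides: float | None = None
    glucose: float | None = None
    magnesium: float | None = None
    creatinine: float | None = None
    extra_markers: dict[str, float] = field(default_factory=dict)
    fit_positive: bool | None = None
    calprotectin_high: bool | None = None
    symptoms: frozenset[str] = frozenset()
    triage_category: int | None = None
    histology: HistologyFindings | None = None

    def __post_init__(self) -> None:
        if not AGE_MIN <= self.age <= AGE_MAX:
            raise ValueError(
                f"age {self.age} outside study eligibility [{AGE_MIN}, {AGE_MAX}]"
            )
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if self.triage_category not in (None, 1, 2, 3):
            raise ValueError(f"triage_category must be 1, 2 or 3, got {self.triage_category!r}")
        unknown = set(self.symptoms) - set(SYMPTOMS)
        if unknown:
            raise ValueError(f"unknown symptoms: {sorted(unknown)}")
        self.symptoms = frozenset(self.symptoms)
        for name in ("bmi", *BLOOD_MARKERS):
            value = getattr(self, name)
            if value is not None and not value > 0:
                raise ValueError(f"{name} must be strictly positive, got {value}")

    def marker_value(self, marker: str) -> float | None:
        """Return a blood-panel value by name, searching extra markers too."""
        if marker in BLOOD_MARKERS:
            return getattr(self, marker)
        return self.extra_markers.get(marker)


def classify_sbd(h: HistologyFindings) -> bool:
    """Classify histology findings as significant bowel disease (SBD).

    SBD is cancer, a high-risk adenoma (>= 3 adenomas at procedure, largest
    adenoma >= 10 mm, villous component, or high-grade dysplasia), or IBD.
    A qualifying finding decides immediately even if other flags are missing;
    a negative answer requires every flag to be present.

    Raises
    ------
    MissingDataError
        If no finding qualifies but some flags are absent, so non-SBD cannot
        be asserted.
    """
    if h.normal:
        return False
    if h.cancer or h.villous_component or h.high_grade_dysplasia or h.ibd:
        return True
    if h.adenoma_count is not None and h.adenoma_count >= 3:
        return True
    if h.max_adenoma_size_mm is not None and h.max_adenoma_size_mm >= 10:
        return True
    required = (
        h.cancer,
        h.adenoma_count,
        h.max_adenoma_size_mm,
        h.villous_component,
        h.high_grade_dysplasia,
        h.ibd,
    )
    if any(v is None for v in required):
        raise MissingDataError(
            "histology findings incomplete: cannot rule out significant bowel disease"
        )
    return False


def categorize_value(value: float | None, range_: ReferenceRange) -> OrdinalCategory | None:
    """Place a marker value into low / normal / high against its range.

    The reference interval is closed: boundary values are normal.  A missing
    value returns ``None`` (the missing-category sentinel), never a guess.
    """
    if value is None:
        return None
    if not math.isfinite(value):
        raise ValueError(f"marker value must be finite, got {value}")
    if range_.low is not None and value < range_.low:
        return OrdinalCategory.LOW
    if range_.high is not None and value > range_.high:
        return OrdinalCategory.HIGH
    return OrdinalCategory.NORMAL


def categorize_age(age: int) -> AgeCategory:
    """Dichotomize age at 65 years; the boundary itself counts as older."""
    return AgeCategory.OLDER if age >= AGE_CUTOFF else AgeCategory.YOUNGER


def categorize_bmi(bmi: float) -> BmiCategory:
    """Assign a BMI (kg/m^2) to the study's five brackets.

    Brackets are half-open: underweight < 18, normal [18, 25), overweight
    [25, 30), obese [30, 40), morbidly obese >= 40.
    """
    if not bmi > 0:
        raise ValueError(f"bmi must be positive, got {bmi}")
    if bmi < 18:
        return BmiCategory.UNDERWEIGHT
    if bmi < 25:
        return BmiCategory.NORMAL
    if bmi < 30:
        return BmiCategory.OVERWEIGHT
    if bmi < 40:
        return BmiCategory.OBESE
    return BmiCategory.MORBIDLY_OBESE


# ---------------------------------------------------------------------------
# Reference-range configuration


def load_reference_ranges(path: str | Path) -> dict[str, ReferenceRange]:
    """Read marker reference ranges from a TOML file.

    Each table is keyed by marker name with ``low``, ``high`` (either may be
    absent, meaning unbounded) and ``abnormal_direction``.
    """
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    ranges = {}
    for name, entry in raw.items():
        ranges[name] = ReferenceRange(
            marker_name=name,
            low=entry.get("low"),
            high=entry.get("high"),
            abnormal_direction=entry.get("abnormal_direction", "either"),
        )
    return ranges


def default_reference_ranges() -> dict[str, ReferenceRange]:
    """The four Blood-Risk-Score marker ranges shipped with the package.

    Triglycerides abnormal when high (> 1.5 mmol/L); glucose high
    (normal 3.0-7.8 mmol/L); magnesium low (normal 0.7-1.1 mmol/L);
    creatinine low (normal 64-108 umol/L).
    """
    ref = resources.files("sbdtriage") / "data" / "reference_ranges.toml"
    with resources.as_file(ref) as path:
        return load_reference_ranges(path)


# ---------------------------------------------------------------------------
# Cohort CSV input/output

#: Exact column order of the cohort CSV interchange format.
COHORT_COLUMNS: tuple[str, ...] = (
    "patient_id",
    "age",
    "sex",
    "bmi",
    "triglycerides",
    "glucose",
    "magnesium",
    "creatinine",
    "fit_positive",
    "calprotectin_high",
    "sym_altered_bowel_habit",
    "sym_rectal_bleeding",
    "sym_diarrhoea",
    "sym_abdominal_pain",
    "sym_ida",
    "triage_category",
    "hist_cancer",
    "hist_adenoma_count",
    "hist_max_adenoma_mm",
    "hist_villous",
    "hist_hgd",
    "hist_ibd",
    "hist_normal",
)

_SYM_COLUMNS = {
    "sym_altered_bowel_habit": "altered_bowel_habit",
    "sym_rectal_bleeding": "rectal_bleeding",
    "sym_diarrhoea": "diarrhoea",
    "sym_abdominal_pain": "abdominal_pain",
    "sym_ida": "iron_deficiency_anaemia",
}

#: Extra blood markers round-trip through columns named ``marker_<name>``.
_EXTRA_MARKER_PREFIX = "marker_"

_HIST_COLUMNS = (
    "hist_cancer",
    "hist_adenoma_count",
    "hist_max_adenoma_mm",
    "hist_villous",
    "hist_hgd",
    "hist_ibd",
    "hist_normal",
)


def _fmt_bool(v: bool | None) -> str:
    return "" if v is None else str(int(v))


def _fmt_num(v: float | int | None) -> str:
    if v is None:
        return ""
    return repr(v) if isinstance(v, float) else str(v)


def _parse_bool(text: str, row: int, col: str) -> bool | None:
    if text == "":
        return None
    if text in ("0", "1"):
        return text == "1"
    raise CohortParseError(f"row {row}: column {col!r}: expected 0/1 or empty, got {text!r}")


def _parse_float(text: str, row: int, col: str) -> float | None:
    if text == "":
        return None
    try:
        return float(text)
    except ValueError:
        raise CohortParseError(f"row {row}: column {col!r}: not a number: {text!r}") from None


def _parse_int(text: str, row: int, col: str) -> int | None:
    if text == "":
        return None
    try:
        return int(text)
    except ValueError:
        raise CohortParseError(f"row {row}: column {col!r}: not an integer: {text!r}") from None


def write_cohort(records: Iterable[PatientRecord], path: str | Path) -> None:
    """Write records to the cohort CSV format (booleans 0/1, missing empty).

    Extra blood markers are appended as ``marker_<name>`` columns; row order
    is preserved, so write/read round-trips are lossless.
    """
    records = list(records)
    extra_names = sorted({m for r in records for m in r.extra_markers})
    header = list(COHORT_COLUMNS) + [_EXTRA_MARKER_PREFIX + m for m in extra_names]
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for r in records:
            h = r.histology
            row = [
                r.patient_id,
                str(r.age),
                r.sex,
                _fmt_num(r.bmi),
                _fmt_num(r.triglycerides),
                _fmt_num(r.glucose),
                _fmt_num(r.magnesium),
                _fmt_num(r.creatinine),
                _fmt_bool(r.fit_positive),
                _fmt_bool(r.calprotectin_high),
            ]
            for col, sym in _SYM_COLUMNS.items():
                row.append("1" if sym in r.symptoms else "0")
            row.append(_fmt_num(r.triage_category))
            if h is None:
                row.extend([""] * len(_HIST_COLUMNS))
            else:
                row.extend(
                    [
                        _fmt_bool(h.cancer),
                        _fmt_num(h.adenoma_count),
                        _fmt_num(h.max_adenoma_size_mm),
                        _fmt_bool(h.villous_component),
                        _fmt_bool(h.high_grade_dysplasia),
                        _fmt_bool(h.ibd),
                        _fmt_bool(h.normal),
                    ]
                )
            for m in extra_names:
                row.append(_fmt_num(r.extra_markers.get(m)))
            writer.writerow(row)


def read_cohort(path: str | Path) -> list[PatientRecord]:
    """Read a cohort CSV written by :func:`write_cohort` (or hand-built).

    Unknown columns are ignored with a warning; malformed numeric fields raise
    :class:`CohortParseError` naming the offending row (1-based, counting the
    header as row 1).
    """
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise CohortParseError(f"{path}: empty file")
        known = set(COHORT_COLUMNS)
        extra_cols = [c for c in reader.fieldnames if c.startswith(_EXTRA_MARKER_PREFIX)]
        unknown = [c for c in reader.fieldnames if c not in known and c not in extra_cols]
        if unknown:
            warnings.warn(f"{path}: ignoring unknown columns {unknown}", stacklevel=2)
        missing = known - set(reader.fieldnames)
        if missing:
            raise CohortParseError(f"{path}: missing required columns {sorted(missing)}")
        records = []
        for i, raw in enumerate(reader):
            rownum = i + 2  # header is row 1
            age = _parse_int(raw["age"], rownum, "age")
            if age is None:
                raise CohortParseError(f"row {rownum}: age is required")
            symptoms = frozenset(
                sym for col, sym in _SYM_COLUMNS.items() if _parse_bool(raw[col], rownum, col)
            )
            hist_raw = {c: raw[c] for c in _HIST_COLUMNS}
            if all(v == "" for v in hist_raw.values()):
                histology = None
            else:
                histology = HistologyFindings(
                    cancer=_parse_bool(hist_raw["hist_cancer"], rownum, "hist_cancer"),
                    adenoma_count=_parse_int(
                        hist_raw["hist_adenoma_count"], rownum, "hist_adenoma_count"
                    ),
                    max_adenoma_size_mm=_parse_float(
                        hist_raw["hist_max_adenoma_mm"], rownum, "hist_max_adenoma_mm"
                    ),
                    villous_component=_parse_bool(hist_raw["hist_villous"], rownum, "hist_villous"),
                    high_grade_dysplasia=_parse_bool(hist_raw["hist_hgd"], rownum, "hist_hgd"),
                    ibd=_parse_bool(hist_raw["hist_ibd"], rownum, "hist_ibd"),
                    normal=bool(_parse_bool(hist_raw["hist_normal"], rownum, "hist_normal")),
                )
            extra = {}
            for col in extra_cols:
                value = _parse_float(raw[col], rownum, col)
                if value is not None:
                    extra[col[len(_EXTRA_MARKER_PREFIX) :]] = value
            try:
                record = PatientRecord(
                    patient_id=raw["patient_id"],
                    age=age,
                    sex=raw["sex"],
                    bmi=_parse_float(raw["bmi"], rownum, "bmi"),
                    triglycerides=_parse_float(raw["triglycerides"], rownum, "triglycerides"),
                    glucose=_parse_float(raw["glucose"], rownum, "glucose"),
                    magnesium=_parse_float(raw["magnesium"], rownum, "magnesium"),
                    creatinine=_parse_float(raw["creatinine"], rownum, "creatinine"),
                    extra_markers=extra,
                    fit_positive=_parse_bool(raw["fit_positive"], rownum, "fit_positive"),
                    calprotectin_high=_parse_bool(
                        raw["calprotectin_high"], rownum, "calprotectin_high"
                    ),
                    symptoms=symptoms,
                    triage_category=_parse_int(raw["triage_category"], rownum, "triage_category"),
                    histology=histology,
                )
            except ValueError as exc:
                raise CohortParseError(f"row {rownum}: {exc}") from exc
            records.append(record)
    return records
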