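"""Infant anthropometry records: domain types, CSV I/O, derived measures, filters.

One record is one infant at one study visit (1, 3, or 6 months of age):
weight, length, five circumferences, six skinfolds, gestational age at
birth, and — when available — reference fat mass (FM, kg) measured by air
displacement plethysmography. BMI is always derived from weight and length
(an input ``bmi`` column is never trusted), and %FM is derived as
``100 * fm_kg / weight``.

Record-level rules implemented here:

* duplicate anthropometric readings are averaged; a skinfold pair that
  disagrees by more than 2 mm requires a third reading;
* records with %FM below 5 are excluded from model development, because
  such values fall below the minimum reported for healthy term infants.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence, Union

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Visit",
    "Sex",
    "InfantRecord",
    "CohortTable",
    "DuplicateMeasurement",
    "CohortError",
    "SchemaError",
    "ValidationError",
    "compute_bmi",
    "resolve_duplicate",
    "exclude_low_fm",
    "load_cohort",
    "write_cohort",
    "CSV_COLUMNS",
    "MEASUREMENT_VARIABLES",
]


class CohortError(Exception):
    """Base class for cohort-level input problems."""


class SchemaError(CohortError):
    """A required CSV column is missing or malformed."""


class ValidationError(CohortError):
    """A cell or record violates a domain invariant."""


class Visit(str, enum.Enum):
    """Study visit: infant age in months."""

    M1 = "1M"
    M3 = "3M"
    M6 = "6M"

    @classmethod
    def coerce(cls, value: Union["Visit", str]) -> "Visit":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).upper())
        except ValueError as exc:
            raise ValidationError(
                f"unknown visit {value!r}; expected one of 1M, 3M, 6M"
            ) from exc


class Sex(str, enum.Enum):
    FEMALE = "female"
    MALE = "male"

    @classmethod
    def coerce(cls, value: Union["Sex", str]) -> "Sex":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).lower())
        except ValueError as exc:
            raise ValidationError(
                f"unknown sex {value!r}; expected 'female' or 'male'"
            ) from exc


def compute_bmi(weight: float, length: float) -> float:
    """Body-mass index in kg/m² from weight in kg and length in cm.

    Raises
    ------
    ValidationError
        If weight or length is not strictly positive.
    """
    if not weight > 0:
        raise ValidationError(f"weight must be > 0 kg, got {weight}")
    if not length > 0:
        raise ValidationError(f"length must be > 0 cm, got {length}")
    return weight / (length / 100.0) ** 2


# Measurement fields shared by the candidate set and the CSV schema, with
# (internal name, csv column, unit) in canonical order.
_MEASUREMENTS = [
    ("weight", "weight_kg", "kg"),
    ("length", "length_cm", "cm"),
    ("head_circ", "head_cm", "cm"),
    ("muac", "muac_cm", "cm"),
    ("waist_circ", "waist_cm", "cm"),
    ("thigh_circ", "thigh_cm", "cm"),
    ("calf_circ", "calf_cm", "cm"),
    ("biceps_sf", "biceps_mm", "mm"),
    ("triceps_sf", "triceps_mm", "mm"),
    ("subscapular_sf", "subscap_mm", "mm"),
    ("waist_sf", "waist_sf_mm", "mm"),
    ("thigh_sf", "thigh_sf_mm", "mm"),
    ("calf_sf", "calf_sf_mm", "mm"),
]

MEASUREMENT_VARIABLES = tuple(name for name, _, _ in _MEASUREMENTS)

#: Mandatory CSV header, in order.
CSV_COLUMNS = (
    ["infant_id", "visit", "sex", "ga_weeks", "age_days"]
    + [csv for _, csv, _ in _MEASUREMENTS]
    + ["fm_kg"]
)

_CSV_TO_FIELD = {csv: name for name, csv, _ in _MEASUREMENTS}
_CSV_TO_FIELD.update(
    {"ga_weeks": "gestational_age_birth", "age_days": "age_days", "fm_kg": "fm_kg"}
)


@dataclass(frozen=True)
class InfantRecord:
    """A single infant-visit observation.

    Lengths and circumferences are in cm, skinfolds in mm, weight and fat
    mass in kg, gestational age at birth in weeks. ``fm_kg`` may be None
    for records used purely for prediction.
    """

    infant_id: str
    visit: Visit
    sex: Sex
    gestational_age_birth: float
    age_days: float
    weight: float
    length: float
    head_circ: float
    muac: float
    waist_circ: float
    thigh_circ: float
    calf_circ: float
    biceps_sf: float
    triceps_sf: float
    subscapular_sf: float
    waist_sf: float
    thigh_sf: float
    calf_sf: float
    fm_kg: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "visit", Visit.coerce(self.visit))
        object.__setattr__(self, "sex", Sex.coerce(self.sex))
        self._validate()

    def _validate(self) -> None:
        if self.gestational_age_birth < 37:
            raise ValidationError(
                f"record {self.infant_id}: gestational_age_birth "
                f"{self.gestational_age_birth} < 37 weeks (study includes term infants only)"
            )
        for name in ("weight", "length") + MEASUREMENT_VARIABLES[2:]:
            value = getattr(self, name)
            if not (isinstance(value, (int, float)) and math.isfinite(value)):
                raise ValidationError(
                    f"record {self.infant_id}: field '{name}' is not a finite number"
                )
            if not value > 0:
                raise ValidationError(
                    f"record {self.infant_id}: field '{name}' must be > 0, got {value}"
                )
        if self.fm_kg is not None:
            if not (0 <= self.fm_kg < self.weight):
                raise ValidationError(
                    f"record {self.infant_id}: fm_kg {self.fm_kg} outside [0, weight)"
                )

    @property
    def bmi(self) -> float:
        """BMI in kg/m², always recomputed from weight and length."""
        return compute_bmi(self.weight, self.length)

    @property
    def fm_pct(self) -> Optional[float]:
        """Fat mass as a percentage of body weight, or None if FM is absent."""
        if self.fm_kg is None:
            return None
        return 100.0 * self.fm_kg / self.weight

    def value_of(self, variable: str) -> float:
        """Numeric value of a model variable (sex encoded female=0, male=1)."""
        if variable == "sex":
            return 1.0 if self.sex is Sex.MALE else 0.0
        if variable == "bmi":
            return self.bmi
        try:
            value = getattr(self, variable)
        except AttributeError as exc:
            raise KeyError(f"record has no variable {variable!r}") from exc
        if value is None:
            raise KeyError(f"record {self.infant_id}: variable {variable!r} is absent")
        return float(value)


@dataclass(frozen=True)
class DuplicateMeasurement:
    """A duplicated anthropometric reading with its resolved value."""

    first: float
    second: float
    third: Optional[float]
    resolved: float


def resolve_duplicate(
    first: float,
    second: float,
    third: Optional[float] = None,
    kind: str = "other",
    rule: str = "mean",
) -> DuplicateMeasurement:
    """Resolve duplicate readings into a single value.

    For skinfolds, a first/second disagreement greater than 2 mm requires a
    third reading; the resolved value is then the mean of all three
    (``rule='mean'``, default) or their median (``rule='median'``).
    Otherwise the resolved value is the mean of the first two readings.
    """
    if kind not in ("skinfold", "other"):
        raise ValueError(f"kind must be 'skinfold' or 'other', got {kind!r}")
    if rule not in ("mean", "median"):
        raise ValueError(f"rule must be 'mean' or 'median', got {rule!r}")
    if kind == "skinfold" and abs(first - second) > 2.0:
        if third is None:
            raise ValidationError(
                f"skinfold readings {first} and {second} differ by "
                f"{abs(first - second):g} mm (> 2 mm): a third measurement is required"
            )
        values = [first, second, third]
        resolved = float(np.median(values)) if rule == "median" else sum(values) / 3.0
        return DuplicateMeasurement(first, second, third, resolved)
    return DuplicateMeasurement(first, second, third, (first + second) / 2.0)


class CohortTable:
    """Validated, ordered collection of :class:`InfantRecord` for one visit.

    Parameters
    ----------
    visit : Visit or str
        Visit shared by every record.
    records : iterable of InfantRecord
        Records, all at `visit`, with unique ``infant_id``.
    provenance : str
        Free text describing where the table came from (source file,
        generator seed, ...).
    """

    def __init__(
        self,
        visit: Union[Visit, str],
        records: Iterable[InfantRecord],
        provenance: str = "",
    ) -> None:
        self.visit = Visit.coerce(visit)
        self.records: list[InfantRecord] = list(records)
        self.provenance = provenance
        seen: set[str] = set()
        for rec in self.records:
            if rec.visit is not self.visit:
                raise ValidationError(
                    f"record {rec.infant_id} has visit {rec.visit.value}, "
                    f"table is {self.visit.value}"
                )
            if rec.infant_id in seen:
                raise ValidationError(f"duplicate infant_id {rec.infant_id!r}")
            seen.add(rec.infant_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[InfantRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> InfantRecord:
        return self.records[i]

    def subset(self, indices: Sequence[int], provenance: Optional[str] = None) -> "CohortTable":
        return CohortTable(
            self.visit,
            [self.records[i] for i in indices],
            provenance if provenance is not None else self.provenance,
        )

    def design_matrix(self, variables: Sequence[str]) -> np.ndarray:
        """(n, p) matrix of the requested variables, in the given order."""
        return np.array(
            [[rec.value_of(v) for v in variables] for rec in self.records], dtype=float
        )

    def fm_array(self) -> np.ndarray:
        """Measured FM (kg) per record; raises if any record lacks it."""
        out = np.empty(len(self.records))
        for i, rec in enumerate(self.records):
            if rec.fm_kg is None:
                raise ValidationError(f"record {rec.infant_id} lacks fm_kg")
            out[i] = rec.fm_kg
        return out

    def to_dataframe(self) -> pd.DataFrame:
        """Standard-schema DataFrame (one row per record), plus derived bmi/fm_pct."""
        rows = []
        for rec in self.records:
            row = {
                "infant_id": rec.infant_id,
                "visit": rec.visit.value,
                "sex": rec.sex.value,
                "ga_weeks": rec.gestational_age_birth,
                "age_days": rec.age_days,
            }
            for name, csv, _ in _MEASUREMENTS:
                row[csv] = getattr(rec, name)
            row["fm_kg"] = rec.fm_kg
            row["bmi"] = rec.bmi
            row["fm_pct"] = rec.fm_pct
            rows.append(row)
        return pd.DataFrame(rows, columns=CSV_COLUMNS + ["bmi", "fm_pct"])


def exclude_low_fm(
    cohort: CohortTable, threshold_pct: float = 5.0
) -> tuple[CohortTable, int]:
    """Remove records whose %FM falls strictly below `threshold_pct`.

    Values this low fall below the minimum reported for healthy term
    infants and are treated as implausible reference measurements. The
    boundary is strict: a record at exactly the threshold is retained.

    Returns the filtered table and the number of records removed.
    """
    kept, removed = [], 0
    for rec in cohort:
        if rec.fm_kg is None:
            raise ValidationError(
                f"record {rec.infant_id} lacks fm_kg; cannot apply %FM exclusion"
            )
        if rec.fm_pct < threshold_pct:
            removed += 1
        else:
            kept.append(rec)
    if removed:
        logger.info(
            "excluded %d record(s) with %%FM < %g at visit %s",
            removed,
            threshold_pct,
            cohort.visit.value,
        )
    return CohortTable(cohort.visit, kept, cohort.provenance), removed


def _parse_cell(raw, row_label: str, column: str) -> float:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)) or raw == "":
        raise ValidationError(f"row {row_label}: column '{column}' is empty")
    try:
        return float(raw)
    except (TypeError, ValueError) as exc:
        raise ValidationError(
            f"row {row_label}: column '{column}' is not numeric: {raw!r}"
        ) from exc


def load_cohort(path: Union[str, Path], visit: Union[Visit, str]) -> CohortTable:
    """Read a cohort CSV (documented schema) and validate every record.

    The ``bmi`` column, if present, is ignored; BMI is recomputed from
    weight and length, and a discrepancy above 0.05 kg/m² is logged.
    Records whose ``visit`` cell differs from `visit` are rejected.
    """
    path = Path(path)
    visit = Visit.coerce(visit)
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed CSV
        raise SchemaError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s) {missing}")

    records = []
    for idx, row in df.iterrows():
        label = f"{idx + 2}"  # 1-based + header line, as a human would count
        rec_visit = Visit.coerce(row["visit"])
        if rec_visit is not visit:
            raise ValidationError(
                f"row {label}: visit {rec_visit.value} does not match requested {visit.value}"
            )
        kwargs = {
            "infant_id": str(row["infant_id"]),
            "visit": rec_visit,
            "sex": Sex.coerce(row["sex"]),
        }
        for csv_col, field_name in _CSV_TO_FIELD.items():
            if csv_col == "fm_kg":
                raw = row["fm_kg"]
                kwargs["fm_kg"] = None if raw == "" else _parse_cell(raw, label, "fm_kg")
            else:
                kwargs[field_name] = _parse_cell(row[csv_col], label, csv_col)
        try:
            rec = InfantRecord(**kwargs)
        except ValidationError as exc:
            raise ValidationError(f"row {label}: {exc}") from exc
        if "bmi" in df.columns and row["bmi"] != "":
            stated = _parse_cell(row["bmi"], label, "bmi")
            if abs(stated - rec.bmi) > 0.05:
                logger.warning(
                    "row %s: input bmi %.3f disagrees with recomputed %.3f; "
                    "input value ignored",
                    label,
                    stated,
                    rec.bmi,
                )
        records.append(rec)
    return CohortTable(visit, records, provenance=str(path))


def write_cohort(cohort: CohortTable, path: Union[str, Path]) -> None:
    """Write the standard cohort CSV (schema columns only, UTF-8, '.' decimal)."""
    df = cohort.to_dataframe()[CSV_COLUMNS]
    df.to_csv(path, index=False, encoding="utf-8")
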