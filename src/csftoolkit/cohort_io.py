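"""Cohort data model, CSV I/O, unit normalization and validation.

A cohort is a table of neuro-ICU patients with paired serum/CSF albumin
and IgG measurements plus the isoelectric-focusing (IEF) reference result
for intrathecal immunoglobulin synthesis (ISI) and the final-diagnosis
grouping (CNS autoimmune disease vs. other).

Canonical units: CSF analytes in mg/L, serum analytes in g/L.  All index
arithmetic downstream converts to dimensionless quotients internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional

import numpy as np
import pandas as pd

from .errors import CohortValidationError, ConfigurationError, SchemaError

#: multiplicative factor that brings a value in the given unit to mg/L
_TO_MG_PER_L = {"mg/L": 1.0, "g/L": 1000.0, "g/dL": 10000.0}
#: multiplicative factor that brings a value in the given unit to g/L
_TO_G_PER_L = {"mg/L": 1e-3, "g/L": 1.0, "g/dL": 10.0}

#: canonical unit of each analyte column
CANONICAL_UNITS = {
    "csf_albumin": "mg/L",
    "csf_igg": "mg/L",
    "serum_albumin": "g/L",
    "serum_igg": "g/L",
}

MANDATORY_COLUMNS = (
    "patient_id",
    "age",
    "sex",
    "isi_positive",
    "cns_ad",
    "csf_albumin",
    "csf_igg",
    "serum_albumin",
    "serum_igg",
)

_TRUTHY = {"1", "true", "yes"}
_FALSY = {"0", "false", "no"}


@dataclass
class PatientRecord:
    """One patient: demographics, IEF reference result and paired analytes.

    Analytes are stored in canonical units (CSF mg/L, serum g/L) and must
    be strictly positive.  ``age`` is integer years; the adult-inclusion
    boundary (default 18, inclusive) is enforced at validation time.
    """

    patient_id: str
    age: int
    sex: str  # "female" | "male"
    isi_positive: bool
    cns_ad: bool
    csf_albumin: float  # mg/L
    csf_igg: float  # mg/L
    serum_albumin: float  # g/L
    serum_igg: float  # g/L
    hiv_positive: Optional[bool] = None
    csf_leukocytes: Optional[float] = None  # per mm^3
    immunosuppression_before_workup: Optional[bool] = None

    _ANALYTES = ("csf_albumin", "csf_igg", "serum_albumin", "serum_igg")

    def validate(self, min_age: int = 18) -> None:
        if self.sex not in ("female", "male"):
            raise CohortValidationError(
                f"patient {self.patient_id!r}: sex must be 'female' or 'male', got {self.sex!r}"
            )
        if self.age < min_age:
            raise CohortValidationError(
                f"patient {self.patient_id!r}: age {self.age} below inclusion boundary {min_age}"
            )
        for name in self._ANALYTES:
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise CohortValidationError(
                    f"patient {self.patient_id!r}: {name} must be a positive number, got {value!r}"
                )
        if self.csf_leukocytes is not None and self.csf_leukocytes < 0:
            raise CohortValidationError(
                f"patient {self.patient_id!r}: csf_leukocytes must be >= 0"
            )


@dataclass
class Cohort:
    """Ordered collection of validated patient records."""

    records: list[PatientRecord] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [r.patient_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortValidationError(f"duplicate patient_id(s): {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PatientRecord]:
        return iter(self.records)

    def to_frame(self) -> pd.DataFrame:
        """Cohort as a DataFrame in canonical units, row order preserved."""
        cols = [f.name for f in dc_fields(PatientRecord)]
        return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in self.records])


def _parse_bool(raw: object, column: str, patient_id: str) -> Optional[bool]:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return None
    if isinstance(raw, (bool, np.bool_)):
        return bool(raw)
    text = str(raw).strip().lower()
    if text in _TRUTHY:
        return True
    if text in _FALSY:
        return False
    if text == "":
        return None
    raise CohortValidationError(
        f"patient {patient_id!r}: cannot interpret {column}={raw!r} as a boolean"
    )


def normalize_analyte(value: float, column: str, unit: str) -> float:
    """Convert ``value`` of ``column`` from ``unit`` to the canonical unit."""
    canonical = CANONICAL_UNITS[column]
    table = _TO_MG_PER_L if canonical == "mg/L" else _TO_G_PER_L
    if unit not in table:
        raise ConfigurationError(
            f"unknown unit {unit!r} for column {column!r}; expected one of {sorted(table)}"
        )
    return value * table[unit]


def read_cohort(
    path: str | Path,
    unit_spec: Optional[Mapping[str, str]] = None,
    min_age: int = 18,
    provenance: str = "",
) -> Cohort:
    """Read a cohort CSV, normalize analyte units, validate every row.

    Parameters
    ----------
    path
        CSV file with a header naming all mandatory columns.
    unit_spec
        Mapping analyte column -> unit ("mg/L", "g/L" or "g/dL") as stored
        in the file.  Columns not listed are assumed already canonical.
    min_age
        Adult-inclusion boundary (inclusive).
    """
    frame = pd.read_csv(path, dtype={"patient_id": str})
    missing = [c for c in MANDATORY_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {missing}")
    unit_spec = dict(unit_spec or {})
    for column in unit_spec:
        if column not in CANONICAL_UNITS:
            raise ConfigurationError(f"unit_spec names unknown analyte column {column!r}")

    records = []
    for _, row in frame.iterrows():
        pid = str(row["patient_id"])
        kwargs: dict = {"patient_id": pid}
        try:
            kwargs["age"] = int(row["age"])
        except (TypeError, ValueError) as exc:
            raise CohortValidationError(f"patient {pid!r}: non-integer age {row['age']!r}") from exc
        kwargs["sex"] = str(row["sex"]).strip().lower()
        for col in ("isi_positive", "cns_ad"):
            parsed = _parse_bool(row[col], col, pid)
            if parsed is None:
                raise CohortValidationError(f"patient {pid!r}: {col} is mandatory")
            kwargs[col] = parsed
        for col in PatientRecord._ANALYTES:
            try:
                value = float(row[col])
            except (TypeError, ValueError) as exc:
                raise CohortValidationError(
                    f"patient {pid!r}: non-numeric {col} value {row[col]!r}"
                ) from exc
            unit = unit_spec.get(col, CANONICAL_UNITS[col])
            kwargs[col] = normalize_analyte(value, col, unit)
        if "hiv_positive" in frame.columns:
            kwargs["hiv_positive"] = _parse_bool(row["hiv_positive"], "hiv_positive", pid)
        if "csf_leukocytes" in frame.columns:
            raw = row["csf_leukocytes"]
            kwargs["csf_leukocytes"] = None if pd.isna(raw) else float(raw)
        if "immunosuppression_before_workup" in frame.columns:
            kwargs["immunosuppression_before_workup"] = _parse_bool(
                row["immunosuppression_before_workup"], "immunosuppression_before_workup", pid
            )
        record = PatientRecord(**kwargs)
        record.validate(min_age=min_age)
        records.append(record)
    return Cohort(records=records, provenance=provenance or str(path))


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write the cohort as CSV in canonical units (round-trips with read_cohort)."""
    cohort.to_frame().to_csv(path, index=False)


def summarize_cohort(
    cohort: Cohort,
    stratify_by: str,
    numeric_fields: Iterable[str] = (
        "age",
        "csf_leukocytes",
        "csf_albumin",
        "csf_igg",
        "serum_albumin",
        "serum_igg",
    ),
) -> pd.DataFrame:
    """Per-stratum n, median and interquartile range of numeric fields.

    Percentiles use linear interpolation between order statistics.  An
    empty stratum yields n=0 with NaN summaries rather than an error.
    Missing optional values are excluded pairwise.
    """
    frame = cohort.to_frame()
    if stratify_by not in frame.columns:
        raise SchemaError(f"unknown stratification field {stratify_by!r}")
    if frame.empty:
        raise CohortValidationError("cannot summarize an empty cohort")
    if not frame[stratify_by].isin([True, False]).all():
        raise ConfigurationError(f"{stratify_by!r} is not a boolean field")

    rows = []
    for stratum in (True, False):
        sub = frame[frame[stratify_by] == stratum]
        for name in numeric_fields:
            if name not in frame.columns:
                continue
            values = pd.to_numeric(sub[name], errors="coerce").dropna().to_numpy(dtype=float)
            if values.size:
                median, q25, q75 = np.percentile(values, [50, 25, 75], method="linear")
            else:
                median = q25 = q75 = np.nan
            rows.append(
                {
                    "stratum": stratum,
                    "field": name,
                    "n": int(values.size),
                    "median": median,
                    "q25": q25,
                    "q75": q75,
                }
            )
    return pd.DataFrame(rows)
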