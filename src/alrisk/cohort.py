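"""Cohort container and per-operation record schema.

One row per consecutive laparoscopic rectal resection, ordered by the
1-based operation index ``seq``. The binary ``leak`` column is the clinical
anastomotic-leak (AL) outcome; every downstream stage (screening, logistic
modelling, nomogram, validation, RA-CUSUM) consumes this container.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

from .errors import DataError

#: Canonical CSV/DataFrame column order.
COLUMNS = [
    "patient_id",
    "seq",
    "sex",
    "age_years",
    "bmi",
    "asa",
    "stage",
    "tumor_size_cm",
    "location",
    "op_time_min",
    "transfusion",
    "neoadjuvant_crt",
    "stapler_firings",
    "leak",
]

SEX_LEVELS = ("F", "M")
LOCATION_LEVELS = ("upper", "mid", "low")  # 8-12, 4-8 and 0-4 cm from the anal verge
ASA_LEVELS = (1, 2, 3)
STAGE_LEVELS = (0, 1, 2, 3, 4)
BINARY_COLUMNS = ("transfusion", "neoadjuvant_crt", "leak")


@dataclass(frozen=True)
class PatientRecord:
    """A single operation: covariates, sequence index and leak outcome."""

    patient_id: str
    seq: int
    sex: str
    age_years: float
    bmi: float
    asa: int
    stage: int
    tumor_size_cm: float
    location: str
    op_time_min: float
    transfusion: int
    neoadjuvant_crt: int
    stapler_firings: int
    leak: int

    def as_dict(self) -> dict:
        return {c: getattr(self, c) for c in COLUMNS}


def validate_frame(df: pd.DataFrame, strict: bool = True) -> pd.DataFrame:
    """Validate and normalise a cohort DataFrame against the schema.

    Returns a seq-sorted copy. Raises :class:`DataError` citing the column
    (and row where applicable) on schema violations.
    """
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"cohort is missing required column(s): {', '.join(missing)}")
    if len(df) == 0:
        raise DataError("cohort is empty")
    out = df.loc[:, COLUMNS].copy()

    for col, caster in [
        ("seq", int),
        ("asa", int),
        ("stage", int),
        ("stapler_firings", int),
        ("transfusion", int),
        ("neoadjuvant_crt", int),
        ("leak", int),
    ]:
        try:
            out[col] = out[col].astype(caster)
        except (ValueError, TypeError) as exc:
            raise DataError(f"column {col!r} is not integer-valued: {exc}") from exc
    for col in ("age_years", "bmi", "tumor_size_cm", "op_time_min"):
        try:
            out[col] = out[col].astype(float)
        except (ValueError, TypeError) as exc:
            raise DataError(f"column {col!r} is not numeric: {exc}") from exc

    if strict:
        _check_levels(out, "sex", SEX_LEVELS)
        _check_levels(out, "location", LOCATION_LEVELS)
        _check_levels(out, "asa", ASA_LEVELS)
        _check_levels(out, "stage", STAGE_LEVELS)
        for col in BINARY_COLUMNS:
            _check_levels(out, col, (0, 1))
        if (out["stapler_firings"] < 0).any():
            row = int(out.index[out["stapler_firings"] < 0][0])
            raise DataError(f"negative stapler_firings at row {row}")

    if out["seq"].duplicated().any():
        dup = int(out.loc[out["seq"].duplicated(), "seq"].iloc[0])
        raise DataError(f"duplicate seq value {dup}")
    out = out.sort_values("seq", kind="stable").reset_index(drop=True)
    expected = np.arange(1, len(out) + 1)
    if not np.array_equal(out["seq"].to_numpy(), expected):
        raise DataError("seq must be contiguous 1..n after sorting")
    return out


def _check_levels(df: pd.DataFrame, col: str, levels: tuple) -> None:
    bad = ~df[col].isin(levels)
    if bad.any():
        row = int(df.index[bad][0])
        raise DataError(
            f"column {col!r} has unsupported value {df[col][bad].iloc[0]!r} at row {row}; "
            f"allowed: {levels}"
        )


@dataclass
class Cohort:
    """An ordered cohort of consecutive operations.

    Wraps a validated pandas DataFrame (one row per operation, sorted by
    ``seq``) plus a provenance string (generator-config hash or file path).
    """

    df: pd.DataFrame
    provenance: str = field(default="unknown")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, provenance: str = "unknown", strict: bool = True) -> "Cohort":
        return cls(validate_frame(df, strict=strict), provenance)

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Cohort):
            return NotImplemented
        return self.df.equals(other.df)

    @property
    def leak(self) -> np.ndarray:
        return self.df["leak"].to_numpy()

    @property
    def n_leaks(self) -> int:
        return int(self.df["leak"].sum())

    def records(self) -> Iterator[PatientRecord]:
        for row in self.df.itertuples(index=False):
            yield PatientRecord(*row)

    def record(self, seq: int) -> PatientRecord:
        sub = self.df[self.df["seq"] == seq]
        if len(sub) != 1:
            raise DataError(f"no record with seq={seq}")
        return PatientRecord(*next(sub.itertuples(index=False)))


def record_frame(record: Mapping | PatientRecord) -> pd.DataFrame:
    """Lift a single record (mapping or PatientRecord) to a 1-row DataFrame."""
    if isinstance(record, PatientRecord):
        record = record.as_dict()
    return pd.DataFrame([dict(record)])
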