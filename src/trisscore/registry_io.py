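"""Patient data model and delimited-text trauma registry I/O.

A registry is a UTF-8 comma-separated table with one header row and one row
per patient.  Canonical columns::

    patient_id, age, sex, trauma_type, cause, gcs, sbp, rr,
    ais_head_neck, ais_face, ais_chest, ais_abdomen, ais_extremities,
    ais_external, outcome, length_of_stay

Anatomical severity is recorded as the maximum Abbreviated Injury Scale
(AIS) grade per body region, over the six conventional ISS regions.
Validation is total: every row is either accepted or attributed a named
violation (row number and field).
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: The six conventional ISS body regions.
REGIONS = ("head_neck", "face", "chest", "abdomen", "extremities", "external")
AIS_COLUMNS = tuple(f"ais_{r}" for r in REGIONS)

SEXES = ("male", "female")
TRAUMA_TYPES = ("blunt", "penetrating")
CAUSES = ("vehicle_accident", "pedestrian_accident", "fall", "assault")
OUTCOMES = ("lived", "died")

REQUIRED_COLUMNS = (
    "patient_id", "age", "sex", "trauma_type", "cause",
    "gcs", "sbp", "rr", *AIS_COLUMNS, "outcome",
)
#: Full canonical column order, including the optional length-of-stay.
COLUMNS = (*REQUIRED_COLUMNS, "length_of_stay")


class RegistryError(ValueError):
    """A registry file or record is malformed."""


class RecordValidationError(RegistryError):
    """A specific row violates a field invariant."""

    def __init__(self, row: int, field_name: str, message: str):
        self.row = row
        self.field = field_name
        super().__init__(f"row {row}, field {field_name}: {message}")


def _check_record(rec: "PatientRecord") -> list[tuple[str, str]]:
    """Return (field, message) pairs for every violated invariant."""
    bad: list[tuple[str, str]] = []
    if not rec.patient_id:
        bad.append(("patient_id", "empty identifier"))
    if not (isinstance(rec.age, (int, np.integer)) and rec.age >= 0):
        bad.append(("age", f"age must be a non-negative integer, got {rec.age!r}"))
    if rec.sex not in SEXES:
        bad.append(("sex", f"expected one of {SEXES}, got {rec.sex!r}"))
    if rec.trauma_type not in TRAUMA_TYPES:
        bad.append(("trauma_type", f"expected one of {TRAUMA_TYPES}, got {rec.trauma_type!r}"))
    if rec.cause not in CAUSES:
        bad.append(("cause", f"expected one of {CAUSES}, got {rec.cause!r}"))
    if not (isinstance(rec.gcs, (int, np.integer)) and 3 <= rec.gcs <= 15):
        bad.append(("gcs", f"GCS must be an integer in [3, 15], got {rec.gcs!r}"))
    if not (isinstance(rec.sbp, (int, float, np.number)) and math.isfinite(rec.sbp) and rec.sbp >= 0):
        bad.append(("sbp", f"SBP must be a finite number >= 0, got {rec.sbp!r}"))
    if not (isinstance(rec.rr, (int, float, np.number)) and math.isfinite(rec.rr) and rec.rr >= 0):
        bad.append(("rr", f"RR must be a finite number >= 0, got {rec.rr!r}"))
    if set(rec.ais) != set(REGIONS):
        bad.append(("ais", f"AIS mapping must cover exactly the regions {REGIONS}"))
    else:
        for region in REGIONS:
            g = rec.ais[region]
            if not (isinstance(g, (int, np.integer)) and 0 <= g <= 6):
                bad.append((f"ais_{region}", f"AIS grade must be an integer in [0, 6], got {g!r}"))
    if rec.outcome not in OUTCOMES:
        bad.append(("outcome", f"expected one of {OUTCOMES}, got {rec.outcome!r}"))
    if rec.length_of_stay is not None and not (
        isinstance(rec.length_of_stay, (int, float, np.number))
        and math.isfinite(rec.length_of_stay)
        and rec.length_of_stay >= 0
    ):
        bad.append(("length_of_stay", f"length of stay must be >= 0, got {rec.length_of_stay!r}"))
    return bad


@dataclass(frozen=True)
class PatientRecord:
    """One trauma patient: demographics, physiology, per-region AIS, outcome.

    Physiology is the admission Glasgow Coma Scale (``gcs``, 3-15), systolic
    blood pressure (``sbp``, mmHg) and respiratory rate (``rr``, breaths/min).
    ``ais`` maps each of the six body regions to the worst AIS grade (0-6)
    sustained there; grade 6 denotes an unsurvivable injury.
    """

    patient_id: str
    age: int
    sex: str
    trauma_type: str
    cause: str
    gcs: int
    sbp: float
    rr: float
    ais: Mapping[str, int]
    outcome: str
    length_of_stay: float | None = None

    def __post_init__(self):
        bad = _check_record(self)
        if bad:
            f, msg = bad[0]
            raise RegistryError(f"invalid PatientRecord {self.patient_id!r}: field {f}: {msg}")
        object.__setattr__(self, "ais", dict(self.ais))

    def to_row(self) -> dict:
        row = {
            "patient_id": self.patient_id, "age": self.age, "sex": self.sex,
            "trauma_type": self.trauma_type, "cause": self.cause,
            "gcs": self.gcs, "sbp": self.sbp, "rr": self.rr,
        }
        for region in REGIONS:
            row[f"ais_{region}"] = self.ais[region]
        row["outcome"] = self.outcome
        row["length_of_stay"] = self.length_of_stay
        return row


@dataclass
class Registry:
    """An ordered collection of validated patient records."""

    records: list[PatientRecord]
    provenance: str = ""
    #: Tally of rows dropped during non-strict reading, keyed by field name.
    dropped: Counter = field(default_factory=Counter, compare=False)

    def __post_init__(self):
        ids = [r.patient_id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = next(i for i, c in Counter(ids).items() if c > 1)
            raise RegistryError(f"duplicate patient_id {dup!r} in registry")

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        """Records as a DataFrame in canonical column order."""
        df = pd.DataFrame([r.to_row() for r in self.records], columns=list(COLUMNS))
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, provenance: str = "") -> "Registry":
        records = [
            PatientRecord(
                patient_id=str(row.patient_id),
                age=int(row.age),
                sex=row.sex,
                trauma_type=row.trauma_type,
                cause=row.cause,
                gcs=int(row.gcs),
                sbp=float(row.sbp),
                rr=float(row.rr),
                ais={region: int(getattr(row, f"ais_{region}")) for region in REGIONS},
                outcome=row.outcome,
                length_of_stay=None if pd.isna(row.length_of_stay) else float(row.length_of_stay),
            )
            for row in df.itertuples(index=False)
        ]
        return cls(records, provenance=provenance)


def _row_violations(df: pd.DataFrame) -> list[tuple[int, str, str]]:
    """Vectorised field checks; returns (positional row, field, message)."""
    out: list[tuple[int, str, str]] = []

    def flag(mask: pd.Series, field_name: str, message: str) -> None:
        for pos in np.flatnonzero(mask.to_numpy()):
            out.append((int(pos), field_name, message))

    def numeric(col: str) -> pd.Series:
        return pd.to_numeric(df[col], errors="coerce")

    flag(df["patient_id"].isna() | (df["patient_id"].astype(str).str.len() == 0),
         "patient_id", "empty identifier")

    age = numeric("age")
    flag(age.isna() | (age < 0), "age", "age must be a non-negative number")
    flag(~df["sex"].isin(SEXES), "sex", f"expected one of {SEXES}")
    flag(~df["trauma_type"].isin(TRAUMA_TYPES), "trauma_type", f"expected one of {TRAUMA_TYPES}")
    flag(~df["cause"].isin(CAUSES), "cause", f"expected one of {CAUSES}")

    gcs = numeric("gcs")
    flag(gcs.isna() | (gcs < 3) | (gcs > 15) | (gcs != gcs.round()),
         "gcs", "GCS must be an integer in [3, 15]")
    for col in ("sbp", "rr"):
        v = numeric(col)
        flag(v.isna() | (v < 0), col, f"{col} must be a number >= 0")
    for col in AIS_COLUMNS:
        v = numeric(col)
        flag(v.isna() | (v < 0) | (v > 6) | (v != v.round()),
             col, "AIS grade must be an integer in [0, 6]")
    flag(~df["outcome"].isin(OUTCOMES), "outcome", f"expected one of {OUTCOMES}")
    if "length_of_stay" in df.columns:
        v = numeric("length_of_stay")
        flag(df["length_of_stay"].notna() & (v.isna() | (v < 0)),
             "length_of_stay", "length of stay must be a number >= 0")
    out.sort()
    return out


def read_registry(path, strict: bool = True, provenance: str | None = None) -> Registry:
    """Read and validate a registry CSV.

    With ``strict`` (default), the first invariant violation raises
    :class:`RecordValidationError` naming the 1-based data row and the field.
    With ``strict=False``, offending rows are dropped; the per-field tally of
    dropped rows is logged and kept on ``Registry.dropped``.

    Fractional ages are floored to whole years on read.
    """
    try:
        df = pd.read_csv(path, dtype={"patient_id": str})
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed CSV
        raise RegistryError(f"cannot parse {path}: {exc}") from exc

    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise RegistryError(f"{path}: missing required column(s): {', '.join(missing)}")
    if "length_of_stay" not in df.columns:
        df["length_of_stay"] = np.nan

    violations = _row_violations(df)
    if violations and strict:
        pos, field_name, message = violations[0]
        raise RecordValidationError(pos + 1, field_name, message)

    dropped = Counter()
    if violations:
        bad_pos = sorted({pos for pos, _, _ in violations})
        for pos, field_name, _ in violations:
            dropped[field_name] += 1
        log.warning("read_registry: dropped %d invalid row(s): %s",
                    len(bad_pos), dict(dropped))
        df = df.drop(df.index[bad_pos]).reset_index(drop=True)

    df["age"] = np.floor(pd.to_numeric(df["age"])).astype(int)
    for col in ("gcs", *AIS_COLUMNS):
        df[col] = pd.to_numeric(df[col]).astype(int)
    for col in ("sbp", "rr", "length_of_stay"):
        df[col] = pd.to_numeric(df[col], errors="coerce")

    registry = Registry.from_frame(df, provenance=provenance or str(path))
    registry.dropped = dropped
    return registry


def write_registry(registry: Registry, path) -> None:
    """Write a registry as canonical CSV; inverse of :func:`read_registry`."""
    df = registry.to_frame()
    df.to_csv(path, index=False)


def validate_frame(df: pd.DataFrame) -> list[tuple[int, str, str]]:
    """Expose the row-level violation list (positional row, field, message)."""
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise RegistryError(f"missing required column(s): {', '.join(missing)}")
    return _row_violations(df)
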