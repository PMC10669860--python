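"""Landmark annotation records and their on-disk formats.

The measurement protocol works on eight named 2D landmarks digitised on a
dental panoramic radiograph (DPR), in raster pixel coordinates (origin at
the top-left of the image, x rightward, y downward, so "apical" for a
mandibular tooth means increasing y):

* ``M1_MESIAL_CUSP``  — radiologically highest mesial cusp point of the
  first molar (36/46); first anchor of the simplified occlusal plane.
* ``M2_DISTAL_CUSP``  — radiologically highest distal cusp point of the
  second molar (37/47); second anchor of the plane.
* ``M2_MESIAL_CEJ``   — mesial cementoenamel junction of the second molar.
* ``M3_MESIAL_CEJ``   — mesial cementoenamel junction of the third molar.
* ``M2_AXIS_CORONAL`` / ``M2_AXIS_APICAL`` — two points on the long axis of
  the second molar (used only for the angulation eligibility check).
* ``M3_AXIS_CORONAL`` / ``M3_AXIS_APICAL`` — likewise for the third molar.

Annotations are exchanged in long format, one landmark per row, grouped
into one :class:`RadiographRecord` per (subject, side, rater, session).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "LANDMARK_LABELS",
    "MEASUREMENT_LABELS",
    "AXIS_LABELS",
    "ANNOTATION_COLUMNS",
    "Landmark",
    "RadiographRecord",
    "CohortTable",
    "AnnotationSchemaError",
    "AnnotationValidationError",
    "read_annotations",
    "write_annotations",
    "read_cohort_table",
    "table1_cohort",
]

LANDMARK_LABELS = (
    "M1_MESIAL_CUSP",
    "M2_DISTAL_CUSP",
    "M2_MESIAL_CEJ",
    "M3_MESIAL_CEJ",
    "M2_AXIS_CORONAL",
    "M2_AXIS_APICAL",
    "M3_AXIS_CORONAL",
    "M3_AXIS_APICAL",
)

#: labels required for a record to be measurable (plane + two CEJ points)
MEASUREMENT_LABELS = (
    "M1_MESIAL_CUSP",
    "M2_DISTAL_CUSP",
    "M2_MESIAL_CEJ",
    "M3_MESIAL_CEJ",
)

AXIS_LABELS = (
    "M2_AXIS_CORONAL",
    "M2_AXIS_APICAL",
    "M3_AXIS_CORONAL",
    "M3_AXIS_APICAL",
)

#: fixed long-format annotation schema; ``mm_per_px`` may be empty
ANNOTATION_COLUMNS = (
    "subject_id",
    "age",
    "sex",
    "side",
    "rater_id",
    "session",
    "label",
    "x",
    "y",
    "mm_per_px",
)

VALID_SEXES = ("female", "male")
VALID_SIDES = (38, 48)


class AnnotationSchemaError(ValueError):
    """File does not conform to the documented column schema."""


class AnnotationValidationError(ValueError):
    """Rows violate a record-level invariant (reported with row numbers)."""


@dataclass(frozen=True)
class Landmark:
    """A labelled point in continuous image pixel coordinates."""

    label: str
    x: float
    y: float

    def __post_init__(self) -> None:
        if self.label not in LANDMARK_LABELS:
            raise ValueError(f"unknown landmark label {self.label!r}")
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"non-finite coordinates for {self.label}")


@dataclass
class RadiographRecord:
    """One annotation event: a subject's tooth read by one rater in one session.

    ``side`` is the FDI number of the third molar assessed (38 = lower left,
    48 = lower right).  ``mm_per_px`` is an optional calibration factor; when
    absent, lengths stay in pixels and millimetre rounding is unavailable.
    """

    subject_id: str
    age: float
    sex: str
    side: int
    rater_id: str
    session: int
    landmarks: dict[str, Landmark] = field(default_factory=dict)
    mm_per_px: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.age < 130.0):
            raise ValueError(f"age {self.age} outside [0, 130)")
        if self.sex not in VALID_SEXES:
            raise ValueError(f"sex must be one of {VALID_SEXES}, got {self.sex!r}")
        if self.side not in VALID_SIDES:
            raise ValueError(f"side must be 38 or 48, got {self.side}")
        if self.session < 1:
            raise ValueError("session must be a positive integer")
        if self.mm_per_px is not None and not self.mm_per_px > 0:
            raise ValueError("mm_per_px must be positive when given")
        for lbl, lm in self.landmarks.items():
            if lbl != lm.label:
                raise ValueError(f"landmark keyed {lbl!r} carries label {lm.label!r}")

    @property
    def key(self) -> tuple[str, int, str, int]:
        return (self.subject_id, self.side, self.rater_id, self.session)

    @property
    def is_measurable(self) -> bool:
        """True when the four quotient-measurement landmarks are all present."""
        return all(lbl in self.landmarks for lbl in MEASUREMENT_LABELS)

    @property
    def has_axes(self) -> bool:
        return all(lbl in self.landmarks for lbl in AXIS_LABELS)

    def point(self, label: str) -> tuple[float, float]:
        lm = self.landmarks[label]
        return (lm.x, lm.y)


def _records_from_rows(rows: Iterable[tuple[int, Mapping[str, object]]]) -> list[RadiographRecord]:
    """Group validated long-format rows into records.

    ``rows`` yields (1-based source row number, mapping) pairs so that
    malformed input is reported with its location.
    """
    groups: dict[tuple, RadiographRecord] = {}
    errors: list[str] = []
    for lineno, row in rows:
        try:
            subject_id = str(row["subject_id"])
            age = float(row["age"])  # type: ignore[arg-type]
            sex = str(row["sex"]).lower()
            side = int(row["side"])  # type: ignore[arg-type]
            rater_id = str(row["rater_id"])
            session = int(row["session"])  # type: ignore[arg-type]
            label = str(row["label"])
            x = float(row["x"])  # type: ignore[arg-type]
            y = float(row["y"])  # type: ignore[arg-type]
            raw_cal = row.get("mm_per_px")
            mm_per_px = None
            if raw_cal is not None and raw_cal == raw_cal and str(raw_cal) != "":
                mm_per_px = float(raw_cal)  # type: ignore[arg-type]
            landmark = Landmark(label=label, x=x, y=y)
        except (KeyError, TypeError, ValueError) as exc:
            errors.append(f"row {lineno}: {exc}")
            continue

        key = (subject_id, side, rater_id, session)
        rec = groups.get(key)
        if rec is None:
            try:
                rec = RadiographRecord(
                    subject_id=subject_id,
                    age=age,
                    sex=sex,
                    side=side,
                    rater_id=rater_id,
                    session=session,
                    mm_per_px=mm_per_px,
                )
            except ValueError as exc:
                errors.append(f"row {lineno}: {exc}")
                continue
            groups[key] = rec
        if landmark.label in rec.landmarks:
            errors.append(
                f"row {lineno}: duplicate landmark {landmark.label} in group "
                f"(subject={subject_id}, side={side}, rater={rater_id}, session={session})"
            )
            continue
        rec.landmarks[landmark.label] = landmark
    if errors:
        raise AnnotationValidationError("; ".join(errors))
    return list(groups.values())


def read_annotations(path: str | Path, dialect: str | None = None) -> list[RadiographRecord]:
    """Read a long-format annotation file (CSV or JSON array of row objects).

    The dialect is inferred from the file suffix when not given.  Missing
    mandatory columns raise :class:`AnnotationSchemaError`; malformed rows and
    duplicate landmark labels within a group raise
    :class:`AnnotationValidationError` naming the offending rows.
    """
    path = Path(path)
    if dialect is None:
        dialect = "json" if path.suffix.lower() == ".json" else "csv"
    if dialect == "csv":
        df = pd.read_csv(path, dtype={"subject_id": str, "rater_id": str},
                         float_precision="round_trip")
        missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns and c != "mm_per_px"]
        if missing:
            raise AnnotationSchemaError(f"{path}: missing mandatory column(s) {missing}")
        if "mm_per_px" not in df.columns:
            df["mm_per_px"] = None
        # +2: 1-based and one header line
        rows = ((i + 2, row) for i, row in enumerate(df.to_dict(orient="records")))
        return _records_from_rows(rows)
    if dialect == "json":
        with open(path) as fh:
            payload = json.load(fh)
        if not isinstance(payload, list):
            raise AnnotationSchemaError(f"{path}: expected a JSON array of row objects")
        for i, row in enumerate(payload):
            missing = [c for c in ANNOTATION_COLUMNS if c not in row and c != "mm_per_px"]
            if missing:
                raise AnnotationSchemaError(f"{path}: element {i} missing key(s) {missing}")
        return _records_from_rows((i + 1, row) for i, row in enumerate(payload))
    raise ValueError(f"unknown dialect {dialect!r}")


def write_annotations(records: Iterable[RadiographRecord], path: str | Path,
                      dialect: str | None = None) -> None:
    """Write records in the long annotation format (inverse of read_annotations).

    Coordinates are written at full precision so a write/read round trip
    reproduces the records exactly.
    """
    path = Path(path)
    if dialect is None:
        dialect = "json" if path.suffix.lower() == ".json" else "csv"
    rows = []
    for rec in records:
        for lbl in LANDMARK_LABELS:
            if lbl not in rec.landmarks:
                continue
            lm = rec.landmarks[lbl]
            rows.append(
                {
                    "subject_id": rec.subject_id,
                    "age": rec.age,
                    "sex": rec.sex,
                    "side": rec.side,
                    "rater_id": rec.rater_id,
                    "session": rec.session,
                    "label": lbl,
                    "x": lm.x,
                    "y": lm.y,
                    "mm_per_px": rec.mm_per_px,
                }
            )
    if dialect == "csv":
        df = pd.DataFrame(rows, columns=list(ANNOTATION_COLUMNS))
        # shortest decimal that round-trips the double exactly
        df.to_csv(path, index=False, float_format=lambda v: repr(float(v)))
    elif dialect == "json":
        with open(path, "w") as fh:
            json.dump(rows, fh, indent=1)
            fh.write("\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


@dataclass(frozen=True)
class CohortTable:
    """Age-by-sex cell counts for a 15-25-year study cohort."""

    counts: Mapping[tuple[int, str], int]

    AGES = tuple(range(15, 26))

    def __post_init__(self) -> None:
        for (age, sex), n in self.counts.items():
            if age not in self.AGES:
                raise ValueError(f"age row {age} outside 15..25")
            if sex not in VALID_SEXES:
                raise ValueError(f"bad sex column {sex!r}")
            if n < 0:
                raise ValueError("counts must be non-negative")

    def cell(self, age: int, sex: str) -> int:
        return int(self.counts.get((age, sex), 0))

    def sex_total(self, sex: str) -> int:
        return sum(self.cell(a, sex) for a in self.AGES)

    def age_total(self, age: int) -> int:
        return sum(self.cell(age, s) for s in VALID_SEXES)

    @property
    def total(self) -> int:
        return sum(self.sex_total(s) for s in VALID_SEXES)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "age": list(self.AGES),
                "female": [self.cell(a, "female") for a in self.AGES],
                "male": [self.cell(a, "male") for a in self.AGES],
            }
        )


def read_cohort_table(path: str | Path) -> CohortTable:
    """Read an age-by-sex cohort table CSV with columns age, female, male."""
    df = pd.read_csv(path)
    for col in ("age", "female", "male"):
        if col not in df.columns:
            raise AnnotationSchemaError(f"{path}: cohort table missing column {col!r}")
    present = set(int(a) for a in df["age"])
    missing = [a for a in CohortTable.AGES if a not in present]
    if missing:
        raise AnnotationSchemaError(f"{path}: missing age row(s) {missing}")
    counts: dict[tuple[int, str], int] = {}
    for _, row in df.iterrows():
        age = int(row["age"])
        counts[(age, "female")] = int(row["female"])
        counts[(age, "male")] = int(row["male"])
    return CohortTable(counts=counts)


def table1_cohort() -> CohortTable:
    """The packaged study cohort composition (423 radiograph series)."""
    with resources.as_file(resources.files("molarq.data") / "cohort_table1.csv") as p:
        return read_cohort_table(p)
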