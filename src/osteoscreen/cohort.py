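"""Participant data model, CSV I/O, and the eligibility cascade.

The analysis set is a roster of postmenopausal women (50-89 y) with five-site
DXA T-scores (L2-4 spine, bilateral femoral neck, bilateral total hip),
anthropometry, and six physical-performance measurements.  Records carrying
exclusion flags (osteoporosis drugs, hormonal therapy, premenopausal,
incomplete performance testing) are removed by :func:`apply_eligibility`
before any analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Optional

import pandas as pd

__all__ = [
    "EXCLUSION_ORDER",
    "CSV_COLUMNS",
    "ParticipantRecord",
    "Roster",
    "ExclusionLog",
    "ValidationError",
    "SchemaError",
    "compute_bmi",
    "apply_eligibility",
    "read_cohort_csv",
    "write_cohort_csv",
]


class ValidationError(ValueError):
    """A record or input value violates a model invariant."""


class SchemaError(ValueError):
    """A cohort CSV does not match the documented schema."""


#: Cascade order: each excluded record is attributed to the FIRST matching reason.
EXCLUSION_ORDER = (
    "osteoporosis_drug",
    "hormonal_therapy",
    "premenopausal",
    "incomplete_tests",
)

_FLAG_COLUMNS = {
    "osteoporosis_drug": "flag_drug",
    "hormonal_therapy": "flag_hormone",
    "premenopausal": "flag_premenopausal",
    "incomplete_tests": "flag_incomplete",
}

#: Exact cohort CSV header (comma-separated, UTF-8, dot decimal, flags 0/1).
CSV_COLUMNS = [
    "id",
    "age",
    "height_cm",
    "weight_kg",
    "tscore_l24",
    "tscore_neck_l",
    "tscore_neck_r",
    "tscore_hip_l",
    "tscore_hip_r",
    "grip_kg",
    "knee_ext_ratio",
    "one_leg_s",
    "tst",
    "standup_pts",
    "locomo25",
    "flag_drug",
    "flag_hormone",
    "flag_premenopausal",
    "flag_incomplete",
]

_MEASUREMENT_FIELDS = (
    "height",
    "weight",
    "tscore_l24",
    "tscore_neck_left",
    "tscore_neck_right",
    "tscore_hip_left",
    "tscore_hip_right",
    "grip",
    "knee_ext",
    "one_leg",
    "tst",
    "standup",
    "locomo25",
)


def compute_bmi(height: float, weight: float) -> float:
    """Body mass index, weight [kg] / (height [cm] / 100) ** 2."""
    if not (height > 0 and weight > 0):
        raise ValidationError(
            f"height and weight must be positive, got height={height}, weight={weight}"
        )
    return weight / (height / 100.0) ** 2


@dataclass(frozen=True)
class ParticipantRecord:
    """One woman's anthropometry, T-scores, performance tests and flags.

    Measurements may be ``None`` only when the record carries the
    ``incomplete_tests`` flag.  ``knee_ext`` is a pure ratio of body weight
    (1.10 means extension strength equal to 1.10 x body weight); ``tst`` is
    the two-step distance divided by height (unitless); ``one_leg`` is
    seconds with a measurement ceiling of 60.
    """

    id: str
    age: int
    height: Optional[float] = None  # cm
    weight: Optional[float] = None  # kg
    tscore_l24: Optional[float] = None
    tscore_neck_left: Optional[float] = None
    tscore_neck_right: Optional[float] = None
    tscore_hip_left: Optional[float] = None
    tscore_hip_right: Optional[float] = None
    grip: Optional[float] = None  # kg, mean of sides
    knee_ext: Optional[float] = None  # ratio of body weight
    one_leg: Optional[float] = None  # s, in [0, 60]
    tst: Optional[float] = None  # unitless ratio
    standup: Optional[int] = None  # points 1-8
    locomo25: Optional[float] = None  # points 0-100
    flags: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "flags", frozenset(self.flags))
        unknown = self.flags - set(EXCLUSION_ORDER)
        if unknown:
            raise ValidationError(f"record {self.id}: unknown flags {sorted(unknown)}")
        if not (isinstance(self.age, int) and 50 <= self.age <= 89):
            raise ValidationError(f"record {self.id}: age must be an integer in 50-89, got {self.age}")
        if "incomplete_tests" not in self.flags:
            missing = [f for f in _MEASUREMENT_FIELDS if getattr(self, f) is None]
            if missing:
                raise ValidationError(
                    f"record {self.id}: missing {missing} without incomplete_tests flag"
                )
        for name in ("height", "weight"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValidationError(f"record {self.id}: {name} must be > 0, got {v}")
        if self.one_leg is not None and not (0.0 <= self.one_leg <= 60.0):
            raise ValidationError(f"record {self.id}: one_leg must be in [0, 60], got {self.one_leg}")
        if self.standup is not None and self.standup not in range(1, 9):
            raise ValidationError(f"record {self.id}: standup must be in 1-8, got {self.standup}")
        if self.locomo25 is not None and not (0.0 <= self.locomo25 <= 100.0):
            raise ValidationError(f"record {self.id}: locomo25 must be in [0, 100], got {self.locomo25}")
        for name in _MEASUREMENT_FIELDS:
            v = getattr(self, name)
            if v is not None and not math.isfinite(float(v)):
                raise ValidationError(f"record {self.id}: {name} is not finite")

    @property
    def bmi(self) -> Optional[float]:
        if self.height is None or self.weight is None:
            return None
        return compute_bmi(self.height, self.weight)

    @property
    def site_tscores(self) -> list:
        """The five measured-site T-scores (missing sites omitted)."""
        return [
            t
            for t in (
                self.tscore_l24,
                self.tscore_neck_left,
                self.tscore_neck_right,
                self.tscore_hip_left,
                self.tscore_hip_right,
            )
            if t is not None
        ]


@dataclass(frozen=True)
class Roster:
    """Ordered collection of participant records with unique ids."""

    records: tuple
    provenance: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate record ids: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ParticipantRecord]:
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]

    def to_frame(self) -> pd.DataFrame:
        """Tabular view with derived columns (bmi, side-averaged neck/hip T-scores)."""
        rows = []
        for r in self.records:
            neck = _mean_or_none(r.tscore_neck_left, r.tscore_neck_right)
            hip = _mean_or_none(r.tscore_hip_left, r.tscore_hip_right)
            rows.append(
                {
                    "id": r.id,
                    "age": r.age,
                    "height": r.height,
                    "weight": r.weight,
                    "bmi": r.bmi,
                    "tscore_l24": r.tscore_l24,
                    "tscore_neck": neck,
                    "tscore_hip": hip,
                    "grip": r.grip,
                    "knee_ext": r.knee_ext,
                    "one_leg": r.one_leg,
                    "tst": r.tst,
                    "standup": r.standup,
                    "locomo25": r.locomo25,
                }
            )
        return pd.DataFrame(rows)


def _mean_or_none(a: Optional[float], b: Optional[float]) -> Optional[float]:
    vals = [v for v in (a, b) if v is not None]
    return sum(vals) / len(vals) if vals else None


@dataclass(frozen=True)
class ExclusionLog:
    """Counts per exclusion reason, in cascade order, plus the included count."""

    counts: dict
    included_count: int

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "counts", {reason: int(self.counts.get(reason, 0)) for reason in EXCLUSION_ORDER}
        )

    @property
    def total_input(self) -> int:
        return self.included_count + sum(self.counts.values())


def apply_eligibility(roster: Roster) -> tuple:
    """Remove flagged records, attributing each to the first matching reason.

    Cascade order: osteoporosis drugs -> hormonal therapy -> premenopausal ->
    incomplete performance testing.  Record order is preserved; the operation
    is idempotent.
    """
    counts = {reason: 0 for reason in EXCLUSION_ORDER}
    included = []
    for record in roster:
        for reason in EXCLUSION_ORDER:
            if reason in record.flags:
                counts[reason] += 1
                break
        else:
            included.append(record)
    log = ExclusionLog(counts=counts, included_count=len(included))
    out = Roster(records=tuple(included), provenance=roster.provenance)
    return out, log


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def _record_to_row(r: ParticipantRecord) -> dict:
    return {
        "id": r.id,
        "age": r.age,
        "height_cm": r.height,
        "weight_kg": r.weight,
        "tscore_l24": r.tscore_l24,
        "tscore_neck_l": r.tscore_neck_left,
        "tscore_neck_r": r.tscore_neck_right,
        "tscore_hip_l": r.tscore_hip_left,
        "tscore_hip_r": r.tscore_hip_right,
        "grip_kg": r.grip,
        "knee_ext_ratio": r.knee_ext,
        "one_leg_s": r.one_leg,
        "tst": r.tst,
        "standup_pts": r.standup,
        "locomo25": r.locomo25,
        "flag_drug": int("osteoporosis_drug" in r.flags),
        "flag_hormone": int("hormonal_therapy" in r.flags),
        "flag_premenopausal": int("premenopausal" in r.flags),
        "flag_incomplete": int("incomplete_tests" in r.flags),
    }


def write_cohort_csv(roster: Roster, path) -> None:
    """Write the roster in the documented CSV schema (full float precision)."""
    df = pd.DataFrame([_record_to_row(r) for r in roster], columns=CSV_COLUMNS)
    # 17 significant digits round-trip any IEEE double exactly
    df.to_csv(path, index=False, float_format="%.17g")


def read_cohort_csv(path) -> Roster:
    """Read a cohort CSV, validating the schema and every cell."""
    df = pd.read_csv(path, dtype={"id": str}, float_precision="round_trip")
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    records = []
    for i, row in df.iterrows():
        rownum = int(i) + 2  # 1-based, after the header line
        try:
            flags = set()
            for reason, col in _FLAG_COLUMNS.items():
                v = int(row[col])
                if v not in (0, 1):
                    raise ValidationError(f"flag {col} must be 0/1, got {v}")
                if v:
                    flags.add(reason)
            records.append(
                ParticipantRecord(
                    id=str(row["id"]),
                    age=int(row["age"]),
                    height=_cell(row["height_cm"]),
                    weight=_cell(row["weight_kg"]),
                    tscore_l24=_cell(row["tscore_l24"]),
                    tscore_neck_left=_cell(row["tscore_neck_l"]),
                    tscore_neck_right=_cell(row["tscore_neck_r"]),
                    tscore_hip_left=_cell(row["tscore_hip_l"]),
                    tscore_hip_right=_cell(row["tscore_hip_r"]),
                    grip=_cell(row["grip_kg"]),
                    knee_ext=_cell(row["knee_ext_ratio"]),
                    one_leg=_cell(row["one_leg_s"]),
                    tst=_cell(row["tst"]),
                    standup=_int_cell(row["standup_pts"]),
                    locomo25=_cell(row["locomo25"]),
                    flags=flags,
                )
            )
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"{path}: row {rownum}: {exc}") from exc
    return Roster(records=tuple(records), provenance=str(path))


def _cell(v) -> Optional[float]:
    if pd.isna(v):
        return None
    return float(v)


def _int_cell(v) -> Optional[int]:
    if pd.isna(v):
        return None
    f = float(v)
    if f != int(f):
        raise ValidationError(f"expected integer, got {v}")
    return int(f)
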