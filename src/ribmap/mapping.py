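"""Fracture-position normalization, sector/bin classification, cohort validation.

The positional datum for every fracture line is its percentage position along
the rib: with D1 the along-rib distance from the costovertebral joint to the
fracture site and D2 the distance from the fracture site to the costochondral
junction, the position is D1/(D1+D2) x 100.  0 % is posterior (at the spine),
100 % anterior.

Positions are classified two ways: into the three CWIS anatomical sectors
(posterior / lateral / anterior; boundary percentages are configurable because
the consensus leaves them unstandardized, defaulting to equal thirds), and into
fixed-width percentage bins (default 10 %) for histograms and frequency
matrices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Literal, Sequence

import numpy as np
import pandas as pd

from .geometry import RIB_INDICES, Side, normalize_side

Sector = Literal["posterior", "lateral", "anterior"]

#: Patient-level associated-fracture flags tracked by the analysis.
FLAG_NAMES: tuple[str, ...] = ("clavicle", "scapula", "thoracic_vertebra", "sternum")

#: Default CWIS sector boundaries (percent): equal thirds, since the consensus
#: leaves the precise boundaries open.
DEFAULT_SECTOR_BOUNDS: tuple[float, float] = (33.33, 66.67)

DEFAULT_BIN_WIDTH: float = 10.0


# ---------------------------------------------------------------------------
# Position normalization
# ---------------------------------------------------------------------------

@dataclass(frozen=True, slots=True)
class FractureMeasurement:
    """Raw along-rib distances: d1 = joint->fracture, d2 = fracture->junction (mm)."""

    d1: float
    d2: float

    def __post_init__(self) -> None:
        if self.d1 < 0 or self.d2 < 0:
            raise ValueError("distances must be non-negative")
        if self.d1 + self.d2 <= 0:
            raise ValueError("d1 + d2 must be positive")

    @property
    def percent(self) -> float:
        return percent_position(self.d1, self.d2)


def percent_position(d1: float, d2: float) -> float:
    """Percentage position of a fracture line: d1 / (d1 + d2) x 100.

    Scale invariant: (k*d1, k*d2) gives the same value for any k > 0, so the
    measurement unit cancels.
    """
    if d1 < 0 or d2 < 0:
        raise ValueError(f"distances must be non-negative, got d1={d1}, d2={d2}")
    total = d1 + d2
    if total <= 0:
        raise ValueError("d1 + d2 must be positive")
    return 100.0 * d1 / total


def classify_sector(
    percent: float, boundaries: tuple[float, float] = DEFAULT_SECTOR_BOUNDS
) -> Sector:
    """Assign a percent position to a CWIS sector.

    Half-open convention: posterior on [0, b1), lateral on [b1, b2), anterior
    on [b2, 100]; the partition covers [0, 100] for any valid boundaries.
    """
    b1, b2 = boundaries
    if not (0.0 <= b1 < b2 <= 100.0):
        raise ValueError(f"boundaries must satisfy 0 <= b1 < b2 <= 100, got {boundaries}")
    if not (0.0 <= percent <= 100.0):
        raise ValueError(f"percent must be in [0, 100], got {percent}")
    if percent < b1:
        return "posterior"
    if percent < b2:
        return "lateral"
    return "anterior"


def n_bins(width: float = DEFAULT_BIN_WIDTH) -> int:
    """Number of position bins for a given width; width must divide 100."""
    k = 100.0 / width
    if width <= 0 or abs(k - round(k)) > 1e-9:
        raise ValueError(f"bin width must divide 100, got {width}")
    return int(round(k))


def bin_index(percent: float, width: float = DEFAULT_BIN_WIDTH) -> int:
    """Left-closed position bin: floor(percent / width); 100 falls in the last bin."""
    k = n_bins(width)
    if not (0.0 <= percent <= 100.0):
        raise ValueError(f"percent must be in [0, 100], got {percent}")
    return min(int(math.floor(percent / width)), k - 1)


# ---------------------------------------------------------------------------
# Cohort containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True, slots=True)
class FractureRecord:
    """One fracture line: where it sits along which rib of which patient."""

    patient_id: str
    rib_index: int
    side: Side
    percent: float

    def __post_init__(self) -> None:
        if self.rib_index not in RIB_INDICES:
            raise ValueError(f"rib_index must be 1-12, got {self.rib_index}")
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")
        if not (0.0 <= self.percent <= 100.0):
            raise ValueError(f"percent must be in [0, 100], got {self.percent}")

    def sector(self, boundaries: tuple[float, float] = DEFAULT_SECTOR_BOUNDS) -> Sector:
        return classify_sector(self.percent, boundaries)

    def bin(self, width: float = DEFAULT_BIN_WIDTH) -> int:
        return bin_index(self.percent, width)


@dataclass(slots=True)
class PatientRecord:
    """One patient: demographics, associated-fracture flags, fracture lines."""

    patient_id: str
    age: float | None = None
    sex: str | None = None
    mechanism: str | None = None
    flags: dict[str, bool] = field(default_factory=dict)
    fractures: list[FractureRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.flags = {name: bool(self.flags.get(name, False)) for name in FLAG_NAMES}
        for rec in self.fractures:
            if rec.patient_id != self.patient_id:
                raise ValueError(
                    f"fracture record for {rec.patient_id!r} attached to patient "
                    f"{self.patient_id!r}"
                )

    def has_fracture_in(self, rib_range: Iterable[int]) -> bool:
        ribs = set(rib_range)
        return any(f.rib_index in ribs for f in self.fractures)


@dataclass(slots=True)
class Cohort:
    """All patients of one study; the unit every statistic operates on."""

    patients: list[PatientRecord]

    def __post_init__(self) -> None:
        ids = [p.patient_id for p in self.patients]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate patient ids: {dupes}")

    def __len__(self) -> int:
        return len(self.patients)

    @property
    def n_fractures(self) -> int:
        return sum(len(p.fractures) for p in self.patients)

    def fracture_records(self) -> Iterator[FractureRecord]:
        for p in self.patients:
            yield from p.fractures

    def fracture_frame(self) -> pd.DataFrame:
        """Flat per-fracture table (patient_id, rib, side, percent)."""
        return pd.DataFrame(
            [(f.patient_id, f.rib_index, f.side, f.percent) for f in self.fracture_records()],
            columns=["patient_id", "rib", "side", "percent"],
        )

    def patient_frame(self) -> pd.DataFrame:
        """Per-patient table: demographics plus one 0/1 column per flag."""
        rows = []
        for p in self.patients:
            row = {"patient_id": p.patient_id, "age": p.age, "sex": p.sex,
                   "mechanism": p.mechanism}
            row.update({name: int(p.flags[name]) for name in FLAG_NAMES})
            rows.append(row)
        return pd.DataFrame(rows, columns=["patient_id", "age", "sex", "mechanism", *FLAG_NAMES])


# ---------------------------------------------------------------------------
# Validation of raw tabular records
# ---------------------------------------------------------------------------

class CohortValidationError(ValueError):
    """Raised when raw cohort tables violate the schema; names the failing row."""


def _parse_bool(value, row: int, column: str) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    if isinstance(value, (int, float, np.integer, np.floating)) and not pd.isna(value):
        if value in (0, 1):
            return bool(value)
    text = str(value).strip().lower()
    if text in ("1", "true", "yes", "y"):
        return True
    if text in ("0", "false", "no", "n", "", "nan"):
        return False
    raise CohortValidationError(f"row {row}: cannot interpret {column}={value!r} as 0/1")


def validate_cohort(
    patients: pd.DataFrame,
    fractures: pd.DataFrame,
    *,
    percent_agreement_tol: float = 0.01,
) -> Cohort:
    """Build a validated :class:`Cohort` from raw patient and fracture tables.

    Fracture rows may give ``percent`` directly, raw distances ``d1``/``d2``
    (converted via :func:`percent_position`), or both — in which case they must
    agree within ``percent_agreement_tol``.  Errors name the offending row
    (0-based data row, header excluded).
    """
    if "patient_id" not in patients.columns:
        raise CohortValidationError("patients table lacks a patient_id column")
    if "patient_id" not in fractures.columns:
        raise CohortValidationError("fractures table lacks a patient_id column")

    ids = patients["patient_id"].astype(str)
    if ids.duplicated().any():
        dupes = sorted(ids[ids.duplicated()].unique())
        raise CohortValidationError(f"duplicate patient ids: {dupes}")

    records: dict[str, list[FractureRecord]] = {pid: [] for pid in ids}
    for row, rec in enumerate(fractures.to_dict("records")):
        pid = str(rec["patient_id"])
        if pid not in records:
            raise CohortValidationError(
                f"row {row}: fracture references unknown patient {pid!r}"
            )
        try:
            rib = int(rec["rib"])
        except (KeyError, TypeError, ValueError):
            raise CohortValidationError(f"row {row}: missing or non-integer rib") from None
        if rib not in RIB_INDICES:
            raise CohortValidationError(f"row {row}: rib index {rib} outside 1-12")
        try:
            side = normalize_side(rec["side"])
        except (KeyError, ValueError) as exc:
            raise CohortValidationError(f"row {row}: {exc}") from None

        pct = rec.get("percent")
        d1, d2 = rec.get("d1"), rec.get("d2")
        has_pct = pct is not None and not pd.isna(pct)
        has_d = (
            d1 is not None and d2 is not None
            and not pd.isna(d1) and not pd.isna(d2)
        )
        if not has_pct and not has_d:
            raise CohortValidationError(
                f"row {row}: needs either percent or both d1 and d2"
            )
        if has_d:
            try:
                derived = percent_position(float(d1), float(d2))
            except ValueError as exc:
                raise CohortValidationError(f"row {row}: {exc}") from None
        if has_pct:
            pct = float(pct)
            if not (0.0 <= pct <= 100.0):
                raise CohortValidationError(
                    f"row {row}: percent {pct} outside [0, 100]"
                )
            if has_d and abs(pct - derived) > percent_agreement_tol:
                raise CohortValidationError(
                    f"row {row}: percent {pct} disagrees with d1/d2-derived "
                    f"{derived:.4f} beyond {percent_agreement_tol}"
                )
        else:
            pct = derived
        records[pid].append(FractureRecord(pid, rib, side, pct))

    patients_out: list[PatientRecord] = []
    for row, rec in enumerate(patients.to_dict("records")):
        pid = str(rec["patient_id"])
        flags = {
            name: _parse_bool(rec.get(name, 0), row, name) for name in FLAG_NAMES
        }
        age = rec.get("age")
        patients_out.append(
            PatientRecord(
                patient_id=pid,
                age=None if age is None or pd.isna(age) else float(age),
                sex=None if pd.isna(rec.get("sex", None)) else str(rec.get("sex")),
                mechanism=(
                    None if pd.isna(rec.get("mechanism", None)) else str(rec.get("mechanism"))
                ),
                flags=flags,
                fractures=records[pid],
            )
        )
    return Cohort(patients_out)
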