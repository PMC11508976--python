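import numpy as np
import pytest

from ribmap import Cohort, FractureRecord, PatientRecord, RibCurve

# Published per-rib fracture-line counts (ribs 1-12) used to rebuild a cohort
# with a known count structure.
TABLE3_LEFT = (20, 37, 56, 65, 68, 55, 56, 45, 36, 23, 15, 4)
TABLE3_RIGHT = (19, 41, 55, 56, 62, 53, 56, 42, 32, 14, 11, 2)


@pytest.fixture(scope="session")
def rib_count_cohort() -> Cohort:
    """Cohort whose per-rib left/right counts equal the published table.

    Positions are immaterial for count statistics; records are spread
    round-robin over 102 patients.
    """
    n_patients = 102
    fractures: list[list[FractureRecord]] = [[] for _ in range(n_patients)]
    i = 0
    for rib in range(1, 13):
        for side, count in (("left", TABLE3_LEFT[rib - 1]), ("right", TABLE3_RIGHT[rib - 1])):
            for _ in range(count):
                pid = f"T{i % n_patients:03d}"
                fractures[i % n_patients].append(FractureRecord(pid, rib, side, 50.0))
                i += 1
    patients = [
        PatientRecord(patient_id=f"T{k:03d}", fractures=fractures[k])
        for k in range(n_patients)
    ]
    return Cohort(patients)


@pytest.fixture
def toy_curve() -> RibCurve:
    """Collinear 3-point chain of total length 3 mm with uneven segments."""
    return RibCurve(5, "right", np.array([[0.0, 0, 0], [1.0, 0, 0], [3.0, 0, 0]]))


def make_cohort(records: list[tuple[str, int, str, float]],
                flags: dict[str, dict[str, bool]] | None = None) -> Cohort:
    """Build a small cohort from (patient_id, rib, side, percent) tuples."""
    flags = flags or {}
    by_pid: dict[str, list[FractureRecord]] = {}
    for pid, rib, side, pct in records:
        by_pid.setdefault(pid, []).append(FractureRecord(pid, rib, side, pct))
    for pid in flags:
        by_pid.setdefault(pid, [])
    return Cohort([
        PatientRecord(patient_id=pid, flags=flags.get(pid, {}), fractures=recs)
        for pid, recs in by_pid.items()
    ])
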