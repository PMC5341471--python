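import numpy as np
import pytest

from rvellipse import (
    CohortSimConfig,
    DistanceTriplet,
    SubjectRecord,
    VolumePair,
    simulate_cohort,
)


def ef_matched_record(
    subject_id: str,
    group: str,
    ef_by_tte_observer: dict[str, float],
    ef_by_cmr_observer: dict[str, float],
    tapse_mm: float | None = None,
    base=(4.0, 8.0, 5.0),
    edv_ml: float = 150.0,
) -> SubjectRecord:
    """Build a subject whose derived per-observer EFs are known exactly.

    The systolic triplet is the diastolic one scaled by the cube root of
    the volume ratio, so the ellipsoid EF equals the requested value.
    """
    tte = {}
    for obs, ef in ef_by_tte_observer.items():
        dia = DistanceTriplet(*base)
        s = (1.0 - ef / 100.0) ** (1.0 / 3.0)
        tte[obs] = [(dia, dia.scaled(s))]
    cmr = {
        obs: VolumePair(edv=edv_ml, esv=edv_ml * (1.0 - ef / 100.0))
        for obs, ef in ef_by_cmr_observer.items()
    }
    return SubjectRecord(
        subject_id=subject_id, group=group, tte_measurements=tte,
        cmr_volumes=cmr, tapse_mm=tapse_mm,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A 37-subject noisy cohort at the default simulator settings."""
    return simulate_cohort(CohortSimConfig(seed=20170307))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
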