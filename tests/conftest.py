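"""Shared fixtures: record builders and the published LR-matrix fixture."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from osteoscreen import (
    LrMatrix,
    ParticipantRecord,
    Roster,
    SyntheticCohortConfig,
    generate_cohort,
)
from osteoscreen.screening import DEFAULT_BMI_GRID, DEFAULT_TST_GRID

# Published positive/negative likelihood-ratio matrices over the default
# cutoff grids (BMI rows ascending, TST columns ascending), used as an input
# fixture for rule extraction.
TABLE6_LR_POS = [
    [22.0, 7.3, 8.6, 7.3, 7.3, 6.1, 5.8, 4.5],
    [12.8, 6.4, 7.3, 6.6, 6.7, 5.8, 5.5, 4.4],
    [9.8, 5.9, 5.5, 5.2, 5.5, 4.4, 4.0, 3.7],
    [11.0, 6.6, 6.1, 5.8, 5.3, 4.3, 3.7, 3.4],
    [9.2, 6.1, 5.8, 5.5, 4.3, 3.4, 3.1, 2.9],
    [10.1, 6.7, 6.3, 6.0, 4.6, 3.7, 3.1, 3.0],
    [5.0, 4.0, 4.0, 4.0, 3.4, 2.8, 2.4, 2.4],
    [5.0, 4.0, 4.0, 4.0, 3.4, 2.8, 2.4, 2.4],
]
TABLE7_LR_NEG = [
    [0.8, 0.7, 0.7, 0.7, 0.8, 0.8, 0.7, 0.7],
    [0.7, 0.7, 0.7, 0.7, 0.7, 0.8, 0.7, 0.6],
    [0.7, 0.7, 0.7, 0.7, 0.7, 0.7, 0.7, 0.6],
    [0.7, 0.7, 0.7, 0.7, 0.7, 0.7, 0.6, 0.5],
    [0.7, 0.7, 0.7, 0.7, 0.7, 0.6, 0.6, 0.5],
    [0.7, 0.6, 0.6, 0.6, 0.7, 0.6, 0.6, 0.5],
    [0.7, 0.7, 0.7, 0.7, 0.7, 0.6, 0.6, 0.5],
    [0.7, 0.7, 0.7, 0.7, 0.7, 0.6, 0.6, 0.5],
]


@pytest.fixture(scope="session")
def published_lr_matrix() -> LrMatrix:
    return LrMatrix.from_values(DEFAULT_BMI_GRID, DEFAULT_TST_GRID, TABLE6_LR_POS, TABLE7_LR_NEG)


def make_record(
    id: str = "r1",
    age: int = 65,
    height: float = 155.0,
    bmi: float | None = 22.0,
    weight: float | None = None,
    tscores: tuple = (-0.5, -1.0, -1.0, -0.8, -0.8),
    grip: float = 22.0,
    knee_ext: float = 1.1,
    one_leg: float = 35.0,
    tst: float = 1.40,
    standup: int = 4,
    locomo25: float = 8.0,
    flags: set = frozenset(),
) -> ParticipantRecord:
    """A valid record with sensible defaults; ``bmi`` sets weight unless given."""
    if weight is None:
        weight = float(bmi) * (height / 100.0) ** 2
    return ParticipantRecord(
        id=id,
        age=age,
        height=height,
        weight=weight,
        tscore_l24=tscores[0],
        tscore_neck_left=tscores[1],
        tscore_neck_right=tscores[2],
        tscore_hip_left=tscores[3],
        tscore_hip_right=tscores[4],
        grip=grip,
        knee_ext=knee_ext,
        one_leg=one_leg,
        tst=tst,
        standup=standup,
        locomo25=locomo25,
        flags=flags,
    )


def random_roster(rng: np.random.Generator, n: int = 40) -> Roster:
    """Small random roster with varied BMI/TST/T-scores for oracle recounts."""
    records = []
    for i in range(n):
        t_rep = float(rng.uniform(-3.5, 0.5))
        records.append(
            make_record(
                id=f"x{i}",
                age=int(rng.integers(50, 90)),
                bmi=float(rng.uniform(18, 28)),
                tscores=(t_rep, t_rep + 0.3, t_rep + 0.4, t_rep + 0.2, t_rep + 0.5),
                tst=float(rng.uniform(0.9, 1.7)),
            )
        )
    return Roster(records=tuple(records))


@pytest.fixture(scope="session")
def default_synth_config() -> SyntheticCohortConfig:
    return SyntheticCohortConfig()


@pytest.fixture(scope="session")
def small_cohort(default_synth_config):
    """One default-size synthetic cohort (n=168), reused across tests."""
    return generate_cohort(default_synth_config, seed=0)
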