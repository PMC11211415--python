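import numpy as np
import pandas as pd
import pytest

from tmstraj.simulate import SimConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 60-subject default-parameter cohort shared across tests."""
    return generate_cohort(SimConfig(n_subjects=60, seed=7))


@pytest.fixture(scope="session")
def medium_cohort():
    """A 250-subject cohort for fitting tests."""
    return generate_cohort(SimConfig(n_subjects=250, seed=5))


@pytest.fixture
def ratings_frame():
    """Tiny hand-built raw ratings table (3 subjects, some missing)."""
    rows = []
    for sid, vals in {
        "a": {0: 3, 1: 3, 2: 4, 3: 5},
        "b": {1: 1, 2: 2, 3: 3},
        "c": {0: 3, 2: 5},
    }.items():
        for sess, r in vals.items():
            rows.append({"subject_id": sid, "session": sess, "rating": r})
    return pd.DataFrame(rows)


def make_coil_log(points, session_offset=1):
    """Coil-log frame from a list of session-mean coordinates."""
    return pd.DataFrame(
        {
            "subject_id": "s",
            "session": np.arange(session_offset, session_offset + len(points)),
            "sample_index": 0,
            "x_mni_mm": [p[0] for p in points],
            "y_mni_mm": [p[1] for p in points],
            "z_mni_mm": [p[2] for p in points],
        }
    )
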