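import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from facersa import FaceSet, SessionBehavior

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def toy_faces():
    return FaceSet(
        pd.DataFrame(
            {
                "face_id": ["f0", "f1", "f2", "f3", "f4", "f5"],
                "sex": ["male", "male", "female", "female", "male", "female"],
                "ethnicity": [
                    "caucasian", "caucasian", "other", "caucasian", "other", "caucasian",
                ],
                "age": [22.0, 35.5, 41.0, 19.0, 28.0, 50.0],
                "db_rating": [2.1, 3.5, 5.9, 4.2, 1.0, 7.0],
            }
        )
    )


@pytest.fixture
def toy_behavior(toy_faces):
    """7 repetitions of each of the 6 faces, deterministic responses."""
    rng = np.random.default_rng(7)
    rows = []
    trial = 0
    for _ in range(7):
        for f in rng.permutation(toy_faces.face_ids):
            rating = int(np.clip(round(toy_faces.table.set_index("face_id").loc[f, "db_rating"]
                                       + rng.integers(-1, 2)), 1, 7))
            rows.append((trial, f, 1 if rating >= 4 else 2, rating))
            trial += 1
    return SessionBehavior(
        pd.DataFrame(rows, columns=["trial_index", "face_id", "yesno", "rating"])
    )
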