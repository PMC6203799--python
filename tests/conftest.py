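import numpy as np
import pandas as pd
import pytest

from tpphen import RearingDataset, default_truth, generate_rearing_dataset


def make_frame(rows):
    """Observation frame from (id, unit, temp, stage, duration) tuples."""
    return pd.DataFrame(
        rows,
        columns=["individual_id", "rearing_unit", "mean_temp", "stage", "duration_days"],
    )


@pytest.fixture
def tiny_dataset() -> RearingDataset:
    """Four individuals at two temperatures with egg + first instar records."""
    rows = []
    for t, ids in ((15.0, ["a", "b", "c", "d"]), (25.0, ["e", "f", "g", "h"])):
        for k, ind in enumerate(ids):
            rows.append((ind, f"U{t:g}", t, "E", 8.0 + k))
            rows.append((ind, f"U{t:g}", t, "L1", 5.0 + k))
    return RearingDataset(make_frame(rows))


@pytest.fixture(scope="session")
def structured_dataset():
    """Synthetic rearing data with strong slow/fast structure (40/40/20)."""
    truth = default_truth(n_per_temp=40, composition=(0.4, 0.4), seed=7)
    return truth, generate_rearing_dataset(truth)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
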