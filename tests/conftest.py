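import numpy as np
import pandas as pd
import pytest

from eegdecode.epochs import EpochSet
from eegdecode.montage import Montage


@pytest.fixture
def tiny_montage() -> Montage:
    """Six-channel montage for fast model/preprocessing tests."""
    return Montage(
        channel_labels=("Fz", "Cz", "Pz", "Oz", "O1", "O2"),
        region_groups={"posterior": ("Oz", "O1", "O2"), "frontal": ("Fz",)},
    )


def make_epochs(data: np.ndarray, montage: Montage, sampling_rate: float = 250.0,
                time_zero_index: int = 0, subjects=None, **meta_cols) -> EpochSet:
    n = data.shape[0]
    meta = {
        "participant_id": subjects if subjects is not None else np.zeros(n, dtype=int),
        "block": np.ones(n, dtype=int),
        "task": ["scene_memory"] * n,
        "trial_index": np.arange(n),
    }
    meta.update(meta_cols)
    return EpochSet(data, sampling_rate, time_zero_index, pd.DataFrame(meta), montage)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
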