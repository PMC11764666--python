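import numpy as np
import pytest

from sleepops.ordinal_core import OrdinalConfig
from sleepops.sleep_io import LabeledEpoch


@pytest.fixture(scope="session")
def default_config() -> OrdinalConfig:
    return OrdinalConfig()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_epoch(stage: str, start: int, samples=None, subject="s1", origin="original"):
    """Tiny labeled epoch helper (8 samples unless given)."""
    if samples is None:
        samples = np.arange(8, dtype=float)
    return LabeledEpoch(
        samples=samples, stage=stage, subject_id=subject, start_sample=start, origin=origin
    )


@pytest.fixture()
def label_sequence():
    """Factory: list of epochs with given stages at consecutive 3000-sample starts."""

    def _make(stages, subject="s1"):
        return [make_epoch(s, i * 3000, subject=subject) for i, s in enumerate(stages)]

    return _make
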